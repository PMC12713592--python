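"""Alignment-quality metrics: migration, AMI label transfer, cosine
similarity of projected shared features, Moran's I, PAS, AUROC/AUPRC.

All metrics are pure functions of their inputs.  Migration follows the
spatial-transcriptomics convention: barycentric-project the target
coordinates through the coupling onto every source point and report the
mean displacement as a percentage of the maximal pairwise extent of the
target slide, after a coupling-weighted rigid registration (default) or in
a common coordinate frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.metrics import (adjusted_mutual_info_score, average_precision_score,
                             roc_auc_score)
from sklearn.neighbors import NearestNeighbors

from .transport import Coupling, barycentric_project, transfer_labels, _plan

__all__ = [
    "EvalReport",
    "migration",
    "ami_transfer",
    "cosine_shared",
    "morans_i",
    "pas_score",
    "auroc_auprc",
    "weighted_rigid_registration",
]


@dataclass
class EvalReport:
    migration_pct: Optional[float] = None
    ami: Optional[float] = None
    cosine_mean: Optional[float] = None
    cosine_median: Optional[float] = None
    morans_i: Optional[np.ndarray] = None
    pas: Optional[float] = None
    auroc: Optional[float] = None
    auprc: Optional[float] = None


def _max_extent(coords: np.ndarray) -> float:
    n = coords.shape[0]
    if n <= 4000:
        return float(pdist(coords).max()) if n > 1 else 0.0
    # hull points suffice for the diameter
    from scipy.spatial import ConvexHull

    hull = coords[ConvexHull(coords).vertices]
    return float(pdist(hull).max())


def weighted_rigid_registration(src: np.ndarray, dst: np.ndarray,
                                w: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimizing sum_i w_i |R s_i + t - d_i|^2
    (Kabsch with weights; proper rotation, no reflection)."""
    w = w / w.sum()
    ms = (w[:, None] * src).sum(axis=0)
    md = (w[:, None] * dst).sum(axis=0)
    H = (src - ms).T @ (w[:, None] * (dst - md))
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    S = np.eye(H.shape[0])
    S[-1, -1] = d
    R = Vt.T @ S @ U.T
    t = md - R @ ms
    return R, t


def migration(P, coords_src: np.ndarray, coords_tgt: np.ndarray,
              register: str = "procrustes") -> float:
    """Mean displacement of a source point mapped into the target frame,
    as a percentage of the target slide's maximal pairwise extent.

    ``procrustes``: a coupling-weighted rigid registration of the source
    onto the projected positions is applied first, so a global rigid offset
    between the frames costs nothing.  ``common_frame``: both slices are
    placed in the target's frame (target mean/extent applied to both) and
    raw displacements are measured.
    """
    P = _plan(P)
    coords_src = np.asarray(coords_src, float)
    coords_tgt = np.asarray(coords_tgt, float)
    r = P.sum(axis=1)
    ok = r > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} zero-mass coupling rows excluded "
                      "from migration")
    proj = np.empty_like(coords_src)
    proj[ok] = (P[ok] @ coords_tgt) / r[ok, None]
    extent = _max_extent(coords_tgt)
    if extent == 0:
        raise ValueError("target slide has zero extent")

    if register == "procrustes":
        R, t = weighted_rigid_registration(coords_src[ok], proj[ok], r[ok])
        disp = np.linalg.norm(coords_src[ok] @ R.T + t - proj[ok], axis=1)
    elif register == "common_frame":
        mu = coords_tgt.mean(axis=0)
        disp = np.linalg.norm((coords_src[ok] - mu) - (proj[ok] - mu), axis=1)
    else:
        raise ValueError("register must be procrustes|common_frame")
    wmean = float((r[ok] * disp).sum() / r[ok].sum())
    return 100.0 * wmean / extent


def ami_transfer(P, labels_src: np.ndarray, labels_tgt: np.ndarray) -> float:
    """AMI between hard-transferred target labels and true source labels.

    Uses threshold 0 so every source point receives its argmax label; the
    adjustment is the expected-MI correction under the permutation model.
    """
    labels_src = np.asarray(labels_src)
    if np.unique(labels_src).size < 2:
        warnings.warn("single-class ground truth; AMI is 0 by definition")
        return 0.0
    lt = transfer_labels(P, labels_tgt, threshold=0.0)
    pred = lt.calls.astype(str)
    return float(adjusted_mutual_info_score(labels_src.astype(str), pred))


def cosine_shared(P, X_src: np.ndarray, Z_tgt: np.ndarray
                  ) -> Tuple[float, float]:
    """Per-point cosine similarity between source shared-feature vectors and
    the barycentric projection of the target's shared features.

    Returns (mean, median) over points where both vectors have nonzero norm
    and the projection is defined; the skipped count is warned.
    """
    X_src = np.asarray(X_src, float)
    Z_tgt = np.asarray(Z_tgt, float)
    if X_src.shape[1] == 0 or X_src.shape[1] != Z_tgt.shape[1]:
        raise ValueError("source and target must share aligned feature columns")
    proj = barycentric_project(P, Z_tgt)
    nx = np.linalg.norm(X_src, axis=1)
    npj = np.linalg.norm(proj, axis=1)
    ok = (nx > 0) & (npj > 0) & np.isfinite(npj)
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} points skipped in cosine (zero norm or "
                      "undefined projection)")
    if not ok.any():
        raise ValueError("no points with defined cosine similarity")
    cos = np.sum(X_src[ok] * proj[ok], axis=1) / (nx[ok] * npj[ok])
    return float(cos.mean()), float(np.median(cos))


def _knn_weight_matrix(coords: np.ndarray, k_neighbors: int) -> np.ndarray:
    n = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    W = np.zeros((n, n))
    W[np.repeat(np.arange(n), k_neighbors), idx[:, 1:].ravel()] = 1.0
    return W


def morans_i(values: np.ndarray, coords: np.ndarray,
             k_neighbors: int = 8,
             weights: Optional[np.ndarray] = None) -> float:
    """Moran's I with row-normalized k-NN weights (or a given W matrix).

    I = (n / sum W) * sum_ij w_ij (v_i - vbar)(v_j - vbar) / sum_i (v_i - vbar)^2.
    Constant input is undefined: returns NaN with a warning.
    """
    v = np.asarray(values, float)
    z = v - v.mean()
    denom = float(np.sum(z ** 2))
    if denom == 0:
        warnings.warn("Moran's I undefined for constant values")
        return float("nan")
    W = _knn_weight_matrix(np.asarray(coords, float), k_neighbors) \
        if weights is None else np.asarray(weights, float)
    rs = W.sum(axis=1)
    Wn = W / np.where(rs == 0, 1.0, rs)[:, None]
    n = v.size
    num = float(z @ Wn @ z)
    return (n / float(Wn.sum())) * num / denom


def pas_score(clusters: np.ndarray, coords: np.ndarray, k_neighbors: int = 8,
              threshold: float = 0.5) -> float:
    """Proportion of abnormal spots: fraction whose k nearest neighbors
    disagree with its cluster label more often than ``threshold``.
    Lower is better (spatially smoother domains)."""
    clusters = np.asarray(clusters)
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    neigh = clusters[idx[:, 1:]]
    frac_diff = (neigh != clusters[:, None]).mean(axis=1)
    return float((frac_diff > threshold).mean())


def auroc_auprc(scores: np.ndarray, labels: np.ndarray) -> Tuple[float, float]:
    """Rank-based AUROC (midrank ties) and step-wise AUPRC."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, float)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    return (float(roc_auc_score(labels, scores)),
            float(average_precision_score(labels, scores)))
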