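"""Feature normalization and CCA-based selection of alignment-informative features.

Distinct modalities can carry "marginal" feature subspaces with no joint
structure across slices.  Fitting the metric on such features injects noise
into the geometry, so an optional pre-processing step pairs samples across
the two slices by spatial nearest neighbor (in per-slice normalized
coordinates — the only pairing information available before alignment),
fits a ridge-regularized CCA on the paired feature matrices, and keeps the
features with substantial loadings on the top canonical components.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import scipy.linalg
from sklearn.neighbors import NearestNeighbors

from .datamodel import SpatialDataset

__all__ = ["FeatureFilterResult", "preprocess", "cca_filter", "regularized_cca"]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def preprocess(ds: SpatialDataset, mode: str = "none", *,
               target_sum: Optional[float] = None) -> SpatialDataset:
    """Normalize the feature matrix.

    ``library_log1p``
        Scale each row (spot) to a common total — ``target_sum`` or, when
        None, the median row total — then apply log1p.  Counts must be
        nonnegative; all-zero rows are left at zero with a warning.
    ``zscore``
        Per-feature standardization.  Note this is a *per-feature* scaling,
        which voids the global feature-isometry invariance guarantee; it is
        an explicit opt-in.
    ``none``
        Identity.
    """
    if mode == "none":
        return ds
    X = ds.features
    if mode == "library_log1p":
        if (X < 0).any():
            raise ValueError("library_log1p requires nonnegative counts")
        totals = X.sum(axis=1)
        zero = totals == 0
        if zero.any():
            warnings.warn(f"{zero.sum()} all-zero rows left unscaled")
        tgt = float(np.median(totals[~zero])) if target_sum is None else float(target_sum)
        scale = np.ones_like(totals)
        scale[~zero] = tgt / totals[~zero]
        return dataclasses.replace(ds, features=np.log1p(X * scale[:, None]))
    if mode == "zscore":
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return dataclasses.replace(ds, features=(X - mu) / sd)
    raise ValueError(f"unknown preprocessing mode '{mode}'")


# ---------------------------------------------------------------------------
# CCA filter
# ---------------------------------------------------------------------------

@dataclass
class FeatureFilterResult:
    selected_M: np.ndarray          # indices into slice-A features
    selected_N: np.ndarray
    correlations: np.ndarray        # canonical correlations, non-increasing
    loadings_M: np.ndarray          # (dA, n_components) correlation-weighted
    loadings_N: np.ndarray          # structure loadings used for selection


def regularized_cca(X: np.ndarray, Y: np.ndarray, n_components: int,
                    ridge: float = 1e-3):
    """Classic CCA with a ridge on both covariance blocks.

    Returns (correlations, Wx, Wy) with correlations clipped to [0, 1] and
    sorted non-increasing; Wx, Wy are the canonical weight matrices.
    """
    n = X.shape[0]
    if n < n_components + 2:
        raise ValueError(
            f"need at least n_components + 2 = {n_components + 2} paired "
            f"samples; got {n}"
        )
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    if (Xc.std(axis=0) == 0).any() or (Yc.std(axis=0) == 0).any():
        warnings.warn("constant feature(s) present; relying on ridge "
                      "regularization of the covariance blocks")
    Cxx = Xc.T @ Xc / n + ridge * np.eye(X.shape[1])
    Cyy = Yc.T @ Yc / n + ridge * np.eye(Y.shape[1])
    Cxy = Xc.T @ Yc / n
    # whiten via inverse square roots (symmetric, PD by the ridge)
    Wxx = scipy.linalg.fractional_matrix_power(Cxx, -0.5).real
    Wyy = scipy.linalg.fractional_matrix_power(Cyy, -0.5).real
    U, svals, Vt = np.linalg.svd(Wxx @ Cxy @ Wyy)
    r = min(n_components, svals.size)
    corr = np.clip(svals[:r], 0.0, 1.0)
    Wx = Wxx @ U[:, :r]
    Wy = Wyy @ Vt.T[:, :r]
    return corr, Wx, Wy


def _normalize_coords(c: np.ndarray) -> np.ndarray:
    c = c - c.mean(axis=0)
    extent = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1)).max() \
        if c.shape[0] <= 2000 else 2.0 * np.abs(c).max()
    return c / (extent if extent > 0 else 1.0)


def _spatial_pairing(dsA: SpatialDataset, dsB: SpatialDataset) -> np.ndarray:
    """Pair every A point with its spatial nearest neighbor in B, both in
    per-slice normalized coordinates."""
    ca = _normalize_coords(dsA.coords)
    cb = _normalize_coords(dsB.coords)
    nn = NearestNeighbors(n_neighbors=1).fit(cb)
    _, idx = nn.kneighbors(ca)
    return np.column_stack([np.arange(dsA.n), idx[:, 0]])


def cca_filter(dsA: SpatialDataset, dsB: SpatialDataset,
               pairing: str = "spatial_nn",
               pairs: Optional[np.ndarray] = None,
               n_components: Optional[int] = None,
               loading_threshold: float = 0.3,
               ridge: float = 1e-3) -> FeatureFilterResult:
    """Select the feature subsets with joint structure across the slices.

    A feature is kept when its maximum absolute canonical weight across the
    top components exceeds ``loading_threshold`` times the per-modality
    maximum absolute weight.
    """
    if n_components is None:
        n_components = min(10, dsA.d, dsB.d)
    if pairing == "given":
        if pairs is None:
            raise ValueError("pairing='given' requires pairs")
        pairs = np.asarray(pairs, dtype=int)
    elif pairing == "spatial_nn":
        pairs = _spatial_pairing(dsA, dsB)
    else:
        raise ValueError(f"unknown pairing '{pairing}'")

    X = dsA.features[pairs[:, 0]]
    Y = dsB.features[pairs[:, 1]]
    corr, Wx, Wy = regularized_cca(X, Y, n_components, ridge)

    def structure_loadings(M: np.ndarray, W: np.ndarray) -> np.ndarray:
        """|corr(feature, canonical variate)| scaled by the canonical
        correlation, so near-null components cannot dominate selection."""
        Mc = M - M.mean(axis=0)
        T = Mc @ W                                   # canonical variates
        sf = Mc.std(axis=0)
        st = T.std(axis=0)
        sf = np.where(sf == 0, np.inf, sf)
        st = np.where(st == 0, np.inf, st)
        C = (Mc.T @ T) / M.shape[0] / np.outer(sf, st)
        return np.abs(C) * corr[None, :]

    Lx = structure_loadings(X, Wx)
    Ly = structure_loadings(Y, Wy)

    def select(L: np.ndarray) -> np.ndarray:
        mag = L.max(axis=1)
        if mag.max() == 0:
            return np.arange(L.shape[0])
        return np.nonzero(mag >= loading_threshold * mag.max())[0]

    return FeatureFilterResult(select(Lx), select(Ly), corr, Lx, Ly)
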