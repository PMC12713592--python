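"""Domain types, configuration, and file I/O for spatial-omics slices.

A slice is a set of spot/cell coordinates in 2D or 3D together with a
feature matrix (gene expression, metabolite intensities, ...).  Readers
accept h5ad (coordinates in ``obsm["spatial"]``), a CSV/TSV coordinate +
CSV feature pair, or MatrixMarket features with a coordinate CSV.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

__all__ = [
    "SpatialDataset",
    "FieldConfig",
    "GraphConfig",
    "GwConfig",
    "CcaConfig",
    "FeaturesConfig",
    "MgwConfig",
    "AlignmentResult",
    "read_dataset",
    "write_result",
    "read_coupling",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SpatialDataset:
    """One spatial slice: ``n`` points with ``k``-dim coordinates and ``d`` features.

    Parameters
    ----------
    coords
        ``(n, k)`` real array, ``k`` in {2, 3}.  Physical units or normalized.
    features
        ``(n, d)`` real array (counts or continuous intensities).
    feature_names
        Length-``d`` names; generated as ``f0..f{d-1}`` when omitted.
    labels
        Optional length-``n`` categorical annotation (cell types, clusters).
    name
        Free-form slice identifier used in logs and manifests.
    """

    coords: np.ndarray
    features: np.ndarray
    feature_names: Optional[Sequence[str]] = None
    labels: Optional[np.ndarray] = None
    name: str = "slice"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.features = np.asarray(self.features, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError(
                f"coords must be (n, k) with k in {{2,3}}; got {self.coords.shape}"
            )
        if self.features.ndim != 2:
            raise ValueError(f"features must be 2-D; got {self.features.shape}")
        if self.coords.shape[0] != self.features.shape[0]:
            raise ValueError(
                f"coords has {self.coords.shape[0]} rows but features has "
                f"{self.features.shape[0]}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("dataset must contain at least one point")
        for arr, what in ((self.coords, "coords"), (self.features, "features")):
            bad = ~np.isfinite(arr)
            if bad.any():
                rows = np.unique(np.nonzero(bad)[0])[:20]
                raise ValueError(
                    f"non-finite entries in {what} at rows {rows.tolist()}"
                )
        if self.feature_names is None:
            self.feature_names = [f"f{i}" for i in range(self.features.shape[1])]
        self.feature_names = list(map(str, self.feature_names))
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length does not match feature count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.coords.shape[0]:
                raise ValueError("labels length does not match number of points")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def check_unique_coords(self, tol: float = 0.0, jitter: bool = False,
                            rng: Optional[np.random.Generator] = None):
        """Warn on duplicate coordinate rows (within ``tol``); jitter on request."""
        ds = self
        order = np.lexsort(ds.coords.T)
        c = ds.coords[order]
        dup = np.all(np.abs(np.diff(c, axis=0)) <= tol, axis=1)
        if dup.any():
            warnings.warn(
                f"{dup.sum()} duplicate coordinate rows (tol={tol}) in '{ds.name}'"
            )
            if jitter:
                rng = rng or np.random.default_rng(0)
                scale = max(tol, 1e-9 * float(np.ptp(ds.coords)))
                coords = ds.coords + rng.normal(0.0, scale, ds.coords.shape)
                ds = dataclasses.replace(ds, coords=coords)
        return ds

    def subset_features(self, idx: Sequence[int]) -> "SpatialDataset":
        idx = np.asarray(idx, dtype=int)
        return dataclasses.replace(
            self,
            features=self.features[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
        )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class FieldConfig:
    hidden_layers: int = 3
    hidden_width: int = 128
    epochs: int = 600
    learning_rate: float = 1e-2
    weight_decay: float = 1e-3  # decoupled L2 on weights (not biases)
    seed: int = 0
    coord_normalization: str = "unit_extent"  # or "none"
    patience: int = 200         # epochs without improvement before early stop
    min_delta: float = 1e-9     # improvement threshold for the plateau check

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.coord_normalization not in ("unit_extent", "none"):
            raise ValueError("coord_normalization must be unit_extent|none")


@dataclass
class GraphConfig:
    k: int = 10
    connect_components: bool = True
    metric_epsilon: float = 0.0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("graph k must be >= 1")
        if self.metric_epsilon < 0:
            raise ValueError("metric_epsilon must be >= 0")


@dataclass
class GwConfig:
    solver: str = "conditional_gradient"  # or "entropic"
    epsilon: float = 1e-2                 # entropic regularization strength
    max_iter: int = 1000
    tol: float = 1e-9
    marginals: str = "uniform"            # or "given"
    squared_distances: bool = True        # cost matrices are d**2 (the printed objective)
    init: str = "auto"                    # auto: best of product + annealed starts

    def __post_init__(self):
        if self.solver not in ("conditional_gradient", "entropic"):
            raise ValueError("solver must be conditional_gradient|entropic")
        if self.init not in ("auto", "product"):
            raise ValueError("init must be auto|product")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class CcaConfig:
    enabled: bool = False
    n_components: int = 10
    loading_threshold: float = 0.3


@dataclass
class FeaturesConfig:
    normalize: str = "none"  # library_log1p | zscore | none
    cca: CcaConfig = dc_field(default_factory=CcaConfig)

    def __post_init__(self):
        if self.normalize not in ("library_log1p", "zscore", "none"):
            raise ValueError("normalize must be library_log1p|zscore|none")


@dataclass
class MgwConfig:
    """Full pipeline configuration; every source of randomness flows from ``seed``."""

    field: FieldConfig = dc_field(default_factory=FieldConfig)
    graph: GraphConfig = dc_field(default_factory=GraphConfig)
    gw: GwConfig = dc_field(default_factory=GwConfig)
    features: FeaturesConfig = dc_field(default_factory=FeaturesConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "MgwConfig":
        d = dict(d)
        kw = {}
        if "field" in d:
            kw["field"] = FieldConfig(**d.pop("field"))
        if "graph" in d:
            kw["graph"] = GraphConfig(**d.pop("graph"))
        if "gw" in d:
            kw["gw"] = GwConfig(**d.pop("gw"))
        if "features" in d:
            f = dict(d.pop("features"))
            if "cca" in f:
                f["cca"] = CcaConfig(**f["cca"])
            kw["features"] = FeaturesConfig(**f)
        kw.update(d)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "MgwConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AlignmentResult:
    """Output of one alignment: the coupling plus everything needed to reproduce it."""

    coupling: "object"              # transport.Coupling
    dM: np.ndarray                  # (n, n) geodesic distances, slice A
    dN: np.ndarray                  # (m, m) geodesic distances, slice B
    objective: float
    provenance: dict = dc_field(default_factory=dict)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_COORD_COLS = ("x", "y", "z")


def _coords_from_frame(df: pd.DataFrame, path) -> np.ndarray:
    cols = [c for c in _COORD_COLS if c in df.columns]
    if len(cols) < 2:
        raise ValueError(
            f"{path}: expected coordinate columns x,y[,z]; found {list(df.columns)}"
        )
    return df[cols].to_numpy(dtype=float)


def read_dataset(path, format: str = None, *, features_path=None,
                 label_column: Optional[str] = None, name: Optional[str] = None
                 ) -> SpatialDataset:
    """Read one slice from disk.

    Parameters
    ----------
    path
        For ``h5ad``: the .h5ad file.  For ``csv_pair``/``mtx``: the coordinate
        CSV/TSV (columns ``x,y[,z]``, optional label column).
    format
        ``h5ad`` | ``csv_pair`` | ``mtx``; inferred from the suffix when None.
    features_path
        Feature CSV (``csv_pair``) or MatrixMarket file (``mtx``).
    label_column
        Name of a categorical column (``obs`` column for h5ad, coordinate-file
        column otherwise) to attach as labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "h5ad" if path.suffix == ".h5ad" else "csv_pair"
    name = name or path.stem

    if format == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        if "spatial" not in adata.obsm:
            raise ValueError(
                f"{path}: no coordinates found in obsm['spatial'] "
                "(the expected spatial slot)"
            )
        coords = np.asarray(adata.obsm["spatial"], dtype=float)
        X = adata.X
        if sp.issparse(X):
            X = X.toarray()
        features = np.asarray(X, dtype=float)
        labels = None
        if label_column is not None:
            if label_column not in adata.obs:
                raise ValueError(f"{path}: obs has no column '{label_column}'")
            labels = adata.obs[label_column].to_numpy()
        return SpatialDataset(coords, features, list(adata.var_names), labels, name)

    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    cdf = pd.read_csv(path, sep=sep, float_precision="round_trip")
    coords = _coords_from_frame(cdf, path)
    labels = None
    if label_column is not None:
        if label_column not in cdf.columns:
            raise ValueError(f"{path}: no column '{label_column}'")
        labels = cdf[label_column].to_numpy()

    if features_path is None:
        raise ValueError("csv_pair/mtx formats require features_path")
    features_path = Path(features_path)
    if not features_path.exists():
        raise FileNotFoundError(features_path)

    if format == "csv_pair":
        fdf = pd.read_csv(features_path, float_precision="round_trip")
        features = fdf.to_numpy(dtype=float)
        fnames = list(fdf.columns)
    elif format == "mtx":
        features = np.asarray(scipy.io.mmread(features_path).todense() if
                              sp.issparse(scipy.io.mmread(features_path)) else
                              scipy.io.mmread(features_path), dtype=float)
        fnames = None
    else:
        raise ValueError(f"unknown format '{format}'")

    if features.shape[0] != coords.shape[0]:
        raise ValueError(
            f"row count mismatch: {coords.shape[0]} coordinates vs "
            f"{features.shape[0]} feature rows"
        )
    return SpatialDataset(coords, features, fnames, labels, name)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_result(result: AlignmentResult, out_dir, *, overwrite: bool = False,
                 save_distances: bool = True) -> dict:
    """Write an alignment to ``out_dir``; returns the manifest dict.

    The coupling is stored losslessly (NPZ, float64) and round-trips
    bit-exactly through :func:`read_coupling`.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is non-empty; pass overwrite=True")
    out_dir.mkdir(parents=True, exist_ok=True)

    P = np.asarray(result.coupling.P, dtype=float)
    np.savez(out_dir / "coupling.npz", P=P,
             a=result.coupling.marginals.a, b=result.coupling.marginals.b)
    files = {"coupling": "coupling.npz"}
    if save_distances:
        np.savez(out_dir / "distances.npz", dM=result.dM, dN=result.dN)
        files["distances"] = "distances.npz"

    manifest = {
        "objective": float(result.objective),
        "shape": list(P.shape),
        "files": files,
        "provenance": result.provenance,
        "diagnostics": {
            "iterations": int(result.coupling.iterations),
            "converged": bool(result.coupling.converged),
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def read_coupling(out_dir) -> np.ndarray:
    """Re-read the coupling matrix written by :func:`write_result`."""
    with np.load(Path(out_dir) / "coupling.npz") as z:
        return z["P"]
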