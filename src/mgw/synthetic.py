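"""Paired synthetic spatial slices with known ground-truth correspondence.

Both slices share a smooth low-dimensional latent field z(s) over the same
coordinates; each modality observes its own smooth nonlinear map of that
latent plus additive Gaussian noise and, optionally, nuisance features that
are independent of the latent.  Because the latent and the modality maps are
sums of Gaussians / affine-tanh compositions, the true space-modality
Jacobian has a closed form, exposed through :class:`OracleField` for tests
that must avoid network-training stochasticity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datamodel import SpatialDataset

__all__ = [
    "SyntheticSpec",
    "make_pair",
    "oracle_fields",
    "apply_rigid",
    "apply_feature_isometry",
    "OracleField",
    "default_preset",
]


# ---------------------------------------------------------------------------
# Latent fields (closed-form z(s) and dz/ds)
# ---------------------------------------------------------------------------

class _GaussianBumps:
    """z_l(s) = sum_r A_lr exp(-|s-c_r|^2 / (2 sig_r^2)).

    Bump count and widths are chosen to give the latent structure at several
    spatial scales, the way tissue has domains and gradients of different
    sizes.  A very smooth latent (few broad bumps) yields nearly flat
    pull-back geometries whose alignment is ambiguous up to rotation, so a
    correspondence-recovery study on it would be ill-posed.
    """

    def __init__(self, latent_dim: int, k: int, rng: np.random.Generator,
                 n_bumps: int = 16):
        self.centers = rng.uniform(0.0, 1.0, (n_bumps, k))
        self.sigma = rng.uniform(0.08, 0.25, n_bumps)
        self.amp = rng.normal(0.0, 1.0, (latent_dim, n_bumps))

    def _basis(self, s: np.ndarray) -> np.ndarray:
        diff = s[:, None, :] - self.centers[None, :, :]      # (m, R, k)
        q = np.sum(diff ** 2, axis=2) / (2.0 * self.sigma ** 2)
        return np.exp(-q), diff

    def __call__(self, s: np.ndarray) -> np.ndarray:
        e, _ = self._basis(s)
        return e @ self.amp.T                                # (m, L)

    def jacobian(self, s: np.ndarray) -> np.ndarray:
        e, diff = self._basis(s)
        # d/ds of exp term: -(s - c_r)/sig^2 * e
        grad = -(diff / self.sigma[None, :, None] ** 2) * e[:, :, None]  # (m,R,k)
        return np.einsum("lr,mrk->mlk", self.amp, grad)      # (m, L, k)


class _Sinusoid:
    """z_l(s) = sum_r A_lr sin(w_r . s + phi_r)."""

    def __init__(self, latent_dim: int, k: int, rng: np.random.Generator,
                 n_waves: int = 6):
        self.freq = rng.uniform(1.0, 4.0, (n_waves, k)) * np.pi
        self.phase = rng.uniform(0.0, 2 * np.pi, n_waves)
        self.amp = rng.normal(0.0, 1.0, (latent_dim, n_waves)) / np.sqrt(n_waves)

    def __call__(self, s: np.ndarray) -> np.ndarray:
        arg = s @ self.freq.T + self.phase                   # (m, R)
        return np.sin(arg) @ self.amp.T

    def jacobian(self, s: np.ndarray) -> np.ndarray:
        arg = s @ self.freq.T + self.phase
        d = np.cos(arg)[:, :, None] * self.freq[None, :, :]  # (m, R, k)
        return np.einsum("lr,mrk->mlk", self.amp, d)


class _Linear:
    def __init__(self, latent_dim: int, k: int, rng: np.random.Generator):
        self.B = rng.normal(0.0, 1.0, (latent_dim, k))

    def __call__(self, s: np.ndarray) -> np.ndarray:
        return s @ self.B.T

    def jacobian(self, s: np.ndarray) -> np.ndarray:
        return np.broadcast_to(self.B, (s.shape[0],) + self.B.shape).copy()


_LATENTS = {"gaussian_bumps": _GaussianBumps, "sinusoid": _Sinusoid,
            "linear": _Linear}


# ---------------------------------------------------------------------------
# Modality maps (latent -> features): affine + pointwise tanh + affine
# ---------------------------------------------------------------------------

class SmoothMap:
    """Smooth embedding latent -> features: f(z) = A z + a W2 tanh(W1 z + c1) + c2.

    The affine core A has orthonormal columns, so the map is an immersion
    (full-rank Jacobian everywhere) perturbed by a mild pointwise
    nonlinearity — the setting the pull-back construction assumes, where
    each modality is a smooth local parametrization of a feature-space
    submanifold.  A saturating map with rank-deficient Jacobians would
    break that assumption and make the two modality geometries genuinely
    incomparable.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 hidden: int = 16, alpha: float = 0.4):
        A = rng.normal(0.0, 1.0, (d_out, d_in))
        U, _, Vt = np.linalg.svd(A, full_matrices=False)
        self.A = U @ Vt                                      # orthonormal columns
        self.W1 = rng.normal(0.0, 0.8 / np.sqrt(d_in), (hidden, d_in))
        self.c1 = rng.normal(0.0, 0.3, hidden)
        self.W2 = rng.normal(0.0, 1.0 / np.sqrt(hidden), (d_out, hidden))
        self.c2 = rng.normal(0.0, 0.2, d_out)
        self.alpha = alpha

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return (z @ self.A.T
                + self.alpha * np.tanh(z @ self.W1.T + self.c1) @ self.W2.T
                + self.c2)

    def jacobian(self, z: np.ndarray) -> np.ndarray:
        h = np.tanh(z @ self.W1.T + self.c1)                 # (m, H)
        dh = 1.0 - h ** 2
        J = self.alpha * np.einsum("oh,mh,hi->moi", self.W2, dh, self.W1)
        return J + self.A[None, :, :]


class IdentityMap:
    def __call__(self, z: np.ndarray) -> np.ndarray:
        return z

    def jacobian(self, z: np.ndarray) -> np.ndarray:
        d = z.shape[1]
        return np.broadcast_to(np.eye(d), (z.shape[0], d, d)).copy()


# ---------------------------------------------------------------------------
# Spec and generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Recipe for one paired-slice simulation; fully deterministic given ``seed``."""

    n_points: int = 1024
    grid: str = "regular"                 # regular | uniform_random
    latent_fn: str = "gaussian_bumps"     # gaussian_bumps | sinusoid | linear
    latent_dim: int = 2
    map_M: str = "random"                 # random | identity
    map_N: str = "random"
    noise_sd: float = 0.05
    n_shared_features: int = 10
    n_independent_features: int = 5
    n_label_clusters: int = 0             # >0: attach labels from latent k-means
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim <= 0:
            raise ValueError("latent_dim must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.latent_fn not in _LATENTS:
            raise ValueError(f"unknown latent_fn '{self.latent_fn}'")
        if self.grid not in ("regular", "uniform_random"):
            raise ValueError(f"unknown grid '{self.grid}'")


def default_preset(seed: int = 0, **overrides) -> SyntheticSpec:
    """The package's standard small study: 32x32 grid, 2-D latent,
    10 shared + 5 independent features per modality, noise sd 0.05."""
    return SyntheticSpec(seed=seed, **overrides)


def _coords(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.grid == "regular":
        side = int(round(np.sqrt(spec.n_points)))
        ax = np.linspace(0.0, 1.0, side)
        xx, yy = np.meshgrid(ax, ax, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()])
    return rng.uniform(0.0, 1.0, (spec.n_points, 2))


def _build(spec: SyntheticSpec):
    """Deterministic construction of coords, latent, maps and noise streams."""
    root = np.random.SeedSequence(spec.seed)
    s_coord, s_latent, s_mapM, s_mapN, s_noise, s_lab = root.spawn(6)
    coords = _coords(spec, np.random.default_rng(s_coord))
    latent = _LATENTS[spec.latent_fn](spec.latent_dim, coords.shape[1],
                                      np.random.default_rng(s_latent))

    def mk_map(kind, seq):
        if kind == "identity":
            return IdentityMap()
        return SmoothMap(spec.latent_dim, spec.n_shared_features,
                         np.random.default_rng(seq))

    map_M = mk_map(spec.map_M, s_mapM)
    map_N = mk_map(spec.map_N, s_mapN)
    return coords, latent, map_M, map_N, s_noise, s_lab


def make_pair(spec: SyntheticSpec):
    """Generate two slices over the same coordinates.

    Returns ``(ds_M, ds_N, ground_truth)`` where ``ground_truth`` is the
    identity permutation (correspondence is by index).  Shared feature
    columns come first, followed by ``n_independent_features`` nuisance
    columns of pure Gaussian noise (unit sd), independent of the latent.
    """
    coords, latent, map_M, map_N, s_noise, s_lab = _build(spec)
    n = coords.shape[0]
    z = latent(coords)
    rng = np.random.default_rng(s_noise)

    def slice_features(mod_map):
        shared = mod_map(z)
        shared = shared + rng.normal(0.0, spec.noise_sd, shared.shape)
        indep = rng.normal(0.0, 1.0, (n, spec.n_independent_features))
        return np.hstack([shared, indep]) if spec.n_independent_features else shared

    X = slice_features(map_M)
    Z = slice_features(map_N)

    labels = None
    if spec.n_label_clusters > 0:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=spec.n_label_clusters, n_init=4,
                    random_state=np.random.default_rng(s_lab).integers(2 ** 31))
        labels = km.fit_predict(z).astype(str)

    d_sh = X.shape[1] - spec.n_independent_features
    names = [f"shared{i}" for i in range(d_sh)] + \
            [f"indep{i}" for i in range(spec.n_independent_features)]
    ds_M = SpatialDataset(coords.copy(), X, names, labels, name="synthetic_M")
    ds_N = SpatialDataset(coords.copy(), Z, list(names), labels, name="synthetic_N")
    return ds_M, ds_N, np.arange(n)


# ---------------------------------------------------------------------------
# Oracle fields with exact Jacobians
# ---------------------------------------------------------------------------

class OracleField:
    """Closed-form field s -> map(z(s)) with exact Jacobian.

    Supports pre-composition with a rigid motion of the coordinates
    (``with_rigid``: the field of a slice whose coordinates were mapped
    s~ = Q s + b) and post-composition with a feature-space similarity
    (``with_feature_isometry``: lam * U f(s) + c).
    """

    def __init__(self, latent, mod_map):
        self.latent = latent
        self.map = mod_map
        self.Q = None
        self.b = None
        self.lam = 1.0
        self.U = None
        self.c = None

    # -- transforms -------------------------------------------------------
    def with_rigid(self, Q: np.ndarray, b: np.ndarray) -> "OracleField":
        out = self._copy()
        out.Q, out.b = np.asarray(Q, float), np.asarray(b, float)
        return out

    def with_feature_isometry(self, lam: float, U: Optional[np.ndarray] = None,
                              c: Optional[np.ndarray] = None) -> "OracleField":
        if lam == 0:
            raise ValueError("scaling must be nonzero")
        out = self._copy()
        out.lam = float(lam)
        out.U = None if U is None else np.asarray(U, float)
        out.c = None if c is None else np.asarray(c, float)
        return out

    def _copy(self) -> "OracleField":
        out = OracleField(self.latent, self.map)
        out.Q, out.b, out.lam, out.U, out.c = self.Q, self.b, self.lam, self.U, self.c
        return out

    # -- evaluation -------------------------------------------------------
    def _base_coords(self, s: np.ndarray) -> np.ndarray:
        if self.Q is None:
            return s
        return (s - self.b) @ self.Q          # Q^T (s - b), row convention

    def predict(self, s: np.ndarray) -> np.ndarray:
        f = self.map(self.latent(self._base_coords(np.asarray(s, float))))
        f = self.lam * f
        if self.U is not None:
            f = f @ self.U.T
        if self.c is not None:
            f = f + self.c
        return f

    def jacobian(self, s: np.ndarray) -> np.ndarray:
        s0 = self._base_coords(np.asarray(s, float))
        z = self.latent(s0)
        J = np.einsum("moi,mik->mok", self.map.jacobian(z),
                      self.latent.jacobian(s0))
        if self.Q is not None:
            J = J @ self.Q.T                  # chain rule for s0 = Q^T(s-b)
        J = self.lam * J
        if self.U is not None:
            J = np.einsum("ou,muk->mok", self.U, J)
        return J


def oracle_fields(spec: SyntheticSpec):
    """Closed-form fields for the *shared* feature blocks of :func:`make_pair`."""
    _, latent, map_M, map_N, _, _ = _build(spec)
    return OracleField(latent, map_M), OracleField(latent, map_N)


# ---------------------------------------------------------------------------
# Group actions on datasets
# ---------------------------------------------------------------------------

def _check_orthogonal(Q: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    Q = np.asarray(Q, float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    if not np.allclose(Q.T @ Q, np.eye(Q.shape[0]), atol=tol):
        raise ValueError("matrix is not orthogonal within tolerance")
    return Q


def apply_rigid(ds: SpatialDataset, Q: np.ndarray, b: np.ndarray) -> SpatialDataset:
    """Rigidly move the slice: coords <- Q coords + b; features untouched."""
    Q = _check_orthogonal(Q)
    b = np.asarray(b, float)
    if Q.shape[0] != ds.k or b.shape != (ds.k,):
        raise ValueError(f"Q must be {ds.k}x{ds.k} and b length {ds.k}")
    return dataclasses.replace(ds, coords=ds.coords @ Q.T + b)


def apply_feature_isometry(ds: SpatialDataset, lam: float, U: np.ndarray,
                           b: np.ndarray) -> SpatialDataset:
    """Similarity transform of feature space: rows <- lam * U x + b."""
    if lam == 0:
        raise ValueError("lam must be nonzero")
    U = _check_orthogonal(U)
    b = np.asarray(b, float)
    if U.shape[0] != ds.d or b.shape != (ds.d,):
        raise ValueError(f"U must be {ds.d}x{ds.d} and b length {ds.d}")
    return dataclasses.replace(ds, features=lam * (ds.features @ U.T) + b)
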