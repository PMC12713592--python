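"""Gromov-Wasserstein alignment on pull-back geodesic distances.

Solves

    P* = argmin_{P in Pi(a,b)}  sum_{i,i',j,j'} (dM(i,i')^2 - dN(j,j')^2)^2 P_ij P_i'j'

i.e. square-loss GW applied to the *squared* geodesic distance matrices,
which is the printed objective of the manifold pull-back problem (a flag
switches to plain distances).  Two solvers:

* ``conditional_gradient`` (default): Frank-Wolfe with exact linear-OT
  inner solves and exact line search.  For uniform marginals with n = m the
  inner problem is solved exactly by the Hungarian algorithm (the vertices
  of the Birkhoff polytope are permutations); otherwise by a sparse HiGHS
  LP.  The energy is non-convex, so by default ("auto") the solver runs
  Frank-Wolfe from two deterministic starts — the product plan a b^T and a
  coarse-to-fine entropic annealing — and returns the lower-objective
  result; within each run the objective is monotonically non-increasing.
* ``entropic``: mirror-descent iterations with a log-domain Sinkhorn inner
  loop at regularization ``epsilon``.

The reported objective is always the unregularized value at the returned P.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment, linprog
from scipy.special import logsumexp

from .datamodel import GwConfig

__all__ = [
    "Marginals",
    "Coupling",
    "LabelTransfer",
    "gw_solve",
    "gw_objective",
    "barycentric_project",
    "transfer_labels",
]


@dataclass
class Marginals:
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        for v, nm in ((self.a, "a"), (self.b, "b")):
            if v.ndim != 1 or (v < 0).any():
                raise ValueError(f"marginal {nm} must be a nonnegative vector")
            if abs(v.sum() - 1.0) > 1e-12:
                raise ValueError(f"marginal {nm} must sum to 1 (got {v.sum()!r})")

    @classmethod
    def uniform(cls, n: int, m: int) -> "Marginals":
        return cls(np.full(n, 1.0 / n), np.full(m, 1.0 / m))


@dataclass
class Coupling:
    """Transport plan with diagnostics; marginals hold within 1e-6."""

    P: np.ndarray
    marginals: Marginals
    objective: float
    iterations: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    def validate(self, tol: float = 1e-6) -> None:
        if (self.P < -1e-15).any():
            raise ValueError("coupling has negative entries")
        ra = np.abs(self.P.sum(axis=1) - self.marginals.a).max()
        rb = np.abs(self.P.sum(axis=0) - self.marginals.b).max()
        if max(ra, rb) > tol:
            raise ValueError(f"marginal violation {max(ra, rb):.2e} > {tol:.0e}")


# ---------------------------------------------------------------------------
# Objective machinery (square loss, Peyre-Cuturi factorization)
# ---------------------------------------------------------------------------

def _const_part(C1, C2, a, b):
    return np.add.outer((C1 ** 2) @ a, (C2 ** 2) @ b)


def gw_objective(C1: np.ndarray, C2: np.ndarray, P: np.ndarray,
                 a: Optional[np.ndarray] = None,
                 b: Optional[np.ndarray] = None) -> float:
    """Square-loss GW energy of P for cost matrices C1, C2 (already squared
    distances in the default pipeline)."""
    a = P.sum(axis=1) if a is None else a
    b = P.sum(axis=0) if b is None else b
    cC = _const_part(C1, C2, a, b)
    return float(np.sum((cC - 2.0 * (C1 @ P @ C2)) * P))


def _linear_ot(G: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact minimizer of <G, T> over Pi(a, b)."""
    n, m = G.shape
    uniform = (n == m and np.allclose(a, 1.0 / n, atol=1e-12)
               and np.allclose(b, 1.0 / m, atol=1e-12))
    if uniform:
        r, c = linear_sum_assignment(G)
        T = np.zeros_like(G)
        T[r, c] = 1.0 / n
        return T
    rows = sp.kron(sp.eye(n), np.ones((1, m)), format="csr")
    cols = sp.kron(np.ones((1, n)), sp.eye(m), format="csr")
    A_eq = sp.vstack([rows, cols[:-1]]).tocsc()
    b_eq = np.concatenate([a, b[:-1]])
    res = linprog(G.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None),
                  method="highs")
    if not res.success:
        raise RuntimeError(f"inner linear OT failed: {res.message}")
    return res.x.reshape(n, m)


def _sinkhorn_stab(G, a, b, eps, max_iter=200, tol=1e-9):
    """Scaling-form Sinkhorn with log-domain absorption of large potentials."""
    n, m = G.shape
    f = np.zeros(n)
    g = np.zeros(m)
    K = np.exp((f[:, None] + g[None, :] - G) / eps)
    u = np.ones(n)
    v = np.ones(m)
    with np.errstate(over="ignore", divide="ignore"):
        for it in range(max_iter):
            u = a / (K @ v)
            v = b / (K.T @ u)
            lu = np.abs(np.log(u)).max()
            lv = np.abs(np.log(v)).max()
            if not np.isfinite(lu + lv) or max(lu, lv) > 50.0:
                f += eps * np.nan_to_num(np.log(u), neginf=-1e3, posinf=1e3)
                g += eps * np.nan_to_num(np.log(v), neginf=-1e3, posinf=1e3)
                K = np.exp((f[:, None] + g[None, :] - G) / eps)
                u[:] = 1.0
                v[:] = 1.0
            elif it % 10 == 9:
                P = u[:, None] * K * v[None, :]
                if np.abs(P.sum(axis=1) - a).max() < tol:
                    break
    return u[:, None] * K * v[None, :]


def _frank_wolfe(P, C1, C2, a, b, cC, max_iter, tol):
    obj = float(np.sum((cC - 2.0 * (C1 @ P @ C2)) * P))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        G = 2.0 * (cC - 2.0 * (C1 @ P @ C2))
        T = _linear_ot(G, a, b)
        D = T - P
        gap = float(np.sum(G * D))          # <= 0 up to round-off
        c2 = -2.0 * float(np.sum((C1 @ D @ C2) * D))
        if c2 > 0.0:
            tau = min(1.0, max(0.0, -gap / (2.0 * c2)))
        else:
            tau = 1.0 if gap + c2 < 0.0 else 0.0
        new_obj = obj + tau * gap + tau * tau * c2
        if tau > 0.0:
            P = P + tau * D
        scale = max(1.0, abs(obj))
        if abs(obj - new_obj) <= tol * scale and abs(gap) <= np.sqrt(tol) * scale:
            obj = new_obj
            converged = True
            break
        obj = new_obj
    obj = float(np.sum((cC - 2.0 * (C1 @ P @ C2)) * P))
    return P, obj, it, converged


def _round_to_polytope(P, a, b):
    """Project an almost-feasible plan onto Pi(a, b) (scaling + rank-1 fix)."""
    r = P.sum(axis=1)
    P = P * np.minimum(a / np.where(r == 0, 1.0, r), 1.0)[:, None]
    c = P.sum(axis=0)
    P = P * np.minimum(b / np.where(c == 0, 1.0, c), 1.0)[None, :]
    da = a - P.sum(axis=1)
    db = b - P.sum(axis=0)
    s = da.sum()
    if s > 0:
        P = P + np.outer(da, db) / s
    return P


def _annealed_init(C1, C2, a, b, cC, levels=(0.5, 0.1, 0.02), outer=8):
    """Coarse-to-fine entropic iterations as a deterministic warm start.

    The plain product init can commit Frank-Wolfe to poor basins of the
    non-convex energy; annealing the entropic smoothing from coarse to fine
    tracks the smoothed optimum down to a sharp plan.
    """
    P = np.outer(a, b)
    scale = float(np.mean(np.abs(2.0 * (cC - 2.0 * (C1 @ P @ C2)))))
    if scale == 0.0 or not np.isfinite(scale):
        return P
    for lv in levels:
        for _ in range(outer):
            G = 2.0 * (cC - 2.0 * (C1 @ P @ C2))
            P = _sinkhorn_stab(G, a, b, lv * scale)
    # Frank-Wolfe preserves any infeasibility of its start; round it away
    return _round_to_polytope(P, a, b)


def _solve_cg(C1, C2, a, b, cfg: GwConfig):
    cC = _const_part(C1, C2, a, b)
    P1, o1, it1, cv1 = _frank_wolfe(np.outer(a, b), C1, C2, a, b, cC,
                                    cfg.max_iter, cfg.tol)
    if cfg.init == "product":
        return P1, o1, it1, cv1
    P0 = _annealed_init(C1, C2, a, b, cC)
    P2, o2, it2, cv2 = _frank_wolfe(P0, C1, C2, a, b, cC, cfg.max_iter, cfg.tol)
    # keep the better of the two deterministic starts
    if o2 < o1:
        return P2, o2, it1 + it2, cv2
    return P1, o1, it1 + it2, cv1


def _sinkhorn_log(G, a, b, eps, max_iter=5000, tol=1e-10):
    K = -G / eps
    la, lb = np.log(a), np.log(b)
    g = np.zeros_like(b)
    for _ in range(max_iter):
        f = eps * (la - logsumexp(K + g[None, :] / eps, axis=1))
        g = eps * (lb - logsumexp(K + f[:, None] / eps, axis=0))
        P = np.exp(K + f[:, None] / eps + g[None, :] / eps)
        # after the g update the column marginals are exact; the row
        # violation is the true convergence measure
        if np.abs(P.sum(axis=1) - a).max() < tol:
            break
    # finish on the row update so the row marginals are exact
    f = eps * (la - logsumexp(K + g[None, :] / eps, axis=1))
    return np.exp(K + f[:, None] / eps + g[None, :] / eps)


def _solve_entropic(C1, C2, a, b, cfg: GwConfig):
    P = np.outer(a, b)
    cC = _const_part(C1, C2, a, b)
    prev = np.inf
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        G = 2.0 * (cC - 2.0 * (C1 @ P @ C2))
        P = _sinkhorn_log(G, a, b, cfg.epsilon)
        obj = float(np.sum((cC - 2.0 * (C1 @ P @ C2)) * P))
        if abs(prev - obj) <= cfg.tol * max(1.0, abs(obj)):
            converged = True
            break
        prev = obj
    # evaluate at the plan's own (approximate) marginals: the factorized
    # energy equals the quadruple sum only with the empirical row/col sums
    obj = gw_objective(C1, C2, P)
    return P, obj, it, converged


def gw_solve(dM: np.ndarray, dN: np.ndarray, marg: Optional[Marginals] = None,
             cfg: Optional[GwConfig] = None) -> Coupling:
    """Solve the pull-back GW problem on geodesic distance matrices."""
    cfg = cfg or GwConfig()
    dM = np.asarray(dM, dtype=float)
    dN = np.asarray(dN, dtype=float)
    if dM.ndim != 2 or dM.shape[0] != dM.shape[1]:
        raise ValueError("dM must be square")
    if dN.ndim != 2 or dN.shape[0] != dN.shape[1]:
        raise ValueError("dN must be square")
    if not (np.isfinite(dM).all() and np.isfinite(dN).all()):
        raise ValueError("distance matrices must be finite")
    marg = marg or Marginals.uniform(dM.shape[0], dN.shape[0])
    if marg.a.shape[0] != dM.shape[0] or marg.b.shape[0] != dN.shape[0]:
        raise ValueError("marginal sizes do not match distance matrices")

    C1 = dM ** 2 if cfg.squared_distances else dM
    C2 = dN ** 2 if cfg.squared_distances else dN
    solver = _solve_cg if cfg.solver == "conditional_gradient" else _solve_entropic
    P, obj, it, converged = solver(C1, C2, marg.a, marg.b, cfg)
    if not converged:
        warnings.warn(f"GW solver hit max_iter={cfg.max_iter} without meeting "
                      f"tol={cfg.tol}")
    return Coupling(P, marg, obj, it, converged,
                    diagnostics={"solver": cfg.solver})


# ---------------------------------------------------------------------------
# Coupling-based transfer
# ---------------------------------------------------------------------------

def _plan(P) -> np.ndarray:
    return P.P if isinstance(P, Coupling) else np.asarray(P, dtype=float)


def barycentric_project(P, values: np.ndarray) -> np.ndarray:
    """Row-normalized coupling-weighted average of target values.

    Rows of P with zero mass produce NaN output rows (reported via warning),
    never silent zeros.
    """
    P = _plan(P)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if values.shape[0] != P.shape[1]:
        raise ValueError("values rows must match coupling columns")
    r = P.sum(axis=1)
    out = np.full((P.shape[0], values.shape[1]), np.nan)
    ok = r > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} coupling rows have zero mass; "
                      "their projections are NaN")
    out[ok] = (P[ok] @ values) / r[ok, None]
    return out


@dataclass
class LabelTransfer:
    classes: np.ndarray          # (L,) label vocabulary
    probabilities: np.ndarray    # (n, L) row label distribution
    calls: np.ndarray            # (n,) hard call or "unassigned"
    confidence: np.ndarray       # (n,) probability of the argmax label


def transfer_labels(P, target_labels: np.ndarray,
                    threshold: float = 0.5) -> LabelTransfer:
    """Per-source label distribution under the coupling and thresholded call.

    The hard call is the argmax label when its row-normalized probability
    reaches ``threshold``; otherwise "unassigned".
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    P = _plan(P)
    target_labels = np.asarray(target_labels)
    if target_labels.shape[0] != P.shape[1]:
        raise ValueError("target_labels must match coupling columns")
    classes, inv = np.unique(target_labels, return_inverse=True)
    onehot = np.zeros((P.shape[1], classes.size))
    onehot[np.arange(P.shape[1]), inv] = 1.0
    mass = P @ onehot
    rows = mass.sum(axis=1)
    prob = np.zeros_like(mass)
    ok = rows > 0
    prob[ok] = mass[ok] / rows[ok, None]
    best = np.argmax(prob, axis=1)
    conf = prob[np.arange(P.shape[0]), best]
    calls = np.where(conf >= threshold, classes.astype(object)[best], "unassigned")
    return LabelTransfer(classes, prob, calls.astype(object), conf)
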