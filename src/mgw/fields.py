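"""Smooth neural fields: coordinates -> features, with exact Jacobians.

Each slice is represented implicitly by a small MLP with SiLU activations
(infinitely differentiable, so the field has smooth Jacobians and represents
a smooth submanifold).  The field is trained by full-batch Adam on the
mean-squared loss.  Jacobians are computed by exact forward-mode
differentiation of the network function — the same chain rule reverse-mode
autodiff would evaluate, not finite differences — and are chain-rule
corrected for the stored input/output normalization so they are expressed
in the original coordinate and feature units.

Input normalization is deliberately isotropic (one scale for all spatial
axes): a per-axis scaling would distort the pull-back metric.  Feature
targets are centered per column and scaled by a single global factor; this
is a similarity transform of feature space, which the alignment objective
is provably invariant to, so it does not change the learned geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np

from .datamodel import FieldConfig, SpatialDataset

__all__ = [
    "FieldModel",
    "FunctionField",
    "IdentityField",
    "fit_field",
    "predict",
    "jacobian",
    "save_field",
    "load_field",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _silu(x: np.ndarray) -> np.ndarray:
    return x * _sigmoid(x)


def _silu_prime(x: np.ndarray) -> np.ndarray:
    s = _sigmoid(x)
    return s * (1.0 + x * (1.0 - s))


@dataclass
class FieldModel:
    """A trained field: affine input/output normalization around a SiLU MLP."""

    weights: List[np.ndarray]          # layer l: (fan_in, fan_out)
    biases: List[np.ndarray]
    in_center: np.ndarray              # (k,)
    in_scale: float                    # single isotropic factor
    out_center: np.ndarray             # (d,)
    out_scale: float
    seed: int = 0
    history: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.weights[0].shape[0]

    @property
    def d(self) -> int:
        return self.weights[-1].shape[1]

    def _forward(self, sn: np.ndarray, want_pre: bool = False):
        pres = []
        a = sn
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            u = a @ W + b
            if want_pre:
                pres.append(u)
            a = _silu(u)
        out = a @ self.weights[-1] + self.biases[-1]
        return (out, pres) if want_pre else out

    def predict(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != self.k:
            raise ValueError(f"coords must be (m, {self.k}); got {coords.shape}")
        if not np.isfinite(coords).all():
            raise ValueError("coords contain non-finite values")
        sn = (coords - self.in_center) / self.in_scale
        return self._forward(sn) * self.out_scale + self.out_center

    def jacobian(self, coords: np.ndarray) -> np.ndarray:
        """Exact (m, d, k) Jacobians in original units.

        Forward-mode: propagate the k tangent directions through every
        layer; the input normalization contributes a factor 1/in_scale and
        the output de-normalization a factor out_scale.
        """
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != self.k:
            raise ValueError(f"coords must be (m, {self.k}); got {coords.shape}")
        m, k = coords.shape
        sn = (coords - self.in_center) / self.in_scale
        # T: (m, k, width) — derivative of current activation wrt inputs
        T = np.broadcast_to(np.eye(k) / self.in_scale, (m, k, k)).copy()
        a = sn
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            u = a @ W + b                      # (m, w_out)
            T = T @ W                          # (m, k, w_out)
            T *= _silu_prime(u)[:, None, :]
            a = _silu(u)
        T = T @ self.weights[-1]               # (m, k, d)
        J = np.swapaxes(T, 1, 2) * self.out_scale
        return J


class FunctionField:
    """Wrap an analytic map and its analytic Jacobian as a field object."""

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray],
                 jac: Callable[[np.ndarray], np.ndarray]):
        self._fn, self._jac = fn, jac

    def predict(self, coords: np.ndarray) -> np.ndarray:
        return self._fn(np.asarray(coords, float))

    def jacobian(self, coords: np.ndarray) -> np.ndarray:
        return self._jac(np.asarray(coords, float))


class IdentityField:
    """phi(s) = s: the field whose pull-back metric is the identity."""

    def predict(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float).copy()

    def jacobian(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, float)
        m, k = coords.shape
        return np.broadcast_to(np.eye(k), (m, k, k)).copy()


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def fit_field(ds: SpatialDataset, cfg: Optional[FieldConfig] = None) -> FieldModel:
    """Fit the field by full-batch Adam on the mean-squared loss.

    Deterministic given ``cfg.seed``.  Raises on divergence (NaN loss) with
    advice to lower the learning rate.  The recorded ``history["mse"]`` is
    the final training MSE in original feature units, averaged per point:
    (1/n) sum_i ||phi(s_i) - X_i||^2.
    """
    cfg = cfg or FieldConfig()
    if ds.n < 3:
        raise ValueError(f"need at least 3 points to fit a field; got {ds.n}")

    rng = np.random.default_rng(cfg.seed)
    S = ds.coords
    X = ds.features

    in_center = S.mean(axis=0)
    in_scale = float(np.sqrt(np.mean((S - in_center) ** 2)))
    if in_scale == 0.0:
        in_scale = 1.0
    out_center = X.mean(axis=0)
    out_scale = float(np.sqrt(np.mean((X - out_center) ** 2)))
    if out_scale == 0.0:
        out_scale = 1.0

    Sn = (S - in_center) / in_scale
    Xn = (X - out_center) / out_scale

    sizes = [ds.k] + [cfg.hidden_width] * cfg.hidden_layers + [ds.d]
    Ws = [rng.normal(0.0, np.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1]))
          for i in range(len(sizes) - 1)]
    bs = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    mW = [np.zeros_like(W) for W in Ws]
    vW = [np.zeros_like(W) for W in Ws]
    mb = [np.zeros_like(b) for b in bs]
    vb = [np.zeros_like(b) for b in bs]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    n = ds.n
    # cosine decay to lr/100: lets Adam settle instead of orbiting the optimum
    lrs = (cfg.learning_rate * (0.01 + 0.99 * 0.5 *
           (1.0 + np.cos(np.pi * np.arange(cfg.epochs) / max(1, cfg.epochs - 1)))))

    best = np.inf
    since_best = 0
    loss = np.inf
    epochs_run = 0
    for t in range(1, cfg.epochs + 1):
        # forward
        acts = [Sn]
        pres = []
        a = Sn
        for W, b in zip(Ws[:-1], bs[:-1]):
            u = a @ W + b
            pres.append(u)
            a = _silu(u)
            acts.append(a)
        out = a @ Ws[-1] + bs[-1]
        resid = out - Xn
        loss = 0.5 * float(np.mean(np.sum(resid ** 2, axis=1)))
        if not np.isfinite(loss):
            raise RuntimeError(
                "field training diverged (non-finite loss); "
                "lower the learning rate or increase normalization"
            )
        epochs_run = t
        if loss < best - cfg.min_delta:
            best = loss
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

        # backward
        g = resid / n                          # dL/d(out)
        gW = [None] * len(Ws)
        gb = [None] * len(Ws)
        gW[-1] = acts[-1].T @ g
        gb[-1] = g.sum(axis=0)
        for li in range(len(Ws) - 2, -1, -1):
            g = (g @ Ws[li + 1].T) * _silu_prime(pres[li])
            gW[li] = acts[li].T @ g
            gb[li] = g.sum(axis=0)

        b1t = 1.0 - beta1 ** t
        b2t = 1.0 - beta2 ** t
        lr = lrs[t - 1]
        for li in range(len(Ws)):
            mW[li] = beta1 * mW[li] + (1 - beta1) * gW[li]
            vW[li] = beta2 * vW[li] + (1 - beta2) * gW[li] ** 2
            Ws[li] -= lr * ((mW[li] / b1t) / (np.sqrt(vW[li] / b2t) + eps)
                            + cfg.weight_decay * Ws[li])
            mb[li] = beta1 * mb[li] + (1 - beta1) * gb[li]
            vb[li] = beta2 * vb[li] + (1 - beta2) * gb[li] ** 2
            bs[li] -= lr * (mb[li] / b1t) / (np.sqrt(vb[li] / b2t) + eps)

    # final-layer least-squares polish: the network is linear in its last
    # layer, so the optimal last-layer weights given the learned hidden
    # representation have a closed form; this strictly reduces the training
    # loss (and makes degenerate targets, e.g. constants, exact).
    a = Sn
    for W, b in zip(Ws[:-1], bs[:-1]):
        a = _silu(a @ W + b)
    A1 = np.hstack([a, np.ones((n, 1))])
    if cfg.weight_decay > 0.0:
        # ridge on the weight block only, consistent with the decay above
        reg = n * cfg.weight_decay * np.eye(A1.shape[1])
        reg[-1, -1] = 0.0
        sol = np.linalg.solve(A1.T @ A1 + reg, A1.T @ Xn)
    else:
        sol, *_ = np.linalg.lstsq(A1, Xn, rcond=None)
    Ws[-1], bs[-1] = sol[:-1], sol[-1]

    model = FieldModel(Ws, bs, in_center, in_scale, out_center, out_scale,
                       seed=cfg.seed)
    pred = model.predict(S)
    mse = float(np.mean(np.sum((pred - X) ** 2, axis=1)))
    model.history = {"mse": mse, "epochs_run": epochs_run,
                     "final_normalized_loss": loss}
    return model


# Functional façade (dispatches to any object with predict/jacobian methods).

def predict(model, coords: np.ndarray) -> np.ndarray:
    return model.predict(coords)


def jacobian(model, coords: np.ndarray) -> np.ndarray:
    J = model.jacobian(coords)
    if not np.isfinite(J).all():
        raise ValueError("Jacobian contains non-finite entries")
    return J


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_field(model: FieldModel, path) -> None:
    arrays = {f"W{i}": W for i, W in enumerate(model.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.biases)})
    np.savez(path, n_layers=len(model.weights), in_center=model.in_center,
             in_scale=model.in_scale, out_center=model.out_center,
             out_scale=model.out_scale, seed=model.seed,
             mse=model.history.get("mse", np.nan), **arrays)


def load_field(path) -> FieldModel:
    with np.load(path) as z:
        L = int(z["n_layers"])
        model = FieldModel(
            [z[f"W{i}"] for i in range(L)], [z[f"b{i}"] for i in range(L)],
            z["in_center"], float(z["in_scale"]), z["out_center"],
            float(z["out_scale"]), seed=int(z["seed"]),
            history={"mse": float(z["mse"])},
        )
    return model
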