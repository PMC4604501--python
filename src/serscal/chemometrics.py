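"""PCA diagnostics and feed-forward neural calibration models.

The regression model is a single-hidden-layer feed-forward network
(1024-20-1 for one analyte, 1024-20-3 for all three) with tanh hidden units
and linear outputs, trained to minimise mean squared error with Moller's
scaled conjugate gradient (SCG) — a conjugate-gradient trainer that
replaces the line search with a scaled Hessian-vector estimate and a
Levenberg-Marquardt style trust parameter.  Early stopping keeps the weight
snapshot with the lowest validation error.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from .exceptions import DegenerateInputError

__all__ = [
    "PCAResult",
    "pca_fit",
    "ANNTopology",
    "TrainConfig",
    "ANNModel",
    "ann_init",
    "scg_minimize",
    "scg_train",
    "ann_predict",
    "calibrate_ann",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Column-mean-centred PCA of a spectra matrix."""

    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # channels x components, orthonormal columns
    explained_variance_fraction: np.ndarray
    mean: np.ndarray  # per-channel mean removed before the SVD

    def reconstruct(self) -> np.ndarray:
        """scores @ loadings' + mean; equals X when all components kept."""
        return self.scores @ self.loadings.T + self.mean


def pca_fit(X: np.ndarray, n_components: int) -> PCAResult:
    """Principal component analysis by mean-centred SVD."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= max_rank:
        raise ValueError(
            f"n_components must be in [1, {max_rank}] for shape {X.shape}"
        )
    p = _SkPCA(n_components=n_components, svd_solver="full").fit(X)
    return PCAResult(
        scores=p.transform(X),
        loadings=p.components_.T,
        explained_variance_fraction=p.explained_variance_ratio_,
        mean=p.mean_,
    )


# ---------------------------------------------------------------------------
# Network containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ANNTopology:
    """Layer sizes of the feed-forward network, e.g. 1024-20-1."""

    n_inputs: int = 1024
    n_hidden: int = 20
    n_outputs: int = 1

    def __post_init__(self) -> None:
        if min(self.n_inputs, self.n_hidden, self.n_outputs) < 1:
            raise ValueError("all layer sizes must be >= 1")

    @classmethod
    def parse(cls, text: str) -> "ANNTopology":
        """Parse a topology string like ``"1024-20-3"``."""
        parts = text.split("-")
        if len(parts) != 3:
            raise ValueError(f"cannot parse topology {text!r}")
        return cls(*(int(p) for p in parts))

    def __str__(self) -> str:
        return f"{self.n_inputs}-{self.n_hidden}-{self.n_outputs}"


@dataclass
class TrainConfig:
    """SCG training and early-stopping settings.

    ``sigma`` and ``lambda_init`` are Moller's constants for the
    finite-difference Hessian-vector estimate and the initial scaling.
    ``patience`` counts epochs without validation improvement before the
    run stops; the returned weights are always the best-validation snapshot.
    """

    max_epochs: int = 300
    patience: int = 20
    seed: int = 0
    sigma: float = 1e-4
    lambda_init: float = 1e-6

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


#: Bounds of the min-max target scaling used for training.
TARGET_RANGE = (0.1, 0.9)


@dataclass
class ANNModel:
    """Weights, scaling and training history of one fitted network.

    Inputs may be centred per channel (``input_center``); targets are
    min-max scaled to [0.1, 0.9] during training (``target_min`` /
    ``target_max``), and predictions are inverse-scaled back to
    concentration units.
    """

    topology: ANNTopology
    w1: np.ndarray  # n_inputs x n_hidden
    b1: np.ndarray  # n_hidden
    w2: np.ndarray  # n_hidden x n_outputs
    b2: np.ndarray  # n_outputs
    input_center: np.ndarray | None = None
    target_min: np.ndarray | None = None
    target_max: np.ndarray | None = None
    history: dict = field(default_factory=lambda: {"train": [], "val": []})
    best_epoch: int | None = None

    # -- parameter vector packing ------------------------------------------
    def pack(self) -> np.ndarray:
        return np.concatenate(
            [self.w1.ravel(), self.b1, self.w2.ravel(), self.b2]
        )

    def unpack(self, vec: np.ndarray) -> None:
        t = self.topology
        i = t.n_inputs * t.n_hidden
        self.w1 = vec[:i].reshape(t.n_inputs, t.n_hidden)
        self.b1 = vec[i : i + t.n_hidden]
        i += t.n_hidden
        j = i + t.n_hidden * t.n_outputs
        self.w2 = vec[i:j].reshape(t.n_hidden, t.n_outputs)
        self.b2 = vec[j : j + t.n_outputs]

    # -- forward pass in scaled space --------------------------------------
    def forward_scaled(self, Xc: np.ndarray) -> np.ndarray:
        """tanh hidden layer, linear output; expects centred inputs."""
        return np.tanh(Xc @ self.w1 + self.b1) @ self.w2 + self.b2

    # -- serialisation ------------------------------------------------------
    def to_json(self) -> str:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        payload = {
            "topology": str(self.topology),
            "w1": arr(self.w1),
            "b1": arr(self.b1),
            "w2": arr(self.w2),
            "b2": arr(self.b2),
            "input_center": arr(self.input_center),
            "target_min": arr(self.target_min),
            "target_max": arr(self.target_max),
            "history": {k: list(map(float, v)) for k, v in self.history.items()},
            "best_epoch": self.best_epoch,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ANNModel":
        d = json.loads(text)

        def arr(v):
            return None if v is None else np.asarray(v, dtype=float)

        return cls(
            topology=ANNTopology.parse(d["topology"]),
            w1=arr(d["w1"]),
            b1=arr(d["b1"]),
            w2=arr(d["w2"]),
            b2=arr(d["b2"]),
            input_center=arr(d["input_center"]),
            target_min=arr(d["target_min"]),
            target_max=arr(d["target_max"]),
            history=d["history"],
            best_epoch=d["best_epoch"],
        )


def ann_init(topology: ANNTopology, seed: int) -> ANNModel:
    """Deterministic weight initialisation, uniform in +-1/sqrt(fan_in)."""
    rng = np.random.default_rng(seed)
    s1 = 1.0 / np.sqrt(topology.n_inputs)
    s2 = 1.0 / np.sqrt(topology.n_hidden)
    return ANNModel(
        topology=topology,
        w1=rng.uniform(-s1, s1, size=(topology.n_inputs, topology.n_hidden)),
        b1=rng.uniform(-s1, s1, size=topology.n_hidden),
        w2=rng.uniform(-s2, s2, size=(topology.n_hidden, topology.n_outputs)),
        b2=rng.uniform(-s2, s2, size=topology.n_outputs),
    )


# ---------------------------------------------------------------------------
# Scaled conjugate gradient (Moller 1993)
# ---------------------------------------------------------------------------

def scg_minimize(
    fun_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    max_iter: int = 1000,
    sigma: float = 1e-4,
    lambda_init: float = 1e-6,
    gtol: float = 0.0,
    callback: Callable[[int, np.ndarray, float], bool] | None = None,
) -> tuple[np.ndarray, float]:
    """Minimise a smooth function with Moller's scaled conjugate gradient.

    No line search: the curvature along the search direction is estimated
    from a one-sided finite difference of the gradient and regularised by a
    scaling parameter ``lambda`` that is raised when the local quadratic
    model fails and lowered when it is accurate.  One iteration corresponds
    to one (attempted) weight update.

    ``callback(k, x, f)`` runs after every iteration; returning True stops
    the optimisation.  Returns ``(x, f)`` at the last iterate.
    """
    w = np.asarray(x0, dtype=float).copy()
    f, grad = fun_and_grad(w)
    if not np.isfinite(f):
        raise FloatingPointError("objective is non-finite at the initial point")
    r = -grad
    p = r.copy()
    lam = lambda_init
    lam_bar = 0.0
    success = True
    n = w.size
    delta = 0.0
    for k in range(1, max_iter + 1):
        p_norm2 = float(p @ p)
        if p_norm2 == 0.0 or np.sqrt(r @ r) <= gtol:
            if callback is not None:
                callback(k, w, f)
            break
        if success:
            sigma_k = sigma / np.sqrt(p_norm2)
            _, grad_s = fun_and_grad(w + sigma_k * p)
            s = (grad_s - (-r)) / sigma_k
            delta = float(p @ s)
        delta_k = delta + (lam - lam_bar) * p_norm2
        if delta_k <= 0:  # make the Hessian estimate positive definite
            lam_bar = 2.0 * (lam - delta_k / p_norm2)
            delta_k = -delta_k + lam * p_norm2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta_k
        f_new, grad_new = fun_and_grad(w + alpha * p)
        if not np.isfinite(f_new):
            raise FloatingPointError(
                f"objective became non-finite at iteration {k} "
                f"(alpha={alpha:.3g}, lambda={lam:.3g})"
            )
        comparison = 2.0 * delta_k * (f - f_new) / mu**2
        if comparison >= 0:
            # successful step
            w = w + alpha * p
            f = f_new
            r_new = -grad_new
            lam_bar = 0.0
            success = True
            if k % n == 0:
                p = r_new.copy()
            else:
                beta = float(r_new @ r_new - r_new @ r) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam = max(lam * 0.25, 1e-20)
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam = lam + delta_k * (1.0 - comparison) / p_norm2
            lam = min(lam, 1e25)
        if callback is not None and callback(k, w, f):
            break
    return w, f


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _mse_and_grad(model: ANNModel, vec: np.ndarray, X: np.ndarray, Y: np.ndarray):
    """Mean squared error over all outputs, and its gradient in ``vec``."""
    t = model.topology
    i = t.n_inputs * t.n_hidden
    w1 = vec[:i].reshape(t.n_inputs, t.n_hidden)
    b1 = vec[i : i + t.n_hidden]
    i += t.n_hidden
    j = i + t.n_hidden * t.n_outputs
    w2 = vec[i:j].reshape(t.n_hidden, t.n_outputs)
    b2 = vec[j:]

    h = np.tanh(X @ w1 + b1)
    out = h @ w2 + b2
    resid = out - Y
    mse = float(np.mean(resid**2))

    d_out = (2.0 / resid.size) * resid
    g_w2 = h.T @ d_out
    g_b2 = d_out.sum(axis=0)
    d_h = (d_out @ w2.T) * (1.0 - h**2)
    g_w1 = X.T @ d_h
    g_b1 = d_h.sum(axis=0)
    grad = np.concatenate([g_w1.ravel(), g_b1, g_w2.ravel(), g_b2])
    return mse, grad


def scg_train(
    model: ANNModel,
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_val: np.ndarray,
    Y_val: np.ndarray,
    config: TrainConfig | None = None,
) -> ANNModel:
    """Train ``model`` by SCG with best-validation early stopping.

    Inputs are expected already preprocessed/centred and targets already
    scaled; this routine neither fits nor applies any scaling.  The history
    records training and validation MSE after every epoch (one SCG
    iteration), and the returned model carries the weight snapshot with the
    lowest validation error (``best_epoch``, 1-based).
    """
    if config is None:
        config = TrainConfig()
    X_train = np.asarray(X_train, float)
    Y_train = np.atleast_2d(np.asarray(Y_train, float).T).T
    X_val = np.asarray(X_val, float)
    Y_val = np.atleast_2d(np.asarray(Y_val, float).T).T
    if np.any(np.ptp(Y_train, axis=0) == 0):
        raise DegenerateInputError("constant training targets")

    train_hist: list[float] = []
    val_hist: list[float] = []
    state = {"best_val": np.inf, "best_w": model.pack(), "best_epoch": 0, "stall": 0}

    def objective(vec: np.ndarray):
        return _mse_and_grad(model, vec, X_train, Y_train)

    def val_mse(vec: np.ndarray) -> float:
        t = model.topology
        i = t.n_inputs * t.n_hidden
        w1 = vec[:i].reshape(t.n_inputs, t.n_hidden)
        b1 = vec[i : i + t.n_hidden]
        i += t.n_hidden
        j = i + t.n_hidden * t.n_outputs
        w2 = vec[i:j].reshape(t.n_hidden, t.n_outputs)
        out = np.tanh(X_val @ w1 + b1) @ w2 + vec[j:]
        return float(np.mean((out - Y_val) ** 2))

    def on_epoch(k: int, vec: np.ndarray, f: float) -> bool:
        train_hist.append(f)
        v = val_mse(vec)
        val_hist.append(v)
        if v < state["best_val"]:
            state["best_val"] = v
            state["best_w"] = vec.copy()
            state["best_epoch"] = k
            state["stall"] = 0
        else:
            state["stall"] += 1
        return state["stall"] >= config.patience

    try:
        scg_minimize(
            objective,
            model.pack(),
            max_iter=config.max_epochs,
            sigma=config.sigma,
            lambda_init=config.lambda_init,
            callback=on_epoch,
        )
    except FloatingPointError as exc:
        raise FloatingPointError(f"SCG training diverged: {exc}") from exc

    model.unpack(state["best_w"])
    model.history = {"train": train_hist, "val": val_hist}
    model.best_epoch = state["best_epoch"]
    return model


# ---------------------------------------------------------------------------
# Scaling helpers and prediction
# ---------------------------------------------------------------------------

def scale_targets(Y: np.ndarray, tmin: np.ndarray, tmax: np.ndarray) -> np.ndarray:
    lo, hi = TARGET_RANGE
    return lo + (hi - lo) * (Y - tmin) / (tmax - tmin)


def unscale_targets(S: np.ndarray, tmin: np.ndarray, tmax: np.ndarray) -> np.ndarray:
    lo, hi = TARGET_RANGE
    return tmin + (S - lo) / (hi - lo) * (tmax - tmin)


def ann_predict(model: ANNModel, X: np.ndarray) -> np.ndarray:
    """Predict concentrations for preprocessed spectra ``X``.

    Applies the model's stored input centring and inverse target scaling;
    returns an (n_samples, n_outputs) array in concentration units.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.topology.n_inputs:
        raise ValueError(
            f"X has {X.shape[1]} channels; model expects {model.topology.n_inputs}"
        )
    Xc = X - model.input_center if model.input_center is not None else X
    out = model.forward_scaled(Xc)
    if model.target_min is not None:
        out = unscale_targets(out, model.target_min, model.target_max)
    return out


def calibrate_ann(
    X_inner: np.ndarray,
    Y_inner: np.ndarray,
    X_tune: np.ndarray,
    Y_tune: np.ndarray,
    topology: ANNTopology,
    config: TrainConfig | None = None,
    center_inputs: bool = True,
) -> ANNModel:
    """Fit scalers on the inner-training set, then SCG-train with tuning.

    Input centring and target min-max scaling are computed on
    ``(X_inner, Y_inner)`` only, so the tuning set steers early stopping
    without leaking into the scaling.
    """
    if config is None:
        config = TrainConfig()
    X_inner = np.asarray(X_inner, float)
    Y_inner = np.atleast_2d(np.asarray(Y_inner, float).T).T
    X_tune = np.asarray(X_tune, float)
    Y_tune = np.atleast_2d(np.asarray(Y_tune, float).T).T

    tmin = Y_inner.min(axis=0)
    tmax = Y_inner.max(axis=0)
    if np.any(tmax == tmin):
        raise DegenerateInputError("constant targets on the inner training set")
    center = X_inner.mean(axis=0) if center_inputs else None

    def prep(X):
        return X - center if center is not None else X

    model = ann_init(topology, config.seed)
    model.input_center = center
    model.target_min = tmin
    model.target_max = tmax
    scg_train(
        model,
        prep(X_inner),
        scale_targets(Y_inner, tmin, tmax),
        prep(X_tune),
        scale_targets(Y_tune, tmin, tmax),
        config,
    )
    return model
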