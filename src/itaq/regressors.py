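"""Predictive models over the 13-dimensional descriptor space.

Three regressors share one contract: features are the 11 ITA quantities
plus HOMO and LUMO energies; targets are the first/second reduction
potentials Q1/Q2 (mV vs SCE) and the Hammett constant sigma_p, each with
an explicit missing-label mask.

* :func:`fit_linear` -- ordinary least squares baseline.
* :func:`fit_mlp` -- a one-hidden-layer (6 ReLU units) multitask network
  trained with masked mean-squared error, Adam, and a reduce-on-plateau
  learning-rate schedule.
* :func:`fit_vqc` -- a hybrid model: a two-layer classical encoder maps the
  13 features to 12 angle-embedded qubits, two trainable entangling layers
  act on the statevector, per-qubit Pauli-Z expectations feed an affine
  head.  Gradients flow end to end (adjoint statevector differentiation
  through the circuit, ordinary backprop elsewhere).

Features and targets are standardized on the training split only; all
reported metrics are computed on de-standardized, original-unit values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .fileio import FEATURE_COLUMNS, TARGET_COLUMNS
from .quantum import circuit_forward, circuit_vjp

__all__ = [
    "metrics",
    "StandardizationSpec",
    "make_split",
    "kfold_splits",
    "LinearModel",
    "fit_linear",
    "MLPConfig",
    "MLPModel",
    "fit_mlp",
    "VQCConfig",
    "VQCModel",
    "fit_vqc",
    "FitReport",
    "evaluate",
]


# ---------------------------------------------------------------------------
# Metrics and reports
# ---------------------------------------------------------------------------

def metrics(pred: np.ndarray, obs: np.ndarray, mask: np.ndarray | None = None) -> dict:
    """RMSE, MAE and R^2 over unmasked pairs (original units)."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    m = np.isfinite(obs) if mask is None else np.asarray(mask, dtype=bool).ravel()
    if m.sum() < 1:
        raise ValueError("metrics need at least one unmasked pair")
    err = pred[m] - obs[m]
    sst = float(np.sum((obs[m] - obs[m].mean()) ** 2))
    if sst == 0.0:
        raise ValueError("R^2 undefined: zero target variance")
    return {
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mae": float(np.mean(np.abs(err))),
        "r2": 1.0 - float(np.sum(err**2)) / sst,
    }


@dataclass
class FitReport:
    """Per-target train/validation metrics plus provenance of the fit."""

    targets: dict = dc_field(default_factory=dict)  # name -> {"train": {...}, "val": {...}}
    split: dict = dc_field(default_factory=dict)
    seed: int | None = None
    loss_history: list = dc_field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"targets": self.targets, "split": self.split, "seed": self.seed,
             "loss_history": self.loss_history},
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


@dataclass
class StandardizationSpec:
    """Exact affine standardize/de-standardize pair, fitted on training data."""

    feature_mean: np.ndarray
    feature_std: np.ndarray
    target_mean: np.ndarray
    target_std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray, Y: np.ndarray, mask: np.ndarray) -> "StandardizationSpec":
        fm, fs = X.mean(axis=0), X.std(axis=0)
        fs = np.where(fs > 0, fs, 1.0)
        tm = np.zeros(Y.shape[1])
        ts = np.ones(Y.shape[1])
        for j in range(Y.shape[1]):
            col = Y[mask[:, j], j]
            if col.size:
                tm[j] = col.mean()
                sd = col.std()
                ts[j] = sd if sd > 0 else 1.0
        return cls(fm, fs, tm, ts)

    def transform_features(self, X):
        return (X - self.feature_mean) / self.feature_std

    def transform_targets(self, Y):
        return (Y - self.target_mean) / self.target_std

    def inverse_targets(self, Ystd):
        return Ystd * self.target_std + self.target_mean


def make_split(
    table: pd.DataFrame,
    seed: int = 0,
    val_fraction: float = 0.2,
    stratify_by: str | None = "family",
) -> tuple[np.ndarray, np.ndarray]:
    """Single train/validation index split, stratified by family when possible."""
    idx = np.arange(len(table))
    strat = None
    if stratify_by and stratify_by in table.columns:
        fam = table[stratify_by].astype(str).values
        counts = pd.Series(fam).value_counts()
        if (counts >= 2).all() and len(counts) > 1:
            strat = fam
    train, val = train_test_split(
        idx, test_size=val_fraction, random_state=seed, stratify=strat
    )
    return np.sort(train), np.sort(val)


def kfold_splits(table: pd.DataFrame, k: int = 5, seed: int = 0):
    """k-fold cross-validation index pairs (train, val)."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(table))
    folds = np.array_split(idx, k)
    for i in range(k):
        val = np.sort(folds[i])
        train = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        yield train, val


def _extract(table: pd.DataFrame, feature_columns, target_columns):
    X = table[list(feature_columns)].to_numpy(dtype=float)
    Y = np.full((len(table), len(target_columns)), np.nan)
    for j, col in enumerate(target_columns):
        if col in table.columns:
            Y[:, j] = pd.to_numeric(table[col], errors="coerce").to_numpy()
    mask = np.isfinite(Y)
    return X, np.where(mask, Y, 0.0), mask


def _report(model, X, Y, mask, split, target_names, seed, loss_history) -> FitReport:
    train_idx, val_idx = split
    rep = FitReport(seed=seed, loss_history=list(map(float, loss_history)),
                    split={"n_train": int(len(train_idx)), "n_val": int(len(val_idx))})
    pred = model.predict(X)
    if pred.ndim == 1:
        pred = pred[:, None]
    for j, name in enumerate(target_names):
        entry = {}
        for part, idx in (("train", train_idx), ("val", val_idx)):
            if len(idx) and mask[idx, j].sum() >= 2:
                entry[part] = metrics(pred[idx, j], np.where(mask[idx, j], Y[idx, j], np.nan))
        rep.targets[name] = entry
    return rep


# ---------------------------------------------------------------------------
# Ordinary least squares
# ---------------------------------------------------------------------------

class LinearModel:
    def __init__(self, coef: np.ndarray, intercept: float, feature_columns, target: str):
        self.coef = np.asarray(coef, dtype=float)
        self.intercept = float(intercept)
        self.feature_columns = list(feature_columns)
        self.target = target

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept


def _collinear_columns(X: np.ndarray, names) -> list[str]:
    bad = []
    for j in range(1, X.shape[1]):
        coef, *_ = np.linalg.lstsq(X[:, :j], X[:, j], rcond=None)
        fitted = X[:, :j] @ coef
        if np.allclose(fitted, X[:, j], atol=1e-8 * max(1.0, np.abs(X[:, j]).max())):
            bad.append(names[j])
    return bad


def fit_linear(
    table: pd.DataFrame,
    feature_columns=FEATURE_COLUMNS,
    target: str = "q1_mv",
) -> tuple[LinearModel, FitReport]:
    """Ordinary least squares on the rows where ``target`` is present."""
    X, Y, mask = _extract(table, feature_columns, [target])
    keep = mask[:, 0]
    if keep.sum() < 2:
        raise ValueError(f"need >= 2 non-missing rows for target {target!r}")
    Xk, yk = X[keep], Y[keep, 0]
    design = np.column_stack([Xk, np.ones(len(Xk))])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, list(feature_columns) + ["intercept"])
        raise np.linalg.LinAlgError(
            f"rank-deficient design; collinear columns: {bad or 'intercept'}"
        )
    beta, *_ = np.linalg.lstsq(design, yk, rcond=None)
    model = LinearModel(beta[:-1], beta[-1], feature_columns, target)
    idx = np.flatnonzero(keep)
    rep = _report(model, X, Y, mask, (idx, np.array([], dtype=int)), [target], None, [])
    return model, rep


# ---------------------------------------------------------------------------
# Shared training machinery
# ---------------------------------------------------------------------------

class _Adam:
    """Adaptive-moment optimizer over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _Plateau:
    """Reduce-on-plateau schedule with a relative improvement threshold."""

    def __init__(self, opt: _Adam, factor: float, patience: int, min_lr: float = 1e-5,
                 threshold: float = 1e-4):
        self.opt = opt
        self.factor, self.patience, self.min_lr = factor, patience, min_lr
        self.threshold = threshold
        self.best = np.inf
        self.stall = 0

    def step(self, loss: float):
        if loss < self.best * (1.0 - self.threshold):
            self.best = loss
            self.stall = 0
        else:
            self.stall += 1
            if self.stall > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.stall = 0


def _masked_mse(pred, Y, mask):
    n = mask.sum()
    if n == 0:
        return 0.0, np.zeros_like(pred)
    err = np.where(mask, pred - Y, 0.0)
    return float(np.sum(err**2) / n), 2.0 * err / n


def _drop_empty_heads(mask, target_names):
    active = [j for j in range(mask.shape[1]) if mask[:, j].any()]
    dropped = [target_names[j] for j in range(mask.shape[1]) if j not in active]
    if dropped:
        warnings.warn(f"targets with no labels excluded: {dropped}", RuntimeWarning,
                      stacklevel=3)
    return active


# ---------------------------------------------------------------------------
# Multilayer perceptron
# ---------------------------------------------------------------------------

@dataclass
class MLPConfig:
    input_dim: int = 13
    hidden_layers: tuple[int, ...] = (6,)
    epochs: int = 2000
    lr: float = 1e-3
    batch_size: int = 32
    scheduler_factor: float = 0.5
    scheduler_patience: int = 10
    early_stop_patience: int = 100
    min_lr: float = 1e-5
    seed: int = 0


class MLPModel:
    """ReLU network trained on standardized data; predicts original units."""

    def __init__(self, weights, biases, spec: StandardizationSpec, target_names):
        self.weights = weights
        self.biases = biases
        self.spec = spec
        self.target_names = list(target_names)

    def _forward(self, Xstd):
        h = Xstd
        acts = [h]
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        out = h @ self.weights[-1] + self.biases[-1]
        return out, acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        out, _ = self._forward(self.spec.transform_features(np.asarray(X, dtype=float)))
        return self.spec.inverse_targets(out)


def _init_layers(dims, rng):
    Ws, bs = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        Ws.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        bs.append(np.zeros(fan_out))
    return Ws, bs


def fit_mlp(
    table: pd.DataFrame,
    config: MLPConfig | None = None,
    split: tuple[np.ndarray, np.ndarray] | None = None,
    feature_columns=FEATURE_COLUMNS,
    target_columns=TARGET_COLUMNS,
) -> tuple[MLPModel, FitReport]:
    """Train the multitask MLP with masked MSE loss."""
    config = config or MLPConfig()
    X, Y, mask = _extract(table, feature_columns, target_columns)
    if split is None:
        split = make_split(table, seed=config.seed)
    train_idx, val_idx = split

    active = _drop_empty_heads(mask[train_idx], list(target_columns))
    names = [target_columns[j] for j in active]
    Ya, maska = Y[:, active], mask[:, active]

    spec = StandardizationSpec.fit(X[train_idx], Ya[train_idx], maska[train_idx])
    Xs = spec.transform_features(X)
    Ys = spec.transform_targets(Ya)

    rng = np.random.default_rng(config.seed)
    dims = [config.input_dim, *config.hidden_layers, len(active)]
    Ws, bs = _init_layers(dims, rng)
    model = MLPModel(Ws, bs, spec, names)

    opt = _Adam(Ws + bs, config.lr)
    sched = _Plateau(opt, config.scheduler_factor, config.scheduler_patience, config.min_lr)
    history = []
    best_val, best_state, stall = np.inf, None, 0

    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            out, acts = model._forward(Xs[batch])
            loss, dout = _masked_mse(out, Ys[batch], maska[batch])
            gWs, gbs = [None] * len(Ws), [None] * len(bs)
            delta = dout
            for layer in range(len(Ws) - 1, -1, -1):
                gWs[layer] = acts[layer].T @ delta
                gbs[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ Ws[layer].T) * (acts[layer] > 0)
            opt.step(gWs + gbs)

        out, _ = model._forward(Xs[train_idx])
        train_loss, _ = _masked_mse(out, Ys[train_idx], maska[train_idx])
        monitor = train_loss
        if len(val_idx):
            vout, _ = model._forward(Xs[val_idx])
            monitor, _ = _masked_mse(vout, Ys[val_idx], maska[val_idx])
        history.append(monitor)
        sched.step(monitor)
        if monitor < best_val - 1e-12:
            best_val, stall = monitor, 0
            best_state = ([W.copy() for W in Ws], [b.copy() for b in bs])
        else:
            stall += 1
            if stall > config.early_stop_patience:
                break

    if best_state is not None:
        model.weights, model.biases = best_state
    rep = _report(model, X, Ya, maska, split, names, config.seed, history)
    return model, rep


# ---------------------------------------------------------------------------
# Hybrid variational-quantum-circuit regressor
# ---------------------------------------------------------------------------

@dataclass
class VQCConfig:
    """Hybrid-model hyperparameters.

    The defaults reflect what 200-epoch circuit training needs in practice:
    a learning rate an order above the MLP's, a near-identity circuit
    start, and an encoder whose output layer begins small so the model
    enters through the smooth small-angle regime.
    """

    input_dim: int = 13
    n_qubits: int = 12
    encoder_hidden: int = 16
    n_layers: int = 2
    epochs: int = 200
    lr: float = 2e-2
    batch_size: int = 16
    scheduler_factor: float = 0.5
    scheduler_patience: int = 20
    min_lr: float = 1e-3
    clip_pi: bool = False
    precision: str = "single"   # statevector precision during training
    circuit_init_sd: float = 0.1
    encoder_out_scale: float = 0.3
    seed: int = 0


class VQCModel:
    """Classical encoder -> angle embedding -> entangling circuit -> affine head."""

    def __init__(self, enc_W1, enc_b1, enc_W2, enc_b2, circuit_params, head_W, head_b,
                 spec: StandardizationSpec, target_names, clip_pi: bool = False,
                 precision: str = "double"):
        self.enc_W1, self.enc_b1 = enc_W1, enc_b1
        self.enc_W2, self.enc_b2 = enc_W2, enc_b2
        self.circuit_params = circuit_params
        self.head_W, self.head_b = head_W, head_b
        self.spec = spec
        self.target_names = list(target_names)
        self.clip_pi = clip_pi
        self.dtype = np.complex64 if precision == "single" else np.complex128

    @property
    def parameters(self):
        return [self.enc_W1, self.enc_b1, self.enc_W2, self.enc_b2,
                self.circuit_params, self.head_W, self.head_b]

    def _encode(self, Xstd):
        h = np.maximum(Xstd @ self.enc_W1 + self.enc_b1, 0.0)
        a = h @ self.enc_W2 + self.enc_b2
        if self.clip_pi:
            a = np.clip(a, -np.pi, np.pi)
        return h, a

    def _forward(self, Xstd):
        h, a = self._encode(Xstd)
        z, state = circuit_forward(a, self.circuit_params, return_state=True,
                                   dtype=self.dtype)
        out = z @ self.head_W + self.head_b
        return out, (h, a, z, state)

    def predict(self, X: np.ndarray) -> np.ndarray:
        out, _ = self._forward(self.spec.transform_features(np.asarray(X, dtype=float)))
        return self.spec.inverse_targets(out)

    def backward(self, Xstd, cache, dout):
        """Gradients of the scalar loss for every parameter array."""
        h, a, z, state = cache
        gW_head = z.T @ dout
        gb_head = dout.sum(axis=0)
        dz = dout @ self.head_W.T
        da, gcirc = circuit_vjp(state, a, self.circuit_params, dz)
        if self.clip_pi:
            raw = h @ self.enc_W2 + self.enc_b2
            da = np.where(np.abs(raw) < np.pi, da, 0.0)
        gW2 = h.T @ da
        gb2 = da.sum(axis=0)
        dh = (da @ self.enc_W2.T) * (h > 0)
        gW1 = Xstd.T @ dh
        gb1 = dh.sum(axis=0)
        return [gW1, gb1, gW2, gb2, gcirc, gW_head, gb_head]


def fit_vqc(
    table: pd.DataFrame,
    config: VQCConfig | None = None,
    split: tuple[np.ndarray, np.ndarray] | None = None,
    feature_columns=FEATURE_COLUMNS,
    target_columns=TARGET_COLUMNS,
) -> tuple[VQCModel, FitReport]:
    """Train the hybrid quantum-classical regressor end to end."""
    config = config or VQCConfig()
    X, Y, mask = _extract(table, feature_columns, target_columns)
    if split is None:
        split = make_split(table, seed=config.seed)
    train_idx, val_idx = split

    active = _drop_empty_heads(mask[train_idx], list(target_columns))
    names = [target_columns[j] for j in active]
    Ya, maska = Y[:, active], mask[:, active]

    spec = StandardizationSpec.fit(X[train_idx], Ya[train_idx], maska[train_idx])
    Xs = spec.transform_features(X)
    Ys = spec.transform_targets(Ya)

    rng = np.random.default_rng(config.seed)
    (W1, W2), (b1, b2) = _init_layers(
        [config.input_dim, config.encoder_hidden, config.n_qubits], rng)
    W2 *= config.encoder_out_scale  # start in the small-angle (near-linear) regime
    # near-identity circuit start: keeps the readout variance non-degenerate
    # and the adjoint gradients well-scaled at the first epochs
    circ = rng.normal(0.0, config.circuit_init_sd,
                      size=(config.n_layers, config.n_qubits))
    Wh = rng.normal(0.0, np.sqrt(1.0 / config.n_qubits),
                    size=(config.n_qubits, len(active)))
    bh = np.zeros(len(active))
    model = VQCModel(W1, b1, W2, b2, circ, Wh, bh, spec, names, config.clip_pi,
                     precision=config.precision)

    opt = _Adam(model.parameters, config.lr)
    sched = _Plateau(opt, config.scheduler_factor, config.scheduler_patience, config.min_lr)
    history = []
    best_val, best_state = np.inf, None

    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            out, cache = model._forward(Xs[batch])
            batch_loss, dout = _masked_mse(out, Ys[batch], maska[batch])
            opt.step(model.backward(Xs[batch], cache, dout))

        if len(val_idx):
            vout, _ = model._forward(Xs[val_idx])
            monitor, _ = _masked_mse(vout, Ys[val_idx], maska[val_idx])
        else:
            out, _ = model._forward(Xs[train_idx])
            monitor, _ = _masked_mse(out, Ys[train_idx], maska[train_idx])
        history.append(monitor)
        sched.step(monitor)
        if monitor < best_val - 1e-12:
            best_val = monitor
            best_state = [p.copy() for p in model.parameters]

    if best_state is not None:
        for p, b in zip(model.parameters, best_state):
            p[...] = b
    rep = _report(model, X, Ya, maska, split, names, config.seed, history)
    return model, rep


def evaluate(model, table: pd.DataFrame, split=None,
             feature_columns=FEATURE_COLUMNS, target_columns=None) -> FitReport:
    """Recompute a FitReport for a fitted model on a (possibly new) table."""
    target_columns = target_columns or getattr(model, "target_names", TARGET_COLUMNS)
    X, Y, mask = _extract(table, feature_columns, target_columns)
    if split is None:
        split = (np.arange(len(table)), np.array([], dtype=int))
    return _report(model, X, Y, mask, split, list(target_columns), None, [])
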