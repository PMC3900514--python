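"""Elman recurrent perceptron for next-year cohort abundance prediction.

Architecture: input -> hidden (+ context copy of the previous hidden state)
-> output, logistic activations throughout.  One sample is a 4-step lag
sequence of per-cell features (own-cell cohort abundances, neighbor-mean
abundances, effort, mean depth, depth sd, SST); the target is the vector of
cohort abundances at the following year.  Training is full-batch gradient
descent with backpropagation through the unrolled lag steps, restarted from
multiple random initializations; the restart with the best held-out Pearson
correlation wins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class EmpnConfig:
    n_inputs: int
    n_outputs: int
    n_hidden: int = 10
    learning_rate: float = 0.1
    max_epochs: int = 500
    tol: float = 1e-5
    restarts: int = 100
    test_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")

    @property
    def n_context(self) -> int:
        # context units mirror the hidden layer one-for-one
        return self.n_hidden


@dataclass
class FeatureScaler:
    """log10(x+1) (optional per feature) followed by min-max to [0, 1].

    Zero-range features are flagged and mapped to 0.
    """

    log_mask: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    degenerate: np.ndarray = None

    def __post_init__(self):
        self.log_mask = np.asarray(self.log_mask, dtype=bool)
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        self.degenerate = self.hi - self.lo <= 0
        if self.degenerate.any():
            logger.warning("scaler: %d feature(s) with zero range map to 0",
                           int(self.degenerate.sum()))

    @classmethod
    def fit(cls, X: np.ndarray, log_mask) -> "FeatureScaler":
        """X has features on the last axis; ranges pooled over leading axes."""
        log_mask = np.asarray(log_mask, dtype=bool)
        Xt = X.copy()
        Xt[..., log_mask] = np.log10(Xt[..., log_mask] + 1.0)
        flat = Xt.reshape(-1, Xt.shape[-1])
        return cls(log_mask=log_mask, lo=flat.min(axis=0), hi=flat.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        Xt = np.asarray(X, dtype=float).copy()
        Xt[..., self.log_mask] = np.log10(Xt[..., self.log_mask] + 1.0)
        rng = np.where(self.degenerate, 1.0, self.hi - self.lo)
        out = (Xt - self.lo) / rng
        out[..., self.degenerate] = 0.0
        return out

    def inverse(self, Xs: np.ndarray) -> np.ndarray:
        rng = np.where(self.degenerate, 1.0, self.hi - self.lo)
        X = np.asarray(Xs, dtype=float) * rng + self.lo
        X[..., self.log_mask] = 10.0 ** X[..., self.log_mask] - 1.0
        return X

    def to_dict(self):
        return {"log_mask": self.log_mask.astype(int).tolist(),
                "lo": self.lo.tolist(), "hi": self.hi.tolist()}

    @classmethod
    def from_dict(cls, d):
        return cls(log_mask=np.asarray(d["log_mask"], dtype=bool),
                   lo=np.asarray(d["lo"]), hi=np.asarray(d["hi"]))


@dataclass
class TrainingTensor:
    """Scaled lag sequences X (n, n_lags, n_features) and targets y (n, n_out)."""

    X: np.ndarray
    y: np.ndarray
    cell_ids: np.ndarray
    feature_names: list
    groups: dict                      # group name -> list of feature indices
    x_scaler: FeatureScaler
    y_scaler: FeatureScaler

    @property
    def n_samples(self):
        return self.X.shape[0]


@dataclass
class TrainedEmpn:
    W_in: np.ndarray      # (hidden, inputs)
    W_ctx: np.ndarray     # (hidden, hidden)
    W_out: np.ndarray     # (outputs, hidden)
    b_h: np.ndarray
    b_o: np.ndarray
    config: EmpnConfig
    x_scaler: FeatureScaler = None
    y_scaler: FeatureScaler = None
    history: list = field(default_factory=list)
    test_r: float = np.nan
    restart_rs: list = field(default_factory=list)

    def __post_init__(self):
        for w in (self.W_in, self.W_ctx, self.W_out, self.b_h, self.b_o):
            if not np.isfinite(w).all():
                raise ValueError("network weights must be finite")

    def to_json(self, path=None) -> str:
        payload = {
            "W_in": self.W_in.tolist(), "W_ctx": self.W_ctx.tolist(),
            "W_out": self.W_out.tolist(), "b_h": self.b_h.tolist(),
            "b_o": self.b_o.tolist(),
            "config": self.config.__dict__,
            "x_scaler": None if self.x_scaler is None else self.x_scaler.to_dict(),
            "y_scaler": None if self.y_scaler is None else self.y_scaler.to_dict(),
            "test_r": self.test_r,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "TrainedEmpn":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls(
            W_in=np.asarray(payload["W_in"]), W_ctx=np.asarray(payload["W_ctx"]),
            W_out=np.asarray(payload["W_out"]), b_h=np.asarray(payload["b_h"]),
            b_o=np.asarray(payload["b_o"]), config=EmpnConfig(**payload["config"]),
            x_scaler=None if payload["x_scaler"] is None
            else FeatureScaler.from_dict(payload["x_scaler"]),
            y_scaler=None if payload["y_scaler"] is None
            else FeatureScaler.from_dict(payload["y_scaler"]),
            test_r=payload["test_r"],
        )


# ---------------------------------------------------------------------------
# dataset construction
# ---------------------------------------------------------------------------

def build_dataset(cohort_layers: dict, effort_layers: dict, env: dict, grid,
                  target_year: int, n_lags: int = 4, neighbor_ray: int = 2,
                  species: str = "") -> TrainingTensor:
    """Assemble lagged per-cell feature sequences and next-year targets.

    Parameters
    ----------
    cohort_layers : dict year -> (n_cells, H) matrix
        Cohort abundances per cell (cohort x sex columns kept separate).
    effort_layers : dict year -> EffortPattern (or count array)
    env : dict with keys "dbar", "dsd" (arrays) and "sst" (dict year -> array)
    grid : GridSpec
    target_year : int
        Year whose abundances are the target; lags are the n_lags preceding
        years.

    Per lag step the features are: H own-cell cohort abundances, H
    neighbor-mean abundances (Chebyshev ray ``neighbor_ray``), effort, mean
    depth, depth sd, SST.  Abundances and effort get log10(x+1); everything
    is min-max scaled to [0, 1].  Cells masked (NaN) in any used year are
    excluded.
    """
    from trawlsim.grid import CellLayer, neighbor_mean

    lag_years = [target_year - n_lags + i for i in range(n_lags)]
    for y in lag_years + [target_year]:
        if y not in cohort_layers:
            raise KeyError(f"missing cohort layers for year {y}")
    for y in lag_years:
        if y not in effort_layers:
            raise KeyError(f"missing effort layer for year {y}")
        if y not in env["sst"]:
            raise KeyError(f"missing SST layer for year {y}")

    H = np.asarray(cohort_layers[lag_years[0]]).shape[1]
    n_features = 2 * H + 4
    feature_names = ([f"cohort_{j}" for j in range(H)]
                     + [f"neighbor_{j}" for j in range(H)]
                     + ["effort", "dbar", "dsd", "sst"])
    groups = {
        "own_cohorts": list(range(H)),
        "neighbor_cohorts": list(range(H, 2 * H)),
        "effort": [2 * H],
        "dbar": [2 * H + 1],
        "dsd": [2 * H + 2],
        "sst": [2 * H + 3],
    }

    dbar = np.asarray(env["dbar"], dtype=float)
    dsd = np.asarray(env["dsd"], dtype=float)

    raw = np.full((grid.n_cells, n_lags, n_features), np.nan)
    for t, y in enumerate(lag_years):
        A = np.asarray(cohort_layers[y], dtype=float)
        nbr = np.empty_like(A)
        for j in range(H):
            layer = CellLayer(grid=grid, name=f"c{j}", year=y, values=A[:, j])
            nbr[:, j] = neighbor_mean(layer, ray=neighbor_ray).values
        eff = effort_layers[y]
        eff = np.asarray(getattr(eff, "counts", eff), dtype=float)
        sst = np.asarray(env["sst"][y], dtype=float)
        raw[:, t, :H] = A
        raw[:, t, H:2 * H] = nbr
        raw[:, t, 2 * H] = eff
        raw[:, t, 2 * H + 1] = dbar
        raw[:, t, 2 * H + 2] = dsd
        raw[:, t, 2 * H + 3] = sst

    target = np.asarray(cohort_layers[target_year], dtype=float)
    ok = (grid.active
          & np.isfinite(raw).all(axis=(1, 2))
          & np.isfinite(target).all(axis=1))
    cell_ids = np.flatnonzero(ok)

    log_mask = np.zeros(n_features, dtype=bool)
    log_mask[:2 * H + 1] = True     # abundances, neighbor means, effort
    x_scaler = FeatureScaler.fit(raw[ok], log_mask)
    y_scaler = FeatureScaler.fit(target[ok], np.ones(H, dtype=bool))
    return TrainingTensor(
        X=x_scaler.transform(raw[ok]), y=y_scaler.transform(target[ok]),
        cell_ids=cell_ids, feature_names=feature_names, groups=groups,
        x_scaler=x_scaler, y_scaler=y_scaler,
    )


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def forward(net: TrainedEmpn, X: np.ndarray, return_states: bool = False):
    """Run lag sequences through the network.

    ``X`` has shape (n, T, n_inputs) (a single sequence (T, n_inputs) is
    promoted).  Context starts at zero, copies the hidden activations after
    every step; the output is read after the last step.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    n, T, d = X.shape
    if d != net.W_in.shape[1]:
        raise ValueError(f"expected {net.W_in.shape[1]} inputs, got {d}")
    h = np.zeros((n, net.W_in.shape[0]))
    states = []
    for t in range(T):
        z = X[:, t] @ net.W_in.T + h @ net.W_ctx.T + net.b_h
        h = sigmoid(z)
        states.append(h)
    out = sigmoid(h @ net.W_out.T + net.b_o)
    if single:
        out = out[0]
    if return_states:
        return out, states
    return out


def _init_net(config: EmpnConfig, rng) -> TrainedEmpn:
    s = 0.5
    return TrainedEmpn(
        W_in=rng.uniform(-s, s, (config.n_hidden, config.n_inputs)),
        W_ctx=rng.uniform(-s, s, (config.n_hidden, config.n_hidden)),
        W_out=rng.uniform(-s, s, (config.n_outputs, config.n_hidden)),
        b_h=rng.uniform(-s, s, config.n_hidden),
        b_o=rng.uniform(-s, s, config.n_outputs),
        config=config,
    )


def _loss_and_grads(net: TrainedEmpn, X, y):
    """Mean squared error and gradients via backprop through the lag steps."""
    n, T, _ = X.shape
    hs = [np.zeros((n, net.W_in.shape[0]))]
    for t in range(T):
        z = X[:, t] @ net.W_in.T + hs[-1] @ net.W_ctx.T + net.b_h
        hs.append(sigmoid(z))
    out = sigmoid(hs[-1] @ net.W_out.T + net.b_o)
    err = out - y
    loss = float(np.mean(err ** 2))

    scale = 2.0 / err.size
    d_out = scale * err * out * (1 - out)               # (n, o)
    gW_out = d_out.T @ hs[-1]
    gb_o = d_out.sum(axis=0)
    d_h = (d_out @ net.W_out) * hs[-1] * (1 - hs[-1])   # (n, hidden)

    gW_in = np.zeros_like(net.W_in)
    gW_ctx = np.zeros_like(net.W_ctx)
    gb_h = np.zeros_like(net.b_h)
    for t in range(T - 1, -1, -1):
        gW_in += d_h.T @ X[:, t]
        gW_ctx += d_h.T @ hs[t]
        gb_h += d_h.sum(axis=0)
        if t > 0:
            d_h = (d_h @ net.W_ctx) * hs[t] * (1 - hs[t])
    return loss, (gW_in, gW_ctx, gW_out, gb_h, gb_o)


def _train_once(X, y, config: EmpnConfig, rng) -> TrainedEmpn:
    net = _init_net(config, rng)
    lr = config.learning_rate
    loss, grads = _loss_and_grads(net, X, y)
    history = [loss]
    for _ in range(config.max_epochs):
        trial = TrainedEmpn(
            W_in=net.W_in - lr * grads[0], W_ctx=net.W_ctx - lr * grads[1],
            W_out=net.W_out - lr * grads[2], b_h=net.b_h - lr * grads[3],
            b_o=net.b_o - lr * grads[4], config=config,
        )
        new_loss, new_grads = _loss_and_grads(trial, X, y)
        if not np.isfinite(new_loss):
            raise FloatingPointError("NaN loss during training")
        if new_loss <= loss:
            # accepted step: history stays nonincreasing
            net, loss, grads = trial, new_loss, new_grads
            history.append(loss)
            lr = min(lr * 1.2, 1e3 * config.learning_rate)
            if len(history) > 1 and history[-2] - history[-1] < config.tol:
                break
        else:
            lr *= 0.5
            if lr < 1e-12:
                break
    net.history = history
    return net


def pearson_r(obs, pred) -> float:
    """Pearson correlation pooled over all outputs; NaN if degenerate."""
    a = np.asarray(obs, dtype=float).ravel()
    b = np.asarray(pred, dtype=float).ravel()
    if a.size < 3:
        raise ValueError("need at least 3 samples")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        logger.warning("Pearson r undefined: zero variance")
        return np.nan
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def evaluate(net: TrainedEmpn, X, y) -> float:
    """Pooled Pearson r between observed and predicted scaled abundances."""
    return pearson_r(y, forward(net, X))


def train(dataset: TrainingTensor, config: EmpnConfig) -> TrainedEmpn:
    """Train with restarts; keep the restart with the best held-out Pearson r.

    The train/test split is by cells under the config seed.  Restarts whose
    loss goes NaN are aborted and logged; an error is raised only if every
    restart aborts.
    """
    rng = np.random.default_rng(config.seed)
    n = dataset.n_samples
    n_test = max(1, int(round(config.test_fraction * n)))
    perm = rng.permutation(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    if train_idx.size == 0:
        raise ValueError("no training samples left after the split")
    Xtr, ytr = dataset.X[train_idx], dataset.y[train_idx]
    Xte, yte = dataset.X[test_idx], dataset.y[test_idx]

    best, best_r, rs = None, -np.inf, []
    for k in range(config.restarts):
        try:
            net = _train_once(Xtr, ytr, config, rng)
        except FloatingPointError:
            logger.warning("restart %d aborted on NaN loss", k)
            rs.append(np.nan)
            continue
        r = evaluate(net, Xte, yte)
        rs.append(r)
        if np.isfinite(r) and r > best_r:
            best, best_r = net, r
    if best is None:
        raise RuntimeError("all restarts aborted")
    best.test_r = best_r
    best.restart_rs = rs
    best.x_scaler = dataset.x_scaler
    best.y_scaler = dataset.y_scaler
    return best


def predict_cohorts(net: TrainedEmpn, X_scaled: np.ndarray) -> np.ndarray:
    """Predicted cohort abundances on the original (individuals) scale."""
    out = forward(net, X_scaled)
    return net.y_scaler.inverse(out)


# ---------------------------------------------------------------------------
# Garson relative importance
# ---------------------------------------------------------------------------

def garson_ri(net: TrainedEmpn, groups: dict) -> dict:
    """Relative importance (percent, summing to 100) per input group.

    Per input i: sum over hidden h of (|w_ih| / sum_k |w_kh|) * sum_o |v_oh|;
    contributions are normalized to 100 and aggregated by ``groups`` (group
    name -> input indices).  All-zero input weights yield equal RI with a
    warning.
    """
    W = np.abs(net.W_in)          # (hidden, inputs)
    V = np.abs(net.W_out)         # (outputs, hidden)
    col = W.sum(axis=1)           # per hidden neuron
    n_in = W.shape[1]
    if W.sum() == 0:
        logger.warning("all input weights are zero; RI set equal across groups")
        contrib = np.full(n_in, 1.0 / n_in)
    else:
        share = np.divide(W, col[:, None], out=np.zeros_like(W),
                          where=col[:, None] > 0)
        contrib = (V.sum(axis=0)[:, None] * share).sum(axis=0)
        if contrib.sum() == 0:
            logger.warning("zero output weights; RI set equal across groups")
            contrib = np.full(n_in, 1.0 / n_in)
    contrib = contrib / contrib.sum()
    ri = {g: float(100.0 * contrib[list(idx)].sum()) for g, idx in groups.items()}
    return ri
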