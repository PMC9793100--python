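"""Multitask / single-task feed-forward networks in NumPy.

Architecture: a linear feature-embedding layer, two shared fully connected
hidden layers of 150 units (each affine -> batch-norm -> ReLU), then one
task-specific module per outcome (one 150-unit hidden layer with
batch-norm + ReLU) ending in a separate head — sigmoid for binary
outcomes, identity for numeric ones.  The single-task variant is the same
network with exactly one task.  Training is full-batch Adam on the summed
loss (binary cross-entropy per binary task plus ``mse_scale`` x mean
squared error per numeric task) with early stopping on an internal
validation slice, patience in epochs.

Implemented directly on NumPy arrays with manual backpropagation: the
models are small (a few hundred rows, <=534 inputs) and full-batch, so
explicit matrix code is both fast and exactly reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


class TrainingError(RuntimeError):
    """Loss became non-finite during training."""


@dataclass
class NetworkConfig:
    n_features: int
    task_specs: Sequence[tuple[str, str]]  # (name, "binary" | "numeric")
    hidden_units: int = 150
    n_shared_layers: int = 2
    max_epochs: int = 35
    patience: int = 1
    mse_scale: float = 1.0
    learning_rate: float = 1e-3
    val_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.hidden_units <= 0:
            raise ValueError("hidden_units must be positive")
        if not self.task_specs:
            raise ValueError("at least one task required")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.mse_scale < 0:
            raise ValueError("mse_scale must be >= 0")
        for _, kind in self.task_specs:
            if kind not in ("binary", "numeric"):
                raise ValueError(f"unknown task kind {kind!r}")

    @property
    def task_names(self) -> list[str]:
        return [n for n, _ in self.task_specs]


def _he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _bn_forward(x, gamma, beta, state, train):
    if train:
        n = x.shape[0]
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        state["mean"] = (1 - _BN_MOMENTUM) * state["mean"] + _BN_MOMENTUM * mu
        unbiased = var * (n / (n - 1)) if n > 1 else var
        state["var"] = (1 - _BN_MOMENTUM) * state["var"] + _BN_MOMENTUM * unbiased
        std = np.sqrt(var + _BN_EPS)
        xhat = (x - mu) / std
        return gamma * xhat + beta, (xhat, gamma, std)
    xhat = (x - state["mean"]) / np.sqrt(state["var"] + _BN_EPS)
    return gamma * xhat + beta, None


def _bn_backward(dy, cache):
    xhat, gamma, std = cache
    dgamma = (dy * xhat).sum(axis=0)
    dbeta = dy.sum(axis=0)
    dxhat = dy * gamma
    dx = (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)) / std
    return dx, dgamma, dbeta


def _sigmoid(z):
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))


class MultitaskNet:
    """Shared-trunk network with per-task modules and heads."""

    def __init__(self, cfg: NetworkConfig, multitask: bool = True):
        cfg.validate()
        if not multitask and len(cfg.task_specs) != 1:
            raise ValueError("single-task network requires exactly one task")
        self.cfg = cfg
        self.multitask = multitask
        H = cfg.hidden_units
        rng = np.random.default_rng(cfg.seed)
        P: dict[str, np.ndarray] = {}
        self.bn_state: dict[str, dict[str, np.ndarray]] = {}

        P["embed.W"] = _he_init(rng, cfg.n_features, H)
        P["embed.b"] = np.zeros(H)
        for l in range(cfg.n_shared_layers):
            P[f"shared{l}.W"] = _he_init(rng, H, H)
            P[f"shared{l}.b"] = np.zeros(H)
            P[f"shared{l}.gamma"] = np.ones(H)
            P[f"shared{l}.beta"] = np.zeros(H)
            self.bn_state[f"shared{l}"] = {"mean": np.zeros(H), "var": np.ones(H)}
        for name, _ in cfg.task_specs:
            P[f"task.{name}.W"] = _he_init(rng, H, H)
            P[f"task.{name}.b"] = np.zeros(H)
            P[f"task.{name}.gamma"] = np.ones(H)
            P[f"task.{name}.beta"] = np.zeros(H)
            self.bn_state[f"task.{name}"] = {"mean": np.zeros(H), "var": np.ones(H)}
            P[f"head.{name}.W"] = _he_init(rng, H, 1)
            P[f"head.{name}.b"] = np.zeros(1)
        self.params = P
        self.n_epochs_run = 0

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, train: bool):
        P = self.params
        cache: dict[str, object] = {"X": X}
        h = X @ P["embed.W"] + P["embed.b"]
        cache["embed.out"] = None  # input cached as X
        for l in range(self.cfg.n_shared_layers):
            cache[f"shared{l}.in"] = h
            pre = h @ P[f"shared{l}.W"] + P[f"shared{l}.b"]
            bn, bncache = _bn_forward(
                pre, P[f"shared{l}.gamma"], P[f"shared{l}.beta"],
                self.bn_state[f"shared{l}"], train,
            )
            cache[f"shared{l}.bn"] = bncache
            cache[f"shared{l}.mask"] = bn > 0
            h = np.maximum(bn, 0.0)
        cache["trunk.out"] = h
        logits: dict[str, np.ndarray] = {}
        for name, _ in self.cfg.task_specs:
            pre = h @ P[f"task.{name}.W"] + P[f"task.{name}.b"]
            bn, bncache = _bn_forward(
                pre, P[f"task.{name}.gamma"], P[f"task.{name}.beta"],
                self.bn_state[f"task.{name}"], train,
            )
            cache[f"task.{name}.bn"] = bncache
            cache[f"task.{name}.mask"] = bn > 0
            m = np.maximum(bn, 0.0)
            cache[f"task.{name}.hidden"] = m
            logits[name] = (m @ P[f"head.{name}.W"] + P[f"head.{name}.b"])[:, 0]
        return logits, cache

    def _loss_and_dlogits(self, logits, Y: dict[str, np.ndarray]):
        """Summed loss and gradient w.r.t. every head's logit."""
        total = 0.0
        dlogits: dict[str, np.ndarray] = {}
        for name, kind in self.cfg.task_specs:
            z = logits[name]
            y = Y[name]
            n = len(y)
            if kind == "binary":
                # numerically stable BCE-with-logits
                total += float(
                    np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
                )
                dlogits[name] = (_sigmoid(z) - y) / n
            else:
                resid = z - y
                total += self.cfg.mse_scale * float(np.mean(resid**2))
                dlogits[name] = self.cfg.mse_scale * 2.0 * resid / n
        return total, dlogits

    def _backward(self, cache, dlogits):
        P = self.params
        G = {k: np.zeros_like(v) for k, v in P.items()}
        dtrunk = np.zeros_like(cache["trunk.out"])
        for name, _ in self.cfg.task_specs:
            dz = dlogits[name][:, None]  # (n, 1)
            m = cache[f"task.{name}.hidden"]
            G[f"head.{name}.W"] = m.T @ dz
            G[f"head.{name}.b"] = dz.sum(axis=0)
            dm = dz @ P[f"head.{name}.W"].T
            dm = dm * cache[f"task.{name}.mask"]
            dpre, dgamma, dbeta = _bn_backward(dm, cache[f"task.{name}.bn"])
            G[f"task.{name}.gamma"] = dgamma
            G[f"task.{name}.beta"] = dbeta
            trunk = cache["trunk.out"]
            G[f"task.{name}.W"] = trunk.T @ dpre
            G[f"task.{name}.b"] = dpre.sum(axis=0)
            dtrunk += dpre @ P[f"task.{name}.W"].T
        dh = dtrunk
        for l in reversed(range(self.cfg.n_shared_layers)):
            dh = dh * cache[f"shared{l}.mask"]
            dpre, dgamma, dbeta = _bn_backward(dh, cache[f"shared{l}.bn"])
            G[f"shared{l}.gamma"] = dgamma
            G[f"shared{l}.beta"] = dbeta
            hin = cache[f"shared{l}.in"]
            G[f"shared{l}.W"] = hin.T @ dpre
            G[f"shared{l}.b"] = dpre.sum(axis=0)
            dh = dpre @ P[f"shared{l}.W"].T
        X = cache["X"]
        G["embed.W"] = X.T @ dh
        G["embed.b"] = dh.sum(axis=0)
        return G

    # -- training / inference ----------------------------------------------

    def fit(self, X: np.ndarray, Y: dict[str, np.ndarray]) -> "MultitaskNet":
        """Full-batch Adam with early stopping on a held-out validation slice.

        A ``val_fraction`` share of the rows (stratified on the any-positive
        indicator when binary tasks exist) is carved out to monitor the
        summed validation loss; training stops once it fails to improve for
        ``patience`` consecutive epochs and the best-epoch weights are
        restored.  Deterministic given ``cfg.seed``.
        """
        cfg = self.cfg
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("X contains missing values; impute upstream")
        Y = {k: np.asarray(v, dtype=float) for k, v in Y.items()}
        n = X.shape[0]
        rng = np.random.default_rng(cfg.seed + 1)

        n_val = max(1, int(round(cfg.val_fraction * n))) if n >= 5 else 0
        order = _stratified_order(rng, Y, cfg, n)
        val_idx, tr_idx = order[:n_val], order[n_val:]
        Xtr, Xval = X[tr_idx], X[val_idx]
        Ytr = {k: v[tr_idx] for k, v in Y.items()}
        Yval = {k: v[val_idx] for k, v in Y.items()}

        opt = _Adam(self.params, cfg.learning_rate)
        best_loss = np.inf
        best_params = None
        best_bn = None
        bad_epochs = 0
        for epoch in range(cfg.max_epochs):
            logits, cache = self._forward(Xtr, train=True)
            loss, dlogits = self._loss_and_dlogits(logits, Ytr)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            grads = self._backward(cache, dlogits)
            opt.step(self.params, grads)
            self.n_epochs_run = epoch + 1

            if n_val:
                vlogits, _ = self._forward(Xval, train=False)
                vloss, _ = self._loss_and_dlogits(vlogits, Yval)
            else:
                vloss = loss
            if vloss < best_loss - 1e-12:
                best_loss = vloss
                best_params = {k: v.copy() for k, v in self.params.items()}
                best_bn = {k: {kk: vv.copy() for kk, vv in s.items()}
                           for k, s in self.bn_state.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= cfg.patience:
                    break
        if best_params is not None:
            self.params = best_params
            self.bn_state = best_bn
        return self

    def predict(self, X: np.ndarray) -> dict[str, np.ndarray]:
        """Per-task scores: probabilities for binary, reals for numeric."""
        logits, _ = self._forward(np.asarray(X, dtype=float), train=False)
        out = {}
        for name, kind in self.cfg.task_specs:
            out[name] = _sigmoid(logits[name]) if kind == "binary" else logits[name]
        return out

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))


def _stratified_order(rng, Y, cfg, n) -> np.ndarray:
    """Shuffle rows so the head of the order is a stratified validation slice.

    Strata are the joint binary-label patterns, so every task's positives —
    including rare ones — are represented proportionally in the validation
    head; within each stratum the order is random, and strata are
    interleaved by largest remainder.
    """
    binary = [name for name, kind in cfg.task_specs if kind == "binary"]
    if not binary:
        return rng.permutation(n)
    patterns = np.zeros(n, dtype=int)
    for i, name in enumerate(binary):
        patterns += (np.asarray(Y[name]) > 0).astype(int) << i
    groups = [rng.permutation(np.flatnonzero(patterns == pat))
              for pat in np.unique(patterns)]
    # round-robin by fractional progress: each position takes the group
    # whose share is most under-represented so far
    taken = np.zeros(len(groups))
    sizes = np.array([len(g) for g in groups], dtype=float)
    order = np.empty(n, dtype=int)
    ptrs = [0] * len(groups)
    for pos in range(n):
        deficit = sizes / n * (pos + 1) - taken
        gi = int(np.argmax(np.where([ptrs[i] < len(groups[i])
                                     for i in range(len(groups))],
                                    deficit, -np.inf)))
        order[pos] = groups[gi][ptrs[gi]]
        ptrs[gi] += 1
        taken[gi] += 1
    return order


def build_network(cfg: NetworkConfig, multitask: bool = True) -> MultitaskNet:
    """Construct the (un-trained) multitask or single-task network."""
    return MultitaskNet(cfg, multitask=multitask)


def train(model: MultitaskNet, X, Y, cfg: NetworkConfig | None = None) -> MultitaskNet:
    """Train ``model`` in place; see :meth:`MultitaskNet.fit`."""
    return model.fit(X, Y)
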