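"""Comparison methods sharing one ``fit(pairs)`` / ``predict(pairs)`` contract.

Three reference methods commonly applied to telemetry regression, at the
standard capacities used for such comparisons, plus a persistence sanity
baseline:

* ``LSTMBaseline`` — a plain single-hidden-layer LSTM (default 100 units)
  reading the window step-wise; a linear head maps the final hidden state to
  the flattened target.  Trained with Adam on the target-only mean squared
  error (no reconstruction term), on the same autodiff tape as the main
  model.
* ``ANNBaseline`` — a dense network with one hidden layer (default 100
  units) on the flattened window, via scikit-learn's ``MLPRegressor``.
* ``RandomForestBaseline`` — one multi-output forest (default 200 trees) on
  the flattened window, via scikit-learn's ``RandomForestRegressor``.
* ``PersistencePredictor`` — repeats the last observed displacement row; no
  training.  Any sequence model worth its parameters must beat it.

All predictors consume :class:`~trackseq.geo.SegmentPair` lists and return
``(n, t_out, 2)`` arrays in physical units, so the evaluation harness is
method-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor

from .autodiff import Adam, Tensor
from .model import ModelConfig, ModelParams, _cell_tensors, _run_layer

__all__ = [
    "BaselineSpec",
    "LSTMBaseline",
    "ANNBaseline",
    "RandomForestBaseline",
    "PersistencePredictor",
    "make_baseline",
]


@dataclass(frozen=True)
class BaselineSpec:
    kind: Literal["lstm", "ann", "random_forest"]
    capacity: int  # hidden units (lstm/ann) or trees (random_forest)
    seed: int = 0

    def __post_init__(self):
        if self.capacity <= 0:
            raise ValueError("capacity must be positive")


def _stack_pairs(pairs):
    if not pairs:
        raise ValueError("no training pairs")
    X = np.stack([p.x for p in pairs]).astype(np.float64)
    Y = np.stack([p.y for p in pairs]).astype(np.float64)
    return X, Y


class _Normalizer:
    """Per-feature z-scoring shared by the sequence baselines."""

    def fit(self, X: np.ndarray) -> None:
        flat = X.reshape(-1, X.shape[-1])
        self.mean = flat.mean(axis=0)
        std = flat.std(axis=0)
        self.std = np.where(std > 0, std, 1.0)

    def x(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std

    def y(self, Y: np.ndarray) -> np.ndarray:
        return (Y - self.mean[:2]) / self.std[:2]

    def y_inv(self, Yn: np.ndarray) -> np.ndarray:
        return Yn * self.std[:2] + self.mean[:2]


class LSTMBaseline:
    """Single-layer LSTM, final state -> linear head, target-only MSE."""

    def __init__(self, t_in: int, t_out: int, n_features: int = 3, hidden_size: int = 100, seed: int = 0):
        self.t_in, self.t_out, self.n_features = t_in, t_out, n_features
        self.hidden_size = hidden_size
        self.seed = seed
        # reuse the model's parameter container: encoder stack only
        self._cfg = ModelConfig(t_in, t_out, n_features, hidden_size, n_layers=1, variant="DD")
        self.params = ModelParams(self._cfg, seed=seed)
        rng = np.random.default_rng(seed + 1)
        lim = np.sqrt(6.0 / (hidden_size + t_out * 2))
        self.params.tensors["out_W"] = Tensor(rng.uniform(-lim, lim, size=(hidden_size, t_out * 2)))
        self.params.tensors["out_b"] = Tensor(np.zeros(t_out * 2))
        self._train_keys = [k for k in self.params.tensors if k.startswith(("enc0_", "out_"))]
        self.norm = _Normalizer()
        self.history_: list[float] = []

    def _final_state(self, Xn: np.ndarray) -> Tensor:
        rows = [Tensor(Xn[:, t, :]) for t in range(Xn.shape[1])]
        hs = _run_layer(rows, _cell_tensors(self.params, "enc0"), self.hidden_size)
        return hs[-1]

    def fit(self, pairs, epochs: int = 100, lr: float = 1e-3, batch_size: int = 64,
            betas=(0.9, 0.999), shuffle_seed: int | None = None, **_):
        X, Y = _stack_pairs(pairs)
        self.norm.fit(X)
        Xn, Yn = self.norm.x(X), self.norm.y(Y).reshape(len(pairs), -1)
        trainable = {k: self.params.tensors[k] for k in self._train_keys}
        opt = Adam(trainable, lr=lr, betas=betas)
        rng = np.random.default_rng(self.seed if shuffle_seed is None else shuffle_seed)
        self.history_ = []
        n = len(pairs)
        for epoch in range(epochs):
            order = rng.permutation(n)
            total, n_batches = 0.0, 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                h = self._final_state(Xn[idx])
                pred = h @ self.params.tensors["out_W"] + self.params.tensors["out_b"]
                L = (pred - Tensor(Yn[idx])).square().sum().scale(1.0 / Yn[idx].size)
                if not np.isfinite(L.data):
                    raise FloatingPointError(f"baseline LSTM diverged at epoch {epoch}")
                opt.zero_grad()
                L.backward()
                opt.step()
                total += float(L.data)
                n_batches += 1
            self.history_.append(total / n_batches)
        return self

    def predict(self, pairs) -> np.ndarray:
        X = np.stack([p.x for p in pairs]).astype(np.float64)
        h = self._final_state(self.norm.x(X))
        pred = (h @ self.params.tensors["out_W"] + self.params.tensors["out_b"]).data
        return self.norm.y_inv(pred.reshape(len(pairs), self.t_out, 2))


class ANNBaseline:
    """One-hidden-layer dense network on the flattened window."""

    def __init__(self, t_in: int, t_out: int, n_features: int = 3, hidden_size: int = 100, seed: int = 0):
        self.t_in, self.t_out = t_in, t_out
        self.hidden_size = hidden_size
        self.seed = seed
        self.norm = _Normalizer()
        self._mlp: MLPRegressor | None = None
        self.history_: list[float] = []

    def fit(self, pairs, epochs: int = 100, lr: float = 1e-3, batch_size: int = 64, **_):
        X, Y = _stack_pairs(pairs)
        self.norm.fit(X)
        Xf = self.norm.x(X).reshape(len(pairs), -1)
        Yf = self.norm.y(Y).reshape(len(pairs), -1)
        self._mlp = MLPRegressor(
            hidden_layer_sizes=(self.hidden_size,),
            solver="adam",
            learning_rate_init=lr,
            batch_size=min(batch_size, len(pairs)),
            max_iter=epochs,
            random_state=self.seed,
        )
        import warnings
        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._mlp.fit(Xf, Yf)
        self.history_ = list(getattr(self._mlp, "loss_curve_", []))
        return self

    def predict(self, pairs) -> np.ndarray:
        X = np.stack([p.x for p in pairs]).astype(np.float64)
        pred = self._mlp.predict(self.norm.x(X).reshape(len(pairs), -1))
        return self.norm.y_inv(np.asarray(pred).reshape(len(pairs), self.t_out, 2))


class RandomForestBaseline:
    """One multi-output random forest on the flattened window."""

    def __init__(self, t_in: int, t_out: int, n_features: int = 3, n_trees: int = 200, seed: int = 0):
        self.t_in, self.t_out = t_in, t_out
        self.n_trees = n_trees
        self.seed = seed
        self._rf: RandomForestRegressor | None = None
        self.history_: list[float] = []

    def fit(self, pairs, **_):
        X, Y = _stack_pairs(pairs)
        self._rf = RandomForestRegressor(n_estimators=self.n_trees, random_state=self.seed, n_jobs=1)
        self._rf.fit(X.reshape(len(pairs), -1), Y.reshape(len(pairs), -1))
        return self

    def predict(self, pairs) -> np.ndarray:
        X = np.stack([p.x for p in pairs]).astype(np.float64)
        pred = self._rf.predict(X.reshape(len(pairs), -1))
        return np.asarray(pred).reshape(len(pairs), self.t_out, 2)


class PersistencePredictor:
    """Repeats the last observed ``(d cos theta, d sin theta)`` row."""

    def __init__(self, t_in: int, t_out: int, **_):
        self.t_out = t_out

    def fit(self, pairs, **_):
        return self

    def predict(self, pairs) -> np.ndarray:
        last = np.stack([p.x[-1, :2] for p in pairs]).astype(np.float64)
        return np.repeat(last[:, None, :], self.t_out, axis=1)


def make_baseline(kind: str, t_in: int, t_out: int, seed: int = 0, capacity: int | None = None):
    """Factory used by the harness and CLI (`lstm`, `ann`, `random_forest`,
    `persistence`)."""
    kind = kind.lower()
    if kind == "lstm":
        return LSTMBaseline(t_in, t_out, hidden_size=capacity or 100, seed=seed)
    if kind == "ann":
        return ANNBaseline(t_in, t_out, hidden_size=capacity or 100, seed=seed)
    if kind in ("random_forest", "rf"):
        return RandomForestBaseline(t_in, t_out, n_trees=capacity or 200, seed=seed)
    if kind == "persistence":
        return PersistencePredictor(t_in, t_out)
    raise ValueError(f"unknown baseline kind {kind!r}")
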