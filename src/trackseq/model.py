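"""Attention dual-decoder LSTM autoencoder for step-feature sequences.

The network couples unsupervised and supervised learning on telemetry
segments: a stacked LSTM encoder reads the input window, a dot-product
attention module summarises the encoder's hidden states into a context of
length ``2M``, and two parallel stacked LSTM decoders consume that context —
the first reconstructs the input window (autoencoding, which shapes the
representation), the second emits the prediction or imputation target.
Linear heads map final-layer decoder states to the 3 input features
(reconstruction) and the 2 displacement outputs respectively.

Cell equations (logistic-sigmoid gates, tanh candidate):

    f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)
    i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)
    o_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)
    C~_t = tanh(W_C [h_{t-1}, x_t] + b_C)
    C_t = f_t * C_{t-1} + i_t * C~_t
    h_t = o_t * tanh(C_t)

Attention over final-layer encoder states ``hen`` with last state ``hl``:

    h_bar = affine(hen)            (one map shared across time steps)
    aw    = softmax_t(hl . h_bar_t)
    av    = aw^T h_bar
    ha    = affine([av, hl])       (length 2M)

Variants: ``"ATDD"`` uses the attention context; ``"DD"`` bypasses attention
and feeds ``[hl, hl]`` to the decoders.  The decoders receive the context
vector repeated at every time step (repeat-vector convention); there is no
teacher forcing.

All arithmetic runs on the package's reverse-mode tape
(:mod:`trackseq.autodiff`) in float64, so the same code path serves the
public single-segment operations, batched training, and gradient checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .autodiff import Adam, Tensor, concat

Variant = Literal["ATDD", "DD"]

__all__ = [
    "ModelConfig",
    "ModelParams",
    "LSTMStep",
    "EncoderState",
    "AttentionResult",
    "DecoderOutputs",
    "lstm_cell_step",
    "encode",
    "attend",
    "decode",
    "forward",
    "loss",
    "TrajectoryAutoencoder",
]


@dataclass(frozen=True)
class ModelConfig:
    """Dimensions and variant of the network.

    ``hidden_size`` (M) and ``n_layers`` (K) default to 64 and 1 — a small
    single-layer configuration suited to windows of a few to a few dozen
    steps.
    """

    t_in: int
    t_out: int
    n_features: int = 3
    hidden_size: int = 64
    n_layers: int = 1
    variant: Variant = "ATDD"


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class ModelParams:
    """All learnable weights as a flat ``{name: Tensor}`` dict.

    LSTM weights are stored for right-multiplication: a gate pre-activation
    is ``[h_{t-1}, x_t] @ W + b`` with ``W`` of shape
    ``(M + input_width, M)``.  Per-layer cell parameters live under prefixes
    ``enc{k}``, ``dec1_{k}``, ``dec2_{k}`` (k = 0-based layer); attention
    weights under ``att_*``; the two output heads under ``head1``/``head2``.
    """

    GATES = ("Wf", "Wi", "Wo", "Wc", "bf", "bi", "bo", "bc")

    def __init__(self, config: ModelConfig, seed: int = 0, init: str = "glorot"):
        self.config = config
        M, F, K = config.hidden_size, config.n_features, config.n_layers
        rng = np.random.default_rng(seed)
        t: dict[str, Tensor] = {}

        def add_cell(prefix: str, input_width: int) -> None:
            for g in ("Wf", "Wi", "Wo", "Wc"):
                w = (
                    _glorot(rng, M + input_width, M)
                    if init == "glorot"
                    else np.zeros((M + input_width, M))
                )
                t[f"{prefix}_{g}"] = Tensor(w)
            for g in ("bf", "bi", "bo", "bc"):
                t[f"{prefix}_{g}"] = Tensor(np.zeros(M))

        for k in range(K):
            add_cell(f"enc{k}", F if k == 0 else M)
        t["att_Wh"] = Tensor(_glorot(rng, M, M) if init == "glorot" else np.zeros((M, M)))
        t["att_bh"] = Tensor(np.zeros(M))
        t["att_Wo"] = Tensor(_glorot(rng, 2 * M, 2 * M) if init == "glorot" else np.zeros((2 * M, 2 * M)))
        t["att_bo"] = Tensor(np.zeros(2 * M))
        for d in (1, 2):
            for k in range(K):
                add_cell(f"dec{d}_{k}", 2 * M if k == 0 else M)
        t["head1_W"] = Tensor(_glorot(rng, M, F) if init == "glorot" else np.zeros((M, F)))
        t["head1_b"] = Tensor(np.zeros(F))
        t["head2_W"] = Tensor(_glorot(rng, M, 2) if init == "glorot" else np.zeros((M, 2)))
        t["head2_b"] = Tensor(np.zeros(2))
        self.tensors = t

    @classmethod
    def zeros(cls, config: ModelConfig) -> "ModelParams":
        return cls(config, seed=0, init="zeros")

    def n_parameters(self) -> int:
        return int(sum(v.data.size for v in self.tensors.values()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.tensors.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.tensors[k].data = np.asarray(v, dtype=np.float64)


# ---------------------------------------------------------------------------
# result containers (single-segment public API)


@dataclass
class LSTMStep:
    f: np.ndarray
    i: np.ndarray
    o: np.ndarray
    c_tilde: np.ndarray
    c: np.ndarray
    h: np.ndarray


@dataclass
class EncoderState:
    hen: list[np.ndarray]  # per layer, T x M
    hl: np.ndarray  # last row of the final layer


@dataclass
class AttentionResult:
    h_bar: np.ndarray  # T x M
    aw: np.ndarray  # T
    av: np.ndarray  # M
    ha: np.ndarray  # 2M


@dataclass
class DecoderOutputs:
    hd1: np.ndarray  # T_rec x M
    hd2: np.ndarray  # T_out x M
    x_hat: np.ndarray  # T_rec x F
    y_hat: np.ndarray  # T_out x 2


# ---------------------------------------------------------------------------
# tape-level building blocks (batched: leading dim B)


def _cell_tensors(params: ModelParams, prefix: str) -> tuple[Tensor, ...]:
    t = params.tensors
    return tuple(t[f"{prefix}_{g}"] for g in ModelParams.GATES)


def _cell_step_t(
    x_t: Tensor, h_prev: Tensor, c_prev: Tensor, cell: tuple[Tensor, ...]
) -> tuple[Tensor, Tensor, Tensor, Tensor, Tensor, Tensor]:
    Wf, Wi, Wo, Wc, bf, bi, bo, bc = cell
    z = concat([h_prev, x_t], axis=1)
    f = (z @ Wf + bf).sigmoid()
    i = (z @ Wi + bi).sigmoid()
    o = (z @ Wo + bo).sigmoid()
    c_tilde = (z @ Wc + bc).tanh()
    c = f * c_prev + i * c_tilde
    h = o * c.tanh()
    return f, i, o, c_tilde, c, h


def _run_layer(inputs: Sequence[Tensor], cell: tuple[Tensor, ...], M: int) -> list[Tensor]:
    B = inputs[0].shape[0]
    h = Tensor(np.zeros((B, M)))
    c = Tensor(np.zeros((B, M)))
    out = []
    for x_t in inputs:
        *_, c, h = _cell_step_t(x_t, h, c, cell)
        out.append(h)
    return out


def _encode_t(x_rows: Sequence[Tensor], params: ModelParams) -> list[list[Tensor]]:
    cfg = params.config
    layers: list[list[Tensor]] = []
    inputs = list(x_rows)
    for k in range(cfg.n_layers):
        inputs = _run_layer(inputs, _cell_tensors(params, f"enc{k}"), cfg.hidden_size)
        layers.append(inputs)
    return layers


def _attend_t(
    hen_K: Sequence[Tensor], hl: Tensor, params: ModelParams
) -> tuple[list[Tensor], Tensor, Tensor, Tensor]:
    t = params.tensors
    h_bar = [h @ t["att_Wh"] + t["att_bh"] for h in hen_K]
    scores = concat([(hb * hl).sum(axis=1, keepdims=True) for hb in h_bar], axis=1)  # B x T
    aw = scores.softmax(axis=1)
    T = len(h_bar)
    av = None
    for ti in range(T):
        term = aw.cols(ti, ti + 1) * h_bar[ti]
        av = term if av is None else av + term
    ha = concat([av, hl], axis=1) @ t["att_Wo"] + t["att_bo"]
    return h_bar, aw, av, ha


def _decode_t(ha: Tensor, t_steps: int, params: ModelParams, which: int) -> list[Tensor]:
    cfg = params.config
    inputs: Sequence[Tensor] = [ha] * t_steps  # context repeated at each step
    for k in range(cfg.n_layers):
        inputs = _run_layer(inputs, _cell_tensors(params, f"dec{which}_{k}"), cfg.hidden_size)
    return list(inputs)


def _forward_t(
    x_rows: Sequence[Tensor], t_out: int, params: ModelParams, variant: Variant
) -> tuple[list[Tensor], list[Tensor], list[Tensor], list[Tensor]]:
    t = params.tensors
    layers = _encode_t(x_rows, params)
    hen_K = layers[-1]
    hl = hen_K[-1]
    if variant == "ATDD":
        _, _, _, ha = _attend_t(hen_K, hl, params)
    elif variant == "DD":
        ha = concat([hl, hl], axis=1)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    hd1 = _decode_t(ha, len(x_rows), params, which=1)
    hd2 = _decode_t(ha, t_out, params, which=2)
    x_hat = [h @ t["head1_W"] + t["head1_b"] for h in hd1]
    y_hat = [h @ t["head2_W"] + t["head2_b"] for h in hd2]
    return hd1, hd2, x_hat, y_hat


def _loss_t(
    x_rows: Sequence[Tensor],
    x_hat: Sequence[Tensor],
    y_rows: Sequence[Tensor],
    y_hat: Sequence[Tensor],
    reduction: str = "sum",
) -> Tensor:
    total = None
    n_elems = 0
    for target, pred in zip(list(x_rows) + list(y_rows), list(x_hat) + list(y_hat)):
        term = (target - pred).square().sum()
        total = term if total is None else total + term
        n_elems += int(np.prod(target.shape))
    if reduction == "mean":
        total = total.scale(1.0 / n_elems)
    elif reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    return total


# ---------------------------------------------------------------------------
# public single-segment operations


def _rows(x: np.ndarray) -> list[Tensor]:
    x = np.asarray(x, dtype=np.float64)
    return [Tensor(x[t][None, :]) for t in range(x.shape[0])]


def lstm_cell_step(x_t, h_prev, c_prev, params: ModelParams, prefix: str = "enc0") -> LSTMStep:
    """One cell update; returns all gate activations and the new states."""
    for name, v in (("x_t", x_t), ("h_prev", h_prev), ("c_prev", c_prev)):
        if not np.all(np.isfinite(np.asarray(v, dtype=np.float64))):
            raise ValueError(f"{name} must be finite")
    xt = Tensor(np.atleast_1d(np.asarray(x_t, dtype=np.float64))[None, :])
    h = Tensor(np.atleast_1d(np.asarray(h_prev, dtype=np.float64))[None, :])
    c = Tensor(np.atleast_1d(np.asarray(c_prev, dtype=np.float64))[None, :])
    f, i, o, c_tilde, c_new, h_new = _cell_step_t(xt, h, c, _cell_tensors(params, prefix))
    return LSTMStep(
        f=f.data[0], i=i.data[0], o=o.data[0], c_tilde=c_tilde.data[0], c=c_new.data[0], h=h_new.data[0]
    )


def encode(x: np.ndarray, params: ModelParams) -> EncoderState:
    """Run the stacked encoder over a ``T x F`` window."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    if x.ndim != 2 or x.shape[1] != params.config.n_features:
        raise ValueError(f"x must be T x {params.config.n_features}")
    layers = _encode_t(_rows(x), params)
    hen = [np.vstack([h.data for h in layer]) for layer in layers]
    return EncoderState(hen=hen, hl=hen[-1][-1].copy())


def attend(hen_K: np.ndarray, hl: np.ndarray, params: ModelParams) -> AttentionResult:
    """Dot-product attention of ``hl`` over the rows of ``hen_K``."""
    hen_K = np.asarray(hen_K, dtype=np.float64)
    rows = [Tensor(r[None, :]) for r in hen_K]
    hl_t = Tensor(np.asarray(hl, dtype=np.float64)[None, :])
    h_bar, aw, av, ha = _attend_t(rows, hl_t, params)
    return AttentionResult(
        h_bar=np.vstack([h.data for h in h_bar]),
        aw=aw.data[0],
        av=av.data[0],
        ha=ha.data[0],
    )


def decode(ha: np.ndarray, t_steps: int, params: ModelParams, which: int = 1) -> np.ndarray:
    """Unroll one decoder stack for ``t_steps`` steps on context ``ha``."""
    if t_steps < 1:
        raise ValueError("t_steps must be >= 1")
    ha_t = Tensor(np.asarray(ha, dtype=np.float64)[None, :])
    states = _decode_t(ha_t, t_steps, params, which)
    return np.vstack([h.data for h in states])


def forward(x: np.ndarray, t_out: int, params: ModelParams, variant: Variant | None = None) -> DecoderOutputs:
    """Full forward pass on one ``T x F`` window."""
    variant = variant or params.config.variant
    x = np.asarray(x, dtype=np.float64)
    hd1, hd2, x_hat, y_hat = _forward_t(_rows(x), t_out, params, variant)
    return DecoderOutputs(
        hd1=np.vstack([h.data for h in hd1]),
        hd2=np.vstack([h.data for h in hd2]),
        x_hat=np.vstack([h.data for h in x_hat]),
        y_hat=np.vstack([h.data for h in y_hat]),
    )


def loss(x, x_hat, y, y_hat, reduction: str = "sum") -> float:
    """Joint squared-error objective over one segment or a batch.

    ``sum``: the literal sum over all reconstruction and output residuals of
    all segments.  ``mean``: the same divided by the total element count
    (the variant used for training stability).
    """
    x, x_hat = np.asarray(x, dtype=np.float64), np.asarray(x_hat, dtype=np.float64)
    y, y_hat = np.asarray(y, dtype=np.float64), np.asarray(y_hat, dtype=np.float64)
    if x.shape != x_hat.shape or y.shape != y_hat.shape:
        raise ValueError("shape mismatch between targets and outputs")
    total = np.sum((x - x_hat) ** 2) + np.sum((y - y_hat) ** 2)
    if reduction == "mean":
        total /= x.size + y.size
    elif reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    return float(total)


# ---------------------------------------------------------------------------
# estimator


class TrajectoryAutoencoder:
    """Scikit-learn-style estimator wrapping the network.

    Features are z-scored per training split; the statistics are stored on
    the estimator (and in checkpoints) so predictions come back in physical
    units.  The target columns share the statistics of feature columns 0–1,
    which they are copies of.
    """

    def __init__(
        self,
        t_in: int,
        t_out: int,
        n_features: int = 3,
        hidden_size: int = 64,
        n_layers: int = 1,
        variant: Variant = "ATDD",
        seed: int = 0,
    ):
        self.config = ModelConfig(t_in, t_out, n_features, hidden_size, n_layers, variant)
        self.seed = seed
        self.params = ModelParams(self.config, seed=seed)
        self.norm_mean = np.zeros(n_features)
        self.norm_std = np.ones(n_features)
        self.history_: list[float] = []

    # -- data plumbing -----------------------------------------------------

    def _stack(self, pairs) -> tuple[np.ndarray, np.ndarray]:
        X = np.stack([p.x for p in pairs]).astype(np.float64)
        Y = np.stack([p.y for p in pairs]).astype(np.float64)
        if X.shape[1:] != (self.config.t_in, self.config.n_features):
            raise ValueError(
                f"pairs have x shape {X.shape[1:]}, model expects "
                f"({self.config.t_in}, {self.config.n_features})"
            )
        return X, Y

    def _normalize(self, X: np.ndarray, Y: np.ndarray | None = None):
        Xn = (X - self.norm_mean) / self.norm_std
        if Y is None:
            return Xn
        Yn = (Y - self.norm_mean[:2]) / self.norm_std[:2]
        return Xn, Yn

    def _denormalize_y(self, Yn: np.ndarray) -> np.ndarray:
        return Yn * self.norm_std[:2] + self.norm_mean[:2]

    # -- training / inference ---------------------------------------------

    def fit(
        self,
        pairs,
        epochs: int = 100,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        batch_size: int = 64,
        reduction: str = "mean",
        shuffle_seed: int | None = None,
        callback=None,
    ) -> "TrajectoryAutoencoder":
        if not pairs:
            raise ValueError("no training pairs")
        X, Y = self._stack(pairs)
        self.norm_mean = X.reshape(-1, X.shape[-1]).mean(axis=0)
        std = X.reshape(-1, X.shape[-1]).std(axis=0)
        self.norm_std = np.where(std > 0, std, 1.0)
        Xn, Yn = self._normalize(X, Y)

        opt = Adam(self.params.tensors, lr=lr, betas=betas)
        rng = np.random.default_rng(self.seed if shuffle_seed is None else shuffle_seed)
        n = len(pairs)
        self.history_ = []
        for epoch in range(epochs):
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = Xn[idx], Yn[idx]
                x_rows = [Tensor(xb[:, t, :]) for t in range(xb.shape[1])]
                y_rows = [Tensor(yb[:, t, :]) for t in range(yb.shape[1])]
                _, _, x_hat, y_hat = _forward_t(x_rows, yb.shape[1], self.params, self.config.variant)
                L = _loss_t(x_rows, x_hat, y_rows, y_hat, reduction=reduction)
                if not np.isfinite(L.data):
                    raise FloatingPointError(f"training diverged at epoch {epoch}: loss={L.data}")
                opt.zero_grad()
                L.backward()
                opt.step()
                epoch_loss += float(L.data)
                n_batches += 1
            self.history_.append(epoch_loss / n_batches)
            if callback is not None:
                callback(epoch, self.history_[-1])
        return self

    def predict(self, pairs) -> np.ndarray:
        """Predicted ``(d cos theta, d sin theta)`` in physical units,
        shape ``(n_segments, t_out, 2)``."""
        X = np.stack([p.x for p in pairs]).astype(np.float64)
        Xn = self._normalize(X)
        x_rows = [Tensor(Xn[:, t, :]) for t in range(Xn.shape[1])]
        _, _, _, y_hat = _forward_t(x_rows, self.config.t_out, self.params, self.config.variant)
        Yn = np.stack([h.data for h in y_hat], axis=1)
        return self._denormalize_y(Yn)

    # -- persistence -------------------------------------------------------

    SCHEMA = "trackseq-checkpoint-1"

    def save(self, path) -> None:
        meta = {
            "schema": self.SCHEMA,
            "kind": "autoencoder",
            "config": vars(self.config).copy()
            if not hasattr(self.config, "__dataclass_fields__")
            else {k: getattr(self.config, k) for k in self.config.__dataclass_fields__},
            "seed": self.seed,
        }
        arrays = {f"param::{k}": v for k, v in self.params.state_dict().items()}
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            norm_mean=self.norm_mean,
            norm_std=self.norm_std,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "TrajectoryAutoencoder":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            if meta.get("schema") != cls.SCHEMA:
                raise ValueError(f"unknown checkpoint schema {meta.get('schema')!r}")
            cfg = meta["config"]
            est = cls(
                t_in=cfg["t_in"],
                t_out=cfg["t_out"],
                n_features=cfg["n_features"],
                hidden_size=cfg["hidden_size"],
                n_layers=cfg["n_layers"],
                variant=cfg["variant"],
                seed=meta["seed"],
            )
            est.norm_mean = z["norm_mean"]
            est.norm_std = z["norm_std"]
            est.params.load_state_dict(
                {k.removeprefix("param::"): z[k] for k in z.files if k.startswith("param::")}
            )
        return est
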