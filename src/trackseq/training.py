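"""Training loop, error metrics, data-splitting cases, and the results harness.

Three evaluation designs are supported, matching standard practice for
multi-individual telemetry:

``one_seal``
    Each individual is its own experiment: its segment sequence is split
    temporally (default 80% train / 20% test, the earlier part training).
``five_seals``
    Individuals are partitioned (seeded) into groups of five; within a
    group each individual is held out once while the other four train the
    model, and results are averaged over the five runs — individuals never
    contribute to both sides of a split.
``all_seals``
    Segments from all individuals are pooled, shuffled with a seed, and
    split 50/50.

Errors are mean absolute error (MAE) and root mean square error (RMSE) over
both displacement output columns jointly, in physical units (km).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .geo import (
    RawTrack,
    SegmentPair,
    featurize,
    make_imputation_pair,
    make_prediction_pair,
    slide_segments,
)

__all__ = [
    "mae",
    "rmse",
    "parse_subcase",
    "build_pairs",
    "ExperimentCase",
    "TrainConfig",
    "split_case",
    "iter_folds",
    "train",
    "run_experiment",
    "MetricsTable",
]

Mode = Literal["prediction", "imputation"]
CaseName = Literal["one_seal", "five_seals", "all_seals"]


def mae(pred: np.ndarray, truth: np.ndarray) -> float:
    pred, truth = np.asarray(pred, dtype=np.float64), np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return float(np.mean(np.abs(pred - truth)))


def rmse(pred: np.ndarray, truth: np.ndarray) -> float:
    pred, truth = np.asarray(pred, dtype=np.float64), np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


_SUBCASE_RE = re.compile(r"^T(\d+)P(\d+)$")


def parse_subcase(label: str, mode: Mode) -> tuple[int, int]:
    """Parse a ``T<a>P<b>`` label into (t_in, t_out).

    For imputation the two lengths must match (interleaved layout).
    """
    m = _SUBCASE_RE.match(label.strip())
    if not m:
        raise ValueError(f"bad subcase label {label!r}; expected e.g. 'T7P1'")
    a, b = int(m.group(1)), int(m.group(2))
    if a < 1 or b < 1:
        raise ValueError("subcase lengths must be >= 1")
    if mode == "imputation" and a != b:
        raise ValueError(f"imputation subcase needs equal lengths, got {label}")
    return a, b


def build_pairs(
    tracks: Sequence[RawTrack],
    t_in: int,
    t_out: int,
    mode: Mode = "prediction",
    stride: int = 1,
    convention: str = "bearing",
) -> list[SegmentPair]:
    """Featurize tracks and slice every sliding window into a supervised
    pair, tagged with its individual and window start for split provenance."""
    window = t_in + t_out
    pairs: list[SegmentPair] = []
    for track in tracks:
        series = featurize(track, convention=convention)
        for w_idx, win in enumerate(slide_segments(series, window, stride)):
            meta = {"individual_id": track.individual_id, "window_start": w_idx * stride}
            if mode == "prediction":
                pairs.append(make_prediction_pair(win, t_in, t_out, **meta))
            else:
                pairs.append(make_imputation_pair(win, t_in, **meta))
    return pairs


@dataclass
class ExperimentCase:
    case: CaseName
    subcase: str | None = None  # set per run; run_experiment fills it per subcase
    mode: Mode = "prediction"
    split_fraction: float = 0.8
    seed: int = 0
    stride: int = 1

    def __post_init__(self):
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must be in (0, 1)")
        if self.subcase is not None:
            parse_subcase(self.subcase, self.mode)  # validate early

    def _layout(self) -> tuple[int, int]:
        if self.subcase is None:
            raise ValueError("ExperimentCase has no subcase set")
        return parse_subcase(self.subcase, self.mode)

    @property
    def t_in(self) -> int:
        return self._layout()[0]

    @property
    def t_out(self) -> int:
        return self._layout()[1]


def _group_by_id(pairs: Sequence[SegmentPair]) -> dict[str, list[SegmentPair]]:
    by: dict[str, list[SegmentPair]] = {}
    for p in pairs:
        by.setdefault(p.individual_id, []).append(p)
    return by


def iter_folds(
    tracks: Sequence[RawTrack], case: ExperimentCase
) -> Iterable[tuple[list[SegmentPair], list[SegmentPair], dict]]:
    """Yield (train_pairs, test_pairs, meta) folds for the case.

    one_seal: one fold per individual (temporal split).  five_seals: seeded
    groups of five individuals, one leave-one-individual-out fold per group
    member.  all_seals: a single pooled shuffled 50/50 fold.
    """
    pairs = build_pairs(tracks, case.t_in, case.t_out, case.mode, case.stride)
    by_id = _group_by_id(pairs)
    ids = sorted(by_id)

    if case.case == "one_seal":
        if len(ids) < 1:
            raise ValueError("one_seal needs at least one track")
        for ind in ids:
            segs = by_id[ind]  # already in temporal order per track
            cut = int(np.floor(case.split_fraction * len(segs)))
            if cut == 0 or cut == len(segs):
                continue
            yield segs[:cut], segs[cut:], {"individual": ind}
    elif case.case == "five_seals":
        if len(ids) < 5:
            raise ValueError("five_seals needs at least 5 tracks")
        rng = np.random.default_rng(case.seed)
        order = [ids[i] for i in rng.permutation(len(ids))]
        n_groups = len(order) // 5
        for g in range(n_groups):
            group = order[g * 5 : (g + 1) * 5]
            for holdout in group:
                train = [p for ind in group if ind != holdout for p in by_id[ind]]
                yield train, list(by_id[holdout]), {"group": g, "holdout": holdout}
    elif case.case == "all_seals":
        if len(ids) < 2:
            raise ValueError("all_seals needs at least 2 tracks")
        rng = np.random.default_rng(case.seed)
        order = rng.permutation(len(pairs))
        cut = len(pairs) // 2
        shuffled = [pairs[i] for i in order]
        yield shuffled[:cut], shuffled[cut:], {"n_segments": len(pairs)}
    else:
        raise ValueError(f"unknown case {case.case!r}")


def split_case(
    tracks: Sequence[RawTrack], case: ExperimentCase
) -> tuple[list[SegmentPair], list[SegmentPair]]:
    """The case's canonical single split.

    one_seal pools the per-individual temporal splits; five_seals returns
    the first leave-one-out fold of the first seeded group (test segments
    come from exactly one individual); all_seals is its single pooled fold.
    """
    folds = list(iter_folds(tracks, case))
    if not folds:
        raise ValueError("no usable folds (too few segments per track?)")
    if case.case == "one_seal":
        train = [p for tr, _, _ in folds for p in tr]
        test = [p for _, te, _ in folds for p in te]
        return train, test
    train, test, _ = folds[0]
    return train, test


@dataclass
class TrainConfig:
    epochs: int = 100
    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 64
    seed: int = 0
    reduction: str = "mean"


def train(model, pairs: Sequence[SegmentPair], config: TrainConfig | None = None):
    """Fit any predictor exposing ``fit(pairs, ...)`` and return
    ``(model, history)`` where history is the per-epoch training loss
    (empty for non-iterative methods)."""
    if not pairs:
        raise ValueError("no training pairs")
    config = config or TrainConfig()
    model.fit(
        list(pairs),
        epochs=config.epochs,
        lr=config.lr,
        batch_size=config.batch_size,
        betas=config.betas,
        shuffle_seed=config.seed,
    )
    return model, list(getattr(model, "history_", []))


@dataclass
class MetricsTable:
    """MAE/RMSE per (subcase x method), plus run metadata.

    ``frame`` has one row per subcase and a two-level column index
    (method, metric).
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def cell(self, subcase: str, method: str) -> tuple[float, float]:
        return (
            float(self.frame.loc[subcase, (method, "MAE")]),
            float(self.frame.loc[subcase, (method, "RMSE")]),
        )

    def percent_reduction(self, reference: str = "LSTM-AE-ATDD") -> pd.DataFrame:
        """Percent by which ``reference``'s errors undercut each other
        method's, per subcase: ``100 * (other - ref) / other``."""
        out = {}
        for method in self.frame.columns.levels[0]:
            if method == reference:
                continue
            for metric in ("MAE", "RMSE"):
                other = self.frame[(method, metric)]
                ref = self.frame[(reference, metric)]
                out[f"{metric}_reduction_vs_{method}_pct"] = 100.0 * (other - ref) / other
        return pd.DataFrame(out, index=self.frame.index)

    def to_csv(self, path) -> None:
        flat = self.frame.copy()
        flat.columns = [f"{m}_{metric}" for m, metric in flat.columns]
        flat.index.name = "subcase"
        flat.to_csv(path)


def _default_methods(t_in: int, t_out: int, seed: int) -> dict[str, Callable[[], object]]:
    from .baselines import make_baseline
    from .model import TrajectoryAutoencoder

    return {
        "LSTM-AE-ATDD": lambda: TrajectoryAutoencoder(t_in, t_out, variant="ATDD", seed=seed),
        "LSTM-AE-DD": lambda: TrajectoryAutoencoder(t_in, t_out, variant="DD", seed=seed),
        "LSTM": lambda: make_baseline("lstm", t_in, t_out, seed=seed),
        "ANN": lambda: make_baseline("ann", t_in, t_out, seed=seed),
        "RF": lambda: make_baseline("random_forest", t_in, t_out, seed=seed),
    }


def run_experiment(
    tracks: Sequence[RawTrack],
    case: ExperimentCase | str,
    subcases: Sequence[str],
    methods: Sequence[str] | dict[str, Callable[[], object]] | None = None,
    train_config: TrainConfig | None = None,
    mode: Mode | None = None,
) -> MetricsTable:
    """Fill the (subcase x method) error table for one evaluation case.

    Fold errors are averaged with equal weight per fold (i.e. per
    individual, not per segment).  Methods may be a list of names from the
    default registry or a mapping of name -> zero-arg factory.
    """
    train_config = train_config or TrainConfig()
    if isinstance(case, str):
        case = ExperimentCase(case=case, mode=mode or "prediction", seed=train_config.seed)
    records: dict[str, dict[tuple[str, str], float]] = {}
    for subcase in subcases:
        t_in, t_out = parse_subcase(subcase, case.mode)
        sub = ExperimentCase(
            case=case.case,
            subcase=subcase,
            mode=case.mode,
            split_fraction=case.split_fraction,
            seed=case.seed,
            stride=case.stride,
        )
        if methods is None or isinstance(methods, (list, tuple)):
            registry = _default_methods(t_in, t_out, train_config.seed)
            if methods is not None:
                registry = {k: registry[k] for k in methods}
        else:
            registry = dict(methods)
        cells: dict[tuple[str, str], list[float]] = {}
        for train_pairs, test_pairs, _meta in iter_folds(tracks, sub):
            truth = np.stack([p.y for p in test_pairs])
            for name in sorted(registry):  # evaluation order must not matter
                model, _ = train(registry[name](), train_pairs, train_config)
                pred = model.predict(test_pairs)
                cells.setdefault((name, "MAE"), []).append(mae(pred, truth))
                cells.setdefault((name, "RMSE"), []).append(rmse(pred, truth))
        records[subcase] = {k: float(np.mean(v)) for k, v in cells.items()}
    frame = pd.DataFrame.from_dict(records, orient="index")
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    frame = frame.sort_index(axis=1)
    meta = {
        "case": case.case,
        "mode": case.mode,
        "seed": train_config.seed,
        "epochs": train_config.epochs,
        "n_tracks": len(tracks),
    }
    return MetricsTable(frame=frame.loc[list(subcases)], metadata=meta)
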