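# trackseq

Trajectory **prediction** and **imputation** for marine-animal satellite
telemetry, built around an attention dual-decoder LSTM autoencoder.

Animal-borne tags produce long sequences of fixes — individual, time,
longitude, latitude — and two questions come up constantly in movement
ecology: where will the animal be at the next fix(es), and what happened
during the gaps? `trackseq` is for researchers who want a sequence model
for both tasks plus everything needed around it: geodesic feature
engineering, segment layouts, reference baselines, an evaluation harness,
and a seeded movement simulator so the whole pipeline runs and benchmarks
offline, without any particular field dataset.

## The model

Tracks are converted to step features: per step, great-circle length `d_t`
(haversine, km) and movement angle `θ_t` (forward azimuth by default, so
that `(d_t cos θ_t, d_t sin θ_t)` are north/east displacement components
and predictions invert back to positions by dead reckoning). The model
input is the window `x ∈ R^{T×3}` of rows `(d_t cos θ_t, d_t sin θ_t, θ_t)`;
the output is the next (or missing) displacement rows `ŷ ∈ R^{T_out×2}`.

The network couples unsupervised and supervised learning:

* a stacked **LSTM encoder** reads `x`, producing hidden states
  `hen ∈ R^{T×M}` with last state `hl`;
* **dot-product attention**: `h̄ = affine(hen)`,
  `aw = softmax_t(hl·h̄_t)`, `av = awᵀh̄`, context `ha = affine([av, hl])`
  of length `2M`;
* two parallel **LSTM decoders** consume `ha` (repeated at each step):
  decoder 1 reconstructs the input (`x̂`, autoencoding — it forces the
  representation to carry the whole window), decoder 2 emits the
  prediction or imputation (`ŷ`);
* joint objective `L = Σ_j (x⁽ʲ⁾−x̂⁽ʲ⁾)² + (y⁽ʲ⁾−ŷ⁽ʲ⁾)²`, minimized with
  Adam.

The full model is called **ATDD**; **DD** drops attention and feeds
`[hl, hl]` to the decoders. Baselines with the conventional capacities —
plain 100-unit LSTM, 100-unit one-hidden-layer ANN, 200-tree random
forest, and a persistence predictor — share one `fit`/`predict` contract.
Everything runs in float64 on a small built-in reverse-mode tape; forward
passes are verified against hand-unrolled recursions and gradients against
finite differences in the test suite.

## Worked example

```python
import numpy as np
from trackseq import (simulate_tracks, default_seal_like_config, ExperimentCase,
                      TrainConfig, TrajectoryAutoencoder, split_case, train, mae, rmse)
from trackseq.baselines import make_baseline

# two-state correlated random walk: transit vs area-restricted search
tracks = simulate_tracks(default_seal_like_config(seed=7, n_individuals=4, n_steps=120))

# T7P1: seven steps in, predict the eighth; per-individual temporal 80/20 split
case = ExperimentCase(case="one_seal", subcase="T7P1", mode="prediction")
train_pairs, test_pairs = split_case(tracks, case)
print(f"{len(train_pairs)} training and {len(test_pairs)} test segments")

model, history = train(TrajectoryAutoencoder(t_in=7, t_out=1, seed=0),
                       train_pairs, TrainConfig(epochs=40, seed=0))
rf, _ = train(make_baseline("random_forest", 7, 1, seed=0), train_pairs, TrainConfig())

truth = np.stack([p.y for p in test_pairs])
print(f"loss: {history[0]:.3f} -> {history[-1]:.3f}")
print(f"ATDD  MAE {mae(model.predict(test_pairs), truth):.3f} km, RMSE {rmse(model.predict(test_pairs), truth):.3f} km")
print(f"RF    MAE {mae(rf.predict(test_pairs), truth):.3f} km, RMSE {rmse(rf.predict(test_pairs), truth):.3f} km")
```

Output:

```
352 training and 92 test segments
loss: 0.805 -> 0.221
ATDD  MAE 0.978 km, RMSE 1.333 km
RF    MAE 1.320 km, RMSE 1.653 km
```

The training loss (normalized feature space) drops by ~4x over 40 epochs;
on held-out segments the attention model's mean displacement error is
about 1 km per 2-hour step versus 1.3 km for the random forest — the
recurrent model exploits the behavioural-regime persistence that a
memoryless regressor cannot.

The same workflows are available from the shell:

```sh
trackseq simulate --seed 7 --out tracks.csv
trackseq train tracks.csv --subcase T7P1 --method atdd --out model.npz
trackseq predict model.npz tracks.csv --subcase T7P1 --geo --out pred.csv
trackseq evaluate tracks.csv --case one_seal --subcases T7P1,T7P4 --out metrics.csv
```

Each command writes a JSON manifest next to its outputs (command, seed,
config, timings) so runs are auditable.

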