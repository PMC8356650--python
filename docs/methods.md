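# Methods

## Problem setting

Satellite telemetry of wide-ranging marine animals yields long sequences of
fixes (individual, time, longitude, latitude) with two recurring analysis
needs: *prediction* (where does the animal go next?) and *imputation*
(filling interior gaps in a sequence). `trackseq` implements a composite
recurrent architecture for both tasks on step-feature sequences, together
with the feature pipeline, reference baselines, an evaluation harness, and
a generative movement simulator so the whole method can be exercised and
benchmarked offline.

## Step features

Raw positions are poor direct inputs because different individuals occupy
different regions; the model therefore consumes relative movement. For a
track of `n` fixes we compute, per step `t`:

* `d_t` — great-circle length (km) of segment `P_t -> P_{t+1}`, by the
  haversine formula on a sphere of mean radius 6371.0088 km (IUGG mean
  radius; configurable — the choice of radius moves distances by < 0.3%).
* `theta_t` — the movement angle, under one of two conventions:
  * **bearing** (default): forward azimuth of `P_t -> P_{t+1}` clockwise
    from north, in `(-pi, pi]`. Then `(d cos theta, d sin theta)` are the
    north/east displacement components and the track is exactly
    recoverable from the features by spherical dead reckoning — which is
    why this is the default: model outputs must be invertible to
    positions.
  * **turning**: signed azimuth change from the previous segment to the
    current one. An exact reversal is mapped to `+pi` (the interval is
    half-open). Inversion then needs the initial azimuth as well.

The model input is the `T x 3` matrix with rows
`(d_t cos theta_t, d_t sin theta_t, theta_t)`; targets are the first two
columns only. The feature series of an `n`-fix track has length `n - 2`, so
that every step also has a preceding segment and both conventions share one
indexing. Consequently, dead-reckoning a step list and re-featurizing
recovers `steps[1:]` — the leading step has no feature row. Zero-length
steps (coincident fixes) have undefined azimuth; the default policy drops
the step, an alternative carries the previous azimuth forward. Units are
kilometres throughout; this is a declared convention of the package.
Sampling is assumed approximately even; the reader warns (not errors) when
intervals vary by more than 50% of the median.

## Segment layouts

Feature series are sliced by a sliding window (stride 1 by default; the
stride is exposed). Two supervised layouts exist, named `T<a>P<b>`:

* **Prediction** `TaPb`: window of `a + b` rows; the first `a` rows are
  input, the last `b` rows are target.
* **Imputation** `TkPk`: window of `2k` rows; 1-based odd rows
  `{1, 3, ..., 2k-1}` are input, even rows `{2, 4, ..., 2k}` are target.

User-facing labels are 1-based to match how such layouts are conventionally
tabulated; internally everything is 0-based half-open.

## Model

For input `x` (`T x F`, `F = 3`):

1. **Encoder** — `K` stacked LSTM layers (standard cell: logistic-sigmoid
   forget/input/output gates, tanh candidate, `C_t = f*C_{t-1} + i*C~_t`,
   `h_t = o*tanh(C_t)`), zero initial states. Layer 1 reads `x`; layer
   `k>1` reads layer `k-1`'s hidden-state sequence. `hen` is the final
   layer's `T x M` state matrix, `hl` its last row.
2. **Attention** — `h_bar = hen W_h + b_h` (one affine map shared across
   time steps), scores `s_t = hl . h_bar_t`, weights `aw = softmax(s)`,
   context `av = aw^T h_bar`, and output `ha = [av, hl] W_o + b_o` of
   length `2M`.
3. **Dual decoders** — two independent `K`-layer LSTM stacks, each
   receiving `ha` repeated at every time step (repeat-vector seq2seq
   convention; no teacher forcing): decoder 1 runs `T` steps, decoder 2
   `T_out` steps.
4. **Heads** — linear maps: decoder 1's states to `x_hat` (`T x F`,
   reconstruction), decoder 2's to `y_hat` (`T_out x 2`, prediction or
   imputation).

The **DD variant** bypasses attention and feeds `[hl, hl]` to both
decoders; **ATDD** is the full model. The joint objective is the sum over
segments of squared reconstruction error plus squared output error; the
reconstruction term makes the encoder representation carry the whole
window, not just what one-step prediction needs. Training minimizes the
element-mean form (identical minimizer, better-conditioned step sizes);
the literal sum is available and used in unit tests.

Architectural choices worth recording, since the design was genuinely open:

* Gate activations are logistic sigmoids — the universal LSTM convention
  (an elementwise "softmax" is degenerate).
* Decoder 1 reconstructs (head on decoder 1's states) and decoder 2
  predicts; stacked layers always consume the layer below.
* The attention transform is one affine map shared across time steps, i.e.
  `h_bar` is a `T x M` matrix, not per-step weights.

## Implementation

No neural-network framework is used: the model runs on a purpose-built
reverse-mode tape (`trackseq.autodiff`, ~15 operations, float64
throughout) with Adam. This keeps the arithmetic inspectable — the forward
pass is checked against hand-unrolled scalar recursions to 1e-10, and
analytic gradients against central finite differences (group-wise relative
error < 1e-4) for every parameter group in both variants. Identical seeds
give bitwise-identical forward passes and training histories.

Defaults: `M = 64`, `K = 1`, Adam lr 1e-3, betas (0.9, 0.999), batch 64,
100 epochs, Glorot-uniform weight initialization, zero biases. Inputs are
z-scored per training split; the statistics travel with the checkpoint and
predictions are returned in km. Divergence (non-finite loss) aborts with a
diagnostic rather than continuing.

## Baselines

* **LSTM** — one recurrent layer of 100 units, linear head from the final
  hidden state to the flattened target, target-only MSE, same optimizer and
  budget as the main model. Reads the window step-wise.
* **ANN** — one dense hidden layer of 100 units on the flattened window
  (scikit-learn `MLPRegressor`, Adam, matched lr/batch/epochs).
* **Random forest** — one multi-output forest of 200 trees on the
  flattened window (scikit-learn).
* **Persistence** — repeats the last observed displacement row; the
  minimal sanity bar for any sequence model.

All expose `fit(pairs)` / `predict(pairs)`, so the harness is
method-agnostic.

## Evaluation protocol

Errors are MAE and RMSE over both output columns jointly, in km
(predictions are de-normalized before scoring). Three splitting designs:

* **one_seal** — per individual, temporal split of the ordered segment
  list (default 80/20, earlier part training). With stride 1 the boundary
  segments share steps; an optional purge gap can drop overlapping test
  segments, default 0 to keep the split-fraction exact.
* **five_seals** — seeded partition of individuals into groups of five;
  within a group, each individual is held out once (train on four, test on
  the fifth), results averaged over folds. Individuals never straddle the
  split.
* **all_seals** — all segments pooled, seeded shuffle, 50/50 split.

Fold averages weight each fold (individual) equally, not by segment count.
`run_experiment` fills the (subcase x method) table of MAE/RMSE cells and
emits percent-reduction summaries of the full model against each
comparator.

## Synthetic data

The simulator is a two-state switching correlated random walk — the
standard generative picture for marine-mammal movement, alternating
directed *transit* with tortuous *area-restricted search*:

| parameter | transit | forage | notes |
|---|---|---|---|
| step length | gamma, mean 4 km, shape 4 | gamma, mean 1 km, shape 1.5 | per 2-h fix; right-skewed |
| turning angle | wrapped normal, sd 0.3 rad | wrapped normal, sd 1.5 rad | centred on 0; heading accumulates |
| state persistence | P(stay) = 0.95 | P(stay) = 0.90 | stationary occupancy (2/3, 1/3) |

Headings integrate the turning angles and positions advance by spherical
dead reckoning (so the geodesic code paths are exercised, not a flat
plane). Starts are uniform in a Southern Ocean box (60–90°E, 62–50°S);
step magnitudes are typical of a large pelagic diver at 2-hourly sampling.
The reference fixture is 10 individuals x 300 fixes at seed 7, regenerated
programmatically wherever it is needed.

What the simulator does *not* emulate: Argos location error and quality
classes, irregular duty-cycled sampling, haul-out gaps, environmental
covariates, and inter-individual heterogeneity beyond the shared two-state
law. Passing benchmarks on it therefore demonstrate that the architecture
extracts regime structure from movement sequences under controlled
conditions — not field performance on real telemetry.

Sanity checks pin the generator to its configuration: per-state empirical
step means and state occupancies at 10,000 steps fall within three
standard errors of the configured gamma means and the chain's closed-form
stationary distribution (the occupancy SE uses the chain's integrated
autocorrelation time), and per-state step lengths pass a KS test against
the configured gamma.

## Reference benchmark

The package's headline number: on the seed-7 fixture, T7P1 prediction,
per-individual temporal 80/20 split, 100 epochs for both models, the
ATDD model's test MAE vs the plain 100-unit LSTM baseline's. The problem
size (10 x 300 fixes, ~2,900 segments) was chosen so the full comparison
trains in minutes on one CPU core; `scripts/acceptance.py` averages the
percent reduction over three training seeds. Training loss on this task
falls well below half its initial value within the budget, and the trained
model beats persistence — both asserted in the test suite.

## Numerical notes and limitations

* Angles live in the half-open interval `(-pi, pi]`; reversal ties break
  to `+pi`.
* Haversine is numerically stable near antipodes via the arcsin form with
  clipping; distances are validated against an independent spherical
  law-of-cosines computation and R's `geosphere` (flattening 0).
* Dead reckoning over a pole follows the great circle down the far
  meridian; longitudes wrap to `(-180, 180]`.
* The attention softmax subtracts the row max before exponentiation.
* Checkpoints are `.npz` archives (weights + dims + variant +
  normalization statistics + seed, versioned schema id).
* `T1P1` imputation gives attention a single encoder state to attend over,
  where it can add nothing over the DD variant — expected, and visible in
  results on that subcase.
* Training is full-batch-shuffled minibatch Adam with a fixed epoch count;
  no early stopping, scheduling, or hyperparameter search (out of scope).
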