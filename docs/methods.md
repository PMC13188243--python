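# Methods

This note documents the models, procedures, parameter choices and known
limitations of `synthtl`.

## ODE systems

Three systems ship in the registry; all states are non-negative
quantities and all rate constants strictly positive.

**SIR** (`sir`).  dS/dt = −βSI/N, dI/dt = βSI/N − γI, dR/dt = γI.
Frequency-dependent incidence (division by the population size N) is
used because it is the standard form for epidemic-wave case-count data.
Default centers: β = 0.3 /day, γ = 0.1 /day, N = 1000, (S₀, I₀, R₀) =
(990, 10, ~0), giving a basic reproduction number of 3 and a single wave
peaking near day 27 on the default daily grid.  S+I+R is conserved;
the test suite checks this to 1e−6 relative over a 200-point trajectory.

**Lotka–Volterra** (`lv`).  dx/dt = αx − βxy, dy/dt = δxy − γy with
prey x and predator y.  Defaults α = 1.1, β = 0.4, δ = 0.1, γ = 0.4,
(x₀, y₀) = (10, 5): sustained oscillations around the coexistence
equilibrium (γ/δ, α/β) = (4, 2.75).

**Substrate–algae–rotifers** (`sar`).  A three-state chemostat with
Monod uptake: substrate is diluted in at concentration S_in and rate
δ_d, algae grow on substrate with maximum rate μ_A and half-saturation
K_A (yield ε_A), rotifers graze algae analogously (μ_R, K_R, ε_R) and
die at rate δ_d + m.  Default centers are in the range of published
rotifer–algae chemostat fits (δ_d = 0.55 /day, S_in = 80 µmol/L,
μ_A = 3.3, K_A = 4.3, ε_A = 0.25, μ_R = 2.25, K_R = 15, ε_R = 0.25,
m = 0.055).  The three-state Monod form is used rather than the
four-state variant with a reproducing-rotifer subclass; users needing
the richer model can register it via `register_system`.

All centers are ordinary config values; every experiment reads them from
its configuration and none are hardcoded in the runners.

## Synthetic dataset generation

Each trajectory draws its kinetic parameters and initial conditions
independently and uniformly from symmetric relative intervals
[c(1−w), c(1+w)] around the centers c.  The half-width w comes from the
diversity class: w(S) = 0.05, w(M) = 0.20, w(L) = 0.50, w(XL) = 0.80.
These defaults preserve the intended strict ordering of interval
lengths while keeping every interval positive; they are plain config
labels and can be overridden per variable or parameter.  Symmetric
relative intervals were chosen over absolute ones because they respect
positivity for any center and make one class meaningful across
variables of very different magnitudes.

Noise is exactly one (kind, operation) pair at a time:

- **Measurement, multiplicative**: every value is multiplied by an
  i.i.d. lognormal factor with log-median 1 and shape
  σ = asinh(IQR/2)/z₀.₇₅, the closed form that gives the factor
  distribution exactly the requested interquartile range.  The closed
  form is checked against a numeric quantile root-finder to 1e−10.
- **Measurement, additive**: i.i.d. Gaussian noise with standard
  deviation level × (per-variable clean standard deviation), scaling
  the perturbation to each variable.
- **Environmental** (additive / multiplicative): one noise value per
  variable per grid interval, held constant on [t_i, t_{i+1}) and
  applied to the rate equations (added, or multiplied as a lognormal
  factor); the solver restarts at every interval with state continuity.
  Additive environmental draws are Gaussian with standard deviation
  level × the per-variable scale of the clean trajectory's derivative,
  so the level is dimensionless across systems.  This discrete scheme is
  the coarse-grained analogue of an SDE sampled at the observation
  times; no sub-grid stochastic integration is performed.

Default noise levels are {0.01, 0.05, 0.1, 0.2, 0.5, 1.0} (IQR for
multiplicative, sd-fraction for additive), six levels spanning
negligible to dominant perturbation on a log-ish scale.

Trajectories that fail to integrate or violate finiteness or
non-negativity are rejected and re-drawn, up to 10 retries per slot,
after which generation fails loudly naming the offending configuration.
Rejection was chosen over clipping because clipping distorts the
dynamics the pre-training is supposed to teach.  Retry counts are stored
in the dataset's provenance, as are every trajectory's sampled
parameters, initial conditions and the master seed — a dataset can be
regenerated exactly from its sidecar.

### Pseudo-real fixture targets

Real observational datasets are deliberately not bundled.  The fixture
generator produces targets with controlled coherence: a *coherent*
target is a trajectory of the same system at the true parameters with
multiplicative observation noise of a given IQR; an *incoherent* target
comes from a structurally different generator — the same system with its
first kinetic parameter scaled ×3 plus a phase-shifted sinusoid per
variable with amplitude 2 clean-standard-deviations (clipped at zero for
non-negative systems) before the same observation noise.  With these
defaults the incoherent target deviates from the coherent trajectory by
more than one clean standard deviation at over 90% of grid points in at
least one variable.  What fixtures do **not** emulate: reporting
artifacts (weekday effects, smoothing), non-stationary process changes,
and observation gaps — conclusions from passing tests transfer to real
data only insofar as those effects are secondary.

## Forecasters and the transfer protocol

Sliding windows of `input_len` points (default 5) predict the next
`horizon` points (default 5) of the target variables; all maximal
stride-1 windows are used.  Four bodies are available — LSTM (1 layer,
64 units), GRU (1 layer, 64 units), CNN (two 1-D convolutions, kernel 3,
32 channels, global average pooling) and DNN (flatten + one 64-unit ReLU
layer) — each followed by the same two-layer perceptron head (32 hidden
units, linear output of horizon × n_targets).  Loss is MSE on
standardized targets; the optimizer is Adam (lr 1e−3, batch 32).  These
sizes keep the models small enough that pre-training on a 1000-series
dataset stays in the minutes range on one CPU; all are config-overridable.

The stack is pure float64 numpy with hand-written reverse-mode
gradients, verified against central finite differences for all four
architectures in the test suite.  Single-threaded numpy makes training
bitwise deterministic for a fixed seed, which the paired-seed and
frozen-parameter contracts rely on.

**Pre-training** holds out 10% of whole series for validation (a
seeded series-level split; a single-series dataset falls back to a
time-tail split with a logged notice), trains with early stopping
(patience 5, max 200 epochs by default) and restores the checkpoint with
minimal validation loss.

**Fine-tuning** updates only the head — the last two parameterised
layers — for exactly 5 epochs on the target's training region, with the
best checkpoint chosen on the last 10% of training windows.  Body
parameters are bit-identical before and after; this is asserted, not
assumed.  The per-variable standardisation fitted on the pre-training
data is reused unchanged at fine-tuning and inference so that the
pre-trained representations stay valid; the uninformed baseline fits its
scaler on the target training data instead, since it has no other source.

**Pairing.**  For seed k, the TL arm and the DL-baseline arm build
bit-identical random initialisations and use the same data ordering; the
arms differ only in whether pre-training replaced the initial
parameters.  This makes per-seed comparisons paired by construction.

## Baselines

The **DL baseline** trains the same architecture from its random
initialisation on the target training region with the full early-stopping
loop.

The **ODE baseline** fits the system's kinetic parameters to the
combined train+validation region by bounded least squares (scipy `trf`)
on the residuals between the simulated trajectory — started from the
first observed state — and all observed variables, each weighted by the
reciprocal of its standard deviation so differently scaled variables
contribute comparably.  A small multi-start (default 10 restarts,
log-uniform perturbations of the starting point within ±50%) guards
against local minima; the best restart is returned with its residual and
convergence flag.  Initial conditions are taken from the data rather
than fitted (a config switch enables fitting them).  Forecasts continue
the calibrated simulation deterministically from the last fitted state;
for non-negative systems started positive the forecast stays positive.
The noiseless recovery test demands parameters back within 1% from
±20%-perturbed starts; under multiplicative observation noise of IQR
0.05 the median relative parameter error stays below 5%.

## Evaluation

MAE and RMSE average over all (window, step, variable) cells of the
evaluation region.  PTA scores, per cell, whether
sign(prediction − origin) equals sign(observation − origin), where the
origin is the value of the target variable at the last input point; a
zero change matches only a zero change, so flat forecasts get no credit
for observed moves.  PTA is anchored at the forecast origin rather than
step-to-step because the forecast's practical claim is the direction of
change from "now"; it is reported as 1−PTA so lower is better
everywhere.

The blocked bootstrap operates on per-time-point error series: the error
at a time point is the mean over all windows and variables whose target
covers it, which defines the time axis operationally despite overlapping
windows.  Each replicate resamples moving blocks of time indices (block
length ⌈N^{1/3}⌉ by default) and seed indices with replacement — the
same blocks and the same seeds in both arms — and recomputes the
aggregate metric difference; the percentile interval at 95% is reported
and a difference is called significant only when the interval excludes
zero (the boundary does not count).  Identical arms therefore yield a
degenerate [0, 0] interval, and null coverage is checked empirically in
the tests (≥90% across 200 permutation repetitions).

## Coherence screening

Series are z-normalized per variable with pooled synthetic-dataset
statistics (the screening compares shapes, not scales), then dependent
multivariate DTW — Euclidean local cost over variables, unconstrained
warping, full-path cost — measures synthetic-to-target distances against
a synthetic-to-synthetic baseline sample.  Derivative DTW first maps
each series through the centered slope estimator
d_i = ((q_i − q_{i−1}) + (q_{i+1} − q_{i−1})/2)/2 and is the more
dynamics-sensitive variant.  The reported shift statistic is the
probability that a random target distance exceeds a random baseline
distance: ~0.5 for a target indistinguishable from the synthetic
ensemble, →1 for incoherent targets.  The report is deliberately
comparative-only — it ranks configurations and never issues an absolute
coherent/incoherent verdict, because the distances have no calibrated
scale across datasets.  A Sakoe–Chiba radius is available as an option
but off by default since the series involved are short.

## Study layout and reduced-scale reproduction

The grid runner enumerates sizes × IC classes × KP classes (16 diversity
configurations per size by default) × architectures × seeds, generates
noise-free synthetic data per cell, and scores TL against the paired DL
baseline and the single ODE calibration; noise enters only in the
follow-up study at the best cell (selected by mean MAE, ties broken by
mean 1−PTA, then smaller size), one (kind, operation) pair at six levels
at a time.  Failed cells are recorded with reasons and never abort the
run; per-cell results are cached on disk keyed by a config hash, making
runs resumable.

The acceptance script and the behavioral tests run the study at reduced
scale, chosen to exercise the full pipeline while completing in minutes
on one CPU: a 91-point daily SIR grid with training boundary at index 18
(before the wave peak at ~27), target variable I, GRU forecaster, 3
seeds, 100 synthetic series for the coherent study (pre-training capped
at 30 epochs) and 1000 series at KP classes S vs XL for the incoherent
study (capped at 15 epochs).  The expected directions — TL beating the
uninformed baseline by a large margin on the coherent truncated wave,
and TL degrading (not improving) from KP class S to XL on the incoherent
target — are asserted as inequalities on seed-averaged MAE, not as
absolute numbers.

## Known limitations

- Environmental noise is piecewise-constant at the observation
  resolution; it is not a sub-grid SDE solver, and noise is uncorrelated
  across variables and intervals with a single level for all variables.
- The identity-noise environmental run agrees with the clean single
  solve only to solver tolerance (1e−6 here), because the clean path
  uses one adaptive solve while environmental noise restarts per
  interval; within the piecewise scheme, identity multiplicative and
  zero additive noise agree bitwise.
- Fine-tuning always runs its fixed epoch budget (checkpointed); there
  is no early stopping inside fine-tuning.
- The ODE calibration is ordinary bounded least squares — no
  identifiability analysis, no data assimilation, no posterior
  uncertainty.
- Multivariate DTW is used only for coherence screening, not as a
  forecast-evaluation metric; no multiple-testing correction is applied
  across grid cells (intervals are per-comparison).
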