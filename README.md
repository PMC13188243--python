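# synthtl

Simulation-based transfer learning for forecasting dynamical biological
systems.

## The problem

Forecasting biological time series — epidemic case counts, predator–prey
population cycles, chemostat dynamics — is hard precisely when it matters
most: early in an outbreak or experiment, when only a short stretch of
data exists and the interesting dynamics (the decline after an infection
peak, the next oscillation cycle) have not yet been observed.  Deep
learning models cannot learn unobserved behavior from data alone, and
mechanistic ordinary differential equation (ODE) models, while encoding
that expected behavior, are rigid when reality deviates from their
assumptions.

`synthtl` implements a middle path and the machinery to decide when it
helps: **simulation-based transfer learning (TL)**.  An ODE model of the
system (SIR for epidemics, Lotka–Volterra or a substrate–algae–rotifer
chemostat for predator–prey) generates a synthetic dataset of plausible
trajectories; a small neural forecaster is pre-trained on it; then only
the model's two-layer output head is fine-tuned on the short observed
series.  Whether this beats (a) the same network trained on the observed
data alone and (b) forecasting with the calibrated ODE itself depends
critically on three synthetic-dataset characteristics, which the package
lets you scan systematically:

- **size** — number of simulated series (1, 10, 100, 1000),
- **diversity** — width of the uniform sampling intervals for initial
  conditions (ICs) and kinetic parameters (KPs) around their centers,
  in four classes S/M/L/XL,
- **noise** — measurement noise (i.i.d. perturbation of observed values)
  or environmental noise (perturbation of the rate equations, held
  constant between grid points so it propagates through the dynamics),
  each additive or multiplicative, at configurable levels.

For an observation grid t_1..t_N, environmental noise solves the system
piecewise on each interval [t_i, t_{i+1}):

    dŷ/dt = dy/dt + e_{t_i},   e_{t_i} ~ iid D   (additive),

with the sum replaced by a product for multiplicative noise, where the
factor is lognormal with log-median 1 and shape chosen so its
interquartile range equals the requested level.

Forecasts are scored by MAE, RMSE and prediction trend accuracy (PTA,
reported as 1−PTA): the fraction of (window, horizon step, variable)
triples whose predicted direction of change from the forecast origin
matches the observed direction.  Paired TL-vs-baseline differences get
confidence intervals from a moving blocked bootstrap over time points
with paired resampling across seeds.  DTW and derivative-DTW *coherence
screening* compares synthetic-to-target distances against a
synthetic-to-synthetic baseline to flag source data whose shapes cannot
match the target — the precursor of negative transfer.

## Worked example

A coherent pseudo-real target: an SIR infection wave (observation noise
IQR 0.05) whose training region (time steps 0–18) ends before the peak,
so the decline is unseen.  Pre-train on 100 synthetic waves at medium
IC/KP diversity, fine-tune the head, and compare with the uninformed
baseline:

```python
import numpy as np
from synthtl import *
from synthtl.synth_generator import TimeGrid, DiversityConfig, NoiseConfig
from synthtl.orchestration import ExperimentConfig, split_target, run_tl_arm, run_dl_arm
from synthtl.evaluation import forecast_mae

sir = get_system("sir")
grid = TimeGrid.regular(0, 90, 91)
target = generate_fixture_target(sir, sir.center_theta(), sir.center_ics(),
                                 grid, 0.05, True, np.random.default_rng(42))
cfg = ExperimentConfig(system="sir", train_end=18, target_vars=["I"],
                       train=TrainConfig(max_epochs=30, patience=5))
split = split_target(target, 18, 5)
ds = generate_dataset(sir, DiversityConfig.from_classes(sir, "M", "M"),
                      NoiseConfig(kind="none"), 100, grid, seed=11)
for seed in (0, 1, 2):
    _, fs_tl = run_tl_arm(ds, split, "GRU", seed, cfg)
    _, fs_dl = run_dl_arm(split, "GRU", seed, cfg)
    print(f"seed {seed}: TL MAE {forecast_mae(fs_tl):.2f}   DL MAE {forecast_mae(fs_dl):.2f}")
```

Output:

```
seed 0: TL MAE 5.56   DL MAE 98.12
seed 1: TL MAE 5.73   DL MAE 121.62
seed 2: TL MAE 5.85   DL MAE 98.79
```

The uninformed network, trained only on the rising phase, keeps
forecasting growth into the test region; the pre-trained network has
seen declines in its synthetic source data and tracks the true wave —
here a ~95% MAE reduction.  On an *incoherent* target (same system
perturbed with a scaled parameter and additive oscillation) the effect
reverses: more KP diversity in the source data makes TL worse, which the
grid runner (`run_grid`) and coherence screening detect.

A CLI mirrors the library for shell use: `synthtl generate`,
`synthtl coherence`, `synthtl baseline-ode`, `synthtl grid`,
`synthtl select-best`, `synthtl noise-study`.

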