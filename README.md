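# driftswitch

A bounded drift-diffusion state-space model of perceptual decision-making
whose neural encoding weights switch at decision commitment, with
single-trial inference of the time of commitment from population spike
trains.

The latent decision variable is a scalar accumulator driven by pulsatile
auditory-click evidence (with multiplicative sensory adaptation and
per-click noise) and diffusion noise; it freezes when it reaches an
absorbing bound at ±B. Each neuron emits Poisson spike counts with rate
`softplus(w·z + b)`, where the encoding weight `w` takes one value during
evidence accumulation and another after commitment, and `b` is a learned
decision-irrelevant baseline (cross-trial drift, stimulus-onset,
pre-movement and spike-history kernels on radial bases). The behavioural
choice is the sign of the latent at the end of the trial.

## What's inside

| module | contents |
| --- | --- |
| `driftswitch.stimuli` | task trial conditions, Poisson click trains, per-click adaptation magnitudes |
| `driftswitch.model` | latent grid, transition/initial distributions, spike and choice emissions, baseline GLM |
| `driftswitch.inference` | forward filtering, forward–backward smoothing, joint MAP fitting, cross-validation, commitment-time detection, particle-filter likelihood oracle |
| `driftswitch.simulate` | generative simulator with per-trial ground truth; parameter-recovery experiments |
| `driftswitch.analyses` | neuron selection (auROC), PSTHs, two-condition R², choice selectivity, engagement index, peri-commitment histograms, state-space trajectories |
| `driftswitch.psychophysics` | psychometric curves, commitment-aligned psychophysical kernels with lapse, commitment/behaviour summaries |
| `driftswitch.session` | HDF5/JSON session container with schema validation |
| `driftswitch.cli` | `driftswitch simulate / fit / commit / analyze` |

## Command-line usage

```bash
# simulate a session from a parameter file (JSON, see params_to_dict)
driftswitch simulate --params params.json --n-trials 500 --seed 1 --out session.h5

# fit the model (config keys = FitConfig fields)
driftswitch fit --session session.h5 --out fitted.json --config fit.yaml --seed 1

# per-trial commitment times (TSV)
driftswitch commit --session session.h5 --fit fitted.json --out commit.tsv

# summary tables: selection, PSTHs, selectivity, engagement, kernels
driftswitch analyze --session session.h5 --fit fitted.json --out analysis/
```

Exit codes: 0 success, 1 validation error, 2 numerical failure. Every run
writes a `run_log.json` with the config hash, seed and package version.

## Library quick start

```python
import numpy as np
from driftswitch import (
    ModelParams, FitConfig, simulate_session, fit_map,
    smooth, detect_commitment, commitment_table,
)
from driftswitch.simulate import random_neurons

rng = np.random.default_rng(0)
params = ModelParams(bound=4.0, sigma_s2=1.0, mu0=0.0,
                     neurons=random_neurons(20, rng))
sim = simulate_session(params, n_trials=500, seed=1)

fitted = fit_map(sim.session, FitConfig(seed=1))
table = commitment_table(sim.session, fitted.params)       # per-trial commitment
post = smooth(sim.session.trial(0), fitted.params)         # latent posterior
print(detect_commitment(post))                             # (step, side) or None
```

## Notes

- Time step is fixed at 0.01 s; the trial clock starts at stimulus onset;
  trial windows run to the earlier of 1 s or fixation exit.
- The latent grid defaults to 99 interior bins plus two absorbing bound
  states; fitting configs may reduce it (`FitConfig.n_interior`).
- The forward–backward pass is JIT-compiled with numba when available and
  falls back to pure numpy otherwise.
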