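"""Generative mode of the model: synthesize sessions with ground truth.

Trials are simulated by Euler-stepping the bounded accumulator at the model
time step with per-click multiplicative noise and per-step diffusion noise,
freezing the latent at the first bound hit, and emitting Poisson spikes
with the regime-appropriate encoding weight. The behavioural choice is the
sign of the latent at the final step. Each trial's true latent path and
first-bound-hit step are recorded, which supports parameter-recovery
experiments and the model-prediction curves for commitment analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from driftswitch.model import (
    BaselineModel,
    BasisConfig,
    ModelParams,
    NeuronParams,
    softplus,
)
from driftswitch.session import GroundTruth, Session, TrialData
from driftswitch.stimuli import (
    StimulusConfig,
    TrialCondition,
    adapt_clicks,
    generate_click_train,
    sample_trial_conditions,
)

__all__ = [
    "SyntheticSession",
    "simulate_session",
    "random_neurons",
    "recovery_experiment",
    "RecoveryReport",
]

#: fixed inter-trial interval (s) giving the cross-trial baseline a support
ITI_S = 5.0
#: fixation exit drawn uniformly this long (s) after stimulus end
MOVE_DELAY_MAX = 0.2


@dataclass(frozen=True)
class SyntheticSession:
    """A simulated session plus its generative settings."""

    session: Session
    params: ModelParams
    conditions: list[TrialCondition]

    @property
    def ground_truth(self) -> GroundTruth:
        return self.session.ground_truth


def random_neurons(
    n_neurons: int,
    rng: np.random.Generator,
    weight_scale: float = 2.0,
    rate_range: tuple[float, float] = (2.0, 20.0),
    basis: Optional[BasisConfig] = None,
) -> tuple[NeuronParams, ...]:
    """Draw per-neuron parameters with a spread of engagement indices.

    Weights are independent normals, so the engagement index covers
    [-1, 1]; baselines are intercept-only at rates drawn log-uniformly
    from ``rate_range``.
    """
    basis = basis or BasisConfig.intercept_only()
    neurons = []
    for _ in range(n_neurons):
        rate = np.exp(rng.uniform(np.log(rate_range[0]), np.log(rate_range[1])))
        coef = np.zeros(basis.n_coef)
        coef[0] = np.log(np.expm1(rate))  # softplus^-1
        neurons.append(
            NeuronParams(
                w_ea=float(rng.normal(0.0, weight_scale)),
                w_dc=float(rng.normal(0.0, weight_scale)),
                baseline=BaselineModel(coef, basis),
            )
        )
    return tuple(neurons)


def _has_history(bm: BaselineModel) -> bool:
    cfg = bm.config
    if cfg.n_hist == 0:
        return False
    start = 1 + cfg.n_cross + cfg.n_stim + cfg.n_move
    return bool(np.any(bm.coef[start:] != 0.0))


def simulate_session(
    params: ModelParams,
    n_trials: int,
    seed: int = 0,
    task_config: Optional[StimulusConfig] = None,
    session_id: str = "synthetic",
) -> SyntheticSession:
    """Simulate a full session under the generative model.

    Per trial: sample a condition and Poisson click trains, adapt the
    clicks, Euler-simulate the bounded accumulator (per-step diffusion
    variance dt; per-click noise variance sigma_s2 per squared magnitude),
    freeze at the first bound hit, emit Poisson spike counts with ``w_ea``
    before and ``w_dc`` after commitment, and set the choice to the sign of
    the final latent. Reproducible under a fixed seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    task_config = task_config or StimulusConfig()
    conditions = sample_trial_conditions(n_trials, task_config, rng)
    dt, B = params.dt, params.bound
    w_ea, w_dc = params.w_ea, params.w_dc
    n_neurons = params.n_neurons

    trials: list[TrialData] = []
    spike_times: list[list[np.ndarray]] = [[] for _ in range(n_neurons)]
    latents, commit_steps, commit_sides = [], [], []
    for i, cond in enumerate(conditions):
        train = generate_click_train(cond, rng)
        move_onset = cond.duration + rng.uniform(0.0, MOVE_DELAY_MAX)
        T = max(1, int(np.floor(min(1.0, move_onset) / dt + 1e-9)))
        adapted = adapt_clicks(train, params.adaptation)
        keep = adapted.times < T * dt
        m = np.zeros(T)
        csq = np.zeros(T)
        if keep.any():
            steps = np.floor(adapted.times[keep] / dt).astype(int)
            signs = np.where(adapted.sides[keep] == "R", 1.0, -1.0)
            np.add.at(m, steps, signs * adapted.magnitudes[keep])
            np.add.at(csq, steps, adapted.magnitudes[keep] ** 2)

        z = np.empty(T)
        z[0] = rng.normal(params.mu0, 1.0)
        commit = -1
        if abs(z[0]) >= B:
            z[0] = B * np.sign(z[0])
            commit = 0
        for t in range(T - 1):
            if commit >= 0:
                z[t + 1] = z[t]
                continue
            u = m[t] + np.sqrt(params.sigma_s2 * csq[t]) * rng.standard_normal() if csq[t] > 0 else m[t]
            znew = z[t] + u + np.sqrt(dt) * rng.standard_normal()
            if abs(znew) >= B:
                znew = B * np.sign(znew)
                commit = t + 1
            z[t + 1] = znew

        committed_mask = np.zeros(T, dtype=bool)
        if commit >= 0:
            committed_mask[commit:] = True
        start_time = i * ITI_S

        if n_neurons:
            W = np.where(committed_mask[None, :], w_dc[:, None], w_ea[:, None])
            sequential = any(_has_history(nn.baseline) for nn in params.neurons)
            for n, nn in enumerate(params.neurons):
                if not sequential:
                    b = nn.baseline.evaluate(T, dt, start_time, move_onset, None)
                    lam = softplus(W[n] * z + b)
                    counts = rng.poisson(lam * dt)
                    st = _counts_to_times(counts, dt, rng)
                else:
                    st_list: list[float] = []
                    for t in range(T):
                        b_t = nn.baseline.evaluate(
                            t + 1, dt, start_time, move_onset, np.array(st_list)
                        )[-1]
                        lam = softplus(W[n, t] * z[t] + b_t)
                        c = rng.poisson(lam * dt)
                        if c:
                            st_list.extend(np.sort(rng.uniform(t * dt, (t + 1) * dt, c)))
                    st = np.array(sorted(st_list))
                spike_times[n].append(st)

        if z[-1] > 0:
            choice = "R"
        elif z[-1] < 0:
            choice = "L"
        else:
            choice = "R" if rng.random() < 0.5 else "L"
        trials.append(
            TrialData(clicks=train, choice=choice, move_onset=move_onset, start_time=start_time)
        )
        latents.append(z)
        commit_steps.append(commit)
        commit_sides.append("" if commit < 0 else ("R" if z[-1] > 0 else "L"))

    gt = GroundTruth(
        latents=latents,
        commit_step=np.array(commit_steps, dtype=int),
        commit_side=np.array(commit_sides, dtype=object),
    )
    session = Session(
        session_id=session_id,
        trials=trials,
        neuron_ids=[f"n{n:03d}" for n in range(n_neurons)],
        spike_times=spike_times,
        ground_truth=gt,
    )
    return SyntheticSession(session=session, params=params, conditions=conditions)


def _counts_to_times(counts: np.ndarray, dt: float, rng: np.random.Generator) -> np.ndarray:
    out = []
    for t in np.nonzero(counts)[0]:
        out.append(np.sort(rng.uniform(t * dt, (t + 1) * dt, counts[t])))
    return np.concatenate(out) if out else np.empty(0)


# ---------------------------------------------------------------------------
# parameter recovery


@dataclass(frozen=True)
class RecoveryReport:
    """Comparison of fitted against generative parameters across sessions."""

    true_params: ModelParams
    fitted: tuple  # per-session FittedModel or None on failure
    failures: tuple[str, ...]
    commit_timing_errors: np.ndarray  # per detected trial, steps
    detected_fraction: float

    def _fitted_ok(self):
        return [f for f in self.fitted if f is not None]

    @property
    def weight_correlation(self) -> float:
        """Correlation between true and fitted (w_ea, w_dc), pooled."""
        tw = np.concatenate([self.true_params.w_ea, self.true_params.w_dc])
        rows = []
        for f in self._fitted_ok():
            rows.append(np.concatenate([f.params.w_ea, f.params.w_dc]))
        if not rows:
            return np.nan
        fw = np.concatenate(rows)
        tw = np.tile(tw, len(rows))
        return float(np.corrcoef(tw, fw)[0, 1])

    def ei_sign_accuracy(self, min_abs_ei: float = 0.5) -> float:
        """Fraction of strongly-engaged neurons whose sign of
        |w_ea| - |w_dc| is recovered.

        Neurons with both true weights zero have undefined engagement and
        are excluded (flagged as NaN), never scored as +/-1.
        """
        from driftswitch.analyses import engagement_index

        true_ei = np.array(
            [
                engagement_index(n.w_ea, n.w_dc) if (n.w_ea or n.w_dc) else np.nan
                for n in self.true_params.neurons
            ]
        )
        mask = np.abs(true_ei) > min_abs_ei
        if not mask.any():
            return np.nan
        hits, total = 0, 0
        for f in self._fitted_ok():
            fit_ei = np.array(
                [
                    engagement_index(n.w_ea, n.w_dc) if (n.w_ea or n.w_dc) else np.nan
                    for n in f.params.neurons
                ]
            )
            ok = np.sign(fit_ei[mask]) == np.sign(true_ei[mask])
            hits += int(np.nansum(ok))
            total += int(mask.sum())
        return hits / total if total else np.nan

    @property
    def bound_relative_errors(self) -> np.ndarray:
        B = self.true_params.bound
        return np.array([abs(f.params.bound - B) / B for f in self._fitted_ok()])

    @property
    def median_commit_timing_error(self) -> float:
        if len(self.commit_timing_errors) == 0:
            return np.nan
        return float(np.median(self.commit_timing_errors))


def recovery_experiment(
    true_params: ModelParams,
    n_trials: int,
    n_sessions: int,
    seed: int = 0,
    fit_config=None,
    threshold: float = 0.8,
    n_neurons: Optional[int] = None,
) -> RecoveryReport:
    """Simulate sessions, refit, and compare to the generative parameters.

    If ``true_params`` carries no neurons and ``n_neurons`` is given,
    per-neuron parameters are drawn with :func:`random_neurons` (seeded).

    Also measures commitment-time accuracy: for trials where a true bound
    hit exists and the posterior detection (under the *fitted* parameters)
    succeeds, records |detected - true| in steps. Fit failures are recorded
    per session, not fatal.
    """
    from driftswitch.inference import (
        FitConfig,
        commitment_table,
        fit_map,
    )

    if n_trials < 1 or n_sessions < 1:
        raise ValueError("n_trials and n_sessions must be positive")
    if not true_params.neurons and n_neurons:
        from dataclasses import replace as _replace

        true_params = _replace(
            true_params,
            neurons=random_neurons(n_neurons, np.random.default_rng(seed)),
        )
    fit_config = fit_config or FitConfig()
    fitted, failures = [], []
    timing_errors = []
    n_detected, n_with_commit = 0, 0
    for s in range(n_sessions):
        sim = simulate_session(true_params, n_trials, seed=seed + s)
        try:
            fm = fit_map(sim.session, fit_config)
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            fitted.append(None)
            failures.append(f"session {s}: {exc}")
            continue
        fitted.append(fm)
        table = commitment_table(sim.session, fm.params, threshold)
        gt = sim.ground_truth
        for _, row in table.iterrows():
            i = int(row["trial"])
            if gt.commit_step[i] < 0:
                continue
            n_with_commit += 1
            if row["commit_step"] >= 0:
                n_detected += 1
                timing_errors.append(abs(int(row["commit_step"]) - int(gt.commit_step[i])))
    return RecoveryReport(
        true_params=true_params,
        fitted=tuple(fitted),
        failures=tuple(failures),
        commit_timing_errors=np.array(timing_errors),
        detected_fraction=(n_detected / n_with_commit) if n_with_commit else np.nan,
    )
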