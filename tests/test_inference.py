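import numpy as np
import pytest

from driftswitch.inference import (
    FitConfig,
    LatentPosterior,
    commitment_table,
    crossvalidate,
    detect_commitment,
    fit_map,
    particle_loglik,
    smooth,
    trial_loglik,
)
from driftswitch.model import (
    LatentGrid,
    ModelParams,
    choice_likelihood,
    discretize_inputs,
    emission_loglik,
    initial_distribution,
    transition_matrix,
)
from driftswitch.session import Session, Trial, TrialData
from driftswitch.simulate import random_neurons, simulate_session
from driftswitch.stimuli import ClickTrain, adapt_clicks

from tests.conftest import intercept_neuron


def _make_trial(params, spike_times, choice="R", move_onset=0.05, right=(0.012,), left=()):
    train = ClickTrain(
        left_times=np.concatenate([[0.0], left]),
        right_times=np.concatenate([[0.0], right]),
        duration=max(move_onset, 0.2),
    )
    return Trial(
        clicks=train,
        choice=choice,
        move_onset=move_onset,
        start_time=0.0,
        spike_times=[np.asarray(s, float) for s in spike_times],
    )


def brute_force_posterior(trial, params):
    """Exhaustive path-sum oracle: enumerate all latent state paths.

    Mirrors the declared model conventions (clicks in step window t drive
    the t -> t+1 transition; choice read out at the final step) but sums
    over every path explicitly instead of recursing.
    """
    import itertools

    dt = params.dt
    grid = params.grid
    T = max(1, int(np.floor(min(1.0, trial.move_onset) / dt + 1e-9)))
    adapted = adapt_clicks(trial.clicks, params.adaptation)
    moments = discretize_inputs(adapted, params.sigma_s2, dt, T)
    mats = [transition_matrix(grid, moments.mean[t], moments.var[t], dt) for t in range(T)]
    pi = initial_distribution(grid, params.mu0)
    counts = np.stack(
        [
            np.bincount(
                np.floor(np.asarray(st)[(np.asarray(st) >= 0) & (np.asarray(st) < T * dt)] / dt).astype(int),
                minlength=T,
            )
            for st in trial.spike_times
        ],
        axis=1,
    ).astype(float)
    baselines = np.stack(
        [
            n.baseline.evaluate(T, dt, trial.start_time, trial.move_onset, trial.spike_times[i])
            for i, n in enumerate(params.neurons)
        ],
        axis=1,
    )
    em = np.stack(
        [
            emission_loglik(counts[t], grid, params.w_ea, params.w_dc, baselines[t], dt)
            for t in range(T)
        ]
    )
    cp = choice_likelihood(trial.choice, grid)
    total = 0.0
    joint = np.zeros((T, grid.n_states))
    for path in itertools.product(range(grid.n_states), repeat=T):
        p = pi[path[0]] * np.exp(em[0, path[0]])
        for t in range(1, T):
            p *= mats[t - 1][path[t - 1], path[t]] * np.exp(em[t, path[t]])
        p *= cp[path[-1]]
        total += p
        for t in range(T):
            joint[t, path[t]] += p
    return np.log(total), joint / total


class TestTrialLoglikOracles:
    def test_matches_exhaustive_path_enumeration(self):
        neurons = (intercept_neuron(1.5, -1.0, 8.0), intercept_neuron(-0.5, 2.0, 15.0))
        params = ModelParams(bound=2.0, sigma_s2=0.5, mu0=0.3, neurons=neurons, n_interior=3)
        rng = np.random.default_rng(3)
        trial = _make_trial(
            params,
            spike_times=[rng.uniform(0, 0.05, 4), rng.uniform(0, 0.05, 6)],
            choice="R",
            move_onset=0.05,
        )
        ll_brute, _ = brute_force_posterior(trial, params)
        ll_filter = trial_loglik(trial, params)
        assert abs(ll_filter - ll_brute) < 1e-10

    def test_matches_exhaustive_for_left_choice(self):
        neurons = (intercept_neuron(0.8, 0.8, 5.0),)
        params = ModelParams(bound=1.5, sigma_s2=1.0, mu0=-0.2, neurons=neurons, n_interior=3)
        trial = _make_trial(
            params, spike_times=[np.array([0.005, 0.031])], choice="L", move_onset=0.04,
            right=(0.012,), left=(0.021,),
        )
        ll_brute, _ = brute_force_posterior(trial, params)
        assert abs(trial_loglik(trial, params) - ll_brute) < 1e-10

    def test_matches_particle_filter(self):
        rng = np.random.default_rng(0)
        neurons = random_neurons(4, rng, weight_scale=1.5)
        params = ModelParams(bound=3.0, sigma_s2=1.0, mu0=0.1, neurons=neurons, n_interior=99)
        sim = simulate_session(params, 3, seed=5)
        for i in range(3):
            tr = sim.session.trial(i)
            ll = trial_loglik(tr, params)
            reps = np.array([particle_loglik(tr, params, 4000, seed=100 + k) for k in range(12)])
            M = reps.max()
            lik = np.exp(reps - M)
            se = lik.std(ddof=1) / np.sqrt(len(reps))
            assert abs(np.exp(ll - M) - lik.mean()) < 3 * se + 1e-12

    def test_symmetric_no_click_no_weight_case(self):
        # flat emissions and a huge bound: loglik = Poisson terms + log 0.5
        from scipy.special import gammaln

        neurons = (intercept_neuron(0.0, 0.0, 10.0),)
        params = ModelParams(bound=500.0, sigma_s2=0.0, mu0=0.0, neurons=neurons, n_interior=99)
        spikes = np.array([0.005, 0.035, 0.081])
        trial = Trial(
            clicks=ClickTrain(left_times=np.array([]), right_times=np.array([]), duration=0.2),
            choice="R",
            move_onset=0.1,
            start_time=0.0,
            spike_times=[spikes],
        )
        T, dt, lam = 10, 0.01, 10.0
        counts = np.bincount((spikes / dt).astype(int), minlength=T)
        expected = np.sum(counts * np.log(lam * dt) - lam * dt - gammaln(counts + 1.0)) + np.log(0.5)
        assert np.isclose(trial_loglik(trial, params), expected, atol=1e-6)

    def test_grid_refinement_convergence(self, demo_params, demo_session):
        tr = demo_session.trial(0)
        coarse = trial_loglik(tr, demo_params.__class__(**{**demo_params.__dict__, "n_interior": 99}))
        fine = trial_loglik(tr, demo_params.__class__(**{**demo_params.__dict__, "n_interior": 199}))
        assert abs(coarse - fine) < 1e-3


class TestSmooth:
    def test_columns_sum_to_one(self, demo_params, demo_session):
        post = smooth(demo_session.trial(1), demo_params)
        assert np.allclose(post.smoothed.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(post.filtered.sum(axis=1), 1.0, atol=1e-10)

    def test_final_step_filtered_equals_smoothed(self, demo_params, demo_session):
        post = smooth(demo_session.trial(2), demo_params)
        assert np.allclose(post.filtered[-1], post.smoothed[-1], atol=1e-12)

    def test_matches_exhaustive_posterior(self):
        neurons = (intercept_neuron(1.0, -0.5, 12.0),)
        params = ModelParams(bound=1.8, sigma_s2=0.4, mu0=0.1, neurons=neurons, n_interior=3)
        trial = _make_trial(params, spike_times=[np.array([0.015, 0.041])], move_onset=0.05)
        _, joint = brute_force_posterior(trial, params)
        post = smooth(trial, params)
        assert np.max(np.abs(post.smoothed - joint)) < 1e-10


class TestDetectCommitment:
    def _posterior(self, left, right):
        left, right = np.asarray(left, float), np.asarray(right, float)
        T = len(left)
        sm = np.zeros((T, 5))
        sm[:, 0] = left
        sm[:, -1] = right
        sm[:, 2] = 1.0 - left - right
        return LatentPosterior(filtered=sm, smoothed=sm, loglik=0.0)

    def test_first_crossing_step_and_side(self):
        post = self._posterior([0, 0, 0, 0], [0.1, 0.5, 0.85, 0.9])
        assert detect_commitment(post, 0.8) == (2, "R")

    def test_never_exceeded_returns_none(self):
        post = self._posterior([0.1, 0.2], [0.3, 0.4])
        assert detect_commitment(post, 0.8) is None

    def test_split_bound_mass_not_detected(self):
        post = self._posterior([0.45, 0.45], [0.45, 0.45])
        assert detect_commitment(post, 0.8) is None

    def test_threshold_validation(self):
        post = self._posterior([0.0], [1.0])
        with pytest.raises(ValueError):
            detect_commitment(post, 1.5)

    def test_configurable_threshold(self):
        post = self._posterior([0, 0], [0.5, 0.7])
        assert detect_commitment(post, 0.4) == (0, "R")


@pytest.fixture(scope="module")
def tiny_sim():
    rng = np.random.default_rng(1)
    neurons = random_neurons(4, rng, weight_scale=2.0)
    params = ModelParams(bound=3.0, sigma_s2=1.0, mu0=0.0, neurons=neurons, n_interior=21)
    return simulate_session(params, 30, seed=2)


class TestFitMap:

    def test_dominating_prior_pins_estimates(self, tiny_sim):
        cfg = FitConfig(
            n_interior=15,
            maxiter=60,
            n_restarts=1,
            prior_sd_latent=1e-4,
            prior_sd_weights=1e-4,
            freeze_baseline=True,
        )
        fm = fit_map(tiny_sim.session, cfg)
        # unconstrained prior means are 0 -> B = e^0 = 1, mu0 = 0, w = 0
        assert abs(np.log(fm.params.bound)) < 0.05
        assert abs(fm.params.mu0) < 0.05
        assert np.all(np.abs(fm.params.w_ea) < 0.05)

    def test_optimum_not_worse_than_initialization(self, tiny_sim):
        cfg = FitConfig(n_interior=15, maxiter=25, n_restarts=1, freeze_baseline=True)
        fm = fit_map(tiny_sim.session, cfg)
        assert fm.log_posterior >= fm.trace[0] - 1e-9

    def test_deterministic_under_seed(self, tiny_sim):
        cfg = FitConfig(n_interior=15, maxiter=10, n_restarts=2, seed=5, freeze_baseline=True)
        a = fit_map(tiny_sim.session, cfg)
        b = fit_map(tiny_sim.session, cfg)
        assert a.params.bound == b.params.bound
        assert np.array_equal(a.params.w_ea, b.params.w_ea)

    def test_requires_neurons(self):
        params = ModelParams(bound=2.0, sigma_s2=1.0, mu0=0.0, neurons=())
        sim = simulate_session(params, 5, seed=0)
        with pytest.raises(ValueError):
            fit_map(sim.session, FitConfig())


class TestCrossValidate:
    def test_folds_disjoint_and_cover(self):
        rng = np.random.default_rng(4)
        neurons = random_neurons(2, rng)
        params = ModelParams(bound=2.5, sigma_s2=1.0, mu0=0.0, neurons=neurons, n_interior=15)
        sim = simulate_session(params, 12, seed=3)
        cfg = FitConfig(n_interior=9, maxiter=5, n_restarts=1, freeze_baseline=True)
        cv = crossvalidate(sim.session, k=3, config=cfg)
        assert set(cv.fold_assignments) == {0, 1, 2}
        assert len(cv.test_loglik) == 12
        assert np.all(np.isfinite(cv.test_loglik))

    def test_leave_one_out_degenerate(self):
        rng = np.random.default_rng(4)
        neurons = random_neurons(1, rng)
        params = ModelParams(bound=2.5, sigma_s2=1.0, mu0=0.0, neurons=neurons, n_interior=9)
        sim = simulate_session(params, 5, seed=3)
        cfg = FitConfig(n_interior=9, maxiter=2, n_restarts=1, freeze_baseline=True)
        cv = crossvalidate(sim.session, k=5, config=cfg)
        assert len(cv.fold_models) == 5

    def test_invalid_folds(self, demo_session):
        with pytest.raises(ValueError):
            crossvalidate(demo_session, k=1)
        with pytest.raises(ValueError):
            crossvalidate(demo_session, k=demo_session.n_trials + 1)


class TestCommitmentTable:
    def test_table_schema_and_times(self, demo_params, demo_session):
        table = commitment_table(demo_session, demo_params)
        assert list(table.columns) == ["trial", "commit_step", "commit_s", "side", "max_bound_prob"]
        assert len(table) == demo_session.n_trials
        det = table[table.commit_step >= 0]
        assert np.allclose(det.commit_s, (det.commit_step + 1) * demo_params.dt)
        und = table[table.commit_step < 0]
        assert und.commit_s.isna().all()
        assert (table.max_bound_prob <= 1.0).all()
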