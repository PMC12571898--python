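import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driftswitch.analyses import (
    causal_gaussian_kernel,
    choice_selectivity,
    compute_pcth,
    compute_psth,
    ei_group,
    engagement_index,
    psth_r2,
    select_neurons,
    state_space_trajectories,
)
from driftswitch.model import ModelParams
from driftswitch.session import GroundTruth, Session, TrialData
from driftswitch.simulate import simulate_session
from driftswitch.stimuli import ClickTrain

from tests.conftest import intercept_neuron


def _session_from_counts(choice_labels, spike_times, move_onset=1.05):
    """Minimal session: one neuron unless spike_times is a list of lists."""
    trials = [
        TrialData(
            clicks=ClickTrain(left_times=np.array([0.0]), right_times=np.array([0.0]), duration=1.0),
            choice=c,
            move_onset=move_onset,
            start_time=5.0 * i,
        )
        for i, c in enumerate(choice_labels)
    ]
    if not isinstance(spike_times[0], list):
        spike_times = [spike_times]
    return Session(
        session_id="toy",
        trials=trials,
        neuron_ids=[f"n{i}" for i in range(len(spike_times))],
        spike_times=[[np.asarray(s, float) for s in per] for per in spike_times],
    )


class TestSelectNeurons:
    def _poisson_session(self, rate_r, rate_l, n_trials=60, seed=0):
        rng = np.random.default_rng(seed)
        choices, spikes = [], []
        for i in range(n_trials):
            c = "R" if i % 2 == 0 else "L"
            rate = rate_r if c == "R" else rate_l
            n = rng.poisson(rate * 1.0)
            spikes.append(np.sort(rng.uniform(0, 1.0, n)))
            choices.append(c)
        return _session_from_counts(choices, spikes)

    def test_indiscriminate_neuron_excluded(self):
        # enough trials that auROC noise stays inside the [0.42, 0.58] band
        s = self._poisson_session(10.0, 10.0, n_trials=400)
        included, table = select_neurons(s)
        assert len(included) == 0
        aurocs = table.filter(like="auroc_w").to_numpy()
        assert np.nanmax(np.abs(aurocs - 0.5)) < 0.15

    def test_selective_neuron_included(self):
        s = self._poisson_session(20.0, 5.0)
        included, _ = select_neurons(s)
        assert list(included) == [0]

    def test_low_rate_neuron_excluded_despite_selectivity(self):
        s = self._poisson_session(1.8, 0.2)
        included, table = select_neurons(s)
        assert len(included) == 0
        assert table.mean_rate[0] < 2.0

    def test_single_choice_flagged(self):
        s = self._poisson_session(10.0, 10.0)
        s = Session(
            session_id="x",
            trials=[
                TrialData(t.clicks, "R", t.move_onset, t.start_time) for t in s.trials
            ],
            neuron_ids=s.neuron_ids,
            spike_times=s.spike_times,
        )
        included, table = select_neurons(s)
        assert len(included) == 0
        assert bool(table.auroc_undefined[0])

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(0.1, 10.0), shift=st.floats(0.0, 5.0))
    def test_auroc_invariant_to_monotone_transform(self, scale, shift):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        counts = rng.poisson(5, 40).astype(float)
        y = rng.random(40) < 0.5
        if len(np.unique(y)) < 2:
            y[0] = ~y[0]
        a = roc_auc_score(y, counts)
        b = roc_auc_score(y, scale * counts + shift)
        assert np.isclose(a, b)


class TestPSTH:
    def test_kernel_unit_sum_and_causal(self):
        k = causal_gaussian_kernel(0.1, 0.3, 0.01)
        assert np.isclose(k.sum(), 1.0)
        assert len(k) == 30
        assert np.all(np.diff(k) < 0)  # decaying forward in time

    def test_flat_for_homogeneous_poisson(self):
        rng = np.random.default_rng(3)
        rate = 10.0
        spikes = [np.sort(rng.uniform(0, 1.0, rng.poisson(rate))) for _ in range(400)]
        s = _session_from_counts(["R"] * 400, spikes)
        psth = compute_psth(s, 0, range(400))
        mid = psth.rate[35:]  # past the kernel's leading edge
        assert np.allclose(mid.mean(), rate, rtol=0.1)

    def test_single_spike_impulse_response(self):
        s = _session_from_counts(["R"], [np.array([0.30])])
        psth = compute_psth(s, 0, [0])
        k = causal_gaussian_kernel(0.1, 0.3, 0.01)
        expected = np.zeros(100)
        expected[30 : 30 + len(k)] = k / 0.01
        assert np.allclose(psth.rate, expected)

    def test_normalized_constant_rate_near_one(self):
        rng = np.random.default_rng(4)
        spikes = [np.sort(rng.uniform(0, 1.0, rng.poisson(20))) for _ in range(300)]
        s = _session_from_counts(["R"] * 300, spikes)
        psth = compute_psth(s, 0, range(300), normalize=True)
        # mean of the normalized PSTH is 1 by construction; the plateau sits
        # slightly above 1 because the causal kernel ramps up at the edge
        assert np.isclose(psth.rate.mean(), 1.0, atol=1e-9)
        assert np.allclose(psth.rate[35:].mean(), 1.0, rtol=0.15)

    def test_empty_condition_errors(self, demo_session):
        with pytest.raises(ValueError):
            compute_psth(demo_session, 0, [])

    def test_merged_equals_weighted_mean_of_conditions(self):
        rng = np.random.default_rng(5)
        spikes = [np.sort(rng.uniform(0, 1.0, rng.poisson(8))) for _ in range(90)]
        s = _session_from_counts(["R"] * 60 + ["L"] * 30, spikes)
        a = compute_psth(s, 0, range(60))
        b = compute_psth(s, 0, range(60, 90))
        both = compute_psth(s, 0, range(90))
        merged = (60 * a.rate + 30 * b.rate) / 90
        assert np.allclose(both.rate, merged)

    def test_bootstrap_ci_brackets_mean(self):
        rng = np.random.default_rng(6)
        spikes = [np.sort(rng.uniform(0, 1.0, rng.poisson(12))) for _ in range(100)]
        s = _session_from_counts(["R"] * 100, spikes)
        psth = compute_psth(s, 0, range(100), n_boot=200, seed=1)
        assert np.all(psth.ci_lo <= psth.rate + 1e-9)
        assert np.all(psth.ci_hi >= psth.rate - 1e-9)


class TestPsthR2:
    def test_perfect_prediction(self):
        r = np.array([1.0, 2.0, 3.0])
        l = np.array([3.0, 2.0, 1.0])
        assert psth_r2(r, l, r, l) == 1.0

    def test_condition_mean_prediction_zero(self):
        r = np.array([1.0, 2.0, 3.0])
        l = np.array([5.0, 6.0, 10.0])
        pr = np.full(3, r.mean())
        pl = np.full(3, l.mean())
        assert np.isclose(psth_r2(r, l, pr, pl), 0.0)

    def test_hand_computed_toy(self):
        r = np.array([2.0, 4.0, 6.0])
        l = np.array([1.0, 1.0, 1.0])
        pr = np.array([2.0, 4.0, 8.0])
        pl = np.array([1.0, 2.0, 1.0])
        ss_res = (6 - 8) ** 2 + (1 - 2) ** 2  # 5
        ss_tot = (2 - 4) ** 2 + (4 - 4) ** 2 + (6 - 4) ** 2  # 8 (l-part is 0)
        assert np.isclose(psth_r2(r, l, pr, pl), 1 - ss_res / ss_tot)

    def test_never_exceeds_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            r, l, pr, pl = rng.normal(size=(4, 10))
            if np.var(r) + np.var(l) == 0:
                continue
            assert psth_r2(r, l, pr, pl) <= 1.0

    def test_constant_observed_errors(self):
        c = np.ones(5)
        with pytest.raises(ValueError):
            psth_r2(c, c, c, c)


class TestChoiceSelectivity:
    def test_constant_difference_gives_ones(self):
        r = np.array([2.0, 3.0, 4.0])
        l = r - 0.7
        sel = choice_selectivity(r, l)
        assert np.allclose(sel.series, 1.0)

    def test_peak_normalized_to_unit(self):
        rng = np.random.default_rng(1)
        r, l = rng.normal(size=(2, 50))
        sel = choice_selectivity(r, l)
        assert np.isclose(abs(sel.series[sel.t_star]), 1.0)
        assert np.max(np.abs(sel.series)) <= 1.0 + 1e-12

    def test_toy_example(self):
        sel = choice_selectivity(np.array([1.0, 3.0]), np.array([1.0, 1.0]))
        assert sel.t_star == 1
        assert np.allclose(sel.series, [0.0, 1.0])

    def test_identical_psths_error(self):
        with pytest.raises(ValueError):
            choice_selectivity(np.ones(3), np.ones(3))


class TestEngagementIndex:
    @pytest.mark.parametrize(
        "w_ea,w_dc,expected",
        [(1.0, 0.0, 1.0), (0.0, 1.0, -1.0), (0.3, 0.3, 0.0), (-2.0, 1.0, 1.0 / 3.0)],
    )
    def test_values(self, w_ea, w_dc, expected):
        assert np.isclose(engagement_index(w_ea, w_dc), expected)

    def test_range(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            w1, w2 = rng.normal(size=2)
            assert -1.0 <= engagement_index(w1, w2) <= 1.0

    def test_zero_weights_undefined(self):
        with pytest.raises(ValueError):
            engagement_index(0.0, 0.0)

    def test_grouping(self):
        assert ei_group(0.5) == "accumulation"
        assert ei_group(1.0 / 3.0) == "accumulation"
        assert ei_group(0.0) == "similar"
        assert ei_group(-1.0 / 3.0) == "similar"
        assert ei_group(-0.34) == "commitment"


@pytest.fixture(scope="module")
def pcth_setup():
    neurons = (
        intercept_neuron(2.0, 2.0, 10.0),  # similar
        intercept_neuron(2.5, 0.0, 10.0),  # accumulation
        intercept_neuron(0.0, 2.5, 10.0),  # commitment
    )
    params = ModelParams(bound=2.5, sigma_s2=1.0, mu0=0.0, neurons=neurons, n_interior=21)
    sim = simulate_session(params, 400, seed=3)
    ei = [engagement_index(n.w_ea, n.w_dc) for n in neurons]
    return sim, ei


class TestPCTH:

    def test_groups_and_lags(self, pcth_setup):
        sim, ei = pcth_setup
        out = compute_pcth(sim.session, sim.ground_truth.commit_step, ei)
        assert set(out.groups) == {"similar", "accumulation", "commitment"}
        assert out.lags[0] == pytest.approx(-0.5)
        assert 0.0 in out.lags

    def test_commitment_neuron_steps_up_at_zero_lag(self, pcth_setup):
        sim, ei = pcth_setup
        out = compute_pcth(sim.session, sim.ground_truth.commit_step, ei)
        series = out.groups["commitment"]["preferred"]
        lag = out.lags
        pre = np.nanmean(series[(lag >= -0.3) & (lag < -0.05)])
        post = np.nanmean(series[(lag >= 0.05) & (lag < 0.3)])
        assert post > pre * 1.5

    def test_shuffle_preserves_multiset_and_smooths_step(self, pcth_setup):
        sim, ei = pcth_setup
        steps = sim.ground_truth.commit_step
        out = compute_pcth(sim.session, steps, ei, shuffle=True, seed=4)
        assert out.n_trials_used == int(np.sum(steps >= 0))
        series = out.groups["commitment"]["preferred"]
        lag = out.lags
        pre = np.nanmean(series[(lag >= -0.3) & (lag < -0.05)])
        post = np.nanmean(series[(lag >= 0.05) & (lag < 0.3)])
        real = compute_pcth(sim.session, steps, ei).groups["commitment"]["preferred"]
        rpre = np.nanmean(real[(lag >= -0.3) & (lag < -0.05)])
        rpost = np.nanmean(real[(lag >= 0.05) & (lag < 0.3)])
        assert (post - pre) < 0.5 * (rpost - rpre)

    def test_no_detected_trials_errors(self, pcth_setup):
        sim, ei = pcth_setup
        with pytest.raises(ValueError):
            compute_pcth(sim.session, np.full(sim.session.n_trials, -1), ei)


class TestStateSpaceTrajectories:
    def test_reconstruction(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 8))
        res = state_space_trajectories(X)
        recon = res.projections_full @ res.axes_full.T
        assert np.allclose(recon, X - res.row_mean, atol=1e-10)

    def test_variance_ordering(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 6)) * np.array([5, 3, 2, 1, 1, 0.5])
        res = state_space_trajectories(X)
        var = res.projections_full.var(axis=0)
        assert np.all(np.diff(var) <= 1e-9)

    def test_mirror_symmetric_conditions(self):
        t = np.linspace(0, 1, 100)
        cond_a = np.outer(t, np.array([1.0, 0.5, -0.3, 0.8]))
        X = np.vstack([cond_a, -cond_a])
        res = state_space_trajectories(X)
        pc1 = res.projections[:, 0]
        assert np.allclose(pc1[:100], -pc1[100:], atol=1e-10)

    def test_too_few_neurons(self):
        with pytest.raises(ValueError):
            state_space_trajectories(np.ones((10, 1)))


class TestFoldWeightReliability:
    def test_identical_folds_give_one(self):
        from driftswitch.analyses import fold_weight_reliability
        from driftswitch.inference import FitConfig, FittedModel

        neurons = tuple(intercept_neuron(w, -w) for w in (1.0, 2.0, -0.5))
        params = ModelParams(bound=2.0, sigma_s2=1.0, mu0=0.0, neurons=neurons)
        fm = FittedModel(
            params=params, log_posterior=0.0, trace=np.empty(0), converged=True,
            grad_norm=0.0, config=FitConfig(),
        )
        assert fold_weight_reliability([fm, fm, fm]) == 1.0

    def test_noisy_folds_below_one(self):
        from driftswitch.analyses import fold_weight_reliability
        from driftswitch.inference import FitConfig, FittedModel

        rng = np.random.default_rng(0)
        models = []
        base = rng.normal(size=6)
        for _ in range(4):
            w = base + rng.normal(0, 1.0, size=6)
            neurons = tuple(intercept_neuron(w[i], w[3 + i]) for i in range(3))
            params = ModelParams(bound=2.0, sigma_s2=1.0, mu0=0.0, neurons=neurons)
            models.append(
                FittedModel(params=params, log_posterior=0.0, trace=np.empty(0),
                            converged=True, grad_norm=0.0, config=FitConfig())
            )
        r = fold_weight_reliability(models)
        assert r < 1.0

    def test_single_fold_rejected(self):
        from driftswitch.analyses import fold_weight_reliability

        with pytest.raises(ValueError):
            fold_weight_reliability([])
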