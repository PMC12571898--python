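"""Latent inference: filtering, smoothing, MAP fitting and commitment times.

The latent accumulator is marginalized on a discretized grid by forward
filtering; forward-backward smoothing yields per-step posteriors over the
grid states given clicks, spikes and the behavioural choice. All model
parameters (three latent parameters plus the per-neuron measurement
parameters) are fit jointly by maximum a posteriori estimation. The
per-trial time of decision commitment is the first step at which the
smoothed posterior probability of a single bound state exceeds a threshold.

Gradients of the log-likelihood with respect to the emission parameters are
computed analytically from the smoothed posteriors (Fisher's identity);
gradients with respect to the three latent parameters use central finite
differences on their unconstrained scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln

from driftswitch._fastpath import fb_kernel
from driftswitch.model import (
    BaselineModel,
    BasisConfig,
    LatentGrid,
    ModelParams,
    NeuronParams,
    choice_likelihood,
    fit_baseline,
    initial_distribution,
    log_softplus,
    softplus,
    state_weights,
    transition_matrices_from_unique,
)
from driftswitch.session import Session, Trial
from driftswitch.stimuli import adapt_clicks

logger = logging.getLogger(__name__)

__all__ = [
    "LatentPosterior",
    "FitConfig",
    "FittedModel",
    "CrossValidationResult",
    "trial_loglik",
    "smooth",
    "fit_map",
    "crossvalidate",
    "session_loglik",
    "detect_commitment",
    "commitment_table",
    "particle_loglik",
]

_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class LatentPosterior:
    """Filtered and smoothed state probabilities of one trial.

    Arrays have shape (n_steps, n_states); states are ordered
    [-B, interior..., +B]. The final filtered step includes the choice
    likelihood, so filtered and smoothed agree there.
    """

    filtered: np.ndarray
    smoothed: np.ndarray
    loglik: float
    floored: bool = False

    @property
    def n_steps(self) -> int:
        return self.smoothed.shape[0]

    @property
    def p_left_bound(self) -> np.ndarray:
        return self.smoothed[:, 0]

    @property
    def p_right_bound(self) -> np.ndarray:
        return self.smoothed[:, -1]


@dataclass(frozen=True)
class FitConfig:
    """Settings for :func:`fit_map` and :func:`crossvalidate`."""

    n_interior: int = 99
    maxiter: int = 150
    n_restarts: int = 3
    restart_scale: float = 0.5
    seed: int = 0
    use_prior: bool = True
    prior_sd_latent: float = 2.0
    prior_sd_weights: float = 5.0
    freeze_baseline: bool = True
    tie_weights: bool = False
    basis: BasisConfig = field(default_factory=BasisConfig.intercept_only)
    fd_step: float = 1e-3
    gtol: float = 1e-4
    init_params: Optional[ModelParams] = None


@dataclass(frozen=True)
class FittedModel:
    """Point estimate with optimizer diagnostics."""

    params: ModelParams
    log_posterior: float
    trace: np.ndarray
    converged: bool
    grad_norm: float
    config: FitConfig
    message: str = ""


@dataclass(frozen=True)
class CrossValidationResult:
    """Per-fold fits and out-of-sample trial log-likelihoods."""

    fold_models: tuple[FittedModel, ...]
    fold_assignments: np.ndarray
    test_loglik: np.ndarray

    @property
    def mean_test_loglik(self) -> float:
        return float(np.mean(self.test_loglik))


# ---------------------------------------------------------------------------
# per-trial preparation


@dataclass
class _TrialPrep:
    n_steps: int
    counts: np.ndarray  # (T, N)
    click_mean: np.ndarray  # (T,) signed sum of adapted magnitudes
    click_sq: np.ndarray  # (T,) sum of squared magnitudes
    choice: str
    baseline: np.ndarray  # (T, N) current baseline values
    designs: Optional[list[np.ndarray]] = None  # per-neuron (T, P)
    # cached structure for fast repeated passes
    uniq_mean: Optional[np.ndarray] = None  # (K,)
    uniq_csq: Optional[np.ndarray] = None  # (K,)
    trans_index: Optional[np.ndarray] = None  # (T,) -> K
    lgam: Optional[np.ndarray] = None  # (T,) sum_n log(y!)


def _bin_spikes(spike_times: np.ndarray, n_steps: int, dt: float) -> np.ndarray:
    t = np.asarray(spike_times, dtype=float)
    t = t[(t >= 0) & (t < n_steps * dt)]
    return np.bincount(np.floor(t / dt).astype(int), minlength=n_steps).astype(float)


def trial_n_steps(move_onset: float, dt: float, max_duration: float = 1.0) -> int:
    """Number of emission steps: up to the earlier of 1 s or fixation exit."""
    return max(1, int(np.floor(min(max_duration, move_onset) / dt + 1e-9)))


def _prepare_trial(
    trial: Trial,
    params: ModelParams,
    baselines: Optional[Sequence[BaselineModel]] = None,
    keep_designs: bool = False,
) -> _TrialPrep:
    dt = params.dt
    T = trial_n_steps(trial.move_onset, dt)
    counts = np.stack(
        [_bin_spikes(st, T, dt) for st in trial.spike_times], axis=1
    ) if trial.spike_times else np.zeros((T, 0))
    adapted = adapt_clicks(trial.clicks, params.adaptation)
    keep = adapted.times < T * dt
    m = np.zeros(T)
    csq = np.zeros(T)
    if keep.any():
        steps = np.floor(adapted.times[keep] / dt).astype(int)
        signs = np.where(adapted.sides[keep] == "R", 1.0, -1.0)
        mags = adapted.magnitudes[keep]
        np.add.at(m, steps, signs * mags)
        np.add.at(csq, steps, mags**2)
    models = baselines if baselines is not None else [n.baseline for n in params.neurons]
    designs = [] if keep_designs else None
    b = np.zeros((T, len(models)))
    for n, bm in enumerate(models):
        X = bm.design(T, dt, trial.start_time, trial.move_onset, trial.spike_times[n])
        b[:, n] = X @ bm.coef
        if keep_designs:
            designs.append(X)
    mv = np.column_stack([m, csq])
    uniq, index = np.unique(mv, axis=0, return_inverse=True)
    lgam = gammaln(counts + 1.0).sum(axis=1)
    return _TrialPrep(
        T,
        counts,
        m,
        csq,
        trial.choice,
        b,
        designs,
        uniq_mean=uniq[:, 0],
        uniq_csq=uniq[:, 1],
        trans_index=index.astype(np.int64),
        lgam=lgam,
    )


# ---------------------------------------------------------------------------
# forward / forward-backward


def _emission_ll(
    counts: np.ndarray,
    grid: LatentGrid,
    w_ea: np.ndarray,
    w_dc: np.ndarray,
    baseline: np.ndarray,
    dt: float,
    want_grad: bool = False,
    lgam: Optional[np.ndarray] = None,
):
    """Summed per-state emission log-likelihood (T, S); optionally the
    per-neuron derivative d loglik / d eta, shape (T, N, S).

    ``lgam`` may pass precomputed per-step sums of log(y!).
    """
    T = counts.shape[0]
    if counts.shape[1] == 0:
        z = np.zeros((T, grid.n_states))
        return (z, np.zeros((T, 0, grid.n_states))) if want_grad else z
    if lgam is None:
        lgam = gammaln(counts + 1.0).sum(axis=1)
    W = state_weights(grid, w_ea, w_dc)
    eta = (W * grid.states[None, :])[None, :, :] + baseline[:, :, None]
    lam = softplus(eta)
    log_lam = log_softplus(eta, sp=lam)
    ll = counts[:, :, None] * (log_lam + np.log(dt)) - lam * dt
    ll_em = ll.sum(axis=1) - lgam[:, None]
    if not want_grad:
        return ll_em
    sig = expit(eta)
    ratio = np.where(lam > 1e-290, sig / np.where(lam > 1e-290, lam, 1.0), 1.0)
    dll_deta = counts[:, :, None] * ratio - dt * sig
    return ll_em, dll_deta


def _fb_core(
    pi: np.ndarray,
    mats: np.ndarray,
    index: np.ndarray,
    ll_em: np.ndarray,
    choice_p: np.ndarray,
    want_smooth: bool,
):
    """Scaled forward (and optionally backward) pass.

    The choice likelihood is folded into the final step's emission. Returns
    (loglik, filtered, smoothed, floored); posterior arrays are None when
    ``want_smooth`` is False.
    """
    shifts = ll_em.max(axis=1)
    E = np.exp(ll_em - shifts[:, None])
    loglik, filtered, smoothed, floored = fb_kernel(
        np.ascontiguousarray(pi),
        np.ascontiguousarray(mats),
        np.ascontiguousarray(index),
        np.ascontiguousarray(E),
        np.ascontiguousarray(choice_p),
        want_smooth,
    )
    if not np.isfinite(loglik):
        return -np.inf, None, None, True
    loglik = float(loglik + shifts.sum())
    if not want_smooth:
        return loglik, None, None, bool(floored)
    return loglik, filtered, smoothed, bool(floored)


def _mats_for(tp: _TrialPrep, grid: LatentGrid, sigma_s2: float, dt: float):
    """Per-trial transition matrices from the cached unique click rows."""
    mats = transition_matrices_from_unique(
        grid, tp.uniq_mean, sigma_s2 * tp.uniq_csq, dt
    )
    return mats, tp.trans_index


def _trial_pass(
    tp: _TrialPrep,
    params: ModelParams,
    grid: LatentGrid,
    pi: np.ndarray,
    want_smooth: bool = False,
    ll_em: Optional[np.ndarray] = None,
    mats_index=None,
):
    """Run one trial's filter (and smoother); pieces can be reused."""
    if ll_em is None:
        ll_em = _emission_ll(
            tp.counts, grid, params.w_ea, params.w_dc, tp.baseline, params.dt,
            lgam=tp.lgam,
        )
    if mats_index is None:
        mats_index = _mats_for(tp, grid, params.sigma_s2, params.dt)
    choice_p = choice_likelihood(tp.choice, grid)
    return _fb_core(pi, *mats_index, ll_em, choice_p, want_smooth)


def trial_loglik(
    trial: Trial,
    params: ModelParams,
    baselines: Optional[Sequence[BaselineModel]] = None,
) -> float:
    """Log-likelihood of one trial's spikes and choice given the clicks.

    Computed by the forward recursion on the discretized latent grid.
    Returns -inf (with a logged diagnostic) if the data have zero
    likelihood, never NaN.
    """
    tp = _prepare_trial(trial, params, baselines)
    grid = params.grid
    pi = initial_distribution(grid, params.mu0)
    ll, _, _, floored = _trial_pass(tp, params, grid, pi)
    if floored:
        logger.warning("trial likelihood underflow: state probabilities floored")
    return ll


def smooth(
    trial: Trial,
    params: ModelParams,
    baselines: Optional[Sequence[BaselineModel]] = None,
) -> LatentPosterior:
    """Forward-backward smoothed posterior over the latent grid."""
    tp = _prepare_trial(trial, params, baselines)
    grid = params.grid
    pi = initial_distribution(grid, params.mu0)
    ll, filt, smo, floored = _trial_pass(tp, params, grid, pi, want_smooth=True)
    if smo is None:
        raise FloatingPointError("zero trial likelihood: cannot smooth")
    return LatentPosterior(filtered=filt, smoothed=smo, loglik=ll, floored=floored)


# ---------------------------------------------------------------------------
# commitment detection


def detect_commitment(
    posterior: LatentPosterior, threshold: float = 0.8
) -> Optional[tuple[int, str]]:
    """First step at which a single bound's posterior exceeds ``threshold``.

    The rule takes the maximum over the two bound-state posteriors
    (commitment is to one side, not to "either bound"). Returns
    ``(step, side)`` or None if the threshold is never exceeded.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    pl, pr = posterior.p_left_bound, posterior.p_right_bound
    best = np.maximum(pl, pr)
    above = np.nonzero(best > threshold)[0]
    if len(above) == 0:
        return None
    step = int(above[0])
    side = "R" if pr[step] >= pl[step] else "L"
    return step, side


def commitment_table(
    session: Session,
    params: ModelParams,
    threshold: float = 0.8,
    baselines: Optional[Sequence[BaselineModel]] = None,
) -> pd.DataFrame:
    """Per-trial commitment times as a table.

    Columns: trial, commit_step, commit_s, side, max_bound_prob. Undetected
    trials have commit_step = -1 and NaN time/side.
    """
    rows = []
    for i in range(session.n_trials):
        post = smooth(session.trial(i), params, baselines)
        peak = float(np.max(np.maximum(post.p_left_bound, post.p_right_bound)))
        hit = detect_commitment(post, threshold)
        if hit is None:
            rows.append((i, -1, np.nan, "", peak))
        else:
            step, side = hit
            rows.append((i, step, (step + 1) * params.dt, side, peak))
    return pd.DataFrame(
        rows, columns=["trial", "commit_step", "commit_s", "side", "max_bound_prob"]
    )


# ---------------------------------------------------------------------------
# MAP fitting


class _Packing:
    """Mapping between the flat unconstrained vector and model parameters."""

    def __init__(self, n_neurons: int, n_coef: int, config: FitConfig):
        self.n_neurons = n_neurons
        self.n_coef = n_coef
        self.tie = config.tie_weights
        self.freeze = config.freeze_baseline
        self.n_weights = n_neurons if self.tie else 2 * n_neurons
        self.n_base = 0 if self.freeze else n_neurons * n_coef
        self.size = 3 + self.n_weights + self.n_base

    def unpack(self, theta: np.ndarray):
        bound = float(np.exp(theta[0]))
        sigma_s2 = float(np.exp(theta[1]))
        mu0 = float(theta[2])
        w = theta[3 : 3 + self.n_weights]
        if self.tie:
            w_ea = w.copy()
            w_dc = w.copy()
        else:
            w_ea = w[: self.n_neurons].copy()
            w_dc = w[self.n_neurons :].copy()
        coefs = None
        if not self.freeze:
            coefs = theta[3 + self.n_weights :].reshape(self.n_neurons, self.n_coef)
        return bound, sigma_s2, mu0, w_ea, w_dc, coefs

    def pack(self, params: ModelParams) -> np.ndarray:
        theta = np.zeros(self.size)
        theta[0] = np.log(params.bound)
        theta[1] = np.log(max(params.sigma_s2, 1e-6))
        theta[2] = params.mu0
        if self.tie:
            theta[3 : 3 + self.n_neurons] = params.w_ea
        else:
            theta[3 : 3 + self.n_neurons] = params.w_ea
            theta[3 + self.n_neurons : 3 + 2 * self.n_neurons] = params.w_dc
        if not self.freeze:
            theta[3 + self.n_weights :] = np.concatenate(
                [n.baseline.coef for n in params.neurons]
            )
        return theta

    def prior_sd(self, config: FitConfig) -> np.ndarray:
        sd = np.empty(self.size)
        sd[:3] = config.prior_sd_latent
        sd[3:] = config.prior_sd_weights
        return sd


def _objective_factory(
    preps: list[_TrialPrep],
    template: ModelParams,
    packing: _Packing,
    config: FitConfig,
):
    dt = template.dt
    n_int = config.n_interior
    h = config.fd_step

    def objective(theta: np.ndarray):
        bound, s2, mu0, w_ea, w_dc, coefs = packing.unpack(theta)
        grid = LatentGrid(bound, n_int)
        pi = initial_distribution(grid, mu0)
        # finite-difference companions for the three latent parameters
        grid_hi = LatentGrid(bound * np.exp(h), n_int)
        grid_lo = LatentGrid(bound * np.exp(-h), n_int)
        pi_B = (initial_distribution(grid_hi, mu0), initial_distribution(grid_lo, mu0))
        pi_mu = (initial_distribution(grid, mu0 + h), initial_distribution(grid, mu0 - h))
        s2_fd = (s2 * np.exp(h), s2 * np.exp(-h))

        total = 0.0
        fd = np.zeros(6)  # [B+, B-, s2+, s2-, mu+, mu-]
        g_ea = np.zeros(packing.n_neurons)
        g_dc = np.zeros(packing.n_neurons)
        g_base = (
            np.zeros((packing.n_neurons, packing.n_coef)) if not packing.freeze else None
        )
        z_int = grid.states[1:-1]
        zB = grid.states
        for tp in preps:
            if coefs is not None:
                base = np.stack(
                    [tp.designs[n] @ coefs[n] for n in range(packing.n_neurons)], axis=1
                )
                tp = replace(tp, baseline=base)
            ll_em, dll = _emission_ll(
                tp.counts, grid, w_ea, w_dc, tp.baseline, dt, want_grad=True,
                lgam=tp.lgam,
            )
            mi = _mats_for(tp, grid, s2, dt)
            choice_p = choice_likelihood(tp.choice, grid)
            ll, _, gamma, _ = _fb_core(pi, *mi, ll_em, choice_p, want_smooth=True)
            if not np.isfinite(ll):
                return np.inf, np.zeros_like(theta)
            total += ll
            # emission-parameter gradients via the smoothed posterior
            wgt = gamma[:, None, :] * dll  # (T, N, S)
            g_ea += np.einsum("tns,s->n", wgt[:, :, 1:-1], z_int)
            g_dc += wgt[:, :, 0].sum(axis=0) * zB[0] + wgt[:, :, -1].sum(axis=0) * zB[-1]
            if g_base is not None:
                q = wgt.sum(axis=2)  # (T, N)
                for n in range(packing.n_neurons):
                    g_base[n] += tp.designs[n].T @ q[:, n]
            # latent-parameter finite differences
            for k, (g2, p2) in enumerate(((grid_hi, pi_B[0]), (grid_lo, pi_B[1]))):
                ll_em2 = _emission_ll(
                    tp.counts, g2, w_ea, w_dc, tp.baseline, dt, lgam=tp.lgam
                )
                mi2 = _mats_for(tp, g2, s2, dt)
                cp2 = choice_likelihood(tp.choice, g2)
                fd[k] += _fb_core(p2, *mi2, ll_em2, cp2, False)[0]
            for k, s2v in enumerate(s2_fd):
                mi2 = _mats_for(tp, grid, s2v, dt)
                fd[2 + k] += _fb_core(pi, *mi2, ll_em, choice_p, False)[0]
            for k, piv in enumerate(pi_mu):
                fd[4 + k] += _fb_core(piv, *mi, ll_em, choice_p, False)[0]

        grad = np.zeros_like(theta)
        grad[0] = (fd[0] - fd[1]) / (2 * h)
        grad[1] = (fd[2] - fd[3]) / (2 * h)
        grad[2] = (fd[4] - fd[5]) / (2 * h)
        if packing.tie:
            grad[3 : 3 + packing.n_neurons] = g_ea + g_dc
        else:
            grad[3 : 3 + packing.n_neurons] = g_ea
            grad[3 + packing.n_neurons : 3 + 2 * packing.n_neurons] = g_dc
        if g_base is not None:
            grad[3 + packing.n_weights :] = g_base.ravel()
        if config.use_prior:
            sd = packing.prior_sd(config)
            total += float(-0.5 * np.sum((theta / sd) ** 2))
            grad = grad - theta / sd**2
        return -total, -grad

    return objective


def _init_params(
    session: Session, config: FitConfig, baselines: list[BaselineModel]
) -> ModelParams:
    """Heuristic initialization: proxy-evidence regression for the weights."""
    from driftswitch.stimuli import AdaptationParams

    dt = 0.01
    adaptation = (
        config.init_params.adaptation if config.init_params is not None else AdaptationParams()
    )
    z_all, y_all = [], []
    for i in range(session.n_trials):
        tr = session.trial(i)
        T = trial_n_steps(tr.move_onset, dt)
        ad = adapt_clicks(tr.clicks, adaptation)
        keep = ad.times < T * dt
        m = np.zeros(T)
        if keep.any():
            steps = np.floor(ad.times[keep] / dt).astype(int)
            np.add.at(m, steps, np.where(ad.sides[keep] == "R", 1.0, -1.0) * ad.magnitudes[keep])
        z = np.cumsum(m)
        counts = np.stack([_bin_spikes(st, T, dt) for st in tr.spike_times], axis=1)
        z_all.append(z)
        y_all.append(counts)
    z = np.concatenate(z_all)
    Y = np.concatenate(y_all)
    var = np.var(z)
    w0 = np.array(
        [np.cov(z, Y[:, n] / dt)[0, 1] / var if var > 1e-12 else 0.0 for n in range(Y.shape[1])]
    )
    neurons = tuple(
        NeuronParams(w_ea=w0[n] * 0.5, w_dc=w0[n] * 0.5, baseline=baselines[n])
        for n in range(Y.shape[1])
    )
    return ModelParams(
        bound=max(1.0, float(np.quantile(np.abs(z), 0.9))),
        sigma_s2=1.0,
        mu0=0.0,
        neurons=neurons,
        adaptation=adaptation,
        dt=dt,
        n_interior=config.n_interior,
    )


def fit_map(session: Session, config: FitConfig | None = None) -> FittedModel:
    """Jointly fit latent and per-neuron parameters by MAP.

    Maximizes the summed trial log-likelihood plus the log of zero-mean
    Gaussian priors over {log B, log sigma_s2, mu0} and all per-neuron
    parameters. Positivity of B and sigma_s2 is enforced by optimizing on
    the log scale. Multiple seeded restarts are run and the best kept.
    """
    config = config or FitConfig()
    if session.n_neurons < 1:
        raise ValueError("at least one neuron is required")
    rng = np.random.default_rng(config.seed)

    if config.init_params is not None and config.init_params.neurons:
        baselines = [n.baseline for n in config.init_params.neurons]
        init = replace(config.init_params, n_interior=config.n_interior)
    else:
        baselines = []
        for n in range(session.n_neurons):
            counts, starts, moves, spikes = [], [], [], []
            for i in range(session.n_trials):
                tr = session.trial(i)
                T = trial_n_steps(tr.move_onset, 0.01)
                counts.append(_bin_spikes(tr.spike_times[n], T, 0.01))
                starts.append(tr.start_time)
                moves.append(tr.move_onset)
                spikes.append(tr.spike_times[n])
            baselines.append(
                fit_baseline(counts, np.array(starts), np.array(moves), spikes, config.basis)
            )
        init = _init_params(session, config, baselines)

    packing = _Packing(session.n_neurons, baselines[0].config.n_coef, config)
    preps = [
        _prepare_trial(session.trial(i), init, baselines, keep_designs=not config.freeze_baseline)
        for i in range(session.n_trials)
    ]
    objective = _objective_factory(preps, init, packing, config)
    theta0 = packing.pack(init)

    best = None
    for r in range(max(1, config.n_restarts)):
        th = theta0.copy()
        if r > 0:
            th = th + rng.normal(0.0, config.restart_scale, size=th.shape)
        trace: list[float] = []

        def traced(x):
            f, g = objective(x)
            trace.append(-f)
            return f, g

        res = minimize(
            traced,
            th,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": config.maxiter, "gtol": config.gtol},
        )
        if best is None or -res.fun > best[0]:
            best = (-res.fun, res, np.array(trace))

    logpost, res, trace = best
    bound, s2, mu0, w_ea, w_dc, coefs = packing.unpack(res.x)
    neurons = []
    for n in range(session.n_neurons):
        bm = baselines[n]
        if coefs is not None:
            bm = BaselineModel(coefs[n], bm.config, bm.session_span)
        neurons.append(NeuronParams(w_ea=float(w_ea[n]), w_dc=float(w_dc[n]), baseline=bm))
    params = ModelParams(
        bound=bound,
        sigma_s2=s2,
        mu0=mu0,
        neurons=tuple(neurons),
        adaptation=init.adaptation,
        dt=init.dt,
        n_interior=config.n_interior,
    )
    return FittedModel(
        params=params,
        log_posterior=float(logpost),
        trace=trace,
        converged=bool(res.success),
        grad_norm=float(np.max(np.abs(res.jac))),
        config=config,
        message=str(res.message),
    )


def session_loglik(
    session: Session,
    params: ModelParams,
    trial_indices: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Per-trial log-likelihoods under fixed parameters."""
    idx = range(session.n_trials) if trial_indices is None else trial_indices
    return np.array([trial_loglik(session.trial(i), params) for i in idx])


def crossvalidate(
    session: Session, k: int = 5, config: FitConfig | None = None
) -> CrossValidationResult:
    """Trial-level k-fold cross-validation.

    Fits on each training split and evaluates per-trial log-likelihood on
    the held-out trials. Folds are disjoint and cover all trials.
    """
    from sklearn.model_selection import KFold

    config = config or FitConfig()
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > session.n_trials:
        raise ValueError("more folds than trials")
    kf = KFold(n_splits=k, shuffle=True, random_state=config.seed)
    assignments = np.empty(session.n_trials, dtype=int)
    test_ll = np.empty(session.n_trials)
    models = []
    for fold, (train_idx, test_idx) in enumerate(kf.split(np.arange(session.n_trials))):
        if len(train_idx) == 0 or len(test_idx) == 0:
            raise ValueError("fold with zero trials")
        sub = session.subset(train_idx)
        fm = fit_map(sub, config)
        models.append(fm)
        assignments[test_idx] = fold
        test_ll[test_idx] = session_loglik(session, fm.params, test_idx)
    return CrossValidationResult(tuple(models), assignments, test_ll)


# ---------------------------------------------------------------------------
# particle Monte-Carlo oracle


def particle_loglik(
    trial: Trial,
    params: ModelParams,
    n_particles: int = 10_000,
    seed: int = 0,
    baselines: Optional[Sequence[BaselineModel]] = None,
) -> float:
    """Bootstrap-particle-filter estimate of the trial log-likelihood.

    Simulates the continuous-state latent (no grid discretization) and is
    therefore an independent check of the discretized forward filter. The
    estimator of the marginal likelihood is unbiased.
    """
    rng = np.random.default_rng(seed)
    tp = _prepare_trial(trial, params, baselines)
    dt, T, N = params.dt, tp.n_steps, tp.counts.shape[1]
    B = params.bound
    w_ea, w_dc = params.w_ea, params.w_dc
    z = rng.normal(params.mu0, 1.0, size=n_particles)
    committed = np.abs(z) >= B
    z = np.where(committed, B * np.sign(z), z)
    logL = 0.0
    lgam = gammaln(tp.counts + 1.0)
    for t in range(T):
        w = np.where(committed[None, :], w_dc[:, None], w_ea[:, None])
        eta = w * z[None, :] + tp.baseline[t][:, None]
        ll = (
            tp.counts[t][:, None] * (log_softplus(eta) + np.log(dt))
            - softplus(eta) * dt
            - lgam[t][:, None]
        ).sum(axis=0)
        if t == T - 1:
            sgn = np.sign(z)
            if trial.choice == "R":
                p = np.where(sgn > 0, 1.0, np.where(sgn == 0, 0.5, 0.0))
            else:
                p = np.where(sgn < 0, 1.0, np.where(sgn == 0, 0.5, 0.0))
            with np.errstate(divide="ignore"):
                ll = ll + np.log(p)
        m = ll.max()
        if not np.isfinite(m):
            return -np.inf
        wgt = np.exp(ll - m)
        mean_w = wgt.mean()
        logL += m + np.log(mean_w)
        if t == T - 1:
            break
        # resample and propagate
        idx = rng.choice(n_particles, size=n_particles, p=wgt / wgt.sum())
        z = z[idx]
        committed = committed[idx]
        free = ~committed
        if free.any():
            drift = tp.click_mean[t]
            var = params.sigma_s2 * tp.click_sq[t]
            noise = rng.normal(0.0, np.sqrt(dt + var), size=free.sum())
            z_free = z[free] + drift + noise
            hit = np.abs(z_free) >= B
            z_free = np.where(hit, B * np.sign(z_free), z_free)
            z[free] = z_free
            newly = np.zeros_like(committed)
            newly[free] = hit
            committed = committed | newly
    return float(logL)
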