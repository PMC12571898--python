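"""Generative model: bounded accumulator, switching spike emissions, baseline.

The latent decision variable z is a scalar that accumulates click-driven
input and Gaussian diffusion noise until it reaches an absorbing bound at
-B or +B, after which it stays fixed. The latent is discretized onto a grid
of interior bins plus two absorbing bound states. Each neuron emits Poisson
spike counts with rate softplus(w * z + b); the encoding weight w switches
from ``w_ea`` (interior states) to ``w_dc`` (bound states). The behavioural
choice is the sign of z at the final step. The baseline b collects
decision-irrelevant structure: a slow cross-trial drift, stimulus-onset and
pre-movement kernels, and spike history, each a linear combination of
Gaussian radial basis functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, ndtr

from driftswitch.stimuli import AdaptationParams, AdaptedClicks

__all__ = [
    "LatentGrid",
    "NeuronParams",
    "ModelParams",
    "InputMoments",
    "BasisConfig",
    "BaselineModel",
    "softplus",
    "log_softplus",
    "discretize_inputs",
    "transition_matrix",
    "transition_matrices",
    "initial_distribution",
    "emission_loglik",
    "choice_likelihood",
    "choice_loglik",
    "fit_baseline",
]

DT_DEFAULT = 0.01


def softplus(x):
    """Overflow-safe softplus, log(1 + exp(x))."""
    return np.logaddexp(0.0, x)


def log_softplus(x, sp=None):
    """log(softplus(x)), stable for very negative x where softplus ~ exp(x).

    ``sp`` may pass a precomputed softplus(x) to avoid recomputation.
    """
    x = np.asarray(x, dtype=float)
    if sp is None:
        sp = softplus(x)
    with np.errstate(divide="ignore"):
        out = np.where(x < -33.0, x, np.log(np.where(sp > 0, sp, 1.0)))
    return out


# ---------------------------------------------------------------------------
# latent grid


@dataclass(frozen=True)
class LatentGrid:
    """Discretization of the latent: interior bins plus two absorbing bounds.

    States are ordered [-B, interior..., +B]; interior bin centres are
    uniform on (-B, B) with one bin centred at 0 (``n_interior`` odd).
    """

    bound: float
    n_interior: int = 99

    def __post_init__(self) -> None:
        if self.bound <= 0:
            raise ValueError("bound must be positive")
        if self.n_interior < 3 or self.n_interior % 2 == 0:
            raise ValueError("n_interior must be an odd integer >= 3")

    @property
    def edges(self) -> np.ndarray:
        """Interior bin edges, length n_interior + 1, spanning [-B, B]."""
        return np.linspace(-self.bound, self.bound, self.n_interior + 1)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def states(self) -> np.ndarray:
        """All state values: [-B, interior centres, +B]."""
        return np.concatenate(([-self.bound], self.centers, [self.bound]))

    @property
    def n_states(self) -> int:
        return self.n_interior + 2

    @property
    def zero_index(self) -> int:
        """Index of the state whose bin is centred at z = 0."""
        return 1 + self.n_interior // 2


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class NeuronParams:
    """Per-neuron emission parameters.

    ``w_ea`` applies at interior (accumulation) states, ``w_dc`` at the two
    bound (commitment) states; ``baseline`` evaluates the decision-irrelevant
    log-rate offset b(m, t).
    """

    w_ea: float
    w_dc: float
    baseline: "BaselineModel"


@dataclass(frozen=True)
class ModelParams:
    """Full model parameterization.

    The latent dynamics have exactly three free parameters: bound height
    ``bound`` (B), per-click noise variance ``sigma_s2`` and initial mean
    ``mu0``. Adaptation constants and the time step are fixed.
    """

    bound: float
    sigma_s2: float
    mu0: float
    neurons: tuple[NeuronParams, ...] = ()
    adaptation: AdaptationParams = field(default_factory=AdaptationParams)
    dt: float = DT_DEFAULT
    n_interior: int = 99

    def __post_init__(self) -> None:
        if self.bound <= 0:
            raise ValueError("bound must be positive")
        if self.sigma_s2 < 0:
            raise ValueError("sigma_s2 must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def grid(self) -> LatentGrid:
        return LatentGrid(self.bound, self.n_interior)

    @property
    def w_ea(self) -> np.ndarray:
        return np.array([n.w_ea for n in self.neurons])

    @property
    def w_dc(self) -> np.ndarray:
        return np.array([n.w_dc for n in self.neurons])

    def with_latent(self, bound=None, sigma_s2=None, mu0=None) -> "ModelParams":
        return replace(
            self,
            bound=self.bound if bound is None else bound,
            sigma_s2=self.sigma_s2 if sigma_s2 is None else sigma_s2,
            mu0=self.mu0 if mu0 is None else mu0,
        )


# ---------------------------------------------------------------------------
# click input moments


@dataclass(frozen=True)
class InputMoments:
    """Per-time-step drift mean and input variance from the adapted clicks.

    ``mean[t]`` is the summed right-minus-left adapted magnitude of clicks in
    the half-open window [t*dt, (t+1)*dt); ``var[t]`` is sigma_s2 times the
    summed squared magnitude over clicks of both sides (per-click noise is
    independent across clicks).
    """

    mean: np.ndarray
    var: np.ndarray

    @property
    def n_steps(self) -> int:
        return len(self.mean)


def discretize_inputs(
    clicks: AdaptedClicks,
    sigma_s2: float,
    dt: float,
    n_steps: int,
) -> InputMoments:
    """Bin adapted clicks into per-step input mean and variance."""
    m = np.zeros(n_steps)
    v = np.zeros(n_steps)
    if len(clicks) == 0:
        return InputMoments(mean=m, var=v)
    steps = np.floor(np.asarray(clicks.times) / dt).astype(int)
    if np.any(steps >= n_steps) or np.any(steps < 0):
        raise ValueError("click time beyond the trial window")
    signs = np.where(np.asarray(clicks.sides) == "R", 1.0, -1.0)
    mags = np.asarray(clicks.magnitudes, dtype=float)
    np.add.at(m, steps, signs * mags)
    np.add.at(v, steps, sigma_s2 * mags**2)
    return InputMoments(mean=m, var=v)


# ---------------------------------------------------------------------------
# transition and initial distributions


def _gaussian_bin_probs(grid: LatentGrid, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """P(bin) of N(mu, sd^2) over grid states, tails to the bounds.

    ``mu``/``sd`` broadcast; returns probabilities with trailing state axis.
    """
    mu = np.asarray(mu, dtype=float)[..., None]
    sd = np.asarray(sd, dtype=float)[..., None]
    cdf = ndtr((grid.edges - mu) / sd)  # (..., n_interior + 1)
    probs = np.empty(mu.shape[:-1] + (grid.n_states,))
    probs[..., 0] = cdf[..., 0]
    probs[..., 1:-1] = np.diff(cdf, axis=-1)
    probs[..., -1] = 1.0 - cdf[..., -1]
    return probs


def transition_matrix(grid: LatentGrid, m_t: float, v_t: float, dt: float) -> np.ndarray:
    """One-step stochastic matrix over grid states; rows are from-states.

    From an interior state z, the next state is N(z + m_t, dt + v_t)
    integrated over bins, with mass past +/-B assigned to the absorbing
    bound states. Bound rows map to themselves with probability 1.
    """
    S = grid.n_states
    P = np.zeros((S, S))
    P[0, 0] = 1.0
    P[-1, -1] = 1.0
    sd = np.sqrt(dt + v_t)
    P[1:-1, :] = _gaussian_bin_probs(grid, grid.centers + m_t, sd)
    return P


def transition_matrices_from_unique(
    grid: LatentGrid,
    uniq_mean: np.ndarray,
    uniq_var: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Stack of transition matrices for unique (drift, variance) rows."""
    S = grid.n_states
    mats = np.zeros((len(uniq_mean), S, S))
    mats[:, 0, 0] = 1.0
    mats[:, -1, -1] = 1.0
    mu = grid.centers[None, :] + np.asarray(uniq_mean)[:, None]
    sd = np.sqrt(dt + np.asarray(uniq_var))[:, None]
    mats[:, 1:-1, :] = _gaussian_bin_probs(grid, mu, sd)
    return mats


def transition_matrices(
    grid: LatentGrid, moments: InputMoments, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-step transition matrices for one trial.

    Returns ``(unique, index)``: ``unique`` has shape (K, S, S) and
    ``index[t]`` selects the matrix driving the step t -> t+1 transition.
    Click-free steps share a single diffusion-only matrix.
    """
    mv = np.column_stack([moments.mean, moments.var])
    uniq, index = np.unique(mv, axis=0, return_inverse=True)
    mats = transition_matrices_from_unique(grid, uniq[:, 0], uniq[:, 1], dt)
    return mats, index.astype(np.int64)


def initial_distribution(grid: LatentGrid, mu0: float) -> np.ndarray:
    """N(mu0, 1) integrated over grid bins; tail mass goes to the bounds."""
    return _gaussian_bin_probs(grid, np.asarray(mu0), np.asarray(1.0))


# ---------------------------------------------------------------------------
# emissions


def state_weights(grid: LatentGrid, w_ea: np.ndarray, w_dc: np.ndarray) -> np.ndarray:
    """Per-state encoding weight matrix, shape (n_neurons, n_states)."""
    w_ea = np.atleast_1d(np.asarray(w_ea, dtype=float))
    w_dc = np.atleast_1d(np.asarray(w_dc, dtype=float))
    W = np.empty((len(w_ea), grid.n_states))
    W[:, 0] = w_dc
    W[:, -1] = w_dc
    W[:, 1:-1] = w_ea[:, None]
    return W


def emission_loglik(
    spike_counts_t: np.ndarray,
    grid: LatentGrid,
    w_ea: np.ndarray,
    w_dc: np.ndarray,
    baseline_t: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Log-likelihood over grid states of one time step's spike counts.

    Each neuron contributes log Poisson(y | lambda * dt) with
    lambda = softplus(w * z + b); w is ``w_ea`` at interior states and
    ``w_dc`` at the two bound states.
    """
    y = np.atleast_1d(np.asarray(spike_counts_t, dtype=float))
    if np.any(y < 0):
        raise ValueError("spike counts must be non-negative")
    W = state_weights(grid, w_ea, w_dc)
    eta = W * grid.states[None, :] + np.atleast_1d(baseline_t)[:, None]
    lam = softplus(eta)
    ll = y[:, None] * (log_softplus(eta) + np.log(dt)) - lam * dt - gammaln(y + 1.0)[:, None]
    return ll.sum(axis=0)


def choice_likelihood(choice: str, grid: LatentGrid) -> np.ndarray:
    """P(choice | z) over grid states: 1 if sign matches, 0 otherwise.

    The bin centred at z = 0 contributes probability 1/2 to either choice.
    """
    if choice not in ("L", "R"):
        raise ValueError(f"choice must be 'L' or 'R', got {choice!r}")
    z = grid.states
    p = np.where(z > 0, 1.0, 0.0) if choice == "R" else np.where(z < 0, 1.0, 0.0)
    p[grid.zero_index] = 0.5
    return p


def choice_loglik(choice: str, grid: LatentGrid) -> np.ndarray:
    """Log of :func:`choice_likelihood`; zero mass maps to -inf."""
    with np.errstate(divide="ignore"):
        return np.log(choice_likelihood(choice, grid))


# ---------------------------------------------------------------------------
# decision-irrelevant baseline


@dataclass(frozen=True)
class BasisConfig:
    """Gaussian radial-basis layout for the baseline model.

    Counts default to 4 bases per component (plus an intercept, giving 17
    baseline coefficients and, with the two encoding weights, 19 parameters
    per neuron). Supports are in seconds; the cross-trial component spans
    the session and is a function of trial start time.
    """

    n_cross: int = 4
    n_stim: int = 4
    n_move: int = 4
    n_hist: int = 4
    stim_window: tuple[float, float] = (0.0, 1.0)
    move_window: tuple[float, float] = (-0.5, 0.0)
    hist_window: tuple[float, float] = (0.0, 0.1)

    @property
    def n_coef(self) -> int:
        return 1 + self.n_cross + self.n_stim + self.n_move + self.n_hist

    @staticmethod
    def intercept_only() -> "BasisConfig":
        return BasisConfig(n_cross=0, n_stim=0, n_move=0, n_hist=0)


def _rbf_centers(lo: float, hi: float, n: int) -> tuple[np.ndarray, float]:
    if n == 0:
        return np.empty(0), 1.0
    if n == 1:
        return np.array([(lo + hi) / 2]), (hi - lo) / 2 or 1.0
    c = np.linspace(lo, hi, n)
    return c, (c[1] - c[0])


def _rbf(x: np.ndarray, centers: np.ndarray, width: float) -> np.ndarray:
    if len(centers) == 0:
        return np.zeros(np.shape(x) + (0,))
    return np.exp(-0.5 * ((np.asarray(x)[..., None] - centers) / width) ** 2)


@dataclass(frozen=True)
class BaselineModel:
    """Evaluated baseline b(m, t) = cross-trial drift + event kernels.

    ``coef`` packs [intercept, cross, stim, move, history] coefficients.
    ``session_span`` is the (first, last) trial start time used to place the
    cross-trial bases.
    """

    coef: np.ndarray
    config: BasisConfig = field(default_factory=BasisConfig)
    session_span: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        coef = np.asarray(self.coef, dtype=float)
        object.__setattr__(self, "coef", coef)
        if len(coef) != self.config.n_coef:
            raise ValueError(
                f"expected {self.config.n_coef} coefficients, got {len(coef)}"
            )

    def design(
        self,
        n_steps: int,
        dt: float,
        trial_start: float,
        move_onset: float,
        spike_times: np.ndarray | None = None,
    ) -> np.ndarray:
        """Design matrix (n_steps, n_coef) for one trial of one neuron.

        Rows correspond to 0.01-s bins from stimulus onset; kernels are
        causal: the stimulus kernel is supported at t >= 0, the movement
        kernel in a window preceding movement onset, and the spike-history
        kernel strictly after each spike.
        """
        cfg = self.config
        t = (np.arange(n_steps) + 0.5) * dt
        cols = [np.ones((n_steps, 1))]
        lo, hi = self.session_span
        c, w = _rbf_centers(lo, hi, cfg.n_cross)
        cols.append(np.broadcast_to(_rbf(np.asarray(trial_start), c, w), (n_steps, cfg.n_cross)))
        c, w = _rbf_centers(*cfg.stim_window, cfg.n_stim)
        stim = _rbf(t, c, w)
        stim[t < cfg.stim_window[0]] = 0.0
        cols.append(stim)
        c, w = _rbf_centers(*cfg.move_window, cfg.n_move)
        rel = t - move_onset
        move = _rbf(rel, c, w)
        move[(rel < cfg.move_window[0]) | (rel > cfg.move_window[1])] = 0.0
        cols.append(move)
        hist = np.zeros((n_steps, cfg.n_hist))
        if cfg.n_hist and spike_times is not None and len(spike_times):
            c, w = _rbf_centers(*cfg.hist_window, cfg.n_hist)
            bins = np.arange(n_steps)
            for tau in np.asarray(spike_times, dtype=float):
                lag = t - tau
                # strictly causal: only bins after the spike's own bin
                mask = (bins > int(np.floor(tau / dt))) & (lag <= cfg.hist_window[1] + 2 * w)
                if mask.any():
                    hist[mask] += _rbf(lag[mask], c, w)
        cols.append(hist)
        return np.concatenate(cols, axis=1)

    def evaluate(
        self,
        n_steps: int,
        dt: float,
        trial_start: float,
        move_onset: float,
        spike_times: np.ndarray | None = None,
    ) -> np.ndarray:
        """Baseline values b(m, t) on the trial's time grid."""
        X = self.design(n_steps, dt, trial_start, move_onset, spike_times)
        return X @ self.coef


def params_to_dict(params: ModelParams) -> dict:
    """JSON-serializable representation of :class:`ModelParams`."""
    return {
        "bound": params.bound,
        "sigma_s2": params.sigma_s2,
        "mu0": params.mu0,
        "dt": params.dt,
        "n_interior": params.n_interior,
        "adaptation": {
            "phi": params.adaptation.phi,
            "tau_phi": params.adaptation.tau_phi,
            "include_stereoclick": params.adaptation.include_stereoclick,
        },
        "neurons": [
            {
                "w_ea": n.w_ea,
                "w_dc": n.w_dc,
                "baseline": {
                    "coef": n.baseline.coef.tolist(),
                    "session_span": list(n.baseline.session_span),
                    "config": {
                        "n_cross": n.baseline.config.n_cross,
                        "n_stim": n.baseline.config.n_stim,
                        "n_move": n.baseline.config.n_move,
                        "n_hist": n.baseline.config.n_hist,
                        "stim_window": list(n.baseline.config.stim_window),
                        "move_window": list(n.baseline.config.move_window),
                        "hist_window": list(n.baseline.config.hist_window),
                    },
                },
            }
            for n in params.neurons
        ],
    }


def params_from_dict(doc: dict) -> ModelParams:
    """Inverse of :func:`params_to_dict`."""
    neurons = []
    for nd in doc.get("neurons", []):
        bd = nd["baseline"]
        cfg = bd.get("config", {})
        config = BasisConfig(
            n_cross=cfg.get("n_cross", 0),
            n_stim=cfg.get("n_stim", 0),
            n_move=cfg.get("n_move", 0),
            n_hist=cfg.get("n_hist", 0),
            stim_window=tuple(cfg.get("stim_window", (0.0, 1.0))),
            move_window=tuple(cfg.get("move_window", (-0.5, 0.0))),
            hist_window=tuple(cfg.get("hist_window", (0.0, 0.1))),
        )
        baseline = BaselineModel(
            np.asarray(bd["coef"], dtype=float),
            config,
            tuple(bd.get("session_span", (0.0, 1.0))),
        )
        neurons.append(NeuronParams(w_ea=nd["w_ea"], w_dc=nd["w_dc"], baseline=baseline))
    ad = doc.get("adaptation", {})
    return ModelParams(
        bound=doc["bound"],
        sigma_s2=doc["sigma_s2"],
        mu0=doc["mu0"],
        neurons=tuple(neurons),
        adaptation=AdaptationParams(
            phi=ad.get("phi", 0.6),
            tau_phi=ad.get("tau_phi", 0.2),
            include_stereoclick=ad.get("include_stereoclick", True),
        ),
        dt=doc.get("dt", DT_DEFAULT),
        n_interior=doc.get("n_interior", 99),
    )


def _softplus_poisson_nll(
    beta: np.ndarray, X: np.ndarray, y: np.ndarray, dt: float, ridge: float
) -> tuple[float, np.ndarray]:
    eta = X @ beta
    lam = softplus(eta)
    nll = float(np.sum(lam * dt - y * (log_softplus(eta) + np.log(dt))))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lam > 0, y / np.where(lam > 0, lam, 1.0), 0.0)
    g = X.T @ (expit(eta) * (dt - ratio))
    nll += 0.5 * ridge * float(beta @ beta)
    g = g + ridge * beta
    return nll, g


def fit_baseline(
    spike_counts: list[np.ndarray],
    trial_starts: np.ndarray,
    move_onsets: np.ndarray,
    spike_times: list[np.ndarray] | None = None,
    config: BasisConfig | None = None,
    dt: float = DT_DEFAULT,
    ridge: float = 1e-4,
) -> BaselineModel:
    """Fit the decision-irrelevant baseline of one neuron.

    A Poisson regression with softplus inverse link of the 0.01-s spike
    counts on the radial-basis design (cross-trial drift, stimulus-onset,
    pre-movement and spike-history kernels). A small ridge penalty guards
    against rank deficiency.

    Parameters
    ----------
    spike_counts
        Per-trial arrays of binned counts.
    trial_starts, move_onsets
        Per-trial trial start times (s, from session start) and movement
        onset times (s, from stimulus onset).
    spike_times
        Per-trial spike times (s), needed when the history basis is active.
    """
    if len(spike_counts) == 0:
        raise ValueError("at least one trial is required")
    config = config or BasisConfig()
    trial_starts = np.asarray(trial_starts, dtype=float)
    span = (float(trial_starts.min()), float(max(trial_starts.max(), trial_starts.min() + 1.0)))
    template = BaselineModel(np.zeros(config.n_coef), config, span)
    X_rows, y_rows = [], []
    for i, y in enumerate(spike_counts):
        st = spike_times[i] if spike_times is not None else None
        X_rows.append(template.design(len(y), dt, trial_starts[i], move_onsets[i], st))
        y_rows.append(np.asarray(y, dtype=float))
    X = np.concatenate(X_rows)
    y = np.concatenate(y_rows)
    beta0 = np.zeros(config.n_coef)
    mean_rate = y.mean() / dt
    # intercept init: softplus(b) = max(mean rate, tiny)
    beta0[0] = np.log(np.expm1(max(mean_rate, 1e-3)))
    res = minimize(
        _softplus_poisson_nll,
        beta0,
        args=(X, y, dt, ridge),
        jac=True,
        method="L-BFGS-B",
    )
    return BaselineModel(res.x, config, span)
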