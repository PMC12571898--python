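"""Neural summary statistics.

Neuron selection by choice-predictive auROC, peri-stimulus time histograms
(PSTH) with causal Gaussian smoothing, the two-condition goodness-of-fit
R^2, choice-selectivity series, engagement indices, peri-commitment time
histograms (PCTH) and trial-averaged state-space trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from driftswitch.inference import trial_n_steps, _bin_spikes
from driftswitch.session import Session

__all__ = [
    "PSTH",
    "SelectivitySeries",
    "PCTHSet",
    "TrajectoryResult",
    "causal_gaussian_kernel",
    "select_neurons",
    "compute_psth",
    "psth_r2",
    "choice_selectivity",
    "engagement_index",
    "ei_group",
    "compute_pcth",
    "fold_weight_reliability",
    "state_space_trajectories",
]

DT = 0.01
#: spike-count windows (s post stimulus onset) for the selection auROC
SELECTION_WINDOWS = ((0.01, 0.21), (0.21, 0.40), (0.41, 0.60), (0.61, 0.90))


# ---------------------------------------------------------------------------
# neuron selection


def _window_counts(session: Session, neuron: int, lo: float, hi: float):
    """Spike counts in [lo, hi) per trial, restricted to trials whose
    emission window covers the window."""
    counts, keep = [], []
    for i in range(session.n_trials):
        tr = session.trials[i]
        T = trial_n_steps(tr.move_onset, DT)
        if T * DT < hi:
            continue
        st = np.asarray(session.spike_times[neuron][i])
        counts.append(int(np.sum((st >= lo) & (st < hi))))
        keep.append(i)
    return np.array(counts), np.array(keep, dtype=int)


def select_neurons(
    session: Session,
    auroc_bounds: tuple[float, float] = (0.42, 0.58),
    min_rate: float = 2.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Choice-selective neuron filter.

    A neuron is included iff its auROC for ideal-observer left/right
    classification from spike counts falls outside ``auroc_bounds`` in any
    of the standard windows, and its average firing rate is at least
    ``min_rate`` spikes/s. Neurons with undefined auROC (all trials one
    choice) are excluded and flagged.
    """
    lo_th, hi_th = auroc_bounds
    rows = []
    included = []
    choices = session.choices
    for n in range(session.n_neurons):
        total_spikes, total_time = 0.0, 0.0
        for i in range(session.n_trials):
            T = trial_n_steps(session.trials[i].move_onset, DT)
            st = np.asarray(session.spike_times[n][i])
            total_spikes += np.sum(st < T * DT)
            total_time += T * DT
        mean_rate = total_spikes / total_time if total_time else 0.0
        aurocs = []
        for lo, hi in SELECTION_WINDOWS:
            counts, keep = _window_counts(session, n, lo, hi)
            y = choices[keep] == "R"
            if len(np.unique(y)) < 2 or len(counts) == 0:
                aurocs.append(np.nan)
                continue
            aurocs.append(roc_auc_score(y, counts))
        aurocs = np.array(aurocs, dtype=float)
        selective = bool(np.any((aurocs < lo_th) | (aurocs > hi_th)))
        ok = selective and mean_rate >= min_rate
        if ok:
            included.append(n)
        rows.append(
            dict(
                neuron=n,
                mean_rate=mean_rate,
                included=ok,
                auroc_undefined=bool(np.all(np.isnan(aurocs))),
                **{f"auroc_w{j}": aurocs[j] for j in range(len(SELECTION_WINDOWS))},
            )
        )
    return np.array(included, dtype=int), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PSTH


def causal_gaussian_kernel(sigma: float = 0.1, width: float = 0.3, dt: float = DT) -> np.ndarray:
    """Causal Gaussian filter taps, truncated at ``width`` and renormalized
    to unit sum so constant inputs are preserved."""
    lags = np.arange(0.0, width, dt)
    k = np.exp(-0.5 * (lags / sigma) ** 2)
    return k / k.sum()


@dataclass(frozen=True)
class PSTH:
    """Trial-averaged smoothed firing rate on a 0.01-s grid."""

    time: np.ndarray
    rate: np.ndarray
    n_trials: int
    condition: str = ""
    ci_lo: Optional[np.ndarray] = None
    ci_hi: Optional[np.ndarray] = None


def _smooth_counts(counts: np.ndarray, kernel: np.ndarray, dt: float) -> np.ndarray:
    """Causal convolution of binned counts, returned as a rate (spikes/s)."""
    return np.convolve(counts, kernel)[: len(counts)] / dt


def _bootstrap_ci(
    per_trial: np.ndarray, n_boot: int, seed: int, method: str
) -> tuple[np.ndarray, np.ndarray]:
    """Across-trial CI of the mean; BCa by default, plain percentile
    fallback (used when BCa is degenerate or explicitly requested)."""
    import warnings

    if method == "bca":
        from scipy.stats import bootstrap

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = bootstrap(
                    (per_trial,),
                    lambda x, axis=0: np.nanmean(x, axis=axis),
                    axis=0,
                    n_resamples=n_boot,
                    method="BCa",
                    rng=np.random.default_rng(seed),
                )
                return res.confidence_interval.low, res.confidence_interval.high
            except Exception:  # degenerate resamples: fall through
                pass
    rng = np.random.default_rng(seed)
    n = per_trial.shape[0]
    boots = np.empty((n_boot, per_trial.shape[1]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for b in range(n_boot):
            boots[b] = np.nanmean(per_trial[rng.integers(0, n, n)], axis=0)
    return np.nanpercentile(boots, 2.5, axis=0), np.nanpercentile(boots, 97.5, axis=0)


def compute_psth(
    session: Session,
    neuron: int,
    trial_indices: Sequence[int],
    condition: str = "",
    normalize: bool = False,
    n_boot: int = 0,
    seed: int = 0,
    sigma: float = 0.1,
    width: float = 0.3,
    max_steps: int = 100,
    ci_method: str = "bca",
) -> PSTH:
    """PSTH of one neuron over a group of trials.

    Each trial's spike train is binned at 0.01 s, convolved with a causal
    Gaussian (sigma 0.1 s, width 0.3 s, unit sum) and averaged across
    trials; a time bin only averages trials still within their window.
    ``normalize`` divides by the neuron's grand-mean rate over all supplied
    trials. With ``n_boot > 0``, across-trial bootstrap CIs are added
    (bias-corrected and accelerated percentile method by default).
    """
    trial_indices = list(trial_indices)
    if not trial_indices:
        raise ValueError("empty trial group")
    kernel = causal_gaussian_kernel(sigma, width, DT)
    per_trial = np.full((len(trial_indices), max_steps), np.nan)
    for row, i in enumerate(trial_indices):
        T = min(max_steps, trial_n_steps(session.trials[i].move_onset, DT))
        counts = _bin_spikes(session.spike_times[neuron][i], T, DT)
        per_trial[row, :T] = _smooth_counts(counts, kernel, DT)
    present = ~np.isnan(per_trial)
    n_present = present.sum(axis=0)
    rate = np.where(n_present > 0, np.nansum(np.where(present, per_trial, 0.0), axis=0), np.nan)
    rate = rate / np.maximum(n_present, 1)
    valid = n_present > 0
    time = (np.arange(max_steps) + 0.5) * DT
    ci_lo = ci_hi = None
    if n_boot > 0:
        ci_lo, ci_hi = _bootstrap_ci(per_trial, n_boot, seed, ci_method)
    if normalize:
        grand = np.nanmean(per_trial)
        if grand > 0:
            rate = rate / grand
            if ci_lo is not None:
                ci_lo, ci_hi = ci_lo / grand, ci_hi / grand
    return PSTH(
        time=time[valid],
        rate=rate[valid],
        n_trials=len(trial_indices),
        condition=condition,
        ci_lo=None if ci_lo is None else ci_lo[valid],
        ci_hi=None if ci_hi is None else ci_hi[valid],
    )


def psth_r2(
    obs_right: np.ndarray,
    obs_left: np.ndarray,
    pred_right: np.ndarray,
    pred_left: np.ndarray,
) -> float:
    """Two-condition coefficient of determination.

    R^2 = 1 - SS_res / SS_tot where SS_res sums squared deviations of the
    predictions from the observed PSTHs over both conditions, and SS_tot
    sums squared deviations of each observed PSTH from its own temporal
    mean.
    """
    obs_r, obs_l = np.asarray(obs_right, float), np.asarray(obs_left, float)
    pred_r, pred_l = np.asarray(pred_right, float), np.asarray(pred_left, float)
    if obs_r.shape != pred_r.shape or obs_l.shape != pred_l.shape:
        raise ValueError("observed and predicted PSTHs must share time grids")
    ss_res = np.sum((obs_r - pred_r) ** 2) + np.sum((obs_l - pred_l) ** 2)
    ss_tot = np.sum((obs_r - obs_r.mean()) ** 2) + np.sum((obs_l - obs_l.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("constant observed PSTHs: R^2 undefined")
    return float(1.0 - ss_res / ss_tot)


# ---------------------------------------------------------------------------
# choice selectivity


@dataclass(frozen=True)
class SelectivitySeries:
    """Right-minus-left PSTH difference normalized at its peak.

    ``series[t_star]`` is exactly +/-1. Normalization is by the peak
    difference only, so off-peak values are not clipped to [-1, 1].
    """

    series: np.ndarray
    t_star: int
    center_of_mass: float


def choice_selectivity(psth_right: np.ndarray, psth_left: np.ndarray) -> SelectivitySeries:
    """Normalized right-left selectivity series and its peak time."""
    r = np.asarray(psth_right, float)
    l = np.asarray(psth_left, float)
    if r.shape != l.shape:
        raise ValueError("PSTHs must share a time grid")
    d = r - l
    if np.all(d == 0):
        raise ValueError("right and left PSTHs identical: selectivity undefined")
    t_star = int(np.argmax(np.abs(d)))
    c = d / d[t_star]
    w = np.abs(c)
    com = float(np.sum(np.arange(len(c)) * w) / np.sum(w))
    return SelectivitySeries(series=c, t_star=t_star, center_of_mass=com)


# ---------------------------------------------------------------------------
# engagement index


def engagement_index(w_ea: float, w_dc: float) -> float:
    """(|w_ea| - |w_dc|) / (|w_ea| + |w_dc|), in [-1, 1].

    +1 means the neuron encodes the latent only during accumulation, -1
    only during commitment. Undefined (raises) when both weights are zero.
    """
    denom = abs(w_ea) + abs(w_dc)
    if denom == 0:
        raise ValueError("engagement index undefined for w_ea = w_dc = 0")
    return (abs(w_ea) - abs(w_dc)) / denom


def ei_group(ei: float) -> str:
    """Group label: accumulation (ei >= 1/3), commitment (ei < -1/3),
    else similar."""
    if ei >= 1.0 / 3.0:
        return "accumulation"
    if ei < -1.0 / 3.0:
        return "commitment"
    return "similar"


# ---------------------------------------------------------------------------
# peri-commitment histograms


@dataclass(frozen=True)
class PCTHSet:
    """Commitment-aligned average responses by engagement group.

    ``lags`` are seconds relative to the detected commitment time. Each
    group maps to (preferred, null, difference) rate series averaged over
    the group's neurons. ``shuffled`` indicates the commitment times were
    permuted among detected trials.
    """

    lags: np.ndarray
    groups: dict
    n_trials_used: int
    shuffled: bool = False


def compute_pcth(
    session: Session,
    commit_steps: np.ndarray,
    ei_values: Sequence[float],
    window: tuple[float, float] = (-0.5, 0.5),
    shuffle: bool = False,
    seed: int = 0,
    sigma: float = 0.05,
    kernel_width: float = 0.15,
) -> PCTHSet:
    """Average commitment-aligned responses in three engagement groups.

    ``commit_steps[i]`` is the detected commitment step of trial i, or -1
    when undetected; only detected trials contribute. The per-neuron
    trial-averaged response is smoothed with a causal Gaussian
    (sigma 0.05 s) and neurons are grouped by engagement index. The
    preferred condition is the choice eliciting the higher firing rate.
    With ``shuffle=True`` the commitment steps are permuted among detected
    trials; times landing beyond a trial's end are clipped to its last
    step.
    """
    commit_steps = np.asarray(commit_steps, dtype=int)
    detected = np.nonzero(commit_steps >= 0)[0]
    if len(detected) == 0:
        raise ValueError("no detected commitment trials")
    steps = commit_steps.copy()
    if shuffle:
        rng = np.random.default_rng(seed)
        steps[detected] = rng.permutation(steps[detected])
    lag_lo = int(np.round(window[0] / DT))
    lag_hi = int(np.round(window[1] / DT))
    lags = np.arange(lag_lo, lag_hi)
    kernel = causal_gaussian_kernel(sigma, kernel_width, DT)
    choices = session.choices
    trial_T = np.array(
        [trial_n_steps(t.move_onset, DT) for t in session.trials], dtype=int
    )

    per_neuron: dict[int, dict[str, np.ndarray]] = {}
    for n in range(session.n_neurons):
        sums = {"R": np.zeros(len(lags)), "L": np.zeros(len(lags))}
        cnts = {"R": np.zeros(len(lags)), "L": np.zeros(len(lags))}
        rates = {"R": [], "L": []}
        for i in detected:
            T = trial_T[i]
            s = min(int(steps[i]), T - 1)  # shuffled step may exceed trial end
            counts = _bin_spikes(session.spike_times[n][i], T, DT)
            smoothed = _smooth_counts(counts, kernel, DT)
            t_idx = s + lags
            valid = (t_idx >= 0) & (t_idx < T)
            ch = choices[i]
            sums[ch][valid] += smoothed[t_idx[valid]]
            cnts[ch][valid] += 1
            rates[ch].append(counts.mean() / DT)
        series = {}
        for ch in ("R", "L"):
            with np.errstate(invalid="ignore"):
                series[ch] = np.where(cnts[ch] > 0, sums[ch] / np.maximum(cnts[ch], 1), np.nan)
        mean_r = np.mean(rates["R"]) if rates["R"] else 0.0
        mean_l = np.mean(rates["L"]) if rates["L"] else 0.0
        pref, null = ("R", "L") if mean_r >= mean_l else ("L", "R")
        per_neuron[n] = {
            "preferred": series[pref],
            "null": series[null],
            "difference": series[pref] - series[null],
        }

    groups: dict[str, dict[str, np.ndarray]] = {}
    for label in ("accumulation", "similar", "commitment"):
        members = [
            n
            for n in range(session.n_neurons)
            if np.isfinite(ei_values[n]) and ei_group(ei_values[n]) == label
        ]
        if not members:
            continue
        groups[label] = {
            key: np.nanmean(np.stack([per_neuron[n][key] for n in members]), axis=0)
            for key in ("preferred", "null", "difference")
        }
    return PCTHSet(
        lags=lags * DT, groups=groups, n_trials_used=len(detected), shuffled=shuffle
    )


def fold_weight_reliability(fold_models) -> float:
    """R^2 of per-neuron encoding weights across cross-validation folds.

    Treats each fold's concatenated (w_ea, w_dc) vector as a prediction of
    the across-fold mean; returns 1 - SS_res/SS_tot pooled over folds.
    Used as a session-reliability gate (e.g. require > 0.9) before pooling
    commitment-aligned analyses across sessions.
    """
    W = np.stack(
        [np.concatenate([fm.params.w_ea, fm.params.w_dc]) for fm in fold_models]
    )
    if W.shape[0] < 2:
        raise ValueError("need at least two folds")
    mean = W.mean(axis=0)
    ss_res = np.sum((W - mean) ** 2)
    ss_tot = np.sum((W - W.mean()) ** 2)
    if ss_tot == 0:
        return np.nan
    return float(1.0 - ss_res / ss_tot)


# ---------------------------------------------------------------------------
# state-space trajectories


@dataclass(frozen=True)
class TrajectoryResult:
    """SVD of the concatenated condition PSTH matrix.

    ``projections`` (rows x 2) are the first two columns of U*S; ``axes``
    are the corresponding right singular vectors; full matrices are kept
    for reconstruction checks.
    """

    projections: np.ndarray
    axes: np.ndarray
    singular_values: np.ndarray
    projections_full: np.ndarray
    axes_full: np.ndarray
    row_mean: np.ndarray


def state_space_trajectories(X: np.ndarray) -> TrajectoryResult:
    """Project condition-concatenated PSTHs onto their principal axes.

    ``X`` has one row per (condition, time) pair and one column per neuron.
    The grand row-mean vector is subtracted from every row (column
    centring) before the singular value decomposition.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be 2-D with at least two neurons")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    US = U * s
    return TrajectoryResult(
        projections=US[:, :2],
        axes=Vt[:2].T,
        singular_values=s,
        projections_full=US,
        axes_full=Vt.T,
        row_mean=mean,
    )
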