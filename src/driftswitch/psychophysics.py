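"""Behavioural statistics: psychometric curves and psychophysical kernels.

The psychophysical kernel measures the time-resolved weight of click
fluctuations on the behavioural choice via logistic regression with an
optional symmetric lapse parameter,
``P(right) = lapse/2 + (1 - lapse) * logistic(b0 + sum_k beta_k x_k)``,
where ``x_k`` is the signed (right - left) click count in lag bin k.
Kernels can be aligned to each trial's detected commitment time or to
stimulus onset (with a temporal-basis parametrization whose size is picked
by cross-validation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import beta as beta_dist

from driftswitch.session import Session

__all__ = [
    "PsychophysicalKernel",
    "click_difference",
    "psychometric_curve",
    "psychophysical_kernel",
    "commitment_behaviour_summary",
    "CommitmentBehaviourSummary",
]


def click_difference(session: Session) -> np.ndarray:
    """#right - #left clicks per trial (the stereoclick pair cancels)."""
    return np.array(
        [len(t.clicks.right_times) - len(t.clicks.left_times) for t in session.trials]
    )


# ---------------------------------------------------------------------------
# psychometric curve


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = beta_dist.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = beta_dist.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def psychometric_curve(
    click_diff: np.ndarray,
    choices: np.ndarray,
    n_bins: int = 8,
) -> pd.DataFrame:
    """Fraction of rightward choices in similar-size click-difference bins.

    Returns a table with bin centres, trial counts, the fraction of right
    choices and Clopper-Pearson 95% confidence bounds.
    """
    click_diff = np.asarray(click_diff)
    choices = np.asarray(choices)
    if len(click_diff) < n_bins:
        raise ValueError("fewer trials than bins")
    order = np.argsort(click_diff, kind="stable")
    splits = np.array_split(order, n_bins)
    rows = []
    for s in splits:
        if len(s) == 0:
            continue
        right = int(np.sum(choices[s] == "R"))
        n = len(s)
        lo, hi = _clopper_pearson(right, n)
        rows.append(
            dict(
                bin_center=float(np.mean(click_diff[s])),
                n_trials=n,
                frac_right=right / n,
                ci_lo=lo,
                ci_hi=hi,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# lapse-logistic kernel


@dataclass(frozen=True)
class PsychophysicalKernel:
    """Per-lag click weights on choice, with an optional lapse.

    ``regularized`` reports that (quasi-)separation was detected and the
    fit was repeated with a stronger ridge penalty.
    """

    lags: np.ndarray  # lag-bin centres (s)
    weights: np.ndarray  # log-odds per click
    weight_se: np.ndarray
    intercept: float
    lapse: float
    alignment: str  # "commitment" or "stimulus"
    n_trials: int
    basis_size: Optional[int] = None
    regularized: bool = False


def _lapse_nll(theta, X, y, fit_lapse, ridge):
    if fit_lapse:
        lapse = 0.5 * expit(theta[0])
        beta = theta[1:]
    else:
        lapse = 0.0
        beta = theta
    p = lapse / 2 + (1 - lapse) * expit(X @ beta)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    nll = -np.sum(np.where(y, np.log(p), np.log1p(-p)))
    nll += 0.5 * ridge * float(beta[1:] @ beta[1:])  # never penalize intercept
    return nll


def _numeric_hessian(f, x, h=1e-4):
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h
            ej[j] = h
            f1 = f(x + ei + ej)
            f2 = f(x + ei - ej)
            f3 = f(x - ei + ej)
            f4 = f(x - ei - ej)
            H[i, j] = H[j, i] = (f1 - f2 - f3 + f4) / (4 * h * h)
    return H


_SEPARATION_LIMIT = 10.0  # log-odds per click beyond which we call separation


def _fit_lapse_logistic(X, y, fit_lapse, ridge=1e-3, separation_ridge=0.1):
    n_beta = X.shape[1]
    theta0 = np.zeros(n_beta + (1 if fit_lapse else 0))
    if fit_lapse:
        theta0[0] = -2.0  # small initial lapse
    res = minimize(_lapse_nll, theta0, args=(X, y, fit_lapse, ridge), method="L-BFGS-B")
    theta = res.x
    regularized = False
    slopes = theta[2:] if fit_lapse else theta[1:]
    if np.max(np.abs(slopes), initial=0.0) > _SEPARATION_LIMIT:
        import warnings

        warnings.warn("separation detected in choice regression; applying ridge")
        regularized = True
        ridge = max(ridge, separation_ridge)
        res = minimize(
            _lapse_nll, theta0, args=(X, y, fit_lapse, ridge), method="L-BFGS-B"
        )
        theta = res.x
    H = _numeric_hessian(lambda t: _lapse_nll(t, X, y, fit_lapse, ridge), theta)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(theta), np.nan)
    if fit_lapse:
        lapse = 0.5 * expit(theta[0])
        return theta[1:], se[1:], float(lapse), theta, regularized
    return theta, se, 0.0, theta, regularized


def _signed_counts(trial, lo: float, hi: float) -> int:
    r = np.asarray(trial.clicks.right_times)
    l = np.asarray(trial.clicks.left_times)
    return int(np.sum((r >= lo) & (r < hi))) - int(np.sum((l >= lo) & (l < hi)))


def _raised_cosine_basis(t: np.ndarray, n: int, span: tuple[float, float]) -> np.ndarray:
    lo, hi = span
    centers = np.linspace(lo, hi, n)
    width = (hi - lo) / max(n - 1, 1) * 2 or 1.0
    arg = np.clip((t[:, None] - centers) * np.pi / width, -np.pi, np.pi)
    return 0.5 * (1 + np.cos(arg))


def psychophysical_kernel(
    session: Session,
    commit_s: Optional[np.ndarray] = None,
    mode: str = "commitment",
    lag_window: tuple[float, float] = (-0.2, 0.2),
    lag_bin: float = 0.1,
    fit_lapse: bool = True,
    basis_sizes: Sequence[int] = (2, 3, 4, 5),
    basis_size: Optional[int] = None,
    seed: int = 0,
    ridge: float = 1e-3,
    margin: float = 0.2,
) -> PsychophysicalKernel:
    """Time-resolved logistic-regression weight of clicks on choice.

    ``mode="commitment"`` aligns lag bins to each trial's commitment time
    ``commit_s`` (NaN/negative = undetected); only trials with the stimulus
    playing at least ``margin`` seconds before and after the commitment
    time qualify. ``mode="stimulus"`` aligns to stimulus onset and
    parametrizes the kernel with a raised-cosine temporal basis whose size
    is chosen by 5-fold cross-validated log-likelihood unless
    ``basis_size`` is given.
    """
    y = session.choices == "R"
    if mode == "commitment":
        if commit_s is None:
            raise ValueError("commitment-aligned mode requires commit_s")
        commit_s = np.asarray(commit_s, dtype=float)
        edges = np.arange(lag_window[0], lag_window[1] + 1e-9, lag_bin)
        lags = 0.5 * (edges[:-1] + edges[1:])
        rows, keep = [], []
        for i, trial in enumerate(session.trials):
            c = commit_s[i]
            if not np.isfinite(c) or c < 0:
                continue
            if c < margin or c + margin > trial.clicks.duration:
                continue
            rows.append([_signed_counts(trial, c + lo, c + hi) for lo, hi in zip(edges[:-1], edges[1:])])
            keep.append(i)
        if not rows:
            raise ValueError("no qualifying trials for the commitment-aligned kernel")
        X = np.column_stack([np.ones(len(rows)), np.array(rows, dtype=float)])
        beta, se, lapse, _, regularized = _fit_lapse_logistic(X, y[keep], fit_lapse, ridge)
        return PsychophysicalKernel(
            lags=lags,
            weights=beta[1:],
            weight_se=se[1:],
            intercept=float(beta[0]),
            lapse=lapse,
            alignment="commitment",
            n_trials=len(rows),
            regularized=regularized,
        )
    if mode != "stimulus":
        raise ValueError(f"unknown mode {mode!r}")

    # stimulus-aligned: fine lag bins compressed through a temporal basis
    edges = np.arange(0.0, 1.0 + 1e-9, lag_bin)
    lags = 0.5 * (edges[:-1] + edges[1:])
    counts = np.array(
        [
            [_signed_counts(t, lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]
            for t in session.trials
        ],
        dtype=float,
    )

    def design(nb):
        Phi = _raised_cosine_basis(lags, nb, (0.0, 1.0))
        return np.column_stack([np.ones(len(counts)), counts @ Phi]), Phi

    if basis_size is None:
        from sklearn.model_selection import KFold

        best = None
        for nb in basis_sizes:
            Xb, _ = design(nb)
            ll = 0.0
            for tr, te in KFold(5, shuffle=True, random_state=seed).split(Xb):
                _, _, _, theta, _ = _fit_lapse_logistic(Xb[tr], y[tr], fit_lapse, ridge)
                ll -= _lapse_nll(theta, Xb[te], y[te], fit_lapse, 0.0)
            if best is None or ll > best[0]:
                best = (ll, nb)
        basis_size = best[1]
    X, Phi = design(basis_size)
    beta, se, lapse, _, regularized = _fit_lapse_logistic(X, y, fit_lapse, ridge)
    weights = Phi @ beta[1:]
    var = np.einsum("tb,b,tb->t", Phi, se[1:] ** 2, Phi)
    return PsychophysicalKernel(
        lags=lags,
        weights=weights,
        weight_se=np.sqrt(var),
        intercept=float(beta[0]),
        lapse=lapse,
        alignment="stimulus",
        n_trials=session.n_trials,
        basis_size=basis_size,
        regularized=regularized,
    )


# ---------------------------------------------------------------------------
# commitment/behaviour summaries


@dataclass(frozen=True)
class CommitmentBehaviourSummary:
    """Accuracy split by commitment detection, and detection rate by
    evidence strength, optionally with a model-simulated counterpart."""

    accuracy_by_detection: pd.DataFrame
    detection_ratio: pd.DataFrame
    model_accuracy_by_detection: Optional[pd.DataFrame] = None
    model_detection_ratio: Optional[pd.DataFrame] = None


def _evidence_tables(
    session: Session, detected: np.ndarray, n_bins: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    diff = click_difference(session)
    strength = np.abs(diff)
    correct = np.sign(diff) == np.where(session.choices == "R", 1, -1)
    usable = diff != 0
    edges = np.quantile(strength[usable], np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1
    which = np.clip(np.searchsorted(edges, strength, side="right") - 1, 0, n_bins - 1)
    overall_det = detected.mean()
    acc_rows, det_rows = [], []
    for b in range(n_bins):
        m = usable & (which == b)
        if not m.any():
            acc_rows.append(dict(bin=b, strength=np.nan, acc_detected=np.nan, acc_undetected=np.nan, n=0))
            det_rows.append(dict(bin=b, strength=np.nan, detection_ratio=np.nan, n=0))
            continue
        md, mu = m & detected, m & ~detected
        acc_rows.append(
            dict(
                bin=b,
                strength=float(strength[m].mean()),
                acc_detected=float(correct[md].mean()) if md.any() else np.nan,
                acc_undetected=float(correct[mu].mean()) if mu.any() else np.nan,
                n=int(m.sum()),
            )
        )
        det_rows.append(
            dict(
                bin=b,
                strength=float(strength[m].mean()),
                detection_ratio=float(detected[m].mean() / overall_det) if overall_det > 0 else np.nan,
                n=int(m.sum()),
            )
        )
    return pd.DataFrame(acc_rows), pd.DataFrame(det_rows)


def commitment_behaviour_summary(
    session: Session,
    commit_steps: np.ndarray,
    model_session: Optional[Session] = None,
    model_commit_steps: Optional[np.ndarray] = None,
    n_bins: int = 4,
) -> CommitmentBehaviourSummary:
    """Commitment-detection behavioural summaries.

    (i) choice accuracy split by whether a commitment time was detected,
    per evidence-strength bin; (ii) the per-bin detection fraction
    normalized by the overall detection fraction. A simulated session with
    its own detection results produces the model-prediction counterpart.
    Bins with zero trials are reported as missing, not zero.
    """
    detected = np.asarray(commit_steps) >= 0
    acc, det = _evidence_tables(session, detected, n_bins)
    macc = mdet = None
    if model_session is not None and model_commit_steps is not None:
        mdetected = np.asarray(model_commit_steps) >= 0
        macc, mdet = _evidence_tables(model_session, mdetected, n_bins)
    return CommitmentBehaviourSummary(
        accuracy_by_detection=acc,
        detection_ratio=det,
        model_accuracy_by_detection=macc,
        model_detection_ratio=mdet,
    )
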