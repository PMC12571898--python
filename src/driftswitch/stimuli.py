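"""Pulsatile-click task stimuli and per-click sensory adaptation.

Trials present two simultaneous Poisson click trains (left/right speakers)
whose rates sum to a fixed combined rate; difficulty is set by the rate
ratio. Every train starts with a click played from both speakers at once
(the "stereoclick"). The effective input magnitude of each click is
depressed multiplicatively by preceding clicks and recovers exponentially
between clicks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TrialCondition",
    "ClickTrain",
    "AdaptationParams",
    "AdaptedClicks",
    "StimulusConfig",
    "DEFAULT_RATE_RATIOS",
    "sample_trial_conditions",
    "generate_click_train",
    "adapt_clicks",
]

#: Default generative click-rate ratios (right-favouring listed; mirrored
#: for left-favouring trials). Endpoints 39:1 (easiest) and 26:14 (hardest);
#: intermediate levels are evenly spaced stand-ins.
DEFAULT_RATE_RATIOS: tuple[tuple[float, float], ...] = (
    (39.0, 1.0),
    (38.0, 2.0),
    (36.0, 4.0),
    (34.0, 6.0),
    (32.0, 8.0),
    (30.0, 10.0),
    (28.0, 12.0),
    (26.0, 14.0),
)


@dataclass(frozen=True)
class TrialCondition:
    """Generative settings of a single trial.

    ``rate_left``/``rate_right`` are the Poisson click rates in clicks/s;
    ``duration`` is the stimulus duration in seconds; ``rewarded_side`` is
    the side with the greater generative rate.
    """

    rate_left: float
    rate_right: float
    duration: float
    rewarded_side: str

    def __post_init__(self) -> None:
        if self.rate_left < 0 or self.rate_right < 0:
            raise ValueError("click rates must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.rewarded_side not in ("L", "R"):
            raise ValueError(f"rewarded_side must be 'L' or 'R', got {self.rewarded_side!r}")


@dataclass(frozen=True)
class ClickTrain:
    """Click times of one trial, in seconds from stimulus onset.

    The stereoclick at t = 0 is present in both ``left_times`` and
    ``right_times``.
    """

    left_times: np.ndarray
    right_times: np.ndarray
    duration: float
    stereoclick_time: float = 0.0

    def __post_init__(self) -> None:
        for name in ("left_times", "right_times"):
            t = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, t)
            if t.size and (np.any(np.diff(t) < 0)):
                raise ValueError(f"{name} must be sorted")
            if t.size and (t[0] < 0 or t[-1] >= self.duration):
                raise ValueError(f"{name} must lie within [0, duration)")


@dataclass(frozen=True)
class AdaptationParams:
    """Multiplicative click depression with exponential recovery.

    ``phi`` in (0, 1] is the per-click depression factor; ``tau_phi`` > 0 is
    the recovery time constant (s). ``phi = 1`` disables adaptation. These
    are fixed constants of the model, not free parameters of any fit; the
    defaults are stand-ins for unpublished values.
    """

    phi: float = 0.6
    tau_phi: float = 0.2
    include_stereoclick: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.phi <= 1.0):
            raise ValueError("phi must be in (0, 1]")
        if self.tau_phi <= 0:
            raise ValueError("tau_phi must be positive")


@dataclass(frozen=True)
class AdaptedClicks:
    """Merged click stream with per-click input magnitudes.

    ``times`` are sorted click times (s); ``sides`` holds 'L'/'R' labels;
    ``magnitudes`` are the adaptation scaling factors in (0, 1].
    """

    times: np.ndarray
    sides: np.ndarray
    magnitudes: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class StimulusConfig:
    """Settings for sampling trial conditions."""

    rate_ratios: Sequence[tuple[float, float]] = field(default=DEFAULT_RATE_RATIOS)
    duration_range: tuple[float, float] = (0.2, 1.0)

    def __post_init__(self) -> None:
        if len(self.rate_ratios) == 0:
            raise ValueError("rate_ratios must not be empty")
        lo, hi = self.duration_range
        if not (0 < lo <= hi):
            raise ValueError("duration range must satisfy 0 < lo <= hi")


def sample_trial_conditions(
    n_trials: int,
    config: StimulusConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> list[TrialCondition]:
    """Draw trial conditions uniformly over allowed rate ratios and sides.

    Each trial picks a ratio uniformly from ``config.rate_ratios``, assigns
    the larger rate to the left or right side with equal probability, and
    draws the duration uniformly from ``config.duration_range``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    config = config or StimulusConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ratios = list(config.rate_ratios)
    idx = rng.integers(0, len(ratios), size=n_trials)
    right_favoured = rng.random(n_trials) < 0.5
    lo, hi = config.duration_range
    durations = rng.uniform(lo, hi, size=n_trials)
    out = []
    for i in range(n_trials):
        hi_rate, lo_rate = ratios[idx[i]]
        if hi_rate < lo_rate:
            hi_rate, lo_rate = lo_rate, hi_rate
        if right_favoured[i]:
            cond = TrialCondition(lo_rate, hi_rate, durations[i], "R")
        else:
            cond = TrialCondition(hi_rate, lo_rate, durations[i], "L")
        out.append(cond)
    return out


def generate_click_train(
    condition: TrialCondition,
    seed: int | np.random.Generator = 0,
) -> ClickTrain:
    """Sample homogeneous Poisson click times for one trial.

    Left and right times are independent Poisson processes at the
    generative rates over [0, duration), plus the stereoclick at t = 0 on
    both sides.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    times = []
    for rate in (condition.rate_left, condition.rate_right):
        n = rng.poisson(rate * condition.duration)
        t = np.sort(rng.uniform(0.0, condition.duration, size=n))
        # keep strictly inside (0, duration) so t = 0 is stereoclick-only
        t = t[t > 0.0]
        times.append(t)
    left = np.concatenate(([0.0], times[0]))
    right = np.concatenate(([0.0], times[1]))
    return ClickTrain(left_times=left, right_times=right, duration=condition.duration)


def adapt_clicks(train: ClickTrain, params: AdaptationParams | None = None) -> AdaptedClicks:
    """Compute the adaptation magnitude of every click.

    Clicks from both sides are merged into one stream. An adaptation state
    ``a`` starts at 1; each click is assigned magnitude ``C = a`` and then
    depresses the state, ``a <- a * phi``. Between clicks the state recovers
    towards 1 with ``da/dt = (1 - a) / tau_phi``. Simultaneous left/right
    clicks (the stereoclick) share the same pre-update state and the
    depression is applied once for the pair.

    With ``include_stereoclick=False`` the stereoclick is dropped from the
    output but still participates in the adaptation bookkeeping.
    """
    params = params or AdaptationParams()
    left = np.asarray(train.left_times, dtype=float)
    right = np.asarray(train.right_times, dtype=float)
    times = np.concatenate([left, right])
    sides = np.concatenate([np.full(len(left), "L"), np.full(len(right), "R")])
    order = np.argsort(times, kind="stable")
    times, sides = times[order], sides[order]

    mags = np.empty(len(times))
    a = 1.0
    prev_t = None
    i = 0
    while i < len(times):
        t = times[i]
        # group exactly-simultaneous clicks: shared state, one depression
        j = i
        while j < len(times) and times[j] == t:
            j += 1
        if prev_t is not None:
            dt = t - prev_t
            a = 1.0 - (1.0 - a) * np.exp(-dt / params.tau_phi)
        mags[i:j] = a
        a *= params.phi
        prev_t = t
        i = j

    if not params.include_stereoclick:
        keep = times != train.stereoclick_time
        times, sides, mags = times[keep], sides[keep], mags[keep]
    return AdaptedClicks(times=times, sides=sides, magnitudes=mags)
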