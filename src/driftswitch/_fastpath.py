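"""Numba-accelerated forward-backward kernel with a numpy fallback."""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

_FLOOR = 1e-300


@njit(cache=True)
def fb_kernel(pi, mats, index, E, choice_p, want_smooth):
    """Scaled forward(-backward) pass; emissions E are pre-shifted.

    Returns (loglik_excluding_shifts, filtered, smoothed, floored). The
    choice likelihood is folded into the final step. ``smoothed`` is only
    meaningful when ``want_smooth``.
    """
    T, S = E.shape
    filtered = np.zeros((T, S))
    smoothed = np.zeros((T, S))
    floored = 0
    loglik = 0.0
    a = pi * E[0]
    if T == 1:
        a = a * choice_p
    s = a.sum()
    if s <= 0.0:
        a = a + _FLOOR
        s = a.sum()
        floored = 1
        if s <= 0.0:
            return -np.inf, filtered, smoothed, 1
    loglik += np.log(s)
    a = a / s
    filtered[0] = a
    for t in range(1, T):
        a = np.dot(a, mats[index[t - 1]]) * E[t]
        if t == T - 1:
            a = a * choice_p
        s = a.sum()
        if s <= 0.0:
            a = a + _FLOOR
            s = a.sum()
            floored = 1
            if s <= 0.0:
                return -np.inf, filtered, smoothed, 1
        loglik += np.log(s)
        a = a / s
        filtered[t] = a
    if not want_smooth:
        return loglik, filtered, smoothed, floored
    smoothed[T - 1] = filtered[T - 1]
    beta = np.ones(S)
    for t in range(T - 2, -1, -1):
        w = E[t + 1] * beta
        if t + 1 == T - 1:
            w = w * choice_p
        beta = np.dot(mats[index[t]], w)
        bs = beta.sum()
        if bs <= 0.0:
            beta = np.full(S, 1.0 / S)
        else:
            beta = beta / bs
        g = filtered[t] * beta
        gs = g.sum()
        if gs > 0.0:
            smoothed[t] = g / gs
        else:
            smoothed[t] = filtered[t]
    return loglik, filtered, smoothed, floored
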