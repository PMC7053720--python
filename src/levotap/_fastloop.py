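"""Numba kernels for the firing-rate network.

The network is tiny (15 scalar units) but is integrated with an explicit
Euler step of 0.1 ms over seconds of simulated time, so the hot loop is
compiled.  The Python reference implementation of a single step lives in
:mod:`levotap.bg_network` (``step_network``); a test pins the two routes
against each other.

Parameter-vector layout (``P``), all float64::

    0 tau_ms   1 dt_ms    2 a        3 u0       4 wL       5 wThM
    6 wMTh     7 alphaGo  8 betaNoGo 9 wChNoGo 10 wNoGoGPe 11 wGoGPi
   12 wGPeGPi 13 wGPiTh  14 tonicGPe 15 tonicGPi 16 tonicCh 17 kChD
   18 stim    19 threshold 20 lag_ms 21 timeout_ms 22 settle_ms

Plastic weights ``W = [wGo0, wGo1, wNoGo0, wNoGo1]``.

State vector ``y`` (15): per channel ``i`` at offset ``7*i`` the units
``S, M, G, N, E, I, Th``; index 14 is the shared cholinergic unit.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

N_STATE = 15
N_PARAMS = 23

# named indices into P
TAU, DT, A, U0, WL, WTHM, WMTH, ALPHAGO, BETANOGO, WCHNOGO, WNOGOGPE, \
    WGOGPI, WGPEGPI, WGPITH, TONICGPE, TONICGPI, TONICCH, KCHD, STIM, \
    THRESH, LAG, TIMEOUT, SETTLE = range(N_PARAMS)


@njit(cache=True, inline="always")
def _sig(u, a, u0):
    return 1.0 / (1.0 + math.exp(-a * (u - u0)))


@njit(cache=True, inline="always")
def _step_once(y, new, P, W, s0, s1, D):
    """One synchronous Euler step; writes the next state through ``new``."""
    a = P[A]
    u0 = P[U0]
    r = P[DT] / P[TAU]
    ch = y[14]
    tot = y[1] + y[8] + 1e-9
    for i in range(2):
        b = 7 * i
        j = 7 * (1 - i)
        stim = s0 if i == 0 else s1
        gate = y[b + 1] / tot
        uS = stim
        uM = y[b + 0] + P[WTHM] * y[b + 6] - P[WL] * y[j + 1]
        uG = W[i] * y[b + 1] + P[ALPHAGO] * D * gate
        uN = W[2 + i] * y[b + 1] - P[BETANOGO] * D + P[WCHNOGO] * ch
        uE = P[TONICGPE] - P[WNOGOGPE] * y[b + 3]
        uI = P[TONICGPI] - P[WGOGPI] * y[b + 2] - P[WGPEGPI] * y[b + 4]
        uTh = P[WMTH] * y[b + 1] - P[WGPITH] * y[b + 5]
        new[b + 0] = y[b + 0] + r * (-y[b + 0] + _sig(uS, a, u0))
        new[b + 1] = y[b + 1] + r * (-y[b + 1] + _sig(uM, a, u0))
        new[b + 2] = y[b + 2] + r * (-y[b + 2] + _sig(uG, a, u0))
        new[b + 3] = y[b + 3] + r * (-y[b + 3] + _sig(uN, a, u0))
        new[b + 4] = y[b + 4] + r * (-y[b + 4] + _sig(uE, a, u0))
        new[b + 5] = y[b + 5] + r * (-y[b + 5] + _sig(uI, a, u0))
        new[b + 6] = y[b + 6] + r * (-y[b + 6] + _sig(uTh, a, u0))
    uCh = P[TONICCH] - P[KCHD] * D
    new[14] = y[14] + r * (-y[14] + _sig(uCh, a, u0))
    for k in range(15):
        y[k] = new[k]


@njit(cache=True)
def integrate(y, P, W, s0, s1, D, n_steps):
    """Advance the state in place by ``n_steps`` Euler steps."""
    new = np.empty(N_STATE)
    for _ in range(n_steps):
        _step_once(y, new, P, W, s0, s1, D)


@njit(cache=True)
def run_selection(y, P, W, s0, s1, D, only_channel, max_steps):
    """Integrate until a motor unit crosses the tap threshold.

    ``only_channel`` = 0/1 restricts the watch to that channel (tapping
    protocol, where the cue defines the required action); -1 watches both
    (training, where the network's own choice matters).  Returns
    ``(choice, steps)`` with ``choice = -1`` on timeout.
    """
    new = np.empty(N_STATE)
    thresh = P[THRESH]
    for n in range(1, max_steps + 1):
        _step_once(y, new, P, W, s0, s1, D)
        if only_channel != 1 and y[1] >= thresh:
            return 0, n
        if only_channel != 0 and y[8] >= thresh:
            return 1, n
    return -1, max_steps


@njit(cache=True)
def tapping_trial(P, W, D, n_cycles, max_duration_ms):
    """Alternate-tapping protocol at constant dopaminergic input ``D``.

    The network settles without stimulus, then the stimulus is presented to
    the cued channel; a tap is registered when that channel's motor unit
    crosses the threshold (or at the timeout), the stimulus stays on for the
    inter-movement lag, then the cue switches.  Returns the tap times (ms)
    actually produced (may be fewer than ``n_cycles`` if the duration cap is
    hit).
    """
    y = np.zeros(N_STATE)
    dt = P[DT]
    integrate(y, P, W, 0.0, 0.0, D, int(P[SETTLE] / dt))
    lag_steps = int(P[LAG] / dt)
    timeout_steps = int(P[TIMEOUT] / dt)
    taps = np.empty(n_cycles)
    t = 0.0
    cue = 0
    count = 0
    for _c in range(n_cycles):
        s0 = P[STIM] if cue == 0 else 0.0
        s1 = P[STIM] if cue == 1 else 0.0
        choice, steps = run_selection(y, P, W, s0, s1, D, cue, timeout_steps)
        lat = steps * dt if choice == cue else P[TIMEOUT]
        t += lat
        taps[count] = t
        count += 1
        integrate(y, P, W, s0, s1, D, lag_steps)
        t += P[LAG]
        cue = 1 - cue
        if t >= max_duration_ms:
            break
    return taps[:count]
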