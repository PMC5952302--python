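"""Optional numba-compiled right-hand side for the network ODE system.

Numerically identical to :func:`crstim.model.derivatives` (same formulas,
same singularity guards); exists only to cut per-call overhead in the
integration hot loop.  Falls back transparently when numba is unavailable.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard install dependency
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco


@njit(cache=True)
def rhs_core(
    V, m, h, n, s, I, A, B, W,
    g_Na, g_K, g_l, V_Na, V_K, V_l, C, V_r_exc,
    out,
):
    """dy/dt for the packed state; W[i] = K * (D @ G)_i (stimulation gain).

    A = c * |M| and B = V_r * A are the cached coupling products; the
    coupling current is S_i = (B@s - V_i (A@s)) / N.
    """
    N = V.size
    As = A @ s
    Bs = B @ s
    for i in range(N):
        v = V[i]
        x = 0.1 * v + 4.0
        if abs(x) < 1e-7:
            am = 1.0
        else:
            am = x / (1.0 - math.exp(-x))
        bm = 4.0 * math.exp(-(v + 65.0) / 18.0)
        ah = 0.07 * math.exp(-(v + 65.0) / 20.0)
        bh = 1.0 / (1.0 + math.exp(-0.1 * v - 3.5))
        u = 0.1 * v + 5.5
        if abs(u) < 1e-7:
            an = 0.1
        else:
            an = 0.1 * u / (1.0 - math.exp(-u))
        bn = 0.125 * math.exp(-(v + 65.0) / 80.0)

        S = (Bs[i] - v * As[i]) / N
        F = (V_r_exc - v) * W[i]
        out[i] = (
            I[i]
            - g_Na * m[i] ** 3 * h[i] * (v - V_Na)
            - g_K * n[i] ** 4 * (v - V_K)
            - g_l * (v - V_l)
            + S
            + F
        ) / C
        out[N + i] = am * (1.0 - m[i]) - bm * m[i]
        out[2 * N + i] = ah * (1.0 - h[i]) - bh * h[i]
        out[3 * N + i] = an * (1.0 - n[i]) - bn * n[i]
        out[4 * N + i] = 0.5 * (1.0 - s[i]) / (1.0 + math.exp(-(v + 5.0) / 12.0)) - 2.0 * s[i]
    return out


@njit(cache=True)
def _stim_gain(t, onsets, onset_len, D, K, tau, cutoff, W):
    """W[i] = K * sum_k D[i,k] G_k(t): alpha-functions of the last onsets.

    ``onsets`` is (Ns, max_len) padded; ``onset_len`` the valid lengths.
    The alpha-function of an onset is truncated ``cutoff`` after it; at
    most the two most recent onsets can contribute.
    """
    Ns = onsets.shape[0]
    Nn = W.size
    for i in range(Nn):
        W[i] = 0.0
    for k in range(Ns):
        n_k = onset_len[k]
        # binary search: first index with onsets[k, idx] > t
        lo, hi = 0, n_k
        while lo < hi:
            mid = (lo + hi) // 2
            if onsets[k, mid] <= t:
                lo = mid + 1
            else:
                hi = mid
        g = 0.0
        for back in range(1, 3):
            j = lo - back
            if j < 0:
                break
            dt = t - onsets[k, j]
            if dt <= cutoff:
                g += dt / tau * math.exp(-dt / tau)
        if g != 0.0:
            gk = K * g
            for i in range(Nn):
                W[i] += gk * D[i, k]
    return W


@njit(cache=True)
def _eval_rhs(
    t, y, dy, I, A, B, W_buf,
    onsets, onset_len, D, K, tau, cutoff, use_stim,
    g_Na, g_K, g_l, V_Na, V_K, V_l, C, V_r_exc,
):
    N = I.size
    if use_stim:
        _stim_gain(t, onsets, onset_len, D, K, tau, cutoff, W_buf)
    else:
        for i in range(N):
            W_buf[i] = 0.0
    rhs_core(
        y[0:N], y[N : 2 * N], y[2 * N : 3 * N], y[3 * N : 4 * N],
        y[4 * N : 5 * N], I, A, B, W_buf,
        g_Na, g_K, g_l, V_Na, V_K, V_l, C, V_r_exc, dy,
    )


# Dormand-Prince RK45 tableau (the classical ode45 pair)
_C2, _C3, _C4, _C5 = 0.2, 0.3, 0.8, 8.0 / 9.0
_A21 = 0.2
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = 19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0
_A61, _A62, _A63, _A64, _A65 = (
    9017.0 / 3168.0, -355.0 / 33.0, 46732.0 / 5247.0, 49.0 / 176.0, -5103.0 / 18656.0,
)
_B1, _B3, _B4, _B5, _B6 = 35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0, -2187.0 / 6784.0, 11.0 / 84.0
_E1, _E3, _E4, _E5, _E6, _E7 = (
    71.0 / 57600.0, -71.0 / 16695.0, 71.0 / 1920.0, -17253.0 / 339200.0, 22.0 / 525.0, -1.0 / 40.0,
)
_SAFETY, _MIN_FACTOR, _MAX_FACTOR = 0.9, 0.2, 10.0


@njit(cache=True)
def integrate_segment(
    t, y, t_bound, h_init,
    I, A, B,
    onsets, onset_len, D, K, tau, cutoff, use_stim,
    g_Na, g_K, g_l, V_Na, V_K, V_l, C, V_r_exc,
    rtol, atol, max_step,
    threshold, lockout, last_spike,
    V_prev_out,
):
    """Adaptive RK45 from ``t`` toward ``t_bound``; stops at spikes.

    Advances ``y`` in place.  Returns (status, t_prev, t_new, h_next,
    n_steps) where status is 1 when ``t_bound`` was reached and 2 when the
    last accepted step contains an upward threshold crossing that passes
    the per-neuron ``lockout`` against ``last_spike`` (the caller then
    detects the exact crossing, applies plasticity, and resumes).
    ``V_prev_out`` receives the membrane potentials at the step start.
    """
    ny = y.size
    N = I.size
    dy = np.empty(ny)
    k1 = np.empty(ny)
    k2 = np.empty(ny)
    k3 = np.empty(ny)
    k4 = np.empty(ny)
    k5 = np.empty(ny)
    k6 = np.empty(ny)
    k7 = np.empty(ny)
    ytmp = np.empty(ny)
    ynew = np.empty(ny)
    W_buf = np.empty(N)

    _eval_rhs(t, y, k1, I, A, B, W_buf, onsets, onset_len, D, K, tau, cutoff,
              use_stim, g_Na, g_K, g_l, V_Na, V_K, V_l, C, V_r_exc)

    h = h_init
    if h <= 0.0 or h > max_step:
        h = max_step
    n_steps = 0
    n_iter = 0
    while t < t_bound:
        if h > max_step:
            h = max_step
        if t + h > t_bound:
            h = t_bound - t
        # stages
        for i in range(ny):
            ytmp[i] = y[i] + h * _A21 * k1[i]
        _eval_rhs(t + _C2 * h, ytmp, k2, I, A, B, W_buf, onsets, onset_len, D,
                  K, tau, cutoff, use_stim, g_Na, g_K, g_l, V_Na, V_K, V_l, C, V_r_exc)
        for i in range(ny):
            ytmp[i] = y[i] + h * (_A31 * k1[i] + _A32 * k2[i])
        _eval_rhs(t + _C3 * h, ytmp, k3, I, A, B, W_buf, onsets, onset_len, D,
                  K, tau, cutoff, use_stim, g_Na, g_K, g_l, V_Na, V_K, V_l, C, V_r_exc)
        for i in range(ny):
            ytmp[i] = y[i] + h * (_A41 * k1[i] + _A42 * k2[i] + _A43 * k3[i])
        _eval_rhs(t + _C4 * h, ytmp, k4, I, A, B, W_buf, onsets, onset_len, D,
                  K, tau, cutoff, use_stim, g_Na, g_K, g_l, V_Na, V_K, V_l, C, V_r_exc)
        for i in range(ny):
            ytmp[i] = y[i] + h * (_A51 * k1[i] + _A52 * k2[i] + _A53 * k3[i] + _A54 * k4[i])
        _eval_rhs(t + _C5 * h, ytmp, k5, I, A, B, W_buf, onsets, onset_len, D,
                  K, tau, cutoff, use_stim, g_Na, g_K, g_l, V_Na, V_K, V_l, C, V_r_exc)
        for i in range(ny):
            ytmp[i] = y[i] + h * (_A61 * k1[i] + _A62 * k2[i] + _A63 * k3[i]
                                  + _A64 * k4[i] + _A65 * k5[i])
        _eval_rhs(t + h, ytmp, k6, I, A, B, W_buf, onsets, onset_len, D,
                  K, tau, cutoff, use_stim, g_Na, g_K, g_l, V_Na, V_K, V_l, C, V_r_exc)
        for i in range(ny):
            ynew[i] = y[i] + h * (_B1 * k1[i] + _B3 * k3[i] + _B4 * k4[i]
                                  + _B5 * k5[i] + _B6 * k6[i])
        _eval_rhs(t + h, ynew, k7, I, A, B, W_buf, onsets, onset_len, D,
                  K, tau, cutoff, use_stim, g_Na, g_K, g_l, V_Na, V_K, V_l, C, V_r_exc)
        # scaled RMS error of the embedded 4th-order difference
        err = 0.0
        for i in range(ny):
            e = h * (_E1 * k1[i] + _E3 * k3[i] + _E4 * k4[i] + _E5 * k5[i]
                     + _E6 * k6[i] + _E7 * k7[i])
            ay = abs(y[i])
            ayn = abs(ynew[i])
            scale = atol + rtol * (ay if ay > ayn else ayn)
            r = e / scale
            err += r * r
        err = math.sqrt(err / ny)
        n_iter += 1
        if n_iter > 100_000_000:
            return 0, t, t, h, n_steps
        if err < 1.0:
            # accepted
            t_prev = t
            t = t + h
            n_steps += 1
            crossing = False
            for i in range(N):
                V_prev_out[i] = y[i]
            for i in range(N):
                if y[i] < threshold and ynew[i] >= threshold:
                    frac = (threshold - y[i]) / (ynew[i] - y[i])
                    tc = t_prev + frac * h
                    if not (tc - last_spike[i] < lockout):
                        crossing = True
            for i in range(ny):
                y[i] = ynew[i]
                k1[i] = k7[i]
            if err == 0.0:
                factor = _MAX_FACTOR
            else:
                factor = _SAFETY * err ** -0.2
                if factor > _MAX_FACTOR:
                    factor = _MAX_FACTOR
                elif factor < _MIN_FACTOR:
                    factor = _MIN_FACTOR
            h = h * factor
            if crossing:
                return 2, t_prev, t, h, n_steps
        else:
            # rejected; a non-finite error norm (overflowed trial step)
            # forces the strongest shrink, as scipy's controller does
            if math.isfinite(err) and err > 0.0:
                factor = _SAFETY * err ** -0.2
                if factor < _MIN_FACTOR:
                    factor = _MIN_FACTOR
            else:
                factor = _MIN_FACTOR
            h = h * factor
            if h < 1e-12:
                return 0, t, t, h, n_steps  # step size underflow
    return 1, t, t, h, n_steps
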