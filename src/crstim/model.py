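"""Hodgkin-Huxley neuron dynamics, ring geometry and synaptic coupling.

The membrane dynamics are the classical HH equations with an injected
constant current, a network coupling current S_i and a stimulation current
F_i.  The connection template M_ij is a Mexican hat of the ring distance:
positive (excitatory) at short range, negative (inhibitory) at long range.
The dynamic weight matrix c stores nonnegative magnitudes in [0, 1]; the
synapse type is carried solely by sign(M_ij).

Public indices are 1-based (matching the stimulation sites 25/75/125/175);
arrays are stored 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .params import NetworkParams

#: window around a removable singularity within which the analytic limit is used
_SING_EPS = 1e-7


class RateConstants(NamedTuple):
    alpha_m: np.ndarray
    beta_m: np.ndarray
    alpha_h: np.ndarray
    beta_h: np.ndarray
    alpha_n: np.ndarray
    beta_n: np.ndarray


def rate_constants(V) -> RateConstants:
    """Voltage-dependent opening/closing rates of the m, h, n gates (1/ms).

    alpha_m and alpha_n have removable 0/0 singularities at V = -40 mV and
    V = -55 mV respectively; within ``_SING_EPS`` of the singular point the
    analytic (L'Hopital) limit is returned.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        # alpha_m = (0.1 V + 4) / (1 - exp(-0.1 V - 4)); write x = 0.1 V + 4
        x = 0.1 * V + 4.0
        alpha_m = np.where(np.abs(x) < _SING_EPS, 1.0, x / (1.0 - np.exp(-x)))
        # alpha_n = (0.01 V + 0.55) / (1 - exp(-0.1 V - 5.5)); write u = 0.1 V + 5.5
        u = 0.1 * V + 5.5
        alpha_n = np.where(np.abs(u) < _SING_EPS, 0.1, 0.1 * u / (1.0 - np.exp(-u)))

    beta_m = 4.0 * np.exp(-(V + 65.0) / 18.0)
    alpha_h = 0.07 * np.exp(-(V + 65.0) / 20.0)
    beta_h = 1.0 / (1.0 + np.exp(-0.1 * V - 3.5))
    beta_n = 0.125 * np.exp(-(V + 65.0) / 80.0)
    return RateConstants(alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)


def gate_steady_state(V):
    """Steady-state gate values x_inf = alpha/(alpha+beta) at potential V."""
    r = rate_constants(V)
    m = r.alpha_m / (r.alpha_m + r.beta_m)
    h = r.alpha_h / (r.alpha_h + r.beta_h)
    n = r.alpha_n / (r.alpha_n + r.beta_n)
    return m, h, n


def ring_distance(i, j, params: NetworkParams):
    """Physical shortest distance on the ring between 1-based indices i, j."""
    diff = np.abs(np.asarray(i) - np.asarray(j))
    return params.d * np.minimum(diff, params.N - diff)


def mexican_hat(i: int, j: int, params: NetworkParams) -> float:
    """Signed connection template value M_ij for a single (1-based) pair."""
    for idx in (i, j):
        if not 1 <= idx <= params.N:
            raise ValueError(f"neuron index {idx} out of range [1, {params.N}]")
    d_ij = float(ring_distance(i, j, params))
    return (1.0 - d_ij**2 / params.sigma1**2) * np.exp(-(d_ij**2) / (2.0 * params.sigma2**2))


def mexican_hat_matrix(params: NetworkParams) -> np.ndarray:
    """Full N x N template; symmetric, ring-periodic, M_ii = 1."""
    idx = np.arange(params.N)
    d_ij = ring_distance(idx[:, None] + 1, idx[None, :] + 1, params)
    return (1.0 - d_ij**2 / params.sigma1**2) * np.exp(-(d_ij**2) / (2.0 * params.sigma2**2))


@dataclass
class NetworkState:
    """Per-neuron dynamic variables plus the weight matrix.

    ``c`` holds weight magnitudes in [0, 1] with c_ii = 0; ``last_spike``
    is NaN for neurons with no detected spike yet.  ``t`` is in ms with
    t = 0 at first-stimulus delivery.
    """

    V: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    s: np.ndarray
    I: np.ndarray
    c: np.ndarray
    last_spike: np.ndarray
    t: float = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(
            V=self.V.copy(), m=self.m.copy(), h=self.h.copy(), n=self.n.copy(),
            s=self.s.copy(), I=self.I.copy(), c=self.c.copy(),
            last_spike=self.last_spike.copy(), t=self.t,
        )

    def pack(self) -> np.ndarray:
        return np.concatenate([self.V, self.m, self.h, self.n, self.s])

    def unpack(self, y: np.ndarray) -> None:
        N = self.V.size
        self.V = y[0:N]
        self.m = y[N : 2 * N]
        self.h = y[2 * N : 3 * N]
        self.n = y[3 * N : 4 * N]
        self.s = y[4 * N : 5 * N]


def reversal_matrix(M: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Per-synapse reversal potential: V_r_exc where M>0, V_r_inh where M<0."""
    return np.where(M > 0, params.V_r_exc, params.V_r_inh)


def coupling_currents(V, s, c, M, params: NetworkParams) -> np.ndarray:
    """Network coupling current S_i for every neuron (uA/cm^2).

    S_i = N^-1 sum_j (V_r,j - V_i) c_ij |M_ij| s_j.  With c_ii = 0 the
    diagonal term contributes nothing.
    """
    A = c * np.abs(M)
    B = reversal_matrix(M, params) * A
    return (B @ s - V * (A @ s)) / params.N


def coupling_current(i: int, state: NetworkState, M: np.ndarray, params: NetworkParams) -> float:
    """Coupling current of the single (1-based) neuron i."""
    if not 1 <= i <= params.N:
        raise ValueError(f"neuron index {i} out of range")
    row = i - 1
    Vr = reversal_matrix(M[row], params)
    summand = (Vr - state.V[row]) * state.c[row] * np.abs(M[row]) * state.s
    return float(summand.sum() / params.N)


def derivatives(state: NetworkState, S, F, params: NetworkParams):
    """Time derivatives of (V, m, h, n, s) for all neurons.

    Membrane:  C dV/dt = I - g_Na m^3 h (V-V_Na) - g_K n^4 (V-V_K)
                          - g_l (V-V_l) + S + F
    Gates:     dx/dt = alpha_x(V)(1-x) - beta_x(V) x
    Synapse:   ds/dt = 0.5 (1-s) / (1 + exp(-(V+5)/12)) - 2 s
    """
    V, m, h, n, s = state.V, state.m, state.h, state.n, state.s
    S = np.asarray(S, dtype=float)
    F = np.asarray(F, dtype=float)
    r = rate_constants(V)
    dV = (
        state.I
        - params.g_Na * m**3 * h * (V - params.V_Na)
        - params.g_K * n**4 * (V - params.V_K)
        - params.g_l * (V - params.V_l)
        + S
        + F
    ) / params.C
    dm = r.alpha_m * (1.0 - m) - r.beta_m * m
    dh = r.alpha_h * (1.0 - h) - r.beta_h * h
    dn = r.alpha_n * (1.0 - n) - r.beta_n * n
    ds = 0.5 * (1.0 - s) / (1.0 + np.exp(-(V + 5.0) / 12.0)) - 2.0 * s
    return dV, dm, dh, dn, ds
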