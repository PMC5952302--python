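"""Event-based spike-timing-dependent plasticity.

Every detected spike updates the spiking neuron's incoming and outgoing
weights against each partner's most recent spike (nearest-spike pairing).
Causal pairs (post fires dt >= 0 after pre) are potentiated on excitatory
synapses; acausal pairs are depressed.  Inhibitory synapses receive the
opposite-signed update.  Weight magnitudes are hard-clamped to
[c_min, c_max].
"""

from __future__ import annotations

import numpy as np

from .model import NetworkState
from .params import StdpParams


def stdp_delta(dt, p: StdpParams = StdpParams()):
    """Raw weight change for a post-minus-pre spike-time difference dt (ms).

    dt >= 0:  beta1 * exp(-dt / (gamma1 tau))          (positive)
    dt <  0:  beta2 * (dt/tau) * exp(dt / (gamma2 tau)) (negative)

    Vectorized over dt; the dt = 0 boundary takes the causal branch.
    """
    dt = np.asarray(dt, dtype=float)
    if not np.all(np.isfinite(dt)):
        raise ValueError("spike-time difference must be finite")
    with np.errstate(over="ignore"):
        pos = p.beta1 * np.exp(-dt / (p.gamma1 * p.tau))
        neg = p.beta2 * (dt / p.tau) * np.exp(dt / (p.gamma2 * p.tau))
    out = np.where(dt >= 0.0, pos, neg)
    return float(out) if out.ndim == 0 else out


def apply_spike(
    neuron: int,
    t_spike: float,
    state: NetworkState,
    M: np.ndarray,
    p: StdpParams,
) -> np.ndarray:
    """Apply the STDP update triggered by a spike of ``neuron`` (1-based).

    For every partner j with a recorded last spike, the incoming weight
    c[neuron, j] is updated with dt = t_spike - last_spike_j (causal branch)
    and the outgoing weight c[j, neuron] with dt = last_spike_j - t_spike.
    Excitatory synapses (M > 0) add +delta*dc, inhibitory ones -delta*dc.
    Partners with no spike history, and the self-synapse, are skipped.

    Mutates ``state.c`` in place and returns it.
    """
    i = neuron - 1
    last = state.last_spike
    if np.isfinite(last[i]) and t_spike < last[i]:
        raise ValueError("t_spike precedes the neuron's recorded last spike")
    partners = np.flatnonzero(np.isfinite(last))
    partners = partners[partners != i]
    if partners.size == 0:
        return state.c

    dt_in = t_spike - last[partners]  # >= 0: this neuron is postsynaptic
    dc_in = stdp_delta(dt_in, p)
    dc_out = stdp_delta(-dt_in, p)

    sgn_in = np.sign(M[i, partners])
    sgn_out = np.sign(M[partners, i])
    c = state.c
    c[i, partners] = np.clip(c[i, partners] + sgn_in * p.delta * dc_in, p.c_min, p.c_max)
    c[partners, i] = np.clip(c[partners, i] + sgn_out * p.delta * dc_out, p.c_min, p.c_max)
    return c
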