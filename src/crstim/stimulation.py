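"""Stimulation schedules and currents for the seven protocols.

Each active protocol delivers exactly one stimulus per site per ON-cycle;
three consecutive ON-cycles alternate with two OFF-cycles.  The protocols
differ only in how the within-cycle onset times are drawn:

* ``PPMS``      - one random offset, reused every ON-cycle; all sites together.
* ``CMNS``      - a fresh shared random offset every ON-cycle (the sham).
* ``UMNS``      - independent random offsets per site per ON-cycle.
* ``RVS_CR``    - coordinated reset: offsets {0, Ts/Ns, 2Ts/Ns, 3Ts/Ns} assigned
                  by a fresh random site permutation every ON-cycle.
* ``fixed_CR``  - one random permutation held for the entire stim-on period.
* ``SVS_CR``    - permutation redrawn after every ``svs_repeats`` ON-cycles.
* ``no_stim``   - empty schedule (control).

Each onset evokes a normalized alpha-function conductance
(dt/tau) exp(-dt/tau) with tau = Ts/(6 Ns), truncated Ts/2 after the onset;
two onsets closer than 2 Ts/Ns sum their conductances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import NetworkParams, StimParams, canonical_protocol
from .model import ring_distance


@dataclass
class OnsetSchedule:
    """Ordered per-site stimulation onsets for one stim-on period.

    ``times[k]`` (ms, ascending, relative to stim-on start), ``cycles[k]``
    (ON-cycle index, 0-based over all cycles) and ``ranks[k]`` (position 1-3
    within the 3-ON block) are parallel arrays for site k (0-based here;
    the exported table uses 1-based site indices).
    """

    protocol: str
    seed: object
    Ts: float
    times: list[np.ndarray] = field(default_factory=list)
    cycles: list[np.ndarray] = field(default_factory=list)
    ranks: list[np.ndarray] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.times)

    @property
    def empty(self) -> bool:
        return self.n_sites == 0 or all(t.size == 0 for t in self.times)

    def all_onsets(self) -> np.ndarray:
        """Merged, sorted, unique onset times across sites (integrator restarts)."""
        if self.empty:
            return np.empty(0)
        return np.unique(np.concatenate(self.times))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            pd.DataFrame(
                {
                    "site_index": np.full(self.times[k].size, k + 1, dtype=int),
                    "onset_ms": self.times[k],
                    "cycle_index": self.cycles[k],
                    "rank_in_block": self.ranks[k],
                }
            )
            for k in range(self.n_sites)
        ]
        if not rows:
            return pd.DataFrame(
                columns=["site_index", "onset_ms", "cycle_index", "rank_in_block"]
            )
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, protocol: str, Ts: float, seed=None) -> "OnsetSchedule":
        sched = cls(protocol=protocol, seed=seed, Ts=Ts)
        if len(df) == 0:
            return sched
        for k in sorted(df["site_index"].unique()):
            sub = df[df["site_index"] == k].sort_values("onset_ms")
            sched.times.append(sub["onset_ms"].to_numpy(float))
            sched.cycles.append(sub["cycle_index"].to_numpy(int))
            sched.ranks.append(sub["rank_in_block"].to_numpy(int))
        return sched

    @classmethod
    def from_tsv(cls, path, protocol: str, Ts: float, seed=None) -> "OnsetSchedule":
        return cls.from_frame(pd.read_csv(path, sep="\t"), protocol, Ts, seed)


def _on_cycle_grid(p: StimParams):
    """(start times, 0-based cycle indices, ranks 1..on_per_block) of ON-cycles."""
    block = p.on_per_block + p.off_per_block
    cyc = np.arange(p.n_cycles)
    pos = cyc % block
    on = pos < p.on_per_block
    return cyc[on] * p.Ts, cyc[on], (pos[on] + 1).astype(int)


def build_schedule(protocol: str, p: StimParams, seed) -> OnsetSchedule:
    """Generate the onset schedule of ``protocol`` for one stim-on period.

    Offsets are drawn uniformly on the half-open cycle [0, Ts); an onset at
    exactly the cycle end belongs to the next cycle.
    """
    protocol = canonical_protocol(protocol)
    sched = OnsetSchedule(protocol=protocol, seed=seed, Ts=p.Ts)
    if protocol == "no_stim":
        return sched

    rng = np.random.default_rng(seed)
    starts, cyc_idx, ranks = _on_cycle_grid(p)
    n_on = starts.size

    if protocol == "PPMS":
        offsets = np.tile(rng.uniform(0.0, p.Ts), (p.Ns, n_on))
    elif protocol == "CMNS":
        offsets = np.tile(rng.uniform(0.0, p.Ts, size=n_on), (p.Ns, 1))
    elif protocol == "UMNS":
        offsets = rng.uniform(0.0, p.Ts, size=(p.Ns, n_on))
    else:  # coordinated-reset variants: slots 0, Ts/Ns, ..., (Ns-1) Ts/Ns
        slots = p.Ts / p.Ns * np.arange(p.Ns)
        if protocol == "RVS_CR":
            perms = np.stack([rng.permutation(p.Ns) for _ in range(n_on)])
        elif protocol == "fixed_CR":
            perms = np.tile(rng.permutation(p.Ns), (n_on, 1))
        else:  # SVS_CR: redraw after every svs_repeats ON-cycle uses
            n_seq = -(-n_on // p.svs_repeats)
            draws = np.stack([rng.permutation(p.Ns) for _ in range(n_seq)])
            perms = np.repeat(draws, p.svs_repeats, axis=0)[:n_on]
        # perms[n, pos] = site activated at slot ``pos`` in ON-cycle n
        offsets = np.empty((p.Ns, n_on))
        for n in range(n_on):
            offsets[perms[n], n] = slots

    for k in range(p.Ns):
        sched.times.append(starts + offsets[k])
        sched.cycles.append(cyc_idx.copy())
        sched.ranks.append(ranks.copy())
    return sched


def spatial_profile(i, site_index, p: StimParams, net: NetworkParams):
    """Quadratic spatial attenuation D(i, x_k) in (0, 1].

    D = 1 / (1 + d^2 dist(i, x_k)^2 / sigma_d^2) with the ring (shortest
    path) neuron distance and the lattice spacing d.
    """
    dist = ring_distance(i, site_index, net)
    return 1.0 / (1.0 + dist**2 / p.sigma_d**2)


def profile_matrix(schedule_sites, p: StimParams, net: NetworkParams) -> np.ndarray:
    """N x Ns attenuation matrix for the configured stimulation sites."""
    idx = np.arange(1, net.N + 1)
    return np.stack(
        [spatial_profile(idx, x_k, p, net) for x_k in schedule_sites], axis=1
    )


def _alpha(dt, tau):
    return dt / tau * np.exp(-dt / tau)


def conductance(t: float, site_onsets: np.ndarray, p: StimParams) -> float:
    """Normalized conductance G_s,k(t) evoked at one site.

    The alpha-function of the most recent onset is truncated Ts/2 after it;
    if the previous onset is still within Ts/2 its tail is added (possible
    when two onsets fall within the 2 Ts/Ns overlap window).
    """
    onsets = np.asarray(site_onsets, dtype=float)
    if onsets.size > 1 and np.any(np.diff(onsets) < 0):
        raise ValueError("site onsets must be sorted ascending")
    idx = np.searchsorted(onsets, t, side="right")
    g = 0.0
    cutoff = p.Ts / 2.0
    for back in (1, 2):
        j = idx - back
        if j < 0:
            break
        dt = t - onsets[j]
        if dt <= cutoff:
            g += _alpha(dt, p.tau_alpha)
    return g


def conductance_vector(t: float, schedule: OnsetSchedule, p: StimParams) -> np.ndarray:
    """G_s,k(t) for all sites of a schedule."""
    return np.array([conductance(t, times, p) for times in schedule.times])


def stim_current(
    i,
    t: float,
    V,
    schedule: OnsetSchedule,
    p: StimParams,
    net: NetworkParams,
):
    """Total stimulation current F_i = (V_r - V_i) K sum_k D(i,x_k) G_s,k(t).

    ``i`` is a 1-based neuron index or array thereof; ``V`` the matching
    membrane potential(s).  Empty schedules yield 0.
    """
    if schedule.empty:
        return np.zeros_like(np.asarray(V, dtype=float))
    G = conductance_vector(t, schedule, p)
    D = np.stack(
        [spatial_profile(i, x_k, p, net) for x_k in net.site_indices], axis=-1
    )
    return (net.V_r_exc - np.asarray(V, dtype=float)) * p.K * (D @ G)
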