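"""Connectivity, synchronization and stimulus-locking metrics.

Connectivity is summarized by the signed network average C_av and the
excitatory/inhibitory averages c_EE, c_II (denominators are the squared
synapse counts, following the printed convention; every comparison in the
study is directional, so the scaling is immaterial).  Synchronization uses
the Kuramoto order parameter over linearly interpolated spike phases.
Stimulus-locked dynamics are quantified by cross-trial phase distributions
and the resetting index E_k; protocol contrasts use the one-sided Wilcoxon
rank-sum (Mann-Whitney) test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .params import NetworkParams
from .stimulation import OnsetSchedule


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

def synapse_counts(M: np.ndarray) -> tuple[int, int]:
    """(N_EE, N_II): excitatory / inhibitory synapse counts off the diagonal."""
    off = ~np.eye(M.shape[0], dtype=bool)
    return int(np.count_nonzero((M > 0) & off)), int(np.count_nonzero((M < 0) & off))


def mean_weights(c: np.ndarray, M: np.ndarray) -> tuple[float, float, float]:
    """Network-average signed weight and the excitatory/inhibitory averages.

    C_av = N^-2 sum sign(M_ij) c_ij;
    c_EE = N_EE^-2 sum over excitatory pairs; c_II = N_II^-2 over inhibitory.
    """
    N = c.shape[0]
    if c.shape != M.shape or c.shape[0] != c.shape[1]:
        raise ValueError("c and M must be square and same shape")
    off = ~np.eye(N, dtype=bool)
    exc = (M > 0) & off
    inh = (M < 0) & off
    n_ee, n_ii = synapse_counts(M)
    C_av = float(np.sum(np.sign(M) * c) / N**2)
    c_EE = float(c[exc].sum() / n_ee**2) if n_ee else 0.0
    c_II = float(c[inh].sum() / n_ii**2) if n_ii else 0.0
    return C_av, c_EE, c_II


def sort_connectivity(c: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Sorted signed connectivity matrix.

    For every unordered pair {i, j} the stronger of (c_ij, c_ji) is placed
    at (min(i,j), max(i,j)) and the weaker at (max(i,j), min(i,j)); the
    result is multiplied elementwise by sign(M).  Reveals uni- vs
    bidirectional coupling motifs across samples.
    """
    if c.shape[0] != c.shape[1]:
        raise ValueError("weight matrix must be square")
    hi = np.maximum(c, c.T)
    lo = np.minimum(c, c.T)
    row, col = np.indices(c.shape)
    out = np.where(row < col, hi, np.where(row > col, lo, c))
    return np.sign(M) * out


def median_iqr_stack(matrices: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise median and inter-quartile range over a stack of matrices.

    Quartiles use linear interpolation of the order statistics.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices")
    stack = np.stack(matrices)
    if any(m.shape != matrices[0].shape for m in matrices):
        raise ValueError("shape mismatch in matrix stack")
    med = np.median(stack, axis=0)
    q1, q3 = np.percentile(stack, [25, 75], axis=0, method="linear")
    return med, q3 - q1


# ---------------------------------------------------------------------------
# phases and synchronization
# ---------------------------------------------------------------------------

def linear_phase(spike_times: np.ndarray, t: float) -> float:
    """Linearly interpolated phase 2 pi (t - t_m)/(t_{m+1} - t_m).

    Defined for t in [t_m, t_{m+1}); returns NaN when t is not bracketed by
    two spikes of the neuron.
    """
    spikes = np.asarray(spike_times, float)
    idx = np.searchsorted(spikes, t, side="right") - 1
    if idx < 0 or idx >= spikes.size - 1:
        return float("nan")
    return 2.0 * np.pi * (t - spikes[idx]) / (spikes[idx + 1] - spikes[idx])


def phase_series(spike_times: np.ndarray, t) -> np.ndarray:
    """Vectorized :func:`linear_phase` over query times ``t``."""
    spikes = np.asarray(spike_times, float)
    t = np.asarray(t, float)
    out = np.full(t.shape, np.nan)
    if spikes.size < 2:
        return out
    idx = np.searchsorted(spikes, t, side="right") - 1
    ok = (idx >= 0) & (idx < spikes.size - 1)
    i = idx[ok]
    out[ok] = 2.0 * np.pi * (t[ok] - spikes[i]) / (spikes[i + 1] - spikes[i])
    return out


def order_parameter(phases) -> tuple[float, float]:
    """Kuramoto order parameter (R, Phi) of a phase collection.

    NaN (undefined) phases are excluded with renormalization; with zero
    defined phases both outputs are NaN.
    """
    ph = np.asarray(phases, float)
    ph = ph[np.isfinite(ph)]
    if ph.size == 0:
        return float("nan"), float("nan")
    z = np.exp(1j * ph).mean()
    return float(np.abs(z)), float(np.angle(z))


def order_parameter_series(
    raster: Sequence[np.ndarray],
    t_grid: np.ndarray,
    members: Optional[Sequence[int]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(R(t), Phi(t)) over a time grid from a spike raster.

    ``members``: optional 1-based neuron indices restricting the population
    (subpopulation order parameter); default is the whole network.
    """
    t_grid = np.asarray(t_grid, float)
    rows = raster if members is None else [raster[j - 1] for j in members]
    z = np.zeros(t_grid.shape, complex)
    count = np.zeros(t_grid.shape, int)
    for spikes in rows:
        ph = phase_series(spikes, t_grid)
        ok = np.isfinite(ph)
        z[ok] += np.exp(1j * ph[ok])
        count += ok
    with np.errstate(invalid="ignore"):
        zm = np.where(count > 0, z / np.maximum(count, 1), np.nan + 0j)
    return np.abs(zm), np.angle(zm)


def r_av(R: np.ndarray, times_ms: np.ndarray, t_ms: float, window_ms: float = 5000.0) -> float:
    """Mean of the order-parameter samples over the window (t - 5 s, t].

    Samples where R is undefined (NaN) are excluded.  Raises when the
    series does not cover the full window.
    """
    R = np.asarray(R, float)
    times_ms = np.asarray(times_ms, float)
    if times_ms.size == 0 or times_ms[0] > t_ms - window_ms + 1e-9:
        raise ValueError("insufficient history for the averaging window")
    mask = (times_ms > t_ms - window_ms) & (times_ms <= t_ms + 1e-9)
    return float(np.nanmean(R[mask]))


def acute_effects(r_pre: float, r_on: float, r_off: float) -> tuple[float, float]:
    """Acute stimulation effect and after-effect of a subpopulation.

    stim_effect = 1 - R_on/R_pre; after_effect = 1 - R_off/R_pre.
    Positive values indicate desynchronization, negative values a
    synchronizing effect.
    """
    if r_pre == 0:
        raise ValueError("pre-stimulation order parameter must be positive")
    return 1.0 - r_on / r_pre, 1.0 - r_off / r_pre


# ---------------------------------------------------------------------------
# subpopulations and stimulus-locked dynamics
# ---------------------------------------------------------------------------

def subpopulation_map(net: NetworkParams) -> dict[int, np.ndarray]:
    """1-based member indices of each stimulation-site subpopulation.

    Each subpopulation holds the N/Ns - 1 neurons nearest its site; the
    boundary neuron equidistant to two sites is excluded (for the default
    geometry: neurons 50, 100, 150, 200).
    """
    half = net.N // (2 * net.Ns)
    out = {}
    for k, site in enumerate(net.site_indices, start=1):
        rel = np.arange(-(half - 1), half)
        out[k] = ((site - 1 + rel) % net.N) + 1
    return out


def boundary_neurons(net: NetworkParams) -> np.ndarray:
    """1-based indices of the excluded neurons equidistant to two sites."""
    half = net.N // (2 * net.Ns)
    return np.array([((s - 1 + half) % net.N) + 1 for s in net.site_indices])


@dataclass
class CrossTrialDistribution:
    """Stimulus-locked phase samples of one subpopulation.

    ``phases[n, l]`` is the subpopulation mean phase at onset n and lag
    ``lags_ms[l]``, in [0, 2 pi); NaN where undefined.  ``L`` is the number
    of onsets retained after window clipping.
    """

    site: int
    lags_ms: np.ndarray
    phases: np.ndarray
    rank_filter: Optional[int] = None

    @property
    def L(self) -> int:
        return self.phases.shape[0]


def cross_trial(
    raster: Sequence[np.ndarray],
    members: Sequence[int],
    schedule: OnsetSchedule,
    site: int,
    rank_filter: Optional[int] = None,
    window_ms: float = 32.0,
    dt_ms: float = 1.0,
    t_record: Optional[tuple[float, float]] = None,
) -> CrossTrialDistribution:
    """Collect the subpopulation mean phase around every stimulation onset.

    ``site`` is 1-based; ``rank_filter`` (1..3) restricts to onsets at one
    position within the 3-ON blocks.  Onsets whose +-window exceeds
    ``t_record`` are skipped (reducing L).
    """
    k = site - 1
    onsets = schedule.times[k]
    if rank_filter is not None:
        onsets = onsets[schedule.ranks[k] == rank_filter]
    if t_record is not None:
        lo, hi = t_record
        onsets = onsets[(onsets - window_ms >= lo) & (onsets + window_ms <= hi)]
    lags = np.arange(-window_ms, window_ms + dt_ms / 2, dt_ms)
    query = onsets[:, None] + lags[None, :]
    _, Phi = order_parameter_series(raster, query.ravel(), members=members)
    phases = np.mod(Phi.reshape(query.shape), 2.0 * np.pi)
    # keep NaN as NaN (mod propagates it)
    return CrossTrialDistribution(
        site=site, lags_ms=lags, phases=phases, rank_filter=rank_filter
    )


def resetting_index(dist: CrossTrialDistribution) -> np.ndarray:
    """E_k(dt) = |L^-1 sum_n exp(i Phi_k(t_k^n + dt))| per lag, in [0, 1].

    Onsets with undefined phase at a lag are excluded with renormalization.
    """
    if dist.L < 1:
        raise ValueError("cross-trial distribution holds no onsets")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        z = np.nanmean(np.exp(1j * dist.phases), axis=0)
    return np.abs(z)


# ---------------------------------------------------------------------------
# statistics and rasters
# ---------------------------------------------------------------------------

@dataclass
class RankSumResult:
    p_value: float
    significant: bool
    side: str
    alpha: float
    median_a: float
    median_b: float
    tie_warning: bool = False


def rank_sum_compare(A, B, side: str = "less", alpha: float = 0.05) -> RankSumResult:
    """One-sided Wilcoxon rank-sum (Mann-Whitney) comparison of two samples.

    ``side="less"`` tests whether A's distribution is shifted below B's
    (the study's left-sided test for decreases).  Uses the exact null
    distribution when there are no ties.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.size < 1 or B.size < 1:
        raise ValueError("both samples must be non-empty")
    if side not in ("less", "greater"):
        raise ValueError("side must be 'less' or 'greater'")
    pooled = np.concatenate([A, B])
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations tied; rank-sum test degenerate", stacklevel=2)
        return RankSumResult(1.0, False, side, alpha, float(np.median(A)),
                             float(np.median(B)), tie_warning=True)
    method = "exact" if np.unique(pooled).size == pooled.size else "auto"
    res = sps.mannwhitneyu(A, B, alternative=side, method=method)
    p = float(res.pvalue)
    return RankSumResult(p, p < alpha, side, alpha,
                         float(np.median(A)), float(np.median(B)))


def spike_counts(
    raster: Sequence[np.ndarray], window: tuple[float, float], bin_ms: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin spike counts across all neurons within a time window.

    Returns (bin_edges, counts); counts[i] is the number of spikes (over
    the whole network) in [edges[i], edges[i+1]).
    """
    lo, hi = window
    edges = np.arange(lo, hi + bin_ms / 2, bin_ms)
    all_spikes = (
        np.concatenate([np.asarray(r) for r in raster if len(r)])
        if any(len(r) for r in raster)
        else np.empty(0)
    )
    counts, _ = np.histogram(all_spikes, bins=edges)
    return edges, counts
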