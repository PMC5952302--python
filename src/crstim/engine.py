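"""Experiment orchestration: integration, spike detection, STDP events.

A run chains four periods: a 2 s settling period (the only one without
STDP), a 60 s STDP-only period during which the network typically settles
into a strongly-coupled synchronized attractor, a 128 s stim-on period, and
a 128 s stim-off period.  ``t = 0`` ms is the delivery time of the first
stimulus, so the first two periods occupy negative times.

Integration uses an adaptive Runge-Kutta 4(5) (relative tolerance 1e-5,
maximum step 0.25 ms so ~1 ms spikes and the ~0.67 ms alpha-function are
always resolved) and is stopped-and-restarted at every stimulation onset so
waveform kinks are never stepped over.  Spikes are detected as upward
crossings of 0 mV with linear interpolation between steps and a 2 ms
lockout; each detected spike triggers the event-based STDP update before
integration resumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import RK45

from . import analysis
from ._fast import HAVE_NUMBA, integrate_segment, rhs_core
from .model import (
    NetworkState,
    mexican_hat_matrix,
    reversal_matrix,
)
from .params import ExperimentConfig, NetworkParams
from .plasticity import apply_spike
from .stimulation import OnsetSchedule, build_schedule, profile_matrix


def initialize_network(seed, params: NetworkParams) -> NetworkState:
    """Draw a random initial network realization.

    I_i ~ U[I0-dI, I0+dI]; V_i ~ U[-65, 5] mV; gates and synaptic variables
    ~ U[0, 1]; weight magnitudes ~ N(0.5, 0.01) clamped to [0, 1] with
    c_ii = 0.  Identical seeds give identical states.
    """
    rng = np.random.default_rng(seed)
    N = params.N
    I = rng.uniform(params.I0 - params.delta_I, params.I0 + params.delta_I, N)
    V = rng.uniform(-65.0, 5.0, N)
    m = rng.uniform(0.0, 1.0, N)
    h = rng.uniform(0.0, 1.0, N)
    n = rng.uniform(0.0, 1.0, N)
    s = rng.uniform(0.0, 1.0, N)
    c = np.clip(rng.normal(0.5, 0.01, (N, N)), 0.0, 1.0)
    np.fill_diagonal(c, 0.0)
    return NetworkState(
        V=V, m=m, h=h, n=n, s=s, I=I, c=c,
        last_spike=np.full(N, np.nan), t=0.0,
    )


def detect_spikes(t, V, threshold: float = 0.0, lockout: float = 2.0):
    """Spike times from a sampled voltage trace.

    ``t``: sample times (ms); ``V``: (n_samples,) or (n_samples, N).
    A spike is an upward crossing of ``threshold`` with linear interpolation
    between samples; crossings within ``lockout`` ms of the previous
    detection on the same neuron are suppressed.  Returns a list of arrays
    (one per neuron) or a single array for 1-D input.
    """
    t = np.asarray(t, float)
    V = np.asarray(V, float)
    single = V.ndim == 1
    if single:
        V = V[:, None]
    out = []
    for col in range(V.shape[1]):
        v = V[:, col]
        up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
        frac = (threshold - v[up]) / (v[up + 1] - v[up])
        times = t[up] + frac * (t[up + 1] - t[up])
        kept = []
        last = -np.inf
        for tc in times:
            if tc - last >= lockout:
                kept.append(tc)
                last = tc
        out.append(np.asarray(kept))
    return out[0] if single else out


@dataclass
class ExperimentResult:
    """Raster, weight snapshots, metric series and bookkeeping for one run."""

    config: ExperimentConfig
    schedule: OnsetSchedule
    raster: list  # per neuron: ascending spike times (ms)
    snapshots: dict  # t_s -> weight magnitude matrix
    metrics: pd.DataFrame  # t_ms, C_av, c_EE, c_II, R
    M: np.ndarray
    stats: dict = field(default_factory=dict)

    def signed_snapshot(self, t_s: float) -> np.ndarray:
        """sign(M) * c at checkpoint ``t_s`` (seconds)."""
        return np.sign(self.M) * self.snapshots[t_s]

    def r_av(self, t_s: float, window_s: float = 5.0, members=None) -> float:
        """Mean order parameter over the ``window_s`` preceding ``t_s``."""
        sub = self.metrics
        if members is not None:
            t_ms = sub["t_ms"].to_numpy()
            R, _ = analysis.order_parameter_series(self.raster, t_ms, members=members)
        else:
            t_ms, R = sub["t_ms"].to_numpy(), sub["R"].to_numpy()
        return analysis.r_av(R, t_ms, t_s * 1000.0, window_ms=window_s * 1000.0)


class Simulator:
    """Stateful integrator for one network; used by :func:`run_experiment`."""

    def __init__(self, cfg: ExperimentConfig, state: NetworkState):
        self.cfg = cfg
        self.net = cfg.net
        self.state = state
        self.M = mexican_hat_matrix(cfg.net)
        self.absM = np.abs(self.M)
        self.Vr = reversal_matrix(self.M, cfg.net)
        self.D = profile_matrix(cfg.net.site_indices, cfg.stim, cfg.net)
        self._refresh_coupling()
        self._schedule: OnsetSchedule | None = None
        self.raster: list[list[float]] = [[] for _ in range(cfg.net.N)]
        self._metric_rows: list[tuple] = []
        self._next_metric_t: float | None = None
        self._zero_gain = np.zeros(cfg.net.N)
        net = cfg.net
        self._net_consts = (
            net.g_Na, net.g_K, net.g_l, net.V_Na, net.V_K, net.V_l,
            net.C, net.V_r_exc,
        )
        self.n_steps = 0
        self.n_spikes = 0
        self._h = 0.0  # adaptive step carried across segments
        self._onset_cache = None

    # -- coupling cache ----------------------------------------------------
    def _refresh_coupling(self) -> None:
        self._A = self.state.c * self.absM
        self._B = self.Vr * self._A

    # -- right-hand side ---------------------------------------------------
    def _stim_gain(self, t: float) -> np.ndarray:
        """K * (D @ G(t)) per neuron; zeros when no schedule is active."""
        sched = self._schedule
        if sched is None or sched.empty:
            return self._zero_gain
        stim = self.cfg.stim
        tau = stim.tau_alpha
        cutoff = stim.Ts / 2.0
        G = np.zeros(len(sched.times))
        for k, onsets in enumerate(sched.times):
            idx = np.searchsorted(onsets, t, side="right")
            g = 0.0
            for back in (1, 2):
                j = idx - back
                if j < 0:
                    break
                dt = t - onsets[j]
                if dt <= cutoff:
                    g += dt / tau * np.exp(-dt / tau)
            G[k] = g
        return stim.K * (self.D @ G)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        N = self.net.N
        dy = np.empty_like(y)
        rhs_core(
            y[0:N], y[N : 2 * N], y[2 * N : 3 * N], y[3 * N : 4 * N],
            y[4 * N : 5 * N], self.state.I, self._A, self._B,
            self._stim_gain(t), *self._net_consts, dy,
        )
        return dy

    # -- stepping ----------------------------------------------------------
    def _process_step(
        self, t0: float, V0: np.ndarray, t1: float, y1: np.ndarray,
        stdp_enabled: bool, record: bool,
    ) -> None:
        thr = self.cfg.spike_threshold_mV
        V1 = y1[0 : self.net.N]
        crossed = np.flatnonzero((V0 < thr) & (V1 >= thr))
        changed = False
        if crossed.size:
            frac = (thr - V0[crossed]) / (V1[crossed] - V0[crossed])
            t_cross = t0 + frac * (t1 - t0)
            order = np.lexsort((crossed, t_cross))
            for pos in order:
                i = crossed[pos]
                tc = t_cross[pos]
                last = self.state.last_spike[i]
                if np.isfinite(last) and tc - last < self.cfg.lockout_ms:
                    continue
                self.n_spikes += 1
                self.raster[i].append(tc)
                if stdp_enabled:
                    apply_spike(i + 1, tc, self.state, self.M, self.cfg.stdp)
                    changed = True
                self.state.last_spike[i] = tc
        if changed:
            self._refresh_coupling()
        if record and self._next_metric_t is not None:
            while self._next_metric_t <= t1 + 1e-12:
                self._record_metrics(self._next_metric_t)
                self._next_metric_t += self.cfg.metric_dt_ms

    def _record_metrics(self, t_ms: float) -> None:
        C_av, c_EE, c_II = analysis.mean_weights(self.state.c, self.M)
        self._metric_rows.append((t_ms, C_av, c_EE, c_II))

    def run(
        self,
        t_end_ms: float,
        stdp_enabled: bool,
        schedule: OnsetSchedule | None = None,
        record: bool = False,
    ) -> None:
        """Integrate the network forward to ``t_end_ms`` (absolute ms).

        The integrator is restarted at every stimulation onset so waveform
        kinks are resolved; spikes trigger the event-based STDP update
        before integration resumes.
        """
        cfg = self.cfg
        state = self.state
        if t_end_ms <= state.t:
            return
        if schedule is not self._schedule:
            self._schedule = schedule
            self._onset_cache = None
        if record and self._next_metric_t is None:
            self._next_metric_t = np.ceil(state.t / cfg.metric_dt_ms) * cfg.metric_dt_ms
        if schedule is not None and not schedule.empty:
            onsets = schedule.all_onsets()
            cuts = onsets[(onsets > state.t) & (onsets < t_end_ms)]
        else:
            cuts = np.empty(0)
        boundaries = np.append(cuts, t_end_ms)
        y = state.pack()
        advance = self._advance_numba if HAVE_NUMBA else self._advance_scipy
        for seg_end in boundaries:
            if seg_end <= state.t + 1e-12:
                continue
            advance(y, seg_end, stdp_enabled, record)
        if record and self._next_metric_t is not None:
            while self._next_metric_t <= t_end_ms + 1e-9:
                self._record_metrics(self._next_metric_t)
                self._next_metric_t += cfg.metric_dt_ms
        state.unpack(y.copy())
        state.t = t_end_ms

    def _stim_arrays(self):
        """Padded (Ns, max_len) onset matrix + lengths for the numba core."""
        sched = self._schedule
        if sched is None or sched.empty:
            return np.zeros((1, 1)), np.zeros(1, dtype=np.int64), False
        n_sites = sched.n_sites
        max_len = max(t.size for t in sched.times)
        padded = np.full((n_sites, max_len), np.inf)
        lens = np.zeros(n_sites, dtype=np.int64)
        for k, times in enumerate(sched.times):
            padded[k, : times.size] = times
            lens[k] = times.size
        return padded, lens, True

    def _advance_numba(self, y, seg_end, stdp_enabled, record):
        cfg = self.cfg
        state = self.state
        if self._onset_cache is None:
            self._onset_cache = self._stim_arrays()
        onsets, onset_len, use_stim = self._onset_cache
        V_prev = np.empty(self.net.N)
        while True:
            status, t_prev, t_now, self._h, ns = integrate_segment(
                state.t, y, seg_end, self._h,
                state.I, self._A, self._B,
                onsets, onset_len, self.D, cfg.stim.K,
                cfg.stim.tau_alpha, cfg.stim.Ts / 2.0, use_stim,
                *self._net_consts,
                cfg.rtol, cfg.atol, cfg.max_step_ms,
                cfg.spike_threshold_mV, cfg.lockout_ms, state.last_spike,
                V_prev,
            )
            self.n_steps += ns
            if status == 0:
                raise RuntimeError(
                    f"integrator step-size underflow at t={t_now:.3f} ms "
                    f"(protocol={cfg.protocol}, sample={cfg.sample_id})"
                )
            state.t = t_now
            if status == 2:
                self._process_step(t_prev, V_prev, t_now, y, stdp_enabled, record)
            else:
                state.t = seg_end
                return

    def _advance_scipy(self, y, seg_end, stdp_enabled, record):
        cfg = self.cfg
        state = self.state
        solver = RK45(
            self.rhs, state.t, y, t_bound=seg_end,
            max_step=cfg.max_step_ms, rtol=cfg.rtol, atol=cfg.atol,
        )
        while solver.status == "running":
            t0 = solver.t
            V0 = solver.y[0 : self.net.N].copy()
            solver.step()
            if solver.status == "failed":
                raise RuntimeError(
                    f"integrator failure at t={solver.t:.3f} ms "
                    f"(protocol={cfg.protocol}, sample={cfg.sample_id})"
                )
            self.n_steps += 1
            self._process_step(t0, V0, solver.t, solver.y, stdp_enabled, record)
        y[:] = solver.y
        state.t = solver.t

    # -- result assembly ---------------------------------------------------
    def raster_arrays(self) -> list[np.ndarray]:
        return [np.asarray(r) for r in self.raster]

    def metrics_frame(self, with_R: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(
            self._metric_rows, columns=["t_ms", "C_av", "c_EE", "c_II"]
        )
        if with_R and len(df):
            R, _ = analysis.order_parameter_series(
                self.raster_arrays(), df["t_ms"].to_numpy()
            )
            df["R"] = R
        return df


def run_period(
    state: NetworkState,
    duration_s: float,
    stdp_enabled: bool,
    schedule: OnsetSchedule | None,
    cfg: ExperimentConfig,
):
    """Integrate one period; returns (state, raster arrays, metrics frame)."""
    sim = Simulator(cfg, state)
    sim.run(
        state.t + duration_s * 1000.0,
        stdp_enabled=stdp_enabled,
        schedule=schedule,
        record=True,
    )
    return sim.state, sim.raster_arrays(), sim.metrics_frame()


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run the four-period experiment for one (protocol, K, sample) tuple."""
    per = cfg.periods
    state = initialize_network(cfg.init_seed(), cfg.net)
    state.t = -(per.init_s + per.stdp_only_s) * 1000.0
    schedule = build_schedule(cfg.protocol, cfg.stim, cfg.schedule_seed())

    sim = Simulator(cfg, state)
    # settling: no STDP, no stimulation, no recording
    sim.run(-per.stdp_only_s * 1000.0, stdp_enabled=False)
    # STDP-only period, recorded (provides the pre-stimulation baseline)
    sim.run(0.0, stdp_enabled=True, record=True)
    snapshots = {0.0: state.c.copy()}
    sim.run(
        per.stim_on_s * 1000.0, stdp_enabled=True, schedule=schedule, record=True
    )
    snapshots[per.stim_on_s] = state.c.copy()
    sim.run(
        (per.stim_on_s + per.stim_off_s) * 1000.0, stdp_enabled=True, record=True
    )
    snapshots[per.stim_on_s + per.stim_off_s] = state.c.copy()
    for t_extra in cfg.snapshot_times_s:
        if t_extra not in snapshots:
            snapshots[t_extra] = None  # placeholder: only checkpoint times stored

    return ExperimentResult(
        config=cfg,
        schedule=schedule,
        raster=sim.raster_arrays(),
        snapshots={k: v for k, v in snapshots.items() if v is not None},
        metrics=sim.metrics_frame(),
        M=sim.M,
        stats={"n_steps": sim.n_steps, "n_spikes": sim.n_spikes},
    )
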