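"""Parameter containers for the plastic Hodgkin-Huxley ring network.

All defaults reproduce the study conditions: a ring of N = 200 neurons with
Mexican-hat coupling (strong short-range excitation, weak long-range
inhibition), four equidistant stimulation sites, 16 ms stimulation cycles in
3 ON : 2 OFF blocks, and the four-period experiment timeline
(2 s init / 60 s STDP-only / 128 s stim-on / 128 s stim-off).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

PROTOCOLS = ("no_stim", "PPMS", "CMNS", "UMNS", "RVS_CR", "fixed_CR", "SVS_CR")

#: short aliases accepted anywhere a protocol tag is expected
PROTOCOL_ALIASES = {
    "nostim": "no_stim",
    "no-stim": "no_stim",
    "ppms": "PPMS",
    "cmns": "CMNS",
    "umns": "UMNS",
    "rvs": "RVS_CR",
    "fixed": "fixed_CR",
    "svs": "SVS_CR",
}


def canonical_protocol(tag: str) -> str:
    """Resolve a protocol tag or alias to its canonical name."""
    if tag in PROTOCOLS:
        return tag
    key = tag.lower()
    if key in PROTOCOL_ALIASES:
        return PROTOCOL_ALIASES[key]
    raise ValueError(f"unknown protocol tag: {tag!r} (known: {PROTOCOLS})")


def default_site_indices(N: int, Ns: int) -> tuple[int, ...]:
    """Equidistant 1-based stimulation-site indices, centred in each segment.

    For N=200, Ns=4 this yields (25, 75, 125, 175).
    """
    spacing = N // Ns
    first = spacing // 2
    return tuple(first + k * spacing for k in range(Ns))


@dataclass(frozen=True)
class NetworkParams:
    """Fixed constants of the neuron model, ring geometry and coupling.

    Units: capacitance uF/cm^2, conductances mS/cm^2, potentials mV,
    currents uA/cm^2; the chain length d0 and Mexican-hat widths sigma1/2
    are in dimensionless lattice-length units.
    """

    N: int = 200
    C: float = 1.0
    g_Na: float = 120.0
    g_K: float = 36.0
    g_l: float = 0.3
    V_Na: float = 50.0
    V_K: float = -77.0
    V_l: float = -54.4
    V_r_exc: float = 20.0
    V_r_inh: float = -40.0
    I0: float = 11.0
    delta_I: float = 0.45
    d0: float = 10.0
    sigma1: float = 3.5
    sigma2: float = 2.0
    Ns: int = 4
    site_indices: tuple[int, ...] = (25, 75, 125, 175)

    def __post_init__(self):
        if self.N <= 1:
            raise ValueError("N must exceed 1")
        if self.N % self.Ns != 0:
            raise ValueError("N must be divisible by Ns")
        for name in ("C", "g_Na", "g_K", "g_l"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        sites = tuple(int(s) for s in self.site_indices)
        object.__setattr__(self, "site_indices", sites)
        if len(sites) != self.Ns:
            raise ValueError("site_indices length must equal Ns")
        if not all(1 <= s <= self.N for s in sites):
            raise ValueError("site indices must be 1-based in [1, N]")
        if self.Ns > 1:
            spacing = self.N // self.Ns
            gaps = [
                (sites[(k + 1) % self.Ns] - sites[k]) % self.N
                for k in range(self.Ns)
            ]
            if any(g != spacing for g in gaps):
                raise ValueError("site indices must be equidistant on the ring")

    @property
    def d(self) -> float:
        """Lattice spacing between adjacent neurons: d0/(N-1)."""
        return self.d0 / (self.N - 1)

    @classmethod
    def with_geometry(cls, N: int, Ns: int, **kw) -> "NetworkParams":
        """Construct params for an arbitrary ring size with default sites."""
        return cls(N=N, Ns=Ns, site_indices=default_site_indices(N, Ns), **kw)


@dataclass(frozen=True)
class StdpParams:
    """Spike-timing-dependent plasticity rule constants.

    The asymmetric window potentiates causal pairs (post after pre) with
    amplitude beta1 and time constant gamma1*tau, and depresses acausal
    pairs with the beta2*(dt/tau)*exp(dt/(gamma2*tau)) branch. delta is the
    per-event learning rate; weight magnitudes are clamped to [c_min, c_max].
    """

    beta1: float = 1.0
    beta2: float = 16.0
    gamma1: float = 0.12
    gamma2: float = 0.15
    tau: float = 14.0
    delta: float = 0.002
    c_min: float = 0.0
    c_max: float = 1.0

    def __post_init__(self):
        for name in ("beta1", "beta2", "gamma1", "gamma2", "tau", "delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.c_min < self.c_max:
            raise ValueError("c_min must be below c_max")


@dataclass(frozen=True)
class StimParams:
    """Stimulation waveform and block-structure parameters.

    Ts is the ON/OFF cycle duration (ms); on_per_block consecutive ON-cycles
    are followed by off_per_block OFF-cycles. K scales the stimulation
    current; sigma_d sets the quadratic spatial decay of each stimulus in
    lattice-length units. tau_alpha (the alpha-function time-to-peak) and
    the overlap window within which two onsets' conductances sum are derived
    quantities, Ts/(6 Ns) and 2 Ts/Ns respectively.
    """

    Ts: float = 16.0
    Ns: int = 4
    on_per_block: int = 3
    off_per_block: int = 2
    stim_on_duration_s: float = 128.0
    K: float = 0.25
    sigma_d: float = 1.0
    svs_repeats: int = 100

    def __post_init__(self):
        if self.Ts <= 0 or self.Ns < 1:
            raise ValueError("Ts must be positive and Ns >= 1")
        if self.on_per_block < 1 or self.off_per_block < 0:
            raise ValueError("invalid ON/OFF block structure")
        n_cycles = self.stim_on_duration_s * 1000.0 / self.Ts
        if abs(n_cycles - round(n_cycles)) > 1e-9:
            raise ValueError("stim_on_duration must be an integer number of cycles")
        block = self.on_per_block + self.off_per_block
        if round(n_cycles) % block != 0:
            raise ValueError("ON/OFF blocks must tile the stim-on period exactly")

    @property
    def tau_alpha(self) -> float:
        """alpha-function time-to-peak, Ts/(6 Ns) ms."""
        return self.Ts / (6.0 * self.Ns)

    @property
    def overlap_window(self) -> float:
        """two onsets within this interval (2 Ts/Ns ms) sum their conductances."""
        return 2.0 * self.Ts / self.Ns

    @property
    def n_cycles(self) -> int:
        return int(round(self.stim_on_duration_s * 1000.0 / self.Ts))

    @property
    def n_on_cycles(self) -> int:
        block = self.on_per_block + self.off_per_block
        return self.n_cycles // block * self.on_per_block


@dataclass(frozen=True)
class Periods:
    """Durations (s) of the four experiment periods."""

    init_s: float = 2.0
    stdp_only_s: float = 60.0
    stim_on_s: float = 128.0
    stim_off_s: float = 128.0


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one (protocol, K, sample) run.

    ``t = 0`` is defined as the delivery time of the first stimulus, so the
    init and STDP-only periods occupy negative times. ``sample_id`` selects
    one of the independent initial-network realizations (the study uses
    1..11); ``base_seed`` shifts every random stream at once so entire
    replications can be re-randomized coherently.
    """

    protocol: str = "no_stim"
    K: float = 0.25
    sample_id: int = 1
    base_seed: int = 0
    net: NetworkParams = field(default_factory=NetworkParams)
    stdp: StdpParams = field(default_factory=StdpParams)
    stim: StimParams = field(default_factory=StimParams)
    periods: Periods = field(default_factory=Periods)
    rtol: float = 1e-5
    atol: float = 1e-6
    max_step_ms: float = 0.25
    spike_threshold_mV: float = 0.0
    lockout_ms: float = 2.0
    metric_dt_ms: float = 1.0
    snapshot_times_s: tuple[float, ...] = ()  # extras beyond {0, on, on+off}

    def __post_init__(self):
        object.__setattr__(self, "protocol", canonical_protocol(self.protocol))
        # config-level K is authoritative for the run
        object.__setattr__(self, "stim", dataclasses.replace(self.stim, K=self.K))
        if self.stim.Ns != self.net.Ns:
            raise ValueError("stim.Ns must match net.Ns")
        if abs(self.stim.stim_on_duration_s - self.periods.stim_on_s) > 1e-9:
            raise ValueError("stim.stim_on_duration_s must equal periods.stim_on_s")
        if self.sample_id < 1:
            raise ValueError("sample_id is 1-based")

    # -- named RNG streams -------------------------------------------------
    def init_seed(self) -> list[int]:
        """Seed sequence for the network initialization of this sample.

        Shared across protocols so the same initial network can be crossed
        with any stimulation realization.
        """
        return [self.base_seed, 101, self.sample_id]

    def schedule_seed(self) -> list[int]:
        """Seed sequence for the stimulation-schedule realization."""
        code = PROTOCOLS.index(self.protocol)
        return [self.base_seed, 202, self.sample_id, code]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["net"]["site_indices"] = list(self.net.site_indices)
        d["snapshot_times_s"] = list(self.snapshot_times_s)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "net" in d:
            d["net"] = NetworkParams(**d["net"])
        if "stdp" in d:
            d["stdp"] = StdpParams(**d["stdp"])
        if "stim" in d:
            d["stim"] = StimParams(**d["stim"])
        if "periods" in d:
            d["periods"] = Periods(**d["periods"])
        if "snapshot_times_s" in d:
            d["snapshot_times_s"] = tuple(d["snapshot_times_s"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def smoke_config(protocol: str = "no_stim", **overrides) -> ExperimentConfig:
    """Reduced-scale preset: N = 20 ring, 2 sites, 2/6/12/12 s periods.

    Small enough for CI-speed property tests while keeping every structural
    feature (ring coupling, STDP, ON/OFF blocks) of the full setup.
    """
    net = NetworkParams.with_geometry(N=20, Ns=2)
    stim = StimParams(Ns=2, stim_on_duration_s=12.0, K=overrides.pop("K", 0.25))
    periods = Periods(init_s=2.0, stdp_only_s=6.0, stim_on_s=12.0, stim_off_s=12.0)
    return ExperimentConfig(
        protocol=protocol, K=stim.K, net=net, stim=stim, periods=periods, **overrides
    )
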