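# Methods

`crstim` is a computational testbed for multichannel desynchronizing
stimulation of a plastic spiking network. It simulates a one-dimensional
ring of Hodgkin–Huxley neurons whose synapses change by spike-timing-
dependent plasticity (STDP), drives the network with seven stimulation
conditions — including three coordinated-reset (CR) variants and a
correlated-noise sham candidate — and measures acute and long-lasting
effects on connectivity and synchrony.

## Network model

Each of the N neurons follows the classical Hodgkin–Huxley membrane
equations with an injected constant current I_i drawn uniformly from
[I₀ − ΔI, I₀ + ΔI] (defaults 11.0 ± 0.45 µA/cm²), a network coupling
current S_i and a stimulation current F_i:

    C V̇_i = I_i − g_Na m_i³ h_i (V_i − V_Na) − g_K n_i⁴ (V_i − V_K)
             − g_l (V_i − V_l) + S_i + F_i
    ẋ_i   = α_x(V_i)(1 − x_i) − β_x(V_i) x_i          x ∈ {m, h, n}
    ṡ_i   = 0.5 (1 − s_i) / (1 + exp[−(V_i + 5)/12]) − 2 s_i

with the standard HH rate functions; the removable 0/0 singularities of
α_m (V = −40 mV) and α_n (V = −55 mV) are replaced by their analytic
limits inside a 10⁻⁷-wide window. At I ≈ 11 µA/cm² an uncoupled neuron
fires tonically with a ≈ 14 ms intrinsic period (measured 14.14 ms by the
test suite and the acceptance script).

Neurons sit on a ring of physical length d₀ = 10 (lattice spacing
d = d₀/(N−1)). The connection template is a Mexican hat of the shortest
ring distance d_ij,

    M_ij = (1 − d_ij²/σ₁²) exp(−d_ij²/(2σ₂²)),   σ₁ = 3.5, σ₂ = 2.0,

so short-range connections are excitatory (M > 0, reversal +20 mV) and
long-range ones inhibitory (M < 0, reversal −40 mV). The coupling current
is the weighted ensemble average

    S_i = N⁻¹ Σ_j (V_r,j − V_i) c_ij |M_ij| s_j .

The dynamic weight matrix c stores nonnegative magnitudes in [0, 1]; the
synapse *type* is carried solely by sign(M_ij). Self-connections are fixed
at c_ii = 0 and excluded from plasticity: a self-synapse is dynamically
spurious here, and only the product c·|M|·s·(V_r − V) enters the dynamics.
All averaging denominators still follow the printed formulas.

## Plasticity

Weights update event-wise at every detected spike with the asymmetric
window

    Δc(dt) = β₁ e^(−dt/(γ₁τ))                 dt ≥ 0
    Δc(dt) = β₂ (dt/τ) e^(dt/(γ₂τ))           dt < 0

(β₁ = 1, β₂ = 16, γ₁ = 0.12, γ₂ = 0.15, τ = 14 ms), scaled by the learning
rate δ = 0.002, added to excitatory weights and subtracted from inhibitory
ones, and hard-clamped to [0, 1]. Pairing is nearest-spike: a new spike of
neuron i pairs with each partner's most recent spike only — the standard
event-based reading of "update at every spike", and the only one that
needs a single stored time per neuron. Simultaneous spikes within one
integrator step are processed in ascending neuron index; dt = 0 takes the
causal (potentiation) branch, as the window is written. With these
parameters the network is multistable: a strongly-coupled synchronized
attractor coexists with weakly-coupled desynchronized states, which is
what makes long-lasting "anti-kindling" possible.

The printed weight-matrix initialization mixes units (µA/cm² mean,
mS/cm² bounds); weights are treated here as dimensionless magnitudes in
[0, 1] scaling the conductance product, which is the only combination the
dynamics sees.

## Stimulation

N_s = 4 equidistant sites (neurons 25/75/125/175 at N = 200) are each
activated exactly once per 16 ms ON-cycle; three ON-cycles alternate with
two OFF-cycles for 128 s, i.e. 8,000 cycles, 4,800 of them ON. The
protocols differ only in how the within-cycle onset times are drawn:

| protocol | onsets within ON-cycle | across sites |
|---|---|---|
| PPMS | one random offset, frozen for the whole period | simultaneous |
| CMNS | fresh uniform offset every ON-cycle | simultaneous |
| UMNS | fresh uniform offset every ON-cycle | independent per site |
| RVS CR | slots 0/4/8/12 ms, fresh site permutation per cycle | sequential |
| fixed CR | slots 0/4/8/12 ms, one permutation throughout | sequential |
| SVS CR | slots 0/4/8/12 ms, permutation redrawn every 100 cycles | sequential |

Uniform draws sample the half-open cycle [0, T_s); an onset exactly at a
cycle end belongs to the next cycle.

Each onset evokes an α-function conductance (Δt/τ_α) e^(−Δt/τ_α) with
τ_α = T_s/(6 N_s) ≈ 0.67 ms, truncated T_s/2 = 8 ms after the onset (where
it has decayed to 0.02 % of its peak); two onsets closer than 2 T_s/N_s
sum their conductances. The current injected into neuron i is

    F_i = (V_r − V_i) · K · Σ_k D(i, x_k) G_k(t),
    D(i, x_k) = 1 / (1 + d² dist(i, x_k)²/σ_d²),

with excitatory reversal V_r = +20 mV and intensity K ∈ {0.10 … 0.25}.
Two spatial choices are the package's own: (i) dist(i, x_k) is the
shortest ring distance, consistent with the ring geometry used everywhere
else (the raw index difference would re-introduce exactly the boundary
effects the ring removes, for neurons near the index wrap); (ii) the decay
rate σ_d is not fixed by the study conditions and is a configuration
parameter, default 1.0 chain-length units — attenuation ≈ 0.39 at the
midpoint between adjacent sites, keeping each stimulus predominantly local
to one subpopulation.

## Simulation procedure

A run chains four periods: 2 s settling (the only period without STDP),
60 s STDP-only (the network "kindles" into the synchronized
strongly-coupled attractor), 128 s stim-on, 128 s stim-off. t = 0 is the
first-stimulus delivery, so the first two periods occupy negative times.
Initial conditions per sample: V ~ U[−65, 5] mV, gates and synaptic
variables ~ U[0, 1], weights ~ N(0.5, 0.01) clamped to [0, 1]. Eleven
samples are realized as eleven seeds of the initialization stream; the
schedule stream is seeded independently per (sample, protocol), so one
initial network can be crossed with any stimulation realization.

Integration is adaptive Runge–Kutta 4(5) (Dormand–Prince) with relative
tolerance 10⁻⁵, absolute tolerance 10⁻⁶ and a 0.25 ms step cap so ~1 ms
action potentials and the 0.67 ms α-function are always resolved. The
integrator is stopped and restarted at every stimulation onset so the
waveform kink is never stepped over. Spikes are detected as upward
crossings of 0 mV with linear interpolation inside the accepted step
(Δt resolution well below 0.05 ms) and a 2 ms lockout against double
detection of one action potential; HH spikes here peak far above 0 mV and
the intrinsic period is 14 ms, so both thresholds are unambiguous. Each
detected spike applies the STDP update before integration resumes. The
hot loop is a numba-compiled port of the same equations; a plain-numpy
reference implementation (`crstim.model.derivatives`) is kept and the
test suite asserts the two agree to 10⁻¹² on random states. A non-finite
embedded-error norm (an overflowing trial step during the random initial
transient) is treated as a rejected step with the maximum shrink factor.

## Metrics

* **Connectivity**: C_av = N⁻² Σ sign(M_ij) c_ij; excitatory and
  inhibitory averages c_EE, c_II with the squared synapse counts N_EE⁻²,
  N_II⁻² as printed (a scaling convention — every comparison made with
  them is directional). Sorted connectivity matrices place, for each
  neuron pair, the stronger weight at (min i j, max i j) and the weaker at
  the mirror position, then multiply by sign(M); medians and IQRs across
  samples (linear interpolation of order statistics) expose uni- vs
  bidirectional motifs.
* **Synchronization**: linear interpolated phase
  φ_j(t) = 2π (t − t_m)/(t_{m+1} − t_m) between consecutive spikes;
  Kuramoto order parameter R over the network or over a subpopulation.
  Neurons without bracketing spikes at a query time are excluded with
  renormalization (the phase is simply undefined there; over a full
  record exclusions are rare). Reported R̄ values average the preceding
  5 s of 1 ms samples.
* **Subpopulations**: each site owns the N/N_s − 1 = 49 nearest neurons;
  the neuron equidistant to two sites (50/100/150/200) is excluded.
  Acute stimulation effect 1 − R̄_on/R̄_pre and after-effect
  1 − R̄_off/R̄_pre (positive = desynchronizing).
* **Stimulus locking**: cross-trial distributions of the subpopulation
  mean phase Φ_k(t_k^n + Δt) on a 1 ms lag grid over Δt ∈ [−32, 32] ms,
  over all 4,800 onsets or the 1,600 of one within-block rank; resetting
  index E_k(Δt) = |L⁻¹ Σ_n e^{iΦ_k}|. Entrainment shows as elevated
  pre-onset E, a phase reset as low pre-onset E rising after the onset.
* **Statistics**: one-sided Wilcoxon rank-sum (Mann–Whitney) with the
  exact null distribution when untied, α = 0.05, via
  `scipy.stats.mannwhitneyu`; an all-tied degenerate input reports p = 1
  with a warning.

## Reduced-scale preset and what it shows

The default test and acceptance workloads use a reduced preset
(`crstim.smoke_config()`): N = 20 neurons, 2 sites, periods 2/6/12/12 s,
all other constants unchanged. This keeps every structural feature — ring
Mexican-hat coupling, multistable STDP, 3:2 ON/OFF blocks, all seven
protocols — at ~1 % of the full computational cost. At this scale the
qualitative study phenomenology reproduces: the unstimulated network
kindles and stays on a synchronized attractor; CR variants drive C_av and
R_av below the control; the correlated-noise sham (CMNS) leaves the mean
weight at or above the control level and shows a slightly *synchronizing*
subpopulation effect; periodic patterns (fixed CR) entrain the
subpopulation phase (elevated pre-onset resetting index) while
non-periodic patterns (CMNS, RVS) produce clean phase resets. Quantitative
magnitudes (e.g. the study's percentage contrasts at N = 200 with 11
samples) are *not* expected to transfer from the reduced preset; the
full-scale grid is available as `scripts/full_study.py` and takes hours of
CPU per intensity. The reduced tests therefore assert directions and
orderings, not magnitudes.

The synthetic workloads also idealize real experiments in the usual ways:
no synaptic or measurement noise, no conduction delays, one neuron model,
and stimulation delivered exactly as scheduled. Passing tests demonstrate
that the algorithms and the inventory of metrics behave as specified on
this model class, not that any particular clinical stimulation protocol is
effective.

## Numerical and design notes

* Tolerances: rtol 10⁻⁵ / atol 10⁻⁶, 0.25 ms step cap; halving the
  tolerance moves the final C_av of a short fixture by < 10⁻³.
* Spike threshold 0 mV, lockout 2 ms, STDP applied at the interpolated
  crossing time.
* The weight matrix changes between integrator steps (event-based
  plasticity); within one accepted step the weights of that step are used,
  the standard event-based approximation.
* Determinism: identical configuration and seeds give bit-identical
  rasters, snapshots and metric tables (asserted in the suite).
* The sorted-connectivity display orientation ("stronger weight in one
  triangle") only affects plots, never statistics.
* Known limitations: no FitzHugh–Rinzel/bursting variants, no conduction
  delays, no synaptic noise, no GPU/cluster execution; per-run
  single-process with an optional multi-process batch launcher.
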