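# crstim

A computational testbed for **multichannel desynchronizing stimulation**
of plastic spiking networks — and for designing *sham* (inactive) control
protocols for it.

Pathologically strong neuronal synchrony is a hallmark of several brain
disorders (Parkinson's disease, tinnitus, epilepsy). Coordinated reset
(CR) stimulation delivers phase-shifted stimuli to distinct neuronal
subpopulations to desynchronize such activity; in the presence of
spike-timing-dependent plasticity (STDP) it can *unlearn* both abnormal
connectivity and abnormal synchrony ("anti-kindling"), an effect that
outlasts the stimulation. Testing such therapies clinically requires a
sham protocol that feels like the treatment but lacks its specific neural
effect. `crstim` implements the simulation testbed used to screen
candidate protocols: a plastic Hodgkin–Huxley ring network, seven
stimulation conditions, and the complete metric suite for classifying
acute and long-lasting effects.

## Model in brief

A ring of N Hodgkin–Huxley neurons (default N = 200) is coupled through a
Mexican-hat template M_ij — strong short-range excitation, weak long-range
inhibition — with dynamic weight magnitudes c_ij ∈ [0, 1]:

    C V̇_i = I_i − g_Na m_i³h_i (V_i − V_Na) − g_K n_i⁴ (V_i − V_K) − g_l (V_i − V_l) + S_i + F_i
    S_i   = N⁻¹ Σ_j (V_r,j − V_i) c_ij |M_ij| s_j

Weights follow an asymmetric STDP window Δc(Δt) (potentiation
β₁e^(−Δt/γ₁τ) for causal pairs, depression β₂(Δt/τ)e^(Δt/γ₂τ) otherwise),
applied event-wise at each detected spike. Four stimulation sites deliver
α-function current pulses, once per site per 16 ms ON-cycle, in 3 ON : 2
OFF blocks for 128 s. The seven conditions — no-stim, PPMS (periodic
simultaneous), CMNS (random simultaneous — the sham candidate), UMNS
(random per-site), and RVS / fixed / SVS coordinated reset — share every
basic parameter and differ only in the pattern of onset times.

Outcomes are measured by the signed mean weight C_av (with excitatory and
inhibitory components c_EE, c_II), the Kuramoto order parameter R over
linearly interpolated spike phases (network and per subpopulation), acute
stimulation/after-effects 1 − R̄_on/R̄_pre and 1 − R̄_off/R̄_pre, sorted
connectivity matrices, stimulus-locked cross-trial phase distributions
with the resetting index E_k(Δt), and one-sided Wilcoxon rank-sum tests
across samples. See `docs/methods.md` for the full account.

## Worked example

Run the reduced-scale preset (20-neuron ring, 2 sites, 2/6/12/12 s
periods) for a coordinated-reset protocol and the no-stim control:

```python
import crstim
from crstim import analysis

ctl = crstim.run_experiment(crstim.smoke_config("no_stim", sample_id=1))
cr  = crstim.run_experiment(crstim.smoke_config("RVS_CR",  sample_id=1))

t_on = cr.config.periods.stim_on_s          # end of stim-on, here 12 s
for name, res in [("no_stim", ctl), ("RVS_CR", cr)]:
    C_av, _, _ = analysis.mean_weights(res.snapshots[t_on], res.M)
    print(f"{name:8s}  C_av={C_av:+.4f}  R_av={res.r_av(t_on):.3f}")
```

prints

```
no_stim   C_av=+0.0819  R_av=0.683
RVS_CR    C_av=-0.0921  R_av=0.382
```

i.e. after 12 s of stimulation the CR-stimulated network has lost its net
excitatory connectivity (C_av driven negative) and roughly half of its
in-phase synchrony, while the unstimulated control stays on its
synchronized, strongly-coupled attractor — the anti-kindling signature at
reduced scale.

The same experiment is available from the shell:

```bash
crstim run --preset smoke --protocol rvs --out out/rvs_run
crstim batch --preset smoke --protocols nostim,rvs,cmns --samples 3 --out out/grid
crstim compare out/grid/summary.csv --a rvs:0.25 --b nostim:0.25 --metric C_av_on --side less
crstim schedule --protocol svs --seed 1 --out svs_schedule.tsv
```

The full-scale study grid (N = 200, 2/60/128/128 s periods, 7 protocols ×
11 samples, hours of CPU per intensity) runs via
`python scripts/full_study.py --K 0.25 --samples 11 --out scratch/full`.

## Layout

| path | contents |
|---|---|
| `src/crstim/model.py` | HH dynamics, ring template, coupling |
| `src/crstim/plasticity.py` | event-based STDP |
| `src/crstim/stimulation.py` | protocol schedules, α-function currents |
| `src/crstim/engine.py` | integration, spike detection, experiments |
| `src/crstim/analysis.py` | connectivity / synchrony / locking metrics |
| `src/crstim/batch.py`, `cli.py`, `io.py` | grid orchestration, CLI, file formats |
| `docs/methods.md` | model, parameters, numerical choices, limitations |
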