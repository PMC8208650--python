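# Methods

## The model

`thetagate` simulates a layer-II medial entorhinal cortex (MEC) microcircuit
of two conductance-based single-compartment cell types coupled by chemical
synapses, and asks when a sequence of afferent pulses is transmitted
reliably through it.

**Stellate cell.** Current balance

    C dV/dt = I_ext − I_Na − I_K − I_L − I_h − I_NaP − I_syn − I_noise

with transient Na (m³h), delayed-rectifier K (n⁴), leak, a persistent Na
current `I_NaP = g_NaP·ms·(V − E_Na)` and an h-current
`I_h = g_h·(0.65·m_hf + 0.35·m_hs)·(V − E_h)` with fast and slow gates.
All gates follow first-order kinetics, `dx/dt = α_x(V)·(1−x) − β_x(V)·x`
or equivalently `dx/dt = (x∞(V) − x)/τ_x(V)` with `x∞ = α/(α+β)`,
`τ = 1/(α+β)`; removable singularities of the rate functions are evaluated
by their series limits.
The slow h-gate steady state is the 58th power of a shallow (15.9 mV)
sigmoid — the high power sharpens it into an activation curve centered
near −75 mV.  The h and persistent-Na currents give the cell theta-band
subthreshold oscillations and post-inhibitory rebound spiking; the rebound
latency after release from sustained inhibition is ≈ 50 ms at default
parameters, which is what locks rebound spikes to the non-receptive half
of an 8 Hz theta cycle.

**Fast-spiking interneuron.** Current balance

    C dV/dt = I_ext + I_pulse − I_Na − I_K − I_L − I_syn − I_noise − I_θ

with Na (m³h, activation slaved to voltage: m = m∞(V)), K (n⁴) and leak.
The h and n gates are accelerated by a factor φ = 5, the fast-spiking
convention of this model family.  The theta drive
`I_θ = A·sin(2πωt + φ₀)·(V − V_th)` enters with a minus sign, so the
interneuron is most excitable at the *trough* of the sinusoid: the
"depolarized" (receptive) half-cycle is where the sinusoid is negative.

**Synapses.** Graded-release conductances with one gate per presynaptic
cell: `ds/dt = F(V_pre)·α_s·(1−s) − β_s·s`, `F(v) = (1 + tanh(v/4))/2`,
`I_syn = g·s·(V_post − E_rev)`.  Inhibition (E_rev = −80 mV) decays with
τ ≈ 9 ms; excitation (E_rev = 0 mV) with τ ≈ 3 ms.  Rate constants are in
ms⁻¹; the values (α_inh = 3.33, β_inh = 0.11, α_exc = 100, β_exc = 0.33)
are only consistent with millisecond-scale synaptic decay in those units.

**Stimuli.**  Sequential pulse trains visit interneuron i at
`t = i·T + k·λ` with plateau p∧ = 1.0 µA/cm², baseline p∨ = −0.05 µA/cm²,
width 40 ms, saturating rise τ_r = 1 ms and decay τ_f = 2 ms (τ values are
not constrained by the source material; they are fast relative to the
40 ms width so the plateau reaches p∧).  On a ring of N interneurons
λ = N·T.  Conductance noise `g·u·(V + 65)` with `u ~ U(−1,1)` is redrawn
per cell every 1 ms; g = 0.02 mS/cm² makes the mean absolute noise current
≈ 10% of the pulse amplitude at a typical 10 mV excursion from the noise
reversal.  (Resampling every integration step would make the integrated
noise power vanish as dt → 0; the 1 ms correlation time keeps the stated
amplitude meaningful.)

## Parameters chosen where the sources are silent

* Leak and capacitance: c_m = 1 µF/cm² both types; interneuron
  g_L = 0.1 mS/cm², E_L = −65 mV (its source model's values); stellate
  E_L = −65 mV and **g_L = 0.55 mS/cm²**.  The stellate leak is the one
  deliberate calibration in the package: at 0.5 the cell sits so close to
  firing onset that subthreshold-oscillation peaks fire "echo" spikes that
  invade the next theta cycle's receptive window, and the isolated cell
  fires rare spikes at the default −2.7 µA/cm² drive; at 0.55 every
  documented qualitative regime holds simultaneously (silent isolated cell
  with > 1 mV oscillation, motif alternation, ring sequence-following).
* Theta/pulse alignment: drive phase offset π, so pulse onsets land at the
  start of the receptive half-cycle.
* Gaussian inhibitory profile width σ = 1.25 ring indices, truncated at the
  5-neighbor fan-out, peak-normalized to g_ie; asymmetric feedback profile
  σ_e = 1.5, offset +2, total outgoing weight 4·g_ei (concentrating the
  full random-regime aggregate 6·g_ei on five neighbors makes single
  synapses strong enough to override the theta gate).
* Regime tunables found by coarse 1-D sweeps: bistable-motif drive
  0.5 µA/cm² with toggle amplitude 2.0; pair-switching pulses weak = 1.0 /
  strong = 2.0 (no theta) and weak = 0.8 with theta; dual-ring competing
  pulses at 0.5 µA/cm² (at 1.0 a pulse overcomes the ≈ 0.8 µA/cm² theta
  trough and phase gating fails).

## Numerics

Production integration is forward Euler at dt = 0.01 ms, the scheme the
model family is defined with.  After every step all gating and synaptic
variables are clamped to [0, 1]; clamp activations are counted and are 0
in every preset at the default step.  Runs abort with a flagged error if
any |V| exceeds 200 mV.  Spikes are upward crossings of 0 mV with linearly
interpolated crossing times and a 2 ms refractory window.  Initial
conditions draw each V from U(−70, −60) mV under the trial seed with gates
at their steady state for the drawn voltage — this desynchronizes
symmetric motifs without biasing a winner.  Topology seeds and trial
(noise + initial-condition) seeds are independent streams.

A classical fixed-step 4th-order Runge–Kutta integrator at dt = 0.001 ms
serves as the numerical oracle in tests.  Spike times of a tonically
firing stellate cell agree with it to < 0.05 ms over 1 s, and motif
switching-event counts match over 2 s.  One caveat is documented rather
than hidden: the tonically firing interneuron's inter-spike interval
carries a ≈ 1% bias at dt = 0.01 ms (its φ-accelerated gates are the
fastest time scale in the model), which compounds on the autonomous limit
cycle to several milliseconds of phase drift per second.  This is a
property of the first-order scheme at the published step, confirmed by
self-convergence of both integrators; oracle comparisons for this cell
therefore use timing not dominated by accumulated phase (the first spike).

## Analyses

**SPIKE dissimilarity.**  The time-resolved dissimilarity profile S(t) of
two spike trains is built from the previous/following spike of each train
and the timing differences to their nearest counterparts in the other
train, normalized by the local mean inter-spike interval; auxiliary spikes
at the interval endpoints make it defined for empty and near-empty trains
(an all-empty pair has distance 0).  S(t) is linear between consecutive
spikes of either train, so its time average is computed by exact piecewise
(trapezoidal) integration — no grid sampling.  The test suite checks this
exact route against an independent brute-force oracle that samples the
profile on a 20 000-point grid (agreement < 10⁻⁴ on random train pairs).
The triangle inequality is not asserted anywhere; the measure is not
guaranteed metric in all conventions.

**Reliability** of a neuron is the mean SPIKE distance over all unordered
pairs of its per-trial spike trains, computed over the analysis window
(250 ms – end; the first 250 ms contain the initial-condition volley, in
which most cells fire once as they relax onto the attractor).  Ring
summaries report the median over the 8 interneurons (ring indices 0–7)
that receive input at every theta frequency simulated.

**Phases** are the theta sinusoid argument at spike time, mod 2π (for
swept drives, the phase-continuous integral of the instantaneous
frequency; for no-theta conditions, the same clock defines phase relative
to the pulse cycle).  Circular means and resultant lengths are computed on
unit vectors.

## Problem sizes

Desk-scale defaults (the paper-scale structure with shortened observation
windows): ring experiments run 40+40 cells for 2 s with 10 noisy trials
(5–8 in `--fast` mode); the frequency sweep covers {6, 8, 10, 12, 14, 15}
Hz at 1.5 s per trial; the 2 Hz run lasts 4.25 s so 8 interneurons are
pulsed; the dual-ring runs are single noise-free 1.5 s trials.  With these
sizes every preset completes in well under 15 minutes on one CPU, and the
whole acceptance script in a few minutes.

## What the synthetic conditions do and do not show

All inputs are generated internally: there is no recorded data anywhere in
the pipeline.  The noise model (uniform conductance noise, 1 ms
correlation) and the perfectly periodic pulse schedule are idealizations;
real afferent drive is burstier and theta is non-sinusoidal.  Passing
tests therefore demonstrate the *mechanism* — rebound time scale matching
the theta period relegates recurrent excitation to the non-receptive
phase, yielding input-locked, trial-reliable sequences — under the stated
conditions, not quantitative agreement with in-vivo spike statistics.

## Known limitations

Single-compartment cells; no conduction delays, synaptic plasticity or
temperature scaling; 1-D ring topologies only (no 2-D torus); the
interneuron phase-drift caveat above; reliability orderings involving
stochastic comparisons at small trial counts (asymmetric-ring and
swept-frequency presets) have margins of only ~2× at `--fast` scale.
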