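# Methods

## Model

One synapse on a deep-layer pyramidal-like postsynaptic cell. State
variables: membrane potential V(t) (mV), calcium concentration Ca(t)
(μM), relative synaptic weight W(t) (dimensionless, baseline 1).

**Weight rule.** dW/dt = η(Ca)·(Ω(Ca) − W). The target
Ω(Ca) = 1 + 4·sig(Ca−α₂, β₂) − sig(Ca−α₁, β₁) with
sig(x, β) = e^{βx}/(1+e^{βx}) encodes the calcium-control hypothesis: no
change near zero calcium, depression (Ω → ~0) between α₁ = 0.35 and
α₂ = 0.55 μM, potentiation (Ω → 4) above. The learning rate
η(Ca) = [p₁/(p₂ + Ca^{p₃}) + p₄]⁻¹ (s⁻¹) with p₁ = 0.1 s, p₃ = 3,
p₄ = 1 s.

**Calcium.** dCa/dt = I_NMDA − Ca/τ_Ca, τ_Ca = 80 ms.
I_NMDA(t) = H(V(t)) · Σᵢ Θ(t−tᵢ)[I_f e^{−(t−tᵢ)/τ_f} + I_s e^{−(t−tᵢ)/τ_s}]
summed over presynaptic spikes only (glutamate gating); I_f = 0.75,
I_s = 0.25, τ_f = 50 ms, τ_s = 200 ms. The voltage gate
H(V) = P₀·|G|·(V_r − V)/[1 + (Mg/3.57)e^{−0.062V}], P₀ = 0.5, Mg = 1,
V_r = 130 mV — non-negative up to the reversal potential, an efflux
above it.

**Membrane potential.** V = V_rest + V_epsp + V_bg, V_rest = −65 mV.
Both terms are sums of the causal kernel K(t) = e^{−t/τ₁} − e^{−t/τ₂}
(τ₁ = 50, τ₂ = 5 ms): V_epsp over the regular presynaptic train with
amplitude `epsp_scale` (default 1 mV — the kernel as written, peak
≈ 0.70 mV), V_bg over a 1 Hz Poisson train with amplitude s·ξᵢ,
s = 20 mV, ξᵢ i.i.d. Normal(1, CV).

## Resolutions of ambiguous constants

Four printed constants admit more than one reading. Each default below
was fixed by requiring the model to reproduce its own published
phenomenology (BCM-shaped control curve; calcium rising with CV at every
frequency; LTD-area ratio falling with CV; a defined LTD/LTP threshold
in every condition); the alternative readings remain selectable in the
configuration, and switching them is the fastest way to see why they
were rejected.

* **p₂ = 1000** (the printed "p₁/10⁻⁴"). This makes η ≈ 1 s⁻¹
  essentially independent of calcium, so W relaxes toward the *time
  average* of Ω. The source model's alternative p₂ = p₁×10⁻⁴ = 1e-5
  (slow learning at low calcium) weights high-calcium episodes so
  heavily that at CV ≥ 3 the mean weight curve never dips below 1 — the
  LTD phase, the object of the whole analysis, disappears.
* **|G_NMDA| = 1/500 μM·ms⁻¹·mV⁻¹.** The printed magnitude 1/140 equals
  3.57 × (1/500) — the magnesium-block constant folded into the source
  model's conductance. Taken literally per (ms·mV), 1/140 makes every
  single-spike calcium transient peak at 1.11 μM, far above α₂, and the
  model potentiates at all frequencies.
* **epsp_scale = 1 mV** (the EPSP equation as printed, no amplitude
  factor). Scaling EPSPs by s instead gives 14 mV unitary EPSPs, which
  compress the LTD phase to a sliver below ~1.2 Hz and invert the
  calcium-versus-CV ordering.
* **Gate sign.** The printed H(V) evaluates negative below the reversal
  potential; the default implements the influx (non-negative)
  convention, with `literal_nmda_sign` keeping the printed sign for
  audit.

## Synthetic drive and replicate design

Presynaptic trains are strictly regular (first spike at t = 0,
configurable phase). Background trains are exact homogeneous Poisson
processes (Poisson count + uniform order statistics). Amplitude factors
are raw Normal(1, CV) draws; at CV = 3 and 5 a large fraction are
negative (transient hyperpolarizations). A truncate-at-zero option
exists but is off by default — the distribution is implemented as
specified, and the hyperpolarizing tail is part of what large-CV
fluctuation means here.

The default design is 5 Poisson trains × 3 amplitude seeds = 15
replicates per CV condition, CV ∈ {0, 1, 3, 5}; the *same* 5 trains are
shared across conditions, so conditions differ only in their amplitude
factors, and the control (CV = 0, ξ ≡ 1) contains the 3 amplitude-seed
copies of each train as identical replicates — its dispersion reflects
train-to-train variability only. All streams derive from one base seed
via `numpy.random.SeedSequence` spawn keys (trains: `(base, 0, i)`;
amplitudes: `(base, 1, cv_index, i, j)`), so any replicate can be
regenerated in isolation and a full pipeline rerun is byte-identical.

What the generator does *not* emulate: inhomogeneous or bursty
background rates, inhibitory synaptic channels with their own kinetics,
correlations between events, conductance-based (rather than additive)
voltage effects, spiking of the postsynaptic cell. Passing tests
therefore certify the model's behaviour under exactly this idealized
drive, not under in-vivo-like input.

## Integration

Fixed-step march, dt = 0.1 ms (validated against τ₂/10), duration
9×10⁴ ms, steady state averaged over stored samples in
[8.5×10⁴, 9.0×10⁴] ms; initial conditions Ca(0) = 0, W(0) = 1 (W has
long memory wherever η is small, so w0 is exposed prominently). Event
times are binned to the nearest step. Each exponential kernel sum is
maintained by recursive accumulators (exact decay + impulse), so a step
is O(1) in spike history; a brute-force rescan oracle pins the recursion
at 1e-10. Calcium takes the exact decay factor e^{−dt/τCa} plus
dt·I_NMDA with the forcing evaluated at the step midpoint (half-step
decay factors on the kernel states and the deposit — precomputed
constants), making the step second-order; the voltage-clamped
single-spike trace matches the analytic convolution to ~1e-8 relative.
W uses forward Euler (it varies on seconds). Halving dt changes the
hardest steady-state means (20 Hz, CV = 5) by far less than 1%.

Calcium is floored at 0 after each step: a background event large enough
to push V above V_r turns the NMDA term into an efflux, and a
concentration cannot go negative. The model functions raise a domain
error on negative calcium precisely so that any integrator sign bug
cannot pass silently; the floor is the physical boundary condition, not
error suppression. Non-finite states abort with the step index and
state name. The march is compiled with numba (pure-Python fallback);
the inlined model functions are pinned to the public ones at 1e-12.

## Statistics

Per replicate and frequency, the steady-state means of W and Ca are the
primary observables; condition curves aggregate replicates (mean, SD,
SEM — SEM is the plotted dispersion).

* **f₀ (LTD/LTP threshold):** scanning the condition-mean W(f) from low
  f, the first return to 1 after a dip below 1, linearly interpolated
  between grid points. Undefined (reported as such) if the curve never
  dips or never recovers.
* **f₊:** min(20 Hz, onset of a plateau |ΔW/Δf| < plateau_tol, the last
  swept frequency). Default plateau_tol = 0 disables plateau detection;
  the swept curves rise to the 20 Hz cap without plateauing.
* **Areas:** trapezoidal on [0, f₀] (LTD) and [f₀, f₊] (LTP), with the
  interpolated f₀ node included and W extended flat below the lowest
  simulated frequency down to 0 Hz (least-assumption extension, recorded
  in output metadata). Two definitions are implemented: `literal`
  (∫W df, the threshold-area formula as printed) and `deviation` (the
  geometric area between the curve and the W = 1 baseline, clipped so
  wrong-side segments contribute zero). The pipeline default is
  `deviation`: it is the shaded-region reading of the published area
  schematics, and it is the one that moves in the reported direction —
  a weaker dip *raises* ∫W df, so the literal ratios increase with CV
  while the reported ratios decrease.
* **Ratios:** condition area / control mean-curve area × 100 (control
  ≡ 100%). Per-replicate ratios use each replicate's own curve and the
  same control denominator; replicates without a defined threshold
  become NaN and are dropped from tests.
* **Group tests:** all pairwise condition comparisons of the
  per-replicate LTD-area ratio, LTP-area ratio, f₀ and Ca-at-f₀; Welch's
  unequal-variance t-test with Holm correction at α = 0.05 by default
  (the choice of test is not dictated by the study design; a permutation
  test on the difference of means is available).

## Problem sizes

The test suite runs reduced designs chosen to keep the whole suite in a
few minutes of CPU: BCM-shape check with 5 control replicates on the
{1, 5, 10, 15, 20} Hz grid; calcium orderings with 2 trains × 2 seeds;
LTD-attenuation orderings with 3 trains × 2 seeds on a 2 Hz-step grid
(at 6 replicates the significance tests are underpowered, so that check
asserts ordering only); the significance claim itself is tested at the
full 15-replicate, 1 Hz-grid design for the two conditions compared.
`scripts/acceptance.py` runs the complete 4-condition, 15-replicate,
1 Hz-grid protocol (1200 simulations).

## Known limitations

* The threshold shift with CV is small here (~0.1 Hz, not significant
  across replicates), and consequently the calcium level *at* the
  threshold increases slightly with CV (the Ca(f) curve shifts up with
  CV at every frequency, and the threshold does not move down far enough
  to compensate). A reported tendency of calcium-at-threshold to
  *decrease* with fluctuation is therefore not reproduced; the
  corresponding check is deliberately left failing rather than weakened.
* The control condition's duplicated replicates (see design above)
  make its dispersion a train-to-train quantity; tests against control
  should be read with that in mind.
* Areas and thresholds are grid-dependent through linear interpolation;
  the default 1 Hz grid samples the dip region (~1–5 Hz) with a handful
  of points.
* Only excitatory, additive background on a passive membrane; no
  postsynaptic spiking, no short-term plasticity, no calcium sources
  besides NMDA receptors.
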