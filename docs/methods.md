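# Methods

## The model in brief

Both packaged circuits are networks of Izhikevich point neurons advanced on
a fixed 1-ms grid for 30,000 iterations.  The membrane equation is
integrated with two 0.5-ms half-steps per iteration (the convention of the
original published integrator); the recovery variable updates once per
millisecond.  Synapses are current-based with fixed weights and a one-step
delay: a spike at iteration `t` delivers a rectangular 1-ms current pulse
`sign · weight` to its targets at `t + 1`.  There is no plasticity, no
conductance dynamics and no explicit neuromodulator concentration — the
dopaminergic VTA population is modelled as ordinary intrinsically bursting
neurons whose projection to the NAc is inhibitory-signed, which realises
dopamine's disinhibitory role in the caregiving pathway (VTA activity lifts
NAc inhibition off the ventral pallidum).

Regions carry an 80/20 excitatory/inhibitory split with local
E→I, I→E and I→I connectivity (`BLMA_i` is purely inhibitory; NAc and VP
are single inhibitory populations).  Reported "exc"/"inh" rates refer to
these sub-populations; the VTA excitatory cells are labelled `da`.

## Stimulation protocol

Levels `L = 0.05`, `M = 0.1`, `H = 0.15`; amplitude nominally 90 mA for
every injection; injectable pools `g(G)` of size `⌊|G|·H⌋` perturbed by 10%
per millisecond; per-step injected subsets `c_t(G) ⊆ g_t(G)` drawn either
with a uniform band count or a deterministic linear ramp (three phases of
10,000 ms).  The packaged schedules follow the two models' phase tables,
including the sustained (M, H) BLMA⊖ stimulus in every phase.  One protocol
choice deserves comment: the packaged schedules leave the mPFC *uninjected*
in phase 1, so its phase-1 activity (~0.8 Hz) is inherited entirely from
the insula relay.  This matches the reported behaviour of the modelled
system (the mPFC is not directly stimulated during the self-pain
condition) and is required for the caregiving drive to be ordered
phase 1 < phase 2 < phase 3; the alternative (a low-level close-other
injection in phase 1) is available through the schedule config.

Fractional counts are floored.  Ramp counts are deterministic (no band),
clipped to the pool size, and anchored to their phase so that the
endpoints reproduce the band levels exactly: the decreasing form starts at
`|G|·H` and ends at `|G|·L`, making the protocol continuous across phase
boundaries.

## Current units and the injection gain

The Izhikevich model is dimensionless in current, so the nominal milliamp
amplitude must be mapped into model units.  The neuron layer applies a
single calibrated conversion gain (0.036 model units per nominal mA in the
shipped set, i.e. an effective somatic drive of ~3.24 per injected
millisecond).  This places injected neurons just above rheobase, where the
population rate is set by first-spike latency against the ~10-ms residence
time in the churning injectable pool.  That regime is forced by the
reference rates themselves: the negatively valent BLMA, which has no
inhibitory afferent during phase 1, fires at ~0.9 Hz under a protocol that
keeps ~12.5% of its cells injected — only a near-rheobase drive yields
that rate, and no setting of connection weights can compensate a
suprathreshold one (a sustained drive of 90 model units would fire
regular-spiking cells at ~170 Hz).

Two numerical guards follow from this regime.  The membrane potential is
clamped to [−90, 10⁴] mV after every half-step: without the lower clamp,
coincident inhibitory pulses push `v` into the far-negative branch of the
quadratic where the discrete map produces non-physical rebound spikes (and
can overflow).  And inhibition is parameterised as many small pulses
(weights ≲ 3 with high connection probability) rather than few strong
ones: strong pulses saturate at the clamp and are additionally cancelled
by post-inhibitory recovery of the adaptation variable, a property we
verified directly and exploited when calibrating.

## The mPFC gradient and injectable pools

Close-other and distant-other stimulation targets live on the mPFC's
ventral–dorsal axis (2000 excitatory cells; index 0 dorsal, high index
ventral).  The negative-binomial distributions printed for the two
populations — close: r=7, p=0.0025 (mean ≈ 2793); distant: r=14, p=0.035
(mean ≈ 386) — parameterise the axis: draws outside the index range are
rejected and resampled, so the close-other distribution concentrates
ventrally and the distant-other distribution dorsally.  The mPFC's
projections to mPOA and BLMA⊕ sample their mPFC-side endpoints from the
close-other distribution, and the insula relay into the mPFC targets the
dorsal (self/distant-other) band — self-pain inputs engage
self-referential representations, keeping the ventral close-other band
quiet during personal distress.

The injectable *pools*, however, are drawn uniformly within the matching
end of the axis (ventral 45% for close, dorsal 75% for distant) rather
than directly from the negative binomials.  The reason is dynamical: at
the near-rheobase amplitude, a pool confined to the distant-other
distribution's ±1σ band (~500 cells, fewer than the ~312 cells injected
per step) is injected continuously and settles into complete
spike-frequency adaptation, extinguishing the weak-empathic-concern phase
entirely.  Band-uniform pools keep membership churning (and the narrow
close band deliberately re-introduces enough adaptation to damp the
end-of-ramp overshoot described below).  Gradient-drawn pools remain
available per pool through the schedule config.

## Rate analysis and state labels

The mean firing rate of a sub-population at a report time is the spike
count in the trailing 1000-ms window divided by window length and
population size; report times default to the phase ends (10/20/30 s).
The window length matches the reporting granularity and smooths burst
structure; it is configurable.

Phase labels are rule-based on the end-of-phase summary: personal distress
= VP below 0.5 Hz with the self-pain network at its cross-phase maximum;
weak vs strong empathic concern split at VP = 2 Hz; compassion
additionally requires an active mOFC (inhibitory rate ≥ 5 Hz) and BLMA⊖
suppressed below 70% of its phase-1 rate.  An all-silent summary raises an
error rather than a label.

## Calibration

The reference table (`data/reference_mfr.csv`) transcribes the quoted
mean firing rates of both models.  The shipped weights/probabilities were
obtained by bounded search (Latin-hypercube seeding plus coordinate-wise
refinement, three seeds per evaluation — the `calibration` module) against
that table, with extensive manual staging: single regions first (the
injection gain and local E→I levels), then the cortical couplings, then
the caregiving pathway.  Only projection weights and probabilities (plus
the scalar injection gain) were free; neuron parameters are the canonical
presets throughout.

### Known deviations of the calibrated set

The packaged set reproduces the headline quantities (the acceptance
targets) within `max(0.3 Hz, 25%)`, but about 15% of the full table's
entries are out of tolerance, for three structural reasons:

1. **Afferent-less regions in low-stimulation phases.**  PI has no
   afferents, so during (L, M) phases its excitatory cells are nearly
   silent and its interneurons, driven only by local E→I, cannot reach the
   reference 2–3.7 Hz.  The same mechanism caps AI's inhibitory rate at
   30 s in the empathy model.
2. **The phase-3 AI/PI "slight rise" of the empathy model** has no
   mechanistic source in that circuit's wiring (nothing projecting to
   AI/PI changes between phases 2 and 3); the model reproduces it only in
   the self-attachment circuit, where the mOFC provides the phase-3 input.
3. **End-of-ramp overshoot.**  A ramp ending at level H injects its whole
   pool every step (duty ~1 versus ~0.83 for the (M, H) band), and in the
   near-rheobase churn regime this raises the region's rate ~1.7× rather
   than ~1.2×.  The aMCC therefore reads ~1.9 Hz at 20 s in the
   self-attachment model (reference 1.11), which also breaks the
   max/min < 1.5 flatness property for that model (it holds for the
   empathy model).  Local inhibition cannot damp this — see the rebound
   cancellation above — and the pool rules are protocol-fixed for the
   aMCC.

The corresponding acceptance-suite checks are left red rather than
loosened; BLMA⊕ at 20 s in the empathy model is likewise allowed to sit
near ~1.5 Hz (reference 0.21) so that the ventral pallidum's weak-concern
rate is robustly classifiable.

## What the simulations do and do not show

The generator of all inputs is the protocol itself — there is no external
data.  Passing tests show that the packaged architecture, under the stated
stimulation rules and the calibrated stand-in connectivity, reproduces the
reference state trajectory and most of its rate table with seeded
reproducibility.  They do not validate the connectivity against anatomy
(the true parameter tables were unavailable and the shipped set is one of
many that fit), nor the biological realism of the near-rheobase regime,
nor any claim about plasticity, neuromodulation or therapy outcomes, which
are outside the model class (fixed weights, current-based synapses).

## Problem sizes and runtime

Packaged populations: 200–250 cells for most regions, 2,500 for the mPFC
(needed so the printed gradient parameters have in-range support),
~4,500–4,800 neurons and ~350,000–400,000 synapses per model.  A full
30-s run takes ~10 s on one core; the acceptance script (ten runs) a few
minutes.  The test suite runs the two models ten seeds each and reuses
those runs across all simulated checks.
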