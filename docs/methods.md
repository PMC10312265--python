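# Methods

## The circuit

Ten populations share a 1-D array of N = 200 index-aligned model neurons:
thalamic relay cells of the core (PV⁺) and matrix (CB⁺) systems, local
thalamic interneurons (PV⁻, CB⁻), the core and matrix sectors of the
thalamic reticular nucleus (TRN_C, TRN_M), and four cortical stages (L3b–4
and L6 for the core, L1–3a and L5 for the matrix). The wiring follows the
anatomy of primate thalamocortical loops:

* core: PV⁺ → L3b–4 → L6 → {TRN_C, optionally PV⁺}; TRN_C ⊣ PV⁺; PV⁺ → TRN_C
* matrix: CB⁺ → L1–3a → L5 → {TRN_M (variable density), optionally CB⁺};
  TRN_M ⊣ CB⁺; CB⁺ → TRN_M
* both TRN sectors inhibit themselves (within-pool only) and, when local
  inhibition is enabled, the local interneurons, which in turn inhibit their
  relay cells. The interneurons receive excitatory drive from their relay
  cells and from the deep cortical stage of their loop (L6 → PV⁻,
  L5 → CB⁻); the cortical limb follows the circuit schematic in which local
  interneurons are innervated "from TRN or from cortex", and its matrix-side
  gain scales with the L5 projection-density fraction exactly like
  L5 → TRN_M, which reproduces the observed gating (local inhibition is
  ineffective in the matrix loop when the L5→TRN_M projection is absent).

Two printed ratio constraints are structural, not calibrated: the
corticothalamic driver of the matrix loop is `l5_cb_over_l6_pv` (default 20)
times the L6→PV⁺ gain, and the L5→TRN_M gain is `l5_trn_fraction` (0–10 %)
of the L6→TRN_C gain. Configurations with `l5_cb_over_l6_pv` above 1000 are
rejected: three orders of magnitude is where the matrix loop loses its
oscillatory tendency.

Projections are Gaussian in array distance with unit-area normalization, so
a projection's `gain` is its total (row-sum) synaptic strength and its width
σ only distributes it. Matrix projections are four times broader than core
ones (σ = 8 vs 2), which is what produces the broad, smeared matrix
activity patterns against focal core ones. Profiles are truncated at the
array edges (no wraparound, no renormalization); all stimuli are delivered
at neuron 100, far from both edges. The integer center offset η implements
the hybrid loop design: η = 0 (the default everywhere) gives the balanced,
functionally-closed loop; nonzero η gives an open loop.

## Dynamics

Each neuron obeys the shunting equation
`dv/dt = −A·v − (v − E_ext)·I_ext − (v − E_inh)·I_inh` with E_ext = +1,
E_inh = −1. Leak rates are population-specific (relay cells are slow
integrators, reticular cells fast — see the shipped configuration). The
phase lag each stage contributes at the ~10 Hz ringing mode is
arctan(ω/A); with a single shared leak the lags degenerate and neither the
damping action of corticothalamic feedback nor the sustaining action of
local inhibition can be expressed, so the per-population rates are part of
the calibration.

Activity is signed around the resting state, interpreted as deviation from
a baseline firing rate. A projection's signed weighted sum is routed by
sign: the positive part enters the matching conductance and the negative
part the opposite one, so below-baseline reticular activity acts as
disinhibition. This keeps I_ext, I_inh ≥ 0 (the conductance interpretation
of the shunting equation) and the [−1, 1] bounds exact, and is linear in
the presynaptic signal near rest — which is what allows relay cells to
rebound above rest after a reticular volley, the mechanism behind every
post-shutdown oscillation in the model. Classic `[v]₊` rectification is
available as the `rectify` switch; under it a hyperpolarized population
transmits nothing, post-shutdown rebounds cannot cross baseline, and the
reference conditions are not reproduced — it exists for comparison, not as
the default.

The spindle mode itself: the core relay–reticular pair (PV⁺ ⇄ TRN_C)
resonates near 10 Hz (ω ≈ √(g_PV→TRN · g_TRN→PV)), and the corticoreticular
limb (PV⁺→L3b–4→L6→TRN_C→PV⁺) supplies the undamping that sets the
ring-down time measured by the STI. The matrix loop is built differently:
its pair is weak, and its oscillation is carried by the four-stage ring
CB⁺→L1–3a→L5→TRN_M→CB⁺, which vanishes when the L5→TRN_M density is zero —
hence the matrix loop's dependence on that projection. Corticothalamic
feedback (L6→PV⁺) damps the core mode; the local-interneuron channel
(cortex→interneuron→relay) undamps it.

### Stimuli

Spindle-like induction: each 100 ms cycle (10 Hz) is a normalized t⁶ ramp
over the first 60 % (slow rise, sharp upturn) followed by five triangular
spike-like peaks of heights 1.00 … 0.92; values lie in [0, 1] and only the
envelope timing matters dynamically. Tonic inputs are squares; pulses are
brief squares. A waveform is converted to excitatory conductance by the
`stimulus_gain` constant (300 s⁻¹), strong enough relative to the leak to
induce approximately the waveform's voltage in the target ("voltage
induction"); spindle-like inputs are delivered to a single reticular
neuron, tonic inputs to a small patch (Gaussian, σ = 3 neurons) of relay
cells.

### Integration

Fixed step dt = 0.5 ms, two-stage exponential (Heun-type) scheme: given the
drives, the shunting equation is linear in v and is advanced by its exact
relaxation toward v∞ = (E_ext·I_ext + E_inh·I_inh)/R at rate
R = A + I_ext + I_inh; the step is repeated with coefficients averaged
between the start and predicted end states. The update is second-order
accurate, unconditionally stable, and confined to [E_inh, E_ext] for
arbitrarily large conductances (the strong-driver conditions reach
R ~ 10³ s⁻¹, where a forward-Euler step at the same dt diverges). Halving
dt changes the baseline STI by ~10⁻⁴ s, far below the 0.02 s convergence
gate the suite enforces. The model contains no randomness; the only seeded
object in the package is the synthetic-trace fixture generator used to test
the analysis metrics.

## Measurements

* **STI** — after stimulus shutdown, local maxima of the lightly smoothed
  trace (5-sample moving average, three-point comparison) count as rebounds
  when their peak reaches `threshold_frac` (default 1 %) of the neuron's
  maximum activity magnitude over the whole trace, driven epoch included.
  The index runs from the onset of the adjacent hyperpolarization (first
  crossing below −threshold, linearly interpolated) to the last counted
  rebound's return below threshold; 0 when no rebound qualifies. Rankings
  across conditions are unchanged for thresholds between 0.5 % and 2 %.
* **Band-pass check** — zero-phase 4th-order Butterworth, 5–15 Hz
  (second-order sections); STI orderings on filtered traces match the raw
  ones on every shipped condition.
* **Similarity angle** — heat maps are vectorized neuron-major and compared
  by θ = arccos(A·B/|A||B|) in degrees; all-population stacked maps are
  used when comparing whole-circuit conditions.
* **Latencies** — onset is the first time a probe site's |v| exceeds 1 % of
  that site's own maximum; silent sites report NaN rather than raising.
* **Spatial spread** — FWHM of |v| across the array at a given sample, with
  linear interpolation at the half-maximum crossings; a single active
  neuron has width 1.

## Calibration

The absolute gains and leak rates are not determined by the ratio
constraints; they were fixed once by searching gain space against the
reference spindle-tendency anchors (core baseline 0.55 s; local inhibition
and raised reticular gain > 1 s; corticothalamic feedback < 0.55 s; both
together 0.55 s; tonic worked example 0.37 s; matrix 0/5/10 % density →
< 0.1 / 0.57 / > 1 s) while requiring the oscillation to stay in the 5–15 Hz
band, and the result ships as the version-stamped default configuration.
`spindleloop.calibrate.calibrate_defaults` exposes the grid-search
operation; it is a development-time tool and nothing re-runs it at
simulation or test time. All reference conditions integrate 2.0 s (0.5 s
stimulus + 1.5 s free evolution) at dt = 0.5 ms with N = 200, so an index
above 1 s is measurable and a single condition runs in a few seconds on one
CPU; indices quoted as "> 1" saturate at the 1.5 s observation window.

## Known limitations

* The model is a rate abstraction: no spikes, no H-/T-current biophysics,
  no conduction delays, no noise-driven spontaneous spindling. Rebounds are
  subthreshold depolarizations read as burst tendency.
* STI is quantized at roughly the oscillation period (a rebound either
  clears the threshold or does not), which makes near-threshold conditions
  sensitive to small parameter changes.
* The matrix corticothalamic driver tolerates being strengthened to about
  2–3× its default before its conductance load quenches the matrix
  oscillation; the reported tolerance of two orders of magnitude is not
  reproduced under this calibration (the three-orders collapse is). The
  corresponding check in the acceptance suite is left failing by design.
* Mixing ("cortical", "corticoreticular", "thalamoreticular") scales
  cross-connections by efficacy × core/matrix fraction, with within-loop
  drives scaled complementarily so ratio 1 (or 0) degenerates to a pure
  loop and 0.5 leaves the baseline untouched; the thalamoreticular cross
  gains follow the receiving reticular sector's synaptic gain. Other
  mixing conventions are conceivable; the qualitative orderings (mix
  intermediate in spread; similarity angle growing with distance from the
  50–50 baseline and with efficacy) are what the suite pins down.
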