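# spindleloop

A rate-based simulator of primate thalamocortical (TC) circuits for studying
sleep-spindle dynamics. The package wires the two anatomically distinct TC
loops — the **core** loop (parvalbumin-positive relay cells driving middle
cortical layers L3b–4 focally, with L6 feedback) and the **matrix** loop
(calbindin-positive relay cells modulating superficial layers L1–3a broadly,
driven by L5) — together with the inhibitory thalamic reticular nucleus
(TRN, split into core and matrix sectors), local thalamic interneurons
(PV⁻/CB⁻), a direct L5→TRN projection of variable density, and three ways of
cross-connecting ("mixing") the loops at the thalamus, the TRN, or the
cortex. It is aimed at computational neuroscientists who want a compact,
fully deterministic circuit model of how loop composition, local inhibition,
and corticothalamic feedback shape spindle generation, sustainment, and
propagation.

## Model

Each of the ten populations lives on a shared 1-D array of N = 200
index-aligned neurons. A neuron is a single shunting compartment

    dv/dt = −A·v − (v − E_ext)·I_ext − (v − E_inh)·I_inh,

with leak rate A, reversal potentials E_ext = +1 and E_inh = −1 (so
v ∈ [−1, 1] always), and total excitatory/inhibitory conductance drives
I_ext, I_inh ≥ 0 summed over the afferent projections. Connectivity between
populations is distance-dependent: the weight from presynaptic neuron j onto
postsynaptic neuron i is a unit-area Gaussian profile

    w(j, i) = gain · N(j − (i + η); σ),

whose width σ is four times broader for matrix projections than for core
ones, and whose integer center offset η realizes the hybrid open/closed-loop
design of the reticulo-thalamic connection: a balanced (η = 0) symmetric
profile is functionally equivalent to a closed loop, a shifted profile to an
open one.

The measurement layer implements the **spindle tendency index (STI)** — the
duration, in seconds, of the above-threshold sequence of post-stimulus
hyperpolarization/rebound events, with a rebound counted when its peak
reaches 1% of the neuron's maximum activity — plus a zero-phase 5–15 Hz
band-pass check, neuron × time heat maps, the cosine-similarity angle
θ = arccos(Â·B̂) between vectorized heat maps, propagation latencies at probe
neurons 100/113/128/147, and spatial full-width at half maximum.

## Worked example

Run the core-loop baseline (a 10 Hz, 0.5 s spindle-like burst input delivered
to reticular neuron 100, then 1.5 s of free evolution) and its
local-inhibition counterpart:

```
$ spindleloop run fig5a
fig5a: STI[PV+] = 0.555 s
$ spindleloop run fig5b
fig5b: STI[PV+] = 1.500 s
```

The first number says that, without local thalamic inhibition, the core loop
sustains its post-stimulus hyperpolarization/rebound sequence for about half
a second — a single spindle-like event. With the PV⁻ interneuron pathway
enabled the same stimulus yields rebound oscillations that outlast the whole
1.5 s observation window (the index saturates at 1.5 s), i.e. local
inhibition converts an isolated spindle into sustained spindling. The same
library calls are available programmatically:

```python
import spindleloop as sl

run = sl.run_preset("fig5a")          # build → integrate → analyze
run.sti                               # 0.555 (seconds)
run.report.band_power["PV+"]          # 5–15 Hz power of the probe trace
run.result.traces["PV+"].shape        # (200 neurons, 4000 samples)
```

`spindleloop list-presets` enumerates all named conditions (loop composition,
L5→TRN density, feedback and inhibition toggles, mixing ratios and
efficacies); `spindleloop run <preset> -o out.h5` stores traces, and
`spindleloop analyze out.h5 --baseline base.h5` reports STI, band power,
onset latencies, and the similarity angle against a baseline run.

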