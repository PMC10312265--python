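"""Named experiment presets: one per reported simulation condition.

Each preset is a declarative delta from the shipped default configuration
plus a stimulus protocol.  All presets integrate 2.0 s at dt = 0.5 ms: 0.5 s
of stimulation followed by 1.5 s of free evolution, long enough to measure
spindle tendencies above 1 s while keeping a single run in the seconds range.
The model is fully deterministic, so every preset is reproducible
bit-identically.

Condition map
-------------
fig2b   core, 0.5 s tonic square to PV+ (the worked STI example)
fig3a-c matrix loop with L5->TRN_M at 0 / 5% / 10% of the L6->TRN_C gain
fig5a/b core loop without / with local thalamic inhibition (PV- pathway)
fig6a-d core loop: baseline, + corticothalamic feedback, x2 TRN_C->PV+
        inhibition, and x2 inhibition + feedback
fig7a-c pure core, 50-50 thalamoreticular mix, pure matrix
fig8a-d cortical mixing at core:matrix ratios 80/20 ... 20/80 (+ the 50-50
        baseline preset fig8_baseline)
fig9a-c cortical mixing at 30/60/90% of plateau synaptic efficacy
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .analysis import AnalysisReport, analyze
from .circuit import CircuitConfig, build_circuit, default_config
from .dynamics import SimulationResult, integrate
from .stimuli import StimulusProtocol

__all__ = ["ExperimentPreset", "PresetRun", "PRESETS", "run_preset", "list_presets"]

#: Probe neuron used for scalar STI readouts (stimulus center).
PROBE_SITE = 100

#: Multiplicative factor on TRN_C->PV+ used by the raised-inhibition
#: conditions (fig6c/fig6d).
TRN_GAIN_FACTOR = 2.0

#: Default stimulus amplitudes.
SPINDLE_AMPLITUDE = 1.0
TONIC_AMPLITUDE = 0.5
#: Spatial width (index units) of the injected tonic patch; the spindle-like
#: reticular induction stays a single-neuron delta.
TONIC_SPATIAL_SIGMA = 3.0


@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    description: str
    measured_population: str
    overrides: dict = field(default_factory=dict)
    scale_gains: dict = field(default_factory=dict)
    stimulus: tuple = ("spindle", "TRN_C")
    baseline: str | None = None

    def config(self, base: CircuitConfig | None = None) -> CircuitConfig:
        cfg = base if base is not None else default_config()
        if self.overrides:
            cfg = cfg.copy_with(**self.overrides)
        if self.scale_gains:
            cfg = cfg.copy_with(
                projections={
                    key: {"gain": cfg.gain(key) * factor}
                    for key, factor in self.scale_gains.items()
                }
            )
        return cfg

    def protocols(self, cfg: CircuitConfig) -> list[StimulusProtocol]:
        kind, target = self.stimulus
        if kind == "tonic":
            return [
                StimulusProtocol(
                    target=target,
                    kind="tonic_square",
                    duration=0.5,
                    amplitude=TONIC_AMPLITUDE,
                    center_index=PROBE_SITE,
                    spatial_sigma=TONIC_SPATIAL_SIGMA,
                )
            ]
        if target == "both":
            r = cfg.mixing_ratio
            core_amp = SPINDLE_AMPLITUDE * min(1.0, 2.0 * r)
            mat_amp = SPINDLE_AMPLITUDE * min(1.0, 2.0 * (1.0 - r))
            out = []
            for trn, amp in (("TRN_C", core_amp), ("TRN_M", mat_amp)):
                if amp > 0:
                    out.append(
                        StimulusProtocol(
                            target=trn,
                            kind="spindle_burst",
                            duration=0.5,
                            amplitude=amp,
                            center_index=PROBE_SITE,
                        )
                    )
            return out
        return [
            StimulusProtocol(
                target=target,
                kind="spindle_burst",
                duration=0.5,
                amplitude=SPINDLE_AMPLITUDE,
                center_index=PROBE_SITE,
            )
        ]


_CORE = {}  # default flags are the core baseline
_MATRIX = {"cortical_feedback_tc": True}
_MIX_BASE = {"cortical_feedback_tc": True, "l5_trn_fraction": 0.05}


def _cortical_mix(ratio: float, efficacy: float) -> dict:
    return dict(
        _MIX_BASE,
        mixing_mode="cortical",
        mixing_ratio=ratio,
        mixing_efficacy=efficacy,
    )


_PRESET_LIST = [
    ExperimentPreset(
        "fig2b",
        "core loop, 0.5 s tonic square to PV+ (worked STI example)",
        "PV+",
        overrides=_CORE,
        stimulus=("tonic", "PV+"),
    ),
    ExperimentPreset(
        "fig3a",
        "matrix loop, no L5->TRN_M projection",
        "CB+",
        overrides=dict(_MATRIX, l5_trn_fraction=0.0),
        stimulus=("spindle", "TRN_M"),
    ),
    ExperimentPreset(
        "fig3b",
        "matrix loop, L5->TRN_M at 5% of the L6->TRN_C gain",
        "CB+",
        overrides=dict(_MATRIX, l5_trn_fraction=0.05),
        stimulus=("spindle", "TRN_M"),
    ),
    ExperimentPreset(
        "fig3c",
        "matrix loop, L5->TRN_M at 10% of the L6->TRN_C gain",
        "CB+",
        overrides=dict(_MATRIX, l5_trn_fraction=0.10),
        stimulus=("spindle", "TRN_M"),
    ),
    ExperimentPreset(
        "fig5a",
        "core loop without local thalamic inhibition",
        "PV+",
        overrides=dict(_CORE, local_inhibition=False),
    ),
    ExperimentPreset(
        "fig5b",
        "core loop with local thalamic inhibition (PV- pathway)",
        "PV+",
        overrides=dict(_CORE, local_inhibition=True),
    ),
    ExperimentPreset(
        "fig6a",
        "core loop baseline: no corticothalamic feedback",
        "PV+",
        overrides=_CORE,
    ),
    ExperimentPreset(
        "fig6b",
        "core loop with L6->PV+ corticothalamic feedback",
        "PV+",
        overrides=dict(_CORE, cortical_feedback_tc=True),
    ),
    ExperimentPreset(
        "fig6c",
        "core loop with raised TRN_C->PV+ inhibition",
        "PV+",
        overrides=_CORE,
        scale_gains={"TRN_C->PV+": TRN_GAIN_FACTOR},
    ),
    ExperimentPreset(
        "fig6d",
        "core loop with raised TRN_C->PV+ inhibition and corticothalamic feedback",
        "PV+",
        overrides=dict(_CORE, cortical_feedback_tc=True),
        scale_gains={"TRN_C->PV+": TRN_GAIN_FACTOR},
    ),
    ExperimentPreset(
        "fig7a",
        "pure core loop engaged (spindle input to TRN_C only)",
        "PV+",
        overrides=_MIX_BASE,
        stimulus=("spindle", "TRN_C"),
        baseline="fig7b",
    ),
    ExperimentPreset(
        "fig7b",
        "50-50 thalamoreticular core/matrix mix",
        "PV+",
        overrides=dict(
            _MIX_BASE,
            mixing_mode="thalamoreticular",
            mixing_ratio=0.5,
            mixing_efficacy=1.0,
        ),
        stimulus=("spindle", "both"),
    ),
    ExperimentPreset(
        "fig7c",
        "pure matrix loop engaged (spindle input to TRN_M only)",
        "CB+",
        overrides=_MIX_BASE,
        stimulus=("spindle", "TRN_M"),
        baseline="fig7b",
    ),
]

for _name, _ratio in (("fig8a", 0.8), ("fig8b", 0.6), ("fig8c", 0.4), ("fig8d", 0.2)):
    _PRESET_LIST.append(
        ExperimentPreset(
            _name,
            f"cortical mixing, core fraction {_ratio:.0%}",
            "PV+",
            overrides=_cortical_mix(_ratio, 1.0),
            stimulus=("spindle", "both"),
            baseline="fig8_baseline",
        )
    )
_PRESET_LIST.append(
    ExperimentPreset(
        "fig8_baseline",
        "cortical mixing, 50-50 baseline",
        "PV+",
        overrides=_cortical_mix(0.5, 1.0),
        stimulus=("spindle", "both"),
    )
)
for _name, _eff in (("fig9a", 0.3), ("fig9b", 0.6), ("fig9c", 0.9)):
    _PRESET_LIST.append(
        ExperimentPreset(
            _name,
            f"cortical mixing, {_eff:.0%} of plateau synaptic efficacy",
            "PV+",
            overrides=_cortical_mix(0.5, _eff),
            stimulus=("spindle", "both"),
            baseline="fig9a",
        )
    )

PRESETS: dict[str, ExperimentPreset] = {p.name: p for p in _PRESET_LIST}


@dataclass
class PresetRun:
    preset: ExperimentPreset
    result: SimulationResult
    sti: float
    report: AnalysisReport


def list_presets() -> list[str]:
    return list(PRESETS)


def run_preset(
    name: str,
    T: float = 2.0,
    dt: float = 5e-4,
    base_config: CircuitConfig | None = None,
    config_overrides: dict | None = None,
) -> PresetRun:
    """Build, integrate, and measure one named condition.

    Returns the simulation plus an analysis report; ``sti`` is the spindle
    tendency index of the preset's measured population at the probe neuron.
    """
    try:
        preset = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose one of {', '.join(PRESETS)}"
        ) from None
    cfg = preset.config(base_config)
    if config_overrides:
        cfg = cfg.copy_with(**config_overrides)
    circuit = build_circuit(cfg)
    result = integrate(circuit, preset.protocols(cfg), T=T, dt=dt)
    report = analyze(result, site=PROBE_SITE, populations=[preset.measured_population])
    sti = report.sti[preset.measured_population]
    return PresetRun(preset=preset, result=result, sti=sti, report=report)
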