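"""Assembly of the ten-population core/matrix thalamocortical network.

The network lives on a shared 1-D array of ``N`` index-aligned neurons per
population.  The core loop couples PV+ thalamic relay cells, the core sector
of the reticular nucleus (TRN_C), local PV- interneurons, and cortical layers
L3b-4 and L6.  The matrix loop mirrors it with CB+ relay cells, TRN_M, CB-
interneurons, and cortical L1-3a and L5.  Feature flags switch local thalamic
inhibition, corticothalamic feedback (L6->PV+, L5->CB+), corticoreticular
feedback (L6->TRN_C and the variable L5->TRN_M projection), and the three
core/matrix mixing schemes on and off.

Two printed ratio constraints are honored structurally rather than as free
gains: the L5->CB+ drive is ``l5_cb_over_l6_pv`` (default 20) times the
L6->PV+ gain, and the L5->TRN_M gain is ``l5_trn_fraction`` (0-10%) of the
L6->TRN_C gain.
"""

from __future__ import annotations

import copy
import importlib.resources
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import ConfigurationError, ConfigurationWarning
from .kernels import ProjectionKernel, build_weight_matrix

__all__ = [
    "POPULATIONS",
    "INHIBITORY_POPULATIONS",
    "PopulationSpec",
    "CircuitConfig",
    "WiredCircuit",
    "default_config",
    "build_circuit",
    "apply_mixing",
    "active_kernels",
]

#: Canonical population order: thalamic relay, local interneurons, reticular
#: sectors, cortical layers.
POPULATIONS = (
    "CB+", "PV+", "CB-", "PV-", "TRN_M", "TRN_C", "L1-3a", "L3b-4", "L5", "L6",
)

#: Populations whose outgoing projections are inhibitory (GABAergic).
INHIBITORY_POPULATIONS = frozenset({"CB-", "PV-", "TRN_M", "TRN_C"})

_ROLES = {
    "CB+": "thalamic-excitatory",
    "PV+": "thalamic-excitatory",
    "CB-": "thalamic-inhibitory",
    "PV-": "thalamic-inhibitory",
    "TRN_M": "reticular",
    "TRN_C": "reticular",
    "L1-3a": "cortical",
    "L3b-4": "cortical",
    "L5": "cortical",
    "L6": "cortical",
}

_MIXING_MODES = ("none", "thalamoreticular", "corticoreticular", "cortical")

#: Projections whose gain is derived (from a ratio constraint or from the
#: mixing settings) instead of being listed with a free gain in the
#: configuration; only their sigma is configurable.
_DERIVED_GAINS = (
    "L5->TRN_M",
    "L5->CB+",
    "L5->CB-",
    "PV+->TRN_M",
    "CB+->TRN_C",
    "L6->TRN_M",
    "L5->TRN_C",
    "L6->L5",
    "L5->L6",
)


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    N: int
    role: str

    def __post_init__(self):
        if self.name not in POPULATIONS:
            raise ConfigurationError(f"unknown population {self.name!r}")
        if self.N < 1:
            raise ConfigurationError("population size must be >= 1")


@dataclass
class CircuitConfig:
    """Declarative description of a core/matrix/mix circuit.

    ``projections`` maps ``"PRE->POST"`` keys to ``{"gain": g, "sigma": s}``
    dictionaries.  The gains of ``L5->TRN_M`` and ``L5->CB+`` are derived from
    ``l5_trn_fraction`` and ``l5_cb_over_l6_pv`` and must not be listed.
    """

    N: int = 200
    decay_A: float = 60.0
    decay_overrides: dict = field(default_factory=dict)
    E_ext: float = 1.0
    E_inh: float = -1.0
    l5_trn_fraction: float = 0.0
    local_inhibition: bool = False
    cortical_feedback_tc: bool = False
    cortical_feedback_trn: bool = True
    mixing_mode: str = "none"
    mixing_ratio: float = 0.5
    mixing_efficacy: float = 0.0
    l5_cb_over_l6_pv: float = 20.0
    cortical_mix_gain: float = 1.0
    stimulus_gain: float = 300.0
    eta_minus: int = 0
    eta_plus: int = 0
    rectify: bool = False
    version: str = "unversioned"
    projections: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.N < 1:
            raise ConfigurationError("N must be >= 1")
        if self.decay_A <= 0:
            raise ConfigurationError("decay_A must be > 0")
        for pop, rate in self.decay_overrides.items():
            if pop not in POPULATIONS:
                raise ConfigurationError(f"decay override for unknown population {pop!r}")
            if rate <= 0:
                raise ConfigurationError(f"decay rate of {pop} must be > 0")
        if not self.E_inh < self.E_ext:
            raise ConfigurationError("E_inh must be < E_ext")
        if not 0.0 <= self.l5_trn_fraction <= 1.0:
            raise ConfigurationError("l5_trn_fraction must lie in [0, 1]")
        if self.l5_cb_over_l6_pv < 0:
            raise ConfigurationError("l5_cb_over_l6_pv must be >= 0")
        if self.l5_cb_over_l6_pv > 1000:
            raise ConfigurationError(
                "l5_cb_over_l6_pv above 1000 (three orders of magnitude) is "
                "rejected: the matrix loop loses its oscillatory tendency"
            )
        if self.stimulus_gain < 0:
            raise ConfigurationError("stimulus_gain must be >= 0")
        if self.mixing_mode not in _MIXING_MODES:
            raise ConfigurationError(
                f"mixing_mode must be one of {_MIXING_MODES}, got {self.mixing_mode!r}"
            )
        if not 0.0 <= self.mixing_ratio <= 1.0:
            raise ConfigurationError("mixing_ratio must lie in [0, 1]")
        if not 0.0 <= self.mixing_efficacy <= 1.0:
            raise ConfigurationError("mixing_efficacy must lie in [0, 1]")
        if self.mixing_mode == "none" and self.mixing_ratio != 0.5:
            warnings.warn(
                "mixing_mode is 'none'; mixing_ratio is ignored",
                ConfigurationWarning,
                stacklevel=2,
            )
        for key in _DERIVED_GAINS:
            entry = self.projections.get(key, {})
            if "gain" in entry:
                raise ConfigurationError(
                    f"gain of {key} is derived from a ratio constraint and "
                    "must not be listed explicitly"
                )
        for key, entry in self.projections.items():
            if "sigma" not in entry:
                raise ConfigurationError(f"projection {key}: missing sigma")
            pre, _, post = key.partition("->")
            if pre not in POPULATIONS or post not in POPULATIONS:
                raise ConfigurationError(f"projection {key}: unknown population")

    # -- accessors ---------------------------------------------------------

    @property
    def populations(self) -> list[PopulationSpec]:
        return [PopulationSpec(name, self.N, _ROLES[name]) for name in POPULATIONS]

    @property
    def kernels(self) -> list[ProjectionKernel]:
        return active_kernels(self)

    def decay(self, pop: str) -> float:
        return float(self.decay_overrides.get(pop, self.decay_A))

    def gain(self, key: str) -> float:
        if key == "L5->TRN_M":
            return self.l5_trn_fraction * self.gain("L6->TRN_C")
        if key == "L5->CB+":
            return self.l5_cb_over_l6_pv * self.gain("L6->PV+")
        if key == "L5->CB-":
            return self.l5_trn_fraction * self.gain("L6->PV-")
        try:
            return float(self.projections[key]["gain"])
        except KeyError as exc:
            raise ConfigurationError(f"no gain configured for {key}") from exc

    def sigma(self, key: str) -> float:
        try:
            return float(self.projections[key]["sigma"])
        except KeyError as exc:
            raise ConfigurationError(f"no sigma configured for {key}") from exc

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "CircuitConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**copy.deepcopy(data))

    def to_dict(self) -> dict:
        out = {
            name: getattr(self, name) for name in self.__dataclass_fields__
        }
        out["projections"] = copy.deepcopy(self.projections)
        return out

    @classmethod
    def from_yaml(cls, path) -> "CircuitConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def copy_with(self, **changes) -> "CircuitConfig":
        """Return a deep copy with scalar fields and/or projection gains
        updated.  Projection overrides use ``"PRE->POST"`` keys mapping to
        ``{"gain": ...}`` / ``{"sigma": ...}`` partial entries."""
        proj = copy.deepcopy(self.projections)
        for key, entry in changes.pop("projections", {}).items():
            proj.setdefault(key, {}).update(entry)
        return replace(self, projections=proj, **changes)


def default_config(**changes) -> CircuitConfig:
    """The shipped, calibrated default configuration."""
    ref = importlib.resources.files("spindleloop.data") / "default_circuit.yaml"
    cfg = CircuitConfig.from_dict(yaml.safe_load(ref.read_text()))
    if changes:
        cfg = cfg.copy_with(**changes)
    return cfg


# ---------------------------------------------------------------------------
# Wiring


def _base_connections(config: CircuitConfig) -> list[tuple[str, float, int]]:
    """(key, gain, center_offset) triples for the non-mixing connections that
    are active under the configuration's feature flags."""
    em, ep = config.eta_minus, config.eta_plus
    conns: list[tuple[str, float, int]] = [
        # thalamoreticular loop (always present)
        ("CB+->TRN_M", config.gain("CB+->TRN_M"), ep),
        ("PV+->TRN_C", config.gain("PV+->TRN_C"), ep),
        ("TRN_M->CB+", config.gain("TRN_M->CB+"), -em),
        ("TRN_C->PV+", config.gain("TRN_C->PV+"), -em),
        ("TRN_M->TRN_M", config.gain("TRN_M->TRN_M"), 0),
        ("TRN_C->TRN_C", config.gain("TRN_C->TRN_C"), 0),
        # thalamocortical and intracortical pathway (always present)
        ("CB+->L1-3a", config.gain("CB+->L1-3a"), ep),
        ("PV+->L3b-4", config.gain("PV+->L3b-4"), ep),
        ("L1-3a->L5", config.gain("L1-3a->L5"), 0),
        ("L3b-4->L6", config.gain("L3b-4->L6"), 0),
    ]
    if config.local_inhibition:
        # The local interneurons receive thalamic, reticular, and cortical
        # excitatory drive (the L6->PV- / L5->CB- legs carry the cortical
        # input shown in the circuit diagram; the matrix-side leg scales with
        # the L5 projection-density fraction like L5->TRN_M).
        conns += [
            ("CB+->CB-", config.gain("CB+->CB-"), 0),
            ("PV+->PV-", config.gain("PV+->PV-"), 0),
            ("CB-->CB+", config.gain("CB-->CB+"), -em),
            ("PV-->PV+", config.gain("PV-->PV+"), -em),
            ("TRN_M->CB-", config.gain("TRN_M->CB-"), 0),
            ("TRN_C->PV-", config.gain("TRN_C->PV-"), 0),
            ("L6->PV-", config.gain("L6->PV-"), 0),
            ("L5->CB-", config.gain("L5->CB-"), 0),
        ]
    if config.cortical_feedback_trn:
        conns += [
            ("L6->TRN_C", config.gain("L6->TRN_C"), 0),
            ("L5->TRN_M", config.gain("L5->TRN_M"), 0),
        ]
    if config.cortical_feedback_tc:
        conns += [
            ("L6->PV+", config.gain("L6->PV+"), 0),
            ("L5->CB+", config.gain("L5->CB+"), 0),
        ]
    return conns


def _mixing_connections(config: CircuitConfig) -> list[tuple[str, float, int]]:
    """Cross-loop connections added by the active mixing mode.

    The core-side cross gain scales with the core fraction ``r`` and the
    matrix-side with ``1 - r``, both multiplied by the mixing efficacy, so a
    0.8 ratio yields a 4:1 core:matrix coupling asymmetry and zero efficacy
    degenerates to the unmixed circuit.
    """
    mode = config.mixing_mode
    if mode == "none" or config.mixing_efficacy == 0.0:
        return []
    r, e = config.mixing_ratio, config.mixing_efficacy
    if mode == "thalamoreticular":
        # cross gains follow the receiving reticular sector's synaptic gain
        return [
            ("PV+->TRN_M", e * r * config.gain("CB+->TRN_M"), config.eta_plus),
            ("CB+->TRN_C", e * (1 - r) * config.gain("PV+->TRN_C"), config.eta_plus),
        ]
    if mode == "corticoreticular":
        return [
            ("L6->TRN_M", e * r * config.gain("L6->TRN_C"), 0),
            ("L5->TRN_C", e * (1 - r) * config.gain("L6->TRN_C"), 0),
        ]
    # cortical: reciprocal L5 <-> L6 coupling
    g = config.cortical_mix_gain
    return [
        ("L6->L5", e * r * g, 0),
        ("L5->L6", e * (1 - r) * g, 0),
    ]


def _loop_drive_multipliers(config: CircuitConfig) -> dict[str, float]:
    """Complementary within-loop scaling under mixing.

    The drives that sustain each loop's oscillation (thalamic and cortical
    input to its TRN sector) are scaled by ``min(1, 2r)`` on the core side and
    ``min(1, 2(1-r))`` on the matrix side, so a 50-50 mix leaves the baseline
    untouched, ratio 1 degenerates to pure core, and ratio 0 to pure matrix.
    """
    if config.mixing_mode == "none" or config.mixing_efficacy == 0.0:
        return {}
    r = config.mixing_ratio
    core = min(1.0, 2.0 * r)
    mat = min(1.0, 2.0 * (1.0 - r))
    return {
        "PV+->TRN_C": core,
        "L6->TRN_C": core,
        "CB+->TRN_M": mat,
        "L5->TRN_M": mat,
    }


def active_kernels(config: CircuitConfig) -> list[ProjectionKernel]:
    """All projection kernels active under the configuration's flags and
    mixing mode, with derived and mixing-scaled gains resolved."""
    mults = _loop_drive_multipliers(config)
    kernels = []
    seen = set()
    for key, gain, offset in _base_connections(config) + _mixing_connections(config):
        if key in seen:
            raise ConfigurationError(f"duplicate projection {key}")
        seen.add(key)
        pre, _, post = key.partition("->")
        sign = "inhibitory" if pre in INHIBITORY_POPULATIONS else "excitatory"
        kernels.append(
            ProjectionKernel(
                pre=pre,
                post=post,
                gain=gain * mults.get(key, 1.0),
                sigma=config.sigma(key),
                center_offset=offset,
                sign=sign,
            )
        )
    return kernels


@dataclass
class WiredCircuit:
    """A circuit with all active weight matrices materialized."""

    config: CircuitConfig
    kernels: list[ProjectionKernel]
    weights: list[np.ndarray]

    @property
    def N(self) -> int:
        return self.config.N

    def incoming(self, post: str) -> set[tuple[str, str]]:
        """Set of (pre, sign) pairs projecting onto ``post``, nonzero gains
        only."""
        return {
            (k.pre, k.sign)
            for k in self.kernels
            if k.post == post and k.gain > 0
        }


def build_circuit(config: CircuitConfig) -> WiredCircuit:
    """Wire the network: resolve active kernels and build weight matrices."""
    config.validate()
    kernels = active_kernels(config)
    weights = [build_weight_matrix(k, config.N).values for k in kernels]
    return WiredCircuit(config=config, kernels=kernels, weights=weights)


def apply_mixing(
    circuit: WiredCircuit, mode: str, ratio: float, efficacy: float
) -> WiredCircuit:
    """Return a re-wired circuit with the given mixing settings applied."""
    if mode == "none" and ratio != 0.5:
        warnings.warn(
            "mixing mode 'none': ratio is ignored", ConfigurationWarning, stacklevel=2
        )
        ratio = 0.5
    cfg = circuit.config.copy_with(
        mixing_mode=mode, mixing_ratio=ratio, mixing_efficacy=efficacy
    )
    return build_circuit(cfg)
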