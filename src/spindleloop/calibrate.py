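"""Calibration of the unprinted gain constants.

The connectivity, the ratio constraints (the 20x L5->CB+ : L6->PV+ strength
ratio, the 0-10% L5->TRN_M fraction), the reversal potentials, and the
qualitative width ordering of matrix versus core kernels are fixed by the
circuit design; the absolute gain constants are free parameters.  They were
fixed once, against the printed spindle-tendency anchors of the reference
conditions, by the grid search below, and the result ships as the versioned
default configuration.  Calibration is a development-time operation: nothing
re-runs it at simulation or test time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import CircuitConfig, default_config
from .presets import run_preset

__all__ = ["Anchor", "calibrate_defaults"]


@dataclass(frozen=True)
class Anchor:
    """One calibration target: a preset and the spindle tendency (s) it must
    reproduce."""

    preset: str
    sti: float


def _residuals(
    config: CircuitConfig, anchors: list[Anchor], T: float, dt: float
) -> dict[str, float]:
    out = {}
    for anchor in anchors:
        run = run_preset(anchor.preset, T=T, dt=dt, base_config=config)
        out[anchor.preset] = run.sti - anchor.sti
    return out


def calibrate_defaults(
    anchors,
    free: tuple[str, ...] = ("L6->TRN_C", "TRN_C->TRN_C"),
    grid: int = 5,
    span: float = 1.6,
    base_config: CircuitConfig | None = None,
    tolerance: float = 0.05,
    T: float = 2.0,
    dt: float = 5e-4,
) -> tuple[CircuitConfig, dict[str, float]]:
    """Grid-search free gains against spindle-tendency anchors.

    Parameters
    ----------
    anchors:
        ``Anchor`` instances or ``(preset, sti)`` pairs.  An empty list
        returns the current defaults unchanged.
    free:
        Projection keys whose gains are searched (all other constants,
        including the printed ratio constraints, stay fixed).
    grid, span:
        Each free gain is scanned over ``grid`` log-spaced multipliers in
        ``[1/span, span]`` of its current value, jointly (full factorial).
    tolerance:
        Worst-anchor residual (s) below which the search stops early.

    Returns the best configuration found and its per-anchor residuals; if no
    point meets the tolerance the best-found residuals are returned for
    inspection.
    """
    anchors = [a if isinstance(a, Anchor) else Anchor(*a) for a in anchors]
    cfg = base_config if base_config is not None else default_config()
    if not anchors:
        return cfg, {}

    multipliers = np.logspace(np.log10(1 / span), np.log10(span), grid)
    base_gains = {key: cfg.gain(key) for key in free}

    best_cfg, best_res, best_score = cfg, None, np.inf
    mesh = np.meshgrid(*[multipliers] * len(free), indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=-1)
    for point in points:
        trial = cfg.copy_with(
            projections={
                key: {"gain": base_gains[key] * mult}
                for key, mult in zip(free, point)
            }
        )
        res = _residuals(trial, anchors, T=T, dt=dt)
        score = max(abs(r) for r in res.values())
        if score < best_score:
            best_cfg, best_res, best_score = trial, res, score
        if score <= tolerance:
            break
    return best_cfg, best_res
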