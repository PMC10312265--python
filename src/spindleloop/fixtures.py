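"""Synthetic single-trace fixtures for exercising the analysis metrics
independently of the circuit simulator.

Every fixture is deterministic given its seed and returns ``(t, v)`` arrays.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError

__all__ = ["make_fixture"]


def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Generate a synthetic voltage trace.

    Kinds
    -----
    damped_cosine:
        Linear ramp to ``amplitude`` over ``[0, t_off]`` followed by
        ``amplitude * exp(-(t-t_off)/tau) * cos(2*pi*f*(t-t_off))``.  The
        closed-form envelope makes the expected spindle tendency index
        computable analytically.
    pure_tone:
        ``amplitude * sin(2*pi*f*t)``.
    step:
        0 before ``t_on``, ``amplitude`` after.
    noise:
        Seeded white Gaussian noise with standard deviation ``sigma``.
    """
    p = dict(params or {})
    dt = p.pop("dt", 5e-4)
    T = p.pop("T", 2.0)
    t = np.arange(int(round(T / dt))) * dt
    if kind == "damped_cosine":
        f = p.pop("f", 10.0)
        tau = p.pop("tau", 0.15)
        amplitude = p.pop("amplitude", 0.5)
        t_off = p.pop("t_off", 0.5)
        _check_empty(kind, p)
        v = np.where(
            t < t_off,
            amplitude * t / t_off,
            amplitude * np.exp(-(t - t_off) / tau) * np.cos(2 * np.pi * f * (t - t_off)),
        )
        return t, v
    if kind == "pure_tone":
        f = p.pop("f", 10.0)
        amplitude = p.pop("amplitude", 1.0)
        _check_empty(kind, p)
        return t, amplitude * np.sin(2 * np.pi * f * t)
    if kind == "step":
        t_on = p.pop("t_on", 0.5)
        amplitude = p.pop("amplitude", 1.0)
        _check_empty(kind, p)
        return t, np.where(t >= t_on, amplitude, 0.0)
    if kind == "noise":
        sigma = p.pop("sigma", 1.0)
        _check_empty(kind, p)
        rng = np.random.default_rng(seed)
        return t, rng.normal(0.0, sigma, size=len(t))
    raise ConfigurationError(f"unknown fixture kind {kind!r}")


def _check_empty(kind: str, leftover: dict) -> None:
    if leftover:
        raise ConfigurationError(
            f"fixture {kind!r}: unknown parameters {sorted(leftover)}"
        )
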