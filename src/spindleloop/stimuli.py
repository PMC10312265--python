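"""External input protocols: spindle-like bursts, tonic squares, pulses.

The spindle-like waveform reproduces the temporal envelope of a reticular
burst sequence: each 1/burst_rate cycle starts with a slow-then-sharp
polynomial ramp (the low-threshold calcium dynamics that precede a burst)
followed by a densely packed train of spike-like peaks.  Only the envelope
timing is dynamically meaningful; the spike rendering inside the burst is
fixed for reproducibility and has no effect on the circuit dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "StimulusProtocol",
    "make_spindle_input",
    "make_tonic_input",
    "make_pulse",
    "spatial_profile",
    "protocol_drive",
]

_KINDS = ("spindle_burst", "tonic_square", "pulse")

#: Fraction of each burst cycle spent on the polynomial ramp before the burst.
RAMP_FRACTION = 0.6
#: Spike-like peak heights inside one burst, slightly decreasing.
BURST_PEAKS = (1.0, 0.98, 0.96, 0.94, 0.92)


@dataclass(frozen=True)
class StimulusProtocol:
    """Time-resolved external drive delivered to one population.

    The drive enters the excitatory conductance of the target, weighted over
    the array by a spatial profile centered at ``center_index`` (a single
    neuron when ``spatial_sigma`` is 0).
    """

    target: str
    kind: str = "spindle_burst"
    onset: float = 0.0
    duration: float = 0.5
    burst_rate: float = 10.0
    amplitude: float = 1.0
    center_index: int = 100
    spatial_sigma: float = 0.0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigurationError(f"stimulus kind must be one of {_KINDS}")
        if self.duration <= 0:
            raise ConfigurationError("stimulus duration must be > 0")
        if self.burst_rate <= 0:
            raise ConfigurationError("burst_rate must be > 0")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ConfigurationError("amplitude must lie in [0, 1]")
        if self.spatial_sigma < 0:
            raise ConfigurationError("spatial_sigma must be >= 0")

    @property
    def t_off(self) -> float:
        return self.onset + self.duration

    def waveform(self, dt: float) -> np.ndarray:
        """Temporal waveform sampled at dt, starting at the onset."""
        if self.kind == "spindle_burst":
            return self.amplitude * make_spindle_input(self.burst_rate, self.duration, dt)
        if self.kind == "tonic_square":
            return make_tonic_input(self.duration, self.amplitude, dt)
        return make_pulse(self.duration, self.amplitude, dt)


def make_spindle_input(burst_rate: float, duration: float, dt: float) -> np.ndarray:
    """Spindle-like burst waveform in [0, 1].

    Each cycle of length ``1/burst_rate`` consists of a normalized ``t**6``
    ramp over the first 60% of the cycle (slow initial rise, sharp upturn)
    followed by five triangular spike-like peaks with slightly decreasing
    heights.  Defaults (10 Hz, 0.5 s) give five cycles at a 100 ms interburst
    interval.
    """
    if burst_rate <= 0:
        raise ConfigurationError("burst_rate must be > 0")
    if dt > 2e-3:
        raise ConfigurationError(
            f"dt={dt} s is too coarse to render burst spikes (needs dt <= 2 ms)"
        )
    cycle = 1.0 / burst_rate
    n_cycles = int(round(duration * burst_rate))
    n_per_cycle = int(round(cycle / dt))
    tc = np.arange(n_per_cycle) * dt / cycle  # cycle phase in [0, 1)

    ramp_peak = 0.6  # ramp rises to the pre-burst depolarization level
    wave_cycle = np.zeros(n_per_cycle)
    in_ramp = tc < RAMP_FRACTION
    wave_cycle[in_ramp] = ramp_peak * (tc[in_ramp] / RAMP_FRACTION) ** 6

    # five triangular spikes over the remaining 40% of the cycle
    burst_phase = (tc - RAMP_FRACTION) / (1.0 - RAMP_FRACTION)  # [0,1) in burst
    n_spikes = len(BURST_PEAKS)
    for s, peak in enumerate(BURST_PEAKS):
        lo, hi = s / n_spikes, (s + 1) / n_spikes
        mid = 0.5 * (lo + hi)
        half = 0.5 * (hi - lo)
        sel = ~in_ramp & (burst_phase >= lo) & (burst_phase < hi)
        tri = 1.0 - np.abs(burst_phase[sel] - mid) / half
        wave_cycle[sel] = peak * tri

    wave = np.tile(wave_cycle, n_cycles)
    n_total = int(round(duration / dt))
    return wave[:n_total]


def make_tonic_input(duration: float, amplitude: float, dt: float) -> np.ndarray:
    """Square waveform: ``amplitude`` for ``duration`` seconds."""
    if duration <= 0:
        raise ConfigurationError("duration must be > 0")
    return np.full(int(round(duration / dt)), amplitude)


def make_pulse(width: float, amplitude: float, dt: float) -> np.ndarray:
    """Brief square pulse of the given width."""
    if width < 0:
        raise ConfigurationError("width must be >= 0")
    return np.full(int(round(width / dt)), amplitude)


def spatial_profile(N: int, center_index: int, spatial_sigma: float) -> np.ndarray:
    """Spatial weighting of the drive over the array.

    A delta at ``center_index`` when ``spatial_sigma`` is 0, otherwise a
    unit-peak Gaussian."""
    if not 0 <= center_index < N:
        raise ConfigurationError(f"center_index {center_index} outside [0, {N})")
    if spatial_sigma == 0:
        profile = np.zeros(N)
        profile[center_index] = 1.0
        return profile
    idx = np.arange(N)
    return np.exp(-0.5 * ((idx - center_index) / spatial_sigma) ** 2)


def protocol_drive(
    protocol: StimulusProtocol, N: int, n_steps: int, dt: float
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Discretize a protocol: (waveform, spatial profile, start, stop)."""
    wave = protocol.waveform(dt)
    start = int(round(protocol.onset / dt))
    stop = min(start + len(wave), n_steps)
    profile = spatial_profile(N, protocol.center_index, protocol.spatial_sigma)
    return wave[: stop - start], profile, start, stop
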