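"""Measurement layer: spindle tendency index, band-pass check, heat maps,
spatiotemporal similarity angle, propagation latencies, spatial spread.

The spindle tendency index (STI) is the total duration, in seconds, of the
above-threshold sequence of hyperpolarization / rebound-depolarization events
after the stimulus is shut down.  A local depolarization maximum counts as a
rebound if its peak reaches 1% of the neuron's maximum activity magnitude
over the whole trace; the index runs from the onset of the post-shutdown
hyperpolarization to the last counted rebound's return below threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .dynamics import SimulationResult
from .errors import AnalysisError

__all__ = [
    "compute_sti",
    "bandpass_check",
    "heatmap",
    "similarity_angle",
    "propagation_latencies",
    "spatial_spread",
    "AnalysisReport",
    "analyze",
]

DEFAULT_SITES = (100, 113, 128, 147)


def _smooth(v: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return v
    k = np.ones(window) / window
    return np.convolve(v, k, mode="same")


def _cross_time(t, y, level, i, rising):
    """Linear-interpolated time at which y crosses ``level`` between samples
    i and i+1."""
    y0, y1 = y[i], y[i + 1]
    if y1 == y0:
        return t[i]
    frac = (level - y0) / (y1 - y0)
    return t[i] + frac * (t[i + 1] - t[i])


def compute_sti(
    trace: np.ndarray,
    t: np.ndarray,
    t_off: float,
    threshold_frac: float = 0.01,
    smooth_window: int = 5,
) -> float:
    """Spindle tendency index of a single-neuron voltage series, in seconds.

    Parameters
    ----------
    trace, t:
        Voltage series and its uniform time axis.
    t_off:
        Stimulus shutdown time; rebounds are counted after it.
    threshold_frac:
        Rebound threshold as a fraction of the neuron's maximum activity
        magnitude over the whole trace (driven epoch included).
    smooth_window:
        Width (samples) of the moving average applied before the three-point
        peak detection.

    Returns 0.0 when no rebound reaches threshold.
    """
    trace = np.asarray(trace, dtype=float)
    t = np.asarray(t, dtype=float)
    if trace.shape != t.shape:
        raise AnalysisError("trace and time axis must have the same shape")
    if t[-1] <= t_off:
        raise AnalysisError(f"trace ends at {t[-1]} s, before t_off={t_off} s")
    if not 0.0 < threshold_frac < 1.0:
        raise AnalysisError("threshold_frac must lie in (0, 1)")

    vmax = np.max(np.abs(trace))
    if vmax == 0.0:
        return 0.0
    thr = threshold_frac * vmax

    vs = _smooth(trace, smooth_window)
    post = t >= t_off
    y = vs[post]
    ty = t[post]
    if len(y) < 3:
        return 0.0

    peaks, _ = signal.find_peaks(y, height=thr)
    if len(peaks) == 0:
        return 0.0

    # start: onset of the hyperpolarization adjacent to shutdown, i.e. the
    # first drop below -thr before the first counted rebound
    first_peak = peaks[0]
    below = np.nonzero(y[:first_peak] < -thr)[0]
    if len(below) > 0:
        i = below[0]
        start = ty[i] if i == 0 else _cross_time(ty, y, -thr, i - 1, rising=False)
    else:
        start = t_off

    # end: return below +thr after the last counted rebound
    last_peak = peaks[-1]
    after = np.nonzero(y[last_peak:] < thr)[0]
    if len(after) > 0:
        j = last_peak + after[0]
        end = _cross_time(ty, y, thr, j - 1, rising=False) if j > 0 else ty[j]
    else:
        end = ty[-1]
    return max(0.0, float(end - start))


def bandpass_check(
    trace: np.ndarray, fs: float, low: float = 5.0, high: float = 15.0
) -> tuple[np.ndarray, float]:
    """Zero-phase band-pass (4th-order Butterworth) plus band power.

    Returns the filtered series and its mean squared amplitude in the band.
    """
    if fs <= 2.0 * high:
        raise AnalysisError(
            f"sampling rate {fs} Hz violates Nyquist for high cut {high} Hz"
        )
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, np.asarray(trace, dtype=float))
    power = float(np.mean(filtered**2))
    return filtered, power


def heatmap(result: SimulationResult, population: str) -> np.ndarray:
    """Raw (neuron index x time) activity matrix of one population."""
    if population not in result.traces:
        raise AnalysisError(f"unknown population {population!r}")
    return result.traces[population]


def similarity_angle(mapA: np.ndarray, mapB: np.ndarray) -> float:
    """Angle (degrees) between two vectorized spatiotemporal maps.

    theta = arccos(A.B / (|A||B|)); 0 deg means identical patterns up to
    positive rescaling.  Maps are vectorized row-major (neuron-major)."""
    a = np.asarray(mapA, dtype=float).ravel()
    b = np.asarray(mapB, dtype=float).ravel()
    if a.shape != b.shape:
        raise AnalysisError("maps must share their shape")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise AnalysisError("similarity angle undefined for an all-zero map")
    cos = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def propagation_latencies(
    result: SimulationResult,
    population: str,
    sites=DEFAULT_SITES,
    threshold_frac: float = 0.01,
) -> dict[int, float]:
    """Activity onset time per probe site.

    Onset is the first time the magnitude of a site's trace exceeds
    ``threshold_frac`` of that trace's own maximum magnitude.  A site that
    never crosses (an identically-zero trace) reports NaN rather than raising.
    """
    hm = heatmap(result, population)
    N = hm.shape[0]
    t = result.times
    out: dict[int, float] = {}
    for site in sites:
        if not 0 <= site < N:
            raise AnalysisError(f"site {site} outside [0, {N})")
        v = np.abs(hm[site])
        vmax = v.max()
        if vmax == 0.0:
            out[site] = float("nan")
            continue
        idx = int(np.argmax(v >= threshold_frac * vmax))
        out[site] = float(t[idx])
    return out


def spatial_spread(hm: np.ndarray, time_index: int) -> float:
    """Full width at half maximum of |v| across the neuron axis at one time
    sample, in index units.  NaN for an all-zero column."""
    col = np.abs(np.asarray(hm, dtype=float)[:, time_index])
    peak = col.max()
    if peak == 0.0:
        return float("nan")
    half = 0.5 * peak
    i0 = int(np.argmax(col))
    idx = np.arange(len(col), dtype=float)

    # walk outward from the peak to the half-maximum crossings
    left = i0
    while left > 0 and col[left - 1] >= half:
        left -= 1
    if left == 0 or col[left - 1] >= half:
        lo = idx[left] - 0.5
    else:
        lo = _cross_time(idx, col, half, left - 1, rising=True)

    right = i0
    n = len(col)
    while right < n - 1 and col[right + 1] >= half:
        right += 1
    if right == n - 1 or col[right + 1] >= half:
        hi = idx[right] + 0.5
    else:
        hi = _cross_time(idx, col, half, right, rising=False)
    return float(hi - lo)


@dataclass
class AnalysisReport:
    """Per-simulation measurement bundle."""

    sti: dict[str, float] = field(default_factory=dict)
    theta_deg: float | None = None
    latencies: dict[int, float] = field(default_factory=dict)
    spatial_fwhm: dict[str, float] = field(default_factory=dict)
    band_power: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": "sti_s", "key": pop, "value": val}
            for pop, val in self.sti.items()
        ]
        if self.theta_deg is not None:
            rows.append({"metric": "theta_deg", "key": "baseline", "value": self.theta_deg})
        rows += [
            {"metric": "onset_s", "key": str(site), "value": val}
            for site, val in self.latencies.items()
        ]
        rows += [
            {"metric": "fwhm_idx", "key": pop, "value": val}
            for pop, val in self.spatial_fwhm.items()
        ]
        rows += [
            {"metric": "band_power", "key": pop, "value": val}
            for pop, val in self.band_power.items()
        ]
        return pd.DataFrame(rows)


def _stacked_map(result: SimulationResult) -> np.ndarray:
    return np.concatenate([result.traces[p] for p in sorted(result.traces)], axis=0)


def analyze(
    result: SimulationResult,
    baseline: SimulationResult | None = None,
    site: int = 100,
    populations=None,
    spread_time: float | None = None,
) -> AnalysisReport:
    """Standard report: STI at the probe site for each population, band
    power, propagation latencies of the most active population, optional
    similarity angle against a baseline simulation."""
    report = AnalysisReport()
    t = result.times
    fs = 1.0 / result.dt
    t_off = result.t_off
    pops = list(populations or result.traces)
    for pop in pops:
        trace = result.trace(pop, site)
        report.sti[pop] = compute_sti(trace, t, t_off)
        report.band_power[pop] = bandpass_check(trace, fs)[1]
    if spread_time is not None:
        ti = int(round(spread_time / result.dt))
        for pop in pops:
            report.spatial_fwhm[pop] = spatial_spread(heatmap(result, pop), ti)
    most_active = max(pops, key=lambda p: np.abs(result.traces[p]).max())
    if np.abs(result.traces[most_active]).max() > 0:
        sites = [s for s in DEFAULT_SITES if s < result.traces[most_active].shape[0]]
        report.latencies = propagation_latencies(result, most_active, sites)
    if baseline is not None:
        report.theta_deg = similarity_angle(
            _stacked_map(result), _stacked_map(baseline)
        )
    return report
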