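"""Shunting dynamics: the membrane equation and its fixed-step integration.

Every model neuron obeys the first-order shunting equation

    dv/dt = -A*v - (v - E_ext)*I_ext - (v - E_inh)*I_inh

with leak rate ``A`` and reversal potentials ``E_ext = +1``, ``E_inh = -1``.
The multiplicative (conductance-like) gating of the two drives confines the
activity to ``[E_inh, E_ext]`` whenever ``I_ext, I_inh >= 0``, and the leak
returns every neuron to rest once all input ceases.

Presynaptic activity is converted to conductance drive in one of two ways:

* sign-routed (default): the signed weighted sum of a projection is split by
  sign, the positive part feeding the matching conductance and the negative
  part the opposite one.  Below-baseline activity of an inhibitory population
  thereby acts as disinhibition, which is what lets thalamic relay cells
  rebound above rest after a reticular volley -- the mechanism behind every
  post-shutdown oscillation in the model.  Near rest this scheme is exactly
  linear in the presynaptic signal.
* rectified (``rectify: true``): classic ``[v]+`` transmission, negative
  activities transmit nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import POPULATIONS, WiredCircuit
from .errors import AnalysisError, IntegrationError
from .stimuli import StimulusProtocol, protocol_drive

__all__ = [
    "shunting_derivative",
    "population_inputs",
    "integrate",
    "SimulationResult",
]

_BOUND_TOL = 1e-6


def shunting_derivative(v, I_ext, I_inh, A, E_ext=1.0, E_inh=-1.0):
    """Rate of change of the shunting membrane equation (pure function)."""
    return -A * v - (v - E_ext) * I_ext - (v - E_inh) * I_inh


def population_inputs(
    circuit: WiredCircuit, states: dict[str, np.ndarray]
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Total excitatory and inhibitory conductance drive per population.

    Both returned drives are elementwise nonnegative in either transmission
    mode."""
    N = circuit.N
    for name, v in states.items():
        if v.shape != (N,):
            raise ValueError(f"state of {name} has shape {v.shape}, expected ({N},)")
    rectify = circuit.config.rectify
    s_exc = {name: np.zeros(N) for name in POPULATIONS}
    s_inh = {name: np.zeros(N) for name in POPULATIONS}
    for kernel, W in zip(circuit.kernels, circuit.weights):
        v_pre = states[kernel.pre]
        if rectify:
            v_pre = np.maximum(v_pre, 0.0)
        drive = W @ v_pre
        if kernel.sign == "excitatory":
            s_exc[kernel.post] += drive
        else:
            s_inh[kernel.post] += drive
    I_ext, I_inh = {}, {}
    for name in POPULATIONS:
        if rectify:
            I_ext[name] = s_exc[name]
            I_inh[name] = s_inh[name]
        else:
            I_ext[name] = np.maximum(s_exc[name], 0.0) + np.maximum(-s_inh[name], 0.0)
            I_inh[name] = np.maximum(s_inh[name], 0.0) + np.maximum(-s_exc[name], 0.0)
    return I_ext, I_inh


@dataclass
class SimulationResult:
    """Voltage traces of all populations plus the provenance that produced
    them.

    ``traces[name]`` has shape ``(N, n_samples)``; the time axis is uniform
    with step ``dt``."""

    traces: dict[str, np.ndarray]
    dt: float
    config: "CircuitConfig"  # noqa: F821 - circular import avoided
    protocols: list[StimulusProtocol] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        n = next(iter(self.traces.values())).shape[1]
        return np.arange(n) * self.dt

    @property
    def t_off(self) -> float:
        """Latest stimulus shutdown time across protocols (0 if none)."""
        return max((p.t_off for p in self.protocols), default=0.0)

    def trace(self, population: str, index: int) -> np.ndarray:
        if population not in self.traces:
            raise AnalysisError(f"population {population!r} was not simulated")
        return self.traces[population][index]

    # -- persistence -------------------------------------------------------

    def to_hdf5(self, path) -> None:
        import json

        import h5py
        import yaml

        with h5py.File(path, "w") as fh:
            fh.attrs["dt"] = self.dt
            fh.attrs["config"] = yaml.safe_dump(self.config.to_dict())
            fh.attrs["protocols"] = json.dumps(
                [vars(p) for p in self.protocols]
            )
            grp = fh.create_group("traces")
            for name, arr in self.traces.items():
                grp.create_dataset(name, data=arr, compression="gzip")

    @classmethod
    def from_hdf5(cls, path) -> "SimulationResult":
        import json

        import h5py
        import yaml

        from .circuit import CircuitConfig

        with h5py.File(path, "r") as fh:
            dt = float(fh.attrs["dt"])
            config = CircuitConfig.from_dict(yaml.safe_load(fh.attrs["config"]))
            protocols = [
                StimulusProtocol(**kw) for kw in json.loads(fh.attrs["protocols"])
            ]
            traces = {name: arr[()] for name, arr in fh["traces"].items()}
        return cls(traces=traces, dt=dt, config=config, protocols=protocols)

    def to_frame(self, populations=None, stride: int = 1) -> pd.DataFrame:
        """Long-format (population, neuron, t, v) table."""
        rows = []
        times = self.times[::stride]
        for name in populations or self.traces:
            arr = self.traces[name][:, ::stride]
            n_idx, n_t = arr.shape
            rows.append(
                pd.DataFrame(
                    {
                        "population": name,
                        "neuron": np.repeat(np.arange(n_idx), n_t),
                        "t": np.tile(times, n_idx),
                        "v": arr.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def integrate(
    circuit: WiredCircuit,
    protocols: StimulusProtocol | list[StimulusProtocol],
    T: float,
    dt: float = 5e-4,
) -> SimulationResult:
    """Fixed-step integration of the full network from rest.

    Uses a two-stage exponential (Heun-type) scheme: per step the signed
    drives are converted to conductances, the linear-in-v shunting relaxation
    is advanced exactly, and the step is repeated with coefficients averaged
    between the start and the predicted end state.  The update is
    second-order accurate, unconditionally stable, and confined to
    ``[E_inh, E_ext]`` for arbitrarily strong conductances.

    The trajectory is deterministic; with no stimulus all traces remain zero.
    If any activity leaves ``[E_inh, E_ext]`` beyond a small tolerance the
    integration aborts with an :class:`IntegrationError` naming ``dt``.
    """
    if isinstance(protocols, StimulusProtocol):
        protocols = [protocols]
    if dt > 1e-3:
        raise IntegrationError(f"dt={dt} s exceeds the 1 ms integration cap")
    for p in protocols:
        if T <= p.t_off:
            raise IntegrationError(
                f"total time T={T} s must exceed stimulus end {p.t_off} s"
            )

    cfg = circuit.config
    N = circuit.N
    n_steps = int(round(T / dt))
    drives = [protocol_drive(p, N, n_steps, dt) for p in protocols]
    targets = [p.target for p in protocols]

    # state and storage
    pops = list(POPULATIONS)
    v = {name: np.zeros(N) for name in pops}
    out = {name: np.empty((N, n_steps)) for name in pops}

    # group projections by (post, sign) for the inner loop
    proj = [
        (k.pre, k.post, k.sign == "inhibitory", W)
        for k, W in zip(circuit.kernels, circuit.weights)
    ]
    E_ext, E_inh = cfg.E_ext, cfg.E_inh
    A = {name: cfg.decay(name) for name in pops}
    rectify = cfg.rectify
    stim_gain = cfg.stimulus_gain
    lo = E_inh - _BOUND_TOL
    hi = E_ext + _BOUND_TOL

    def conductances(state, step):
        """Per-population (R, S) with R = A + I_ext + I_inh and
        S = E_ext*I_ext + E_inh*I_inh, evaluated at ``state``."""
        s_exc = {name: 0.0 for name in pops}
        s_inh = {name: 0.0 for name in pops}
        for pre, post, is_inh, W in proj:
            v_pre = state[pre]
            if rectify:
                v_pre = np.maximum(v_pre, 0.0)
            drive = W @ v_pre
            if is_inh:
                s_inh[post] = s_inh[post] + drive
            else:
                s_exc[post] = s_exc[post] + drive
        for (wave, profile, start, stop), target in zip(drives, targets):
            if start <= step < stop:
                s_exc[target] = (
                    s_exc[target] + stim_gain * wave[step - start] * profile
                )
        R, S = {}, {}
        for name in pops:
            se, si = s_exc[name], s_inh[name]
            if rectify:
                I_ext, I_inh = se, si
            else:
                I_ext = np.maximum(se, 0.0) + np.maximum(-si, 0.0)
                I_inh = np.maximum(si, 0.0) + np.maximum(-se, 0.0)
            R[name] = A[name] + I_ext + I_inh
            S[name] = E_ext * I_ext + E_inh * I_inh
        return R, S

    def exp_step(state, R, S):
        # With the drives frozen the shunting equation is linear in v,
        # relaxing toward v_inf = S/R at rate R; the exponential update is
        # unconditionally stable and stays in [E_inh, E_ext] for arbitrarily
        # large conductances.
        new = {}
        for name in pops:
            v_inf = S[name] / R[name]
            new[name] = v_inf + (state[name] - v_inf) * np.exp(-R[name] * dt)
        return new

    for step in range(n_steps):
        # Heun-style exponential step: predict with drives at the current
        # state, re-evaluate drives at the prediction, and advance with the
        # averaged relaxation coefficients (second-order accurate, bounded).
        R1, S1 = conductances(v, step)
        v_pred = exp_step(v, R1, S1)
        nxt = min(step + 1, n_steps - 1)
        R2, S2 = conductances(v_pred, nxt)
        Rbar = {name: 0.5 * (R1[name] + R2[name]) for name in pops}
        Sbar = {name: 0.5 * (S1[name] + S2[name]) for name in pops}
        v = exp_step(v, Rbar, Sbar)
        for name in pops:
            out[name][:, step] = v[name]
        if step % 200 == 0:
            for name in pops:
                m = v[name]
                if not np.all(np.isfinite(m)) or not np.all((m >= lo) & (m <= hi)):
                    raise IntegrationError(
                        f"activity left [{E_inh}, {E_ext}] at t="
                        f"{step * dt:.4f} s with dt={dt}; reduce dt or gains"
                    )
    for name in pops:
        m = out[name]
        if not np.all((m >= lo) & (m <= hi)):
            raise IntegrationError(
                f"activity left [{E_inh}, {E_ext}] with dt={dt}; "
                "reduce dt or gains"
            )
    return SimulationResult(traces=out, dt=dt, config=cfg, protocols=protocols)
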