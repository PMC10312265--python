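"""Distance-dependent Gaussian connectivity profiles.

Every projection between two model populations is described by a Gaussian
weight profile over the shared 1-D neuron array: the strength of the
connection from presynaptic neuron ``j`` onto postsynaptic neuron ``i`` is a
normal density in ``j - i``, optionally shifted by an integer center offset.
A zero offset makes the profile symmetric about the reciprocal neuron, which
realizes the hybrid-loop idea: a reticular cell inhibiting a symmetric
neighborhood of the thalamic cell that excites it behaves like two balanced
open loops, i.e. functionally like a closed loop.  A nonzero offset breaks
the symmetry and yields a genuinely open loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "ProjectionKernel",
    "WeightMatrix",
    "gaussian_weight",
    "build_weight_matrix",
    "loop_character",
]

_SIGNS = ("excitatory", "inhibitory")


@dataclass(frozen=True)
class ProjectionKernel:
    """One pre -> post Gaussian connection profile.

    Parameters
    ----------
    pre, post:
        Population identifiers (see :mod:`spindleloop.circuit`).
    gain:
        Dimensionless synaptic strength multiplying the unit-area Gaussian
        profile.  Must be nonnegative; the sign of the projection lives in
        ``sign``, never in the weights.
    sigma:
        Width of the profile in neuron-index units; strictly positive.
    center_offset:
        Integer shift of the profile center (the open-loop offset).  With
        offset 0 the weight from ``i + k`` equals the weight from ``i - k``.
    sign:
        ``"excitatory"`` or ``"inhibitory"``; decides whether the projection
        feeds the excitatory or the inhibitory conductance of the target.
    """

    pre: str
    post: str
    gain: float
    sigma: float
    center_offset: int = 0
    sign: str = "excitatory"

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ConfigurationError(
                f"kernel {self.pre}->{self.post}: gain must be >= 0, got {self.gain}"
            )
        if self.sigma <= 0:
            raise ConfigurationError(
                f"kernel {self.pre}->{self.post}: sigma must be > 0, got {self.sigma}"
            )
        if self.sign not in _SIGNS:
            raise ConfigurationError(
                f"kernel {self.pre}->{self.post}: sign must be one of {_SIGNS}"
            )
        if self.center_offset != int(self.center_offset):
            raise ConfigurationError("center_offset must be an integer")


@dataclass(frozen=True)
class WeightMatrix:
    """Nonnegative N x N weight matrix; entry [i, j] couples presynaptic j to
    postsynaptic i."""

    values: np.ndarray
    pre: str
    post: str


def gaussian_weight(j, i, sigma: float, center_offset: int = 0):
    """Unit-area Gaussian weight from presynaptic index ``j`` onto
    postsynaptic index ``i``.

    Returns ``1/(sigma*sqrt(2*pi)) * exp(-((j - (i + offset))/sigma)**2 / 2)``.
    Vectorized over ``i`` and ``j``.
    """
    if sigma <= 0:
        raise ConfigurationError(f"sigma must be > 0, got {sigma}")
    j = np.asarray(j, dtype=float)
    i = np.asarray(i, dtype=float)
    z = (j - (i + center_offset)) / sigma
    return np.exp(-0.5 * z * z) / (sigma * np.sqrt(2.0 * np.pi))


def build_weight_matrix(kernel: ProjectionKernel, N: int) -> WeightMatrix:
    """Materialize a kernel as an N x N weight matrix.

    Profiles are truncated at the array edges: no wraparound and no
    renormalization, so boundary rows simply lose the tail mass that falls
    outside the array.
    """
    if N < 1:
        raise ConfigurationError(f"population size must be >= 1, got {N}")
    idx = np.arange(N)
    values = kernel.gain * gaussian_weight(
        idx[np.newaxis, :], idx[:, np.newaxis], kernel.sigma, kernel.center_offset
    )
    return WeightMatrix(values=values, pre=kernel.pre, post=kernel.post)


def loop_character(kernel: ProjectionKernel) -> str:
    """Classify a TRN<->thalamus kernel as ``"closed_equivalent"`` or
    ``"open"``.

    A centered (offset 0) Gaussian is symmetric about the reciprocal index:
    the two implied open loops in opposite directions balance, so the loop is
    functionally closed.  Any nonzero shift leaves an unbalanced open loop.
    """
    return "closed_equivalent" if kernel.center_offset == 0 else "open"
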