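"""Photometric scaling of copula stacks to physical detector units.

Three deterministic, linear steps: rescale arbitrary copula units to a
photon current rate (photons/s) using the diffusion-theory or measured
Phi(rho); integrate consecutive rate-frames over an exposure time into
photons; and convert photons to photo-electrons with the quantum
efficiency.  Being pure scalings/sums, none of them changes kappa^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .copula import FrameStack
from .theory import ParameterError

__all__ = [
    "ExposurePlan",
    "scale_to_photon_rate",
    "integrate_exposure",
    "to_electrons",
]


@dataclass(frozen=True)
class ExposurePlan:
    """An exposure expressed as an integer number of summed frames.

    ``T_x`` is snapped to an exact multiple of the frame bin width:
    T_x = n_summed * t_frame.
    """

    T_x: float
    n_summed: int

    @classmethod
    def from_exposure(cls, T_x: float, t_frame: float) -> "ExposurePlan":
        n = max(1, round(T_x / t_frame))
        return cls(T_x=n * t_frame, n_summed=n)

    def __post_init__(self) -> None:
        if self.n_summed < 1:
            raise ParameterError("n_summed must be >= 1")


def scale_to_photon_rate(stack: FrameStack, phi: float) -> FrameStack:
    """Rescale a copula-unit stack so its grand mean equals Phi (photons/s).

    Divides by the mean over all pixels and frames and multiplies by phi;
    relative spatial/temporal structure (and hence kappa^2) is unchanged.
    """
    if stack.units_tag != "copula-a.u.":
        raise ParameterError("scale_to_photon_rate expects a copula-unit stack")
    mean = stack.data.mean()
    if mean <= 0:
        raise ParameterError("degenerate stack: nonpositive mean")
    return stack.replace(stack.data / mean * phi, units_tag="photons/s")


def integrate_exposure(
    stack: FrameStack, plan: ExposurePlan, extract_all: bool = False
) -> FrameStack:
    """Sum consecutive rate-frames into exposures of T_x = n_summed*t_frame.

    Each output frame is t_frame * sum of ``n_summed`` consecutive
    photons/s frames, i.e. photons accumulated during the exposure.  By
    default one exposure (the first n_summed frames) is extracted; with
    ``extract_all`` every complete non-overlapping block becomes an
    exposure frame.
    """
    if stack.units_tag != "photons/s":
        raise ParameterError("integrate_exposure expects a photons/s stack")
    n = plan.n_summed
    if stack.n_frames < n:
        raise ParameterError(
            f"stack has {stack.n_frames} frames; exposure needs {n}"
        )
    n_exp = stack.n_frames // n if extract_all else 1
    ny, nx = stack.grid
    out = np.empty((ny, nx, n_exp))
    for e in range(n_exp):
        block = stack.data[:, :, e * n : (e + 1) * n]
        out[:, :, e] = stack.t_frame * block.sum(axis=2)
    result = stack.replace(out, units_tag="photons")
    result.meta["T_x"] = plan.T_x
    return result


def to_electrons(stack: FrameStack, QE: float) -> FrameStack:
    """Convert photons to mean photo-electrons via the quantum efficiency.

    Deterministic scaling; the stochastic photon-selection component is
    subsumed in the later shot-noise step.
    """
    if stack.units_tag != "photons":
        raise ParameterError("to_electrons expects a photons stack")
    if not 0.0 < QE <= 1.0:
        raise ParameterError("QE must lie in (0, 1]")
    return stack.replace(stack.data * QE, units_tag="electrons")
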