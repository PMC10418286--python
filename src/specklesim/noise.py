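"""Camera noise model: shot noise and synthesized dark frames.

Four noise terms, parameterized from a camera specification sheet:

* photon shot noise — per-pixel Poisson draws with mean equal to the
  noise-free electron count;
* dark signal non-uniformity (DSNU) — per-pixel logistic draws giving
  each pixel its mean dark signal;
* dark-current shot noise — Poisson draws about the per-pixel DSNU mean;
* read-out noise — normal draws, independent of exposure time.

Dark-current shot plus read-out noise compose a dark frame that is added
to the shot-noised signal; dark-frame subtraction in the contrast module
always uses an independently simulated dark frame, as in a real
calibration.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .copula import FrameStack
from .theory import ParameterError

__all__ = [
    "DetectorSpec",
    "DarkFrame",
    "apply_shot_noise",
    "simulate_dsnu",
    "apply_dark_shot",
    "simulate_read_noise",
    "make_dark_frame",
    "add_detector_noise",
]


@dataclass(frozen=True)
class DetectorSpec:
    """Camera noise/QE parameters as printed on a specification sheet.

    ``dsnu_mean`` is in electrons per exposure, or electrons/second when
    ``rate_mode`` is set (the mean dark current is then multiplied by the
    exposure time).  Variances are in e-^2.
    """

    QE: float
    dsnu_mean: float
    dsnu_var: float
    read_mean: float
    read_var: float
    rate_mode: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.QE <= 1.0:
            raise ParameterError("QE must lie in (0, 1]")
        if self.dsnu_var < 0 or self.read_var < 0:
            raise ParameterError("variances must be nonnegative")

    def dark_current_mean(self, T: float) -> float:
        """Mean dark signal mu(I_delta) in e- for exposure T (seconds)."""
        return self.dsnu_mean * T if self.rate_mode else self.dsnu_mean


_dark_frame_counter = itertools.count()


@dataclass
class DarkFrame:
    """One independent realization of the total dark frame I_d + I_r.

    ``uid`` uniquely identifies the realization for the lifetime of the
    process, so the contrast correction can verify it never subtracts the
    very frame that was added to the signal.
    """

    data: np.ndarray
    spec: DetectorSpec
    T: float
    seed: object = None
    uid: int = field(default_factory=lambda: next(_dark_frame_counter))


def apply_shot_noise(stack: FrameStack, seed) -> FrameStack:
    """Replace each pixel by a Poisson draw with mean = its electron count.

    Applies the defining Poisson property mu = sigma^2 of photon shot
    noise.  Negative inputs (possible only after upstream corrections) are
    clamped to zero with a warning.
    """
    if stack.units_tag != "electrons":
        raise ParameterError("shot noise applies to electron-unit stacks")
    if stack.noise_tag != "~":
        raise ParameterError("shot noise already applied")
    rng = np.random.default_rng(seed)
    data = stack.data
    if np.any(data < 0):
        warnings.warn("negative electron means clamped to 0 for Poisson draw",
                      stacklevel=2)
        data = np.clip(data, 0.0, None)
    out = rng.poisson(data).astype(float)
    return stack.replace(out, noise_tag="s")


def simulate_dsnu(spec: DetectorSpec, grid: tuple[int, int], T: float, seed) -> np.ndarray:
    """Per-pixel dark-signal means I_delta from a logistic distribution.

    The logistic shape parameter follows from the spec-sheet variance,
    s_l = sqrt(3*var)/pi; negatives are clamped to zero since the values
    serve as Poisson means downstream.
    """
    rng = np.random.default_rng(seed)
    mean = spec.dark_current_mean(T)
    if spec.dsnu_var == 0:
        return np.full(grid, max(mean, 0.0))
    s_l = math.sqrt(3.0 * spec.dsnu_var) / math.pi
    draws = rng.logistic(loc=mean, scale=s_l, size=grid)
    return np.clip(draws, 0.0, None)


def apply_dark_shot(dsnu_field: np.ndarray, seed) -> np.ndarray:
    """Dark-current shot noise: Poisson draw about each pixel's dark mean."""
    if np.any(dsnu_field < 0):
        raise ParameterError("dark-signal means must be nonnegative")
    rng = np.random.default_rng(seed)
    return rng.poisson(dsnu_field).astype(float)


def simulate_read_noise(spec: DetectorSpec, grid: tuple[int, int], seed) -> np.ndarray:
    """Read-out signal: normal draws, independent of exposure time.

    Values may be negative; real cameras report the read signal about an
    offset, so no clamping is applied.
    """
    rng = np.random.default_rng(seed)
    return rng.normal(spec.read_mean, math.sqrt(spec.read_var), size=grid)


def make_dark_frame(spec: DetectorSpec, grid: tuple[int, int], T: float, seed) -> DarkFrame:
    """Synthesize one dark frame df = I_d + I_r for exposure T.

    Composes DSNU -> dark shot and adds read-out noise; every call with a
    new seed is an independent realization.
    """
    seq = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_dsnu, s_shot, s_read = seq.spawn(3)
    dsnu = simulate_dsnu(spec, grid, T, s_dsnu)
    dark = apply_dark_shot(dsnu, s_shot)
    read = simulate_read_noise(spec, grid, s_read)
    return DarkFrame(data=dark + read, spec=spec, T=T, seed=seed)


def add_detector_noise(stack: FrameStack, darks) -> FrameStack:
    """Add one dark frame per exposure frame; noise state becomes "sdr".

    ``darks`` is a :class:`DarkFrame` (single-exposure stack) or a list
    with one dark frame per exposure frame.  The identity of each added
    dark frame is recorded so the correction step can verify it subtracts
    an independent realization.
    """
    if stack.noise_tag != "s":
        raise ParameterError("add_detector_noise expects a shot-noised stack")
    if isinstance(darks, DarkFrame):
        darks = [darks]
    if len(darks) != stack.n_frames:
        raise ParameterError(
            f"need {stack.n_frames} dark frames, got {len(darks)}"
        )
    out = stack.data.copy()
    for e, df in enumerate(darks):
        if df.data.shape != stack.grid:
            raise ParameterError("dark frame shape mismatch")
        out[:, :, e] += df.data
    result = stack.replace(out, noise_tag="sdr")
    result.meta["added_dark_ids"] = [df.uid for df in darks]
    return result
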