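"""Speckle contrast estimation, noise corrections, and performance metrics.

kappa^2 is the variance-to-squared-mean ratio of speckle intensity over a
spatial pixel window (one value per exposure/experiment) or a temporal
window of repeated experiments (one value per pixel).  Detector noise
inflates both the mean (dark + read offset) and the variance (shot, dark
shot, read); the corrections here subtract an independently simulated
dark frame to fix the offset and subtract the shot and dark-frame
variances to fix the variance, following the standard camera-noise
correction used in speckle-contrast instruments.

A residual model bias gamma — the difference between the noise-free and
noisy simulated kappa^2 — transfers the simulated noise offset onto the
theoretical semi-infinite kappa^2, producing the model-corrected
kappa^2'.  Accuracy (percent error), precision (CV) and SNR quantify
system performance over repeated experiments.

Variance convention: population variance (divide by the sample count) in
both windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .copula import ExperimentSet, FrameStack
from .noise import DarkFrame
from .theory import ParameterError

__all__ = [
    "Window",
    "ContrastSet",
    "BiasRecord",
    "spatial_kappa2",
    "temporal_kappa2",
    "subtract_dark_offset",
    "corrected_kappa2",
    "bias_gamma",
    "model_corrected_kappa2",
    "accuracy_percent_error",
    "precision_cv",
    "snr",
    "percent_error_vs_attenuation",
]


@dataclass(frozen=True)
class Window:
    """A statistics window: spatial pixel rectangle or temporal repeat set.

    ``extent`` is a half-open rectangle (i0, j0, i1, j1); for a temporal
    window it selects the pixels whose per-pixel statistics are reported.
    ``n_speckles(diameter)`` is the number of independent speckles the
    window samples, pixel count / diameter^2.
    """

    kind: str = "spatial"  # "spatial" (wz) or "temporal" (wt)
    extent: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("spatial", "temporal"):
            raise ParameterError("window kind must be 'spatial' or 'temporal'")

    def slice_of(self, data: np.ndarray) -> np.ndarray:
        if self.extent is None:
            return data
        i0, j0, i1, j1 = self.extent
        if i1 > data.shape[0] or j1 > data.shape[1] or i0 < 0 or j0 < 0:
            raise ParameterError("window extends beyond the frame")
        return data[i0:i1, j0:j1]

    def n_pixels(self, grid: tuple[int, int]) -> int:
        if self.extent is None:
            return grid[0] * grid[1]
        i0, j0, i1, j1 = self.extent
        return (i1 - i0) * (j1 - j0)

    def n_speckles(self, speckle_diameter: float, grid: tuple[int, int]) -> float:
        return self.n_pixels(grid) / speckle_diameter**2


@dataclass
class ContrastSet:
    """kappa^2 values with their window and noise/correction provenance."""

    values: np.ndarray
    noise_state: str = "~"
    window: Window | None = None
    kappa2_hat_ref: float | None = None
    has_negative: bool = False

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        self.has_negative = bool(np.any(self.values < 0))

    def mean(self) -> float:
        return float(self.values.mean())

    def std(self) -> float:
        return float(self.values.std())


@dataclass(frozen=True)
class BiasRecord:
    """Noise bias gamma = mean(noise-free kappa^2) - mean(noisy kappa^2)."""

    gamma: float
    source_states: tuple[str, str] = ("~", "~")
    n_experiments: int = 0


def _window_stats(frame: np.ndarray, window: Window | None):
    sel = frame if window is None else window.slice_of(frame)
    mu = sel.mean()
    var = sel.var()  # population convention
    return mu, var


def spatial_kappa2(stack: FrameStack, window: Window | None = None) -> ContrastSet:
    """Spatial kappa^2 = var/mean^2 over the pixel window, per exposure."""
    if window is not None and window.kind != "spatial":
        raise ParameterError("spatial_kappa2 needs a spatial window")
    vals = np.empty(stack.n_frames)
    for e in range(stack.n_frames):
        mu, var = _window_stats(stack.data[:, :, e], window)
        if mu == 0:
            raise ParameterError("zero mean intensity in window")
        vals[e] = var / mu**2
    return ContrastSet(vals, noise_state=stack.noise_tag, window=window)


def temporal_kappa2(experiments: ExperimentSet, window: Window | None = None) -> ContrastSet:
    """Temporal kappa^2 per pixel: var/mean^2 over repeated experiments.

    Each experiment contributes its (single) exposure frame; statistics
    are taken pixel-wise across experiments, restricted to the window's
    pixel set.
    """
    if experiments.epsilon_N < 2:
        raise ParameterError("temporal kappa^2 needs >= 2 experiments")
    frames = []
    state = None
    for st in experiments.stacks:
        frame = st.data[:, :, 0]
        frames.append(frame if window is None else window.slice_of(frame))
        state = st.noise_tag
    cube = np.stack(frames, axis=0)
    mu = cube.mean(axis=0)
    var = cube.var(axis=0)
    if np.any(mu == 0):
        raise ParameterError("zero mean intensity at some pixel")
    return ContrastSet((var / mu**2).ravel(), noise_state=state, window=window)


def subtract_dark_offset(stack: FrameStack, dark_corr) -> FrameStack:
    """Subtract an independent dark frame: state "sdr" -> "sd'r'".

    ``dark_corr`` must be a fresh realization, never the dark frame that
    was added to the stack — subtracting the identical frame would cancel
    the dark noise exactly, which no real calibration can do.
    """
    if stack.noise_tag != "sdr":
        raise ParameterError("subtract_dark_offset expects an 'sdr' stack")
    darks = [dark_corr] if isinstance(dark_corr, DarkFrame) else list(dark_corr)
    added = set(stack.meta.get("added_dark_ids", []))
    for df in darks:
        if df.uid in added:
            raise ParameterError(
                "dark correction must use an independent dark-frame "
                "realization, not the one added to the signal"
            )
    if len(darks) == 1 and stack.n_frames > 1:
        darks = darks * stack.n_frames
    if len(darks) != stack.n_frames:
        raise ParameterError("need one correction dark frame per exposure")
    out = stack.data.copy()
    for e, df in enumerate(darks):
        out[:, :, e] -= df.data
    result = stack.replace(out, noise_tag="sd'r'")
    result.meta["correction_dark_ids"] = [df.uid for df in darks]
    return result


def corrected_kappa2(
    stack: FrameStack,
    dark_corr=None,
    window: Window | None = None,
) -> ContrastSet:
    """Shot/dark/read-noise corrected kappa^2 (state "s'd'r'").

    Per exposure: (var_signal - var_shot - var_df) / mean^2, where the
    shot variance is estimated as the window mean (Poisson property) and
    var_df is the window variance of the correction dark frame.  Only the
    noise terms actually applied to the stack are subtracted: a noise-free
    "~" stack gets zero subtractions (identical to the uncorrected
    kappa^2); an "s" stack with ``dark_corr=None`` gets the shot-only
    variant (state "s'"); a dark-offset-subtracted "sd'r'" stack with a
    correction dark frame gets the full correction.  Negative results at
    very low signal are retained (not clipped) and flagged.
    """
    if stack.noise_tag == "~":
        if dark_corr is not None:
            raise ParameterError("noise-free stack has no dark frame to correct")
        return spatial_kappa2(stack, window)
    if dark_corr is None:
        if stack.noise_tag != "s":
            raise ParameterError("shot-only correction expects an 's' stack")
        darks = [None] * stack.n_frames
        state = "s'"
    else:
        if stack.noise_tag != "sd'r'":
            raise ParameterError(
                "full correction expects a dark-offset-subtracted stack"
            )
        darks = [dark_corr] if isinstance(dark_corr, DarkFrame) else list(dark_corr)
        if len(darks) == 1 and stack.n_frames > 1:
            darks = darks * stack.n_frames
        state = "s'd'r'"
    vals = np.empty(stack.n_frames)
    for e in range(stack.n_frames):
        mu, var_signal = _window_stats(stack.data[:, :, e], window)
        if mu == 0:
            raise ParameterError("zero mean intensity in window")
        var_shot = mu
        var_df = 0.0
        if darks[e] is not None:
            sel = darks[e].data if window is None else window.slice_of(darks[e].data)
            var_df = sel.var()
        vals[e] = (var_signal - var_shot - var_df) / mu**2
    return ContrastSet(vals, noise_state=state, window=window)


def bias_gamma(ref: ContrastSet, noisy: ContrastSet, n_experiments: int | None = None) -> BiasRecord:
    """gamma = mean(noise-free kappa^2) - mean(noisy kappa^2) over experiments."""
    if ref.noise_state != "~":
        raise ParameterError("reference set must be the noise-free state '~'")
    if ref.values.shape != noisy.values.shape:
        raise ParameterError("ref and noisy sets must come from matched runs")
    n = n_experiments if n_experiments is not None else ref.values.size
    return BiasRecord(
        gamma=float(ref.values.mean() - noisy.values.mean()),
        source_states=("~", noisy.noise_state),
        n_experiments=n,
    )


def model_corrected_kappa2(
    kappa2_hat: float,
    bias: BiasRecord,
    sigma2: float,
    n_draws: int = 500,
    seed=None,
    convention: str = "as-printed",
) -> ContrastSet:
    """Model-corrected kappa^2': normal draws about the theory value.

    The semi-infinite theoretical kappa^2 is shifted by the simulated
    noise bias and spread with the simulated inter-experiment variance:
    mean = kappa^2_hat + gamma ("as-printed") or kappa^2_hat - gamma
    ("bias-added"), variance = sigma^2 of the noisy kappa^2 over
    experiments.
    """
    if sigma2 < 0:
        raise ParameterError("sigma2 must be nonnegative")
    if convention == "as-printed":
        mean = kappa2_hat + bias.gamma
    elif convention == "bias-added":
        mean = kappa2_hat - bias.gamma
    else:
        raise ParameterError("convention must be 'as-printed' or 'bias-added'")
    rng = np.random.default_rng(seed)
    draws = rng.normal(mean, math.sqrt(sigma2), size=n_draws)
    out = ContrastSet(draws, noise_state=bias.source_states[1] + "'",
                      kappa2_hat_ref=kappa2_hat)
    return out


def accuracy_percent_error(values: ContrastSet, kappa2_hat: float) -> float:
    """Accuracy metric: 100 * (mean(kappa^2) - kappa^2_hat) / kappa^2_hat."""
    return 100.0 * (values.mean() - kappa2_hat) / kappa2_hat


def precision_cv(values: ContrastSet) -> float:
    """Precision metric: coefficient of variation, 100 * std / mean."""
    return 100.0 * values.std() / values.mean()


def snr(values: ContrastSet) -> float:
    """Signal-to-noise ratio mean/std (the reciprocal of CV/100)."""
    return values.mean() / values.std()


def percent_error_vs_attenuation(kappa2_by_rate, rates=None) -> np.ndarray:
    """Percent error of kappa^2 against its value at the highest count rate.

    The reference is the kappa^2 measured at the maximum detected
    intensity, not the theoretical value: 100*(k2(I) - k2(I_max))/k2(I_max).
    ``kappa2_by_rate`` is a sequence of kappa^2 values; ``rates`` (same
    length) identifies the maximum-rate entry, defaulting to the last.
    """
    vals = np.asarray(kappa2_by_rate, dtype=float)
    if rates is not None:
        ref = vals[int(np.argmax(np.asarray(rates)))]
    else:
        ref = vals[-1]
    return 100.0 * (vals - ref) / ref
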