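"""Stacks of correlated speckle frames with a prescribed decorrelation law.

Frames are spatially structured speckle patterns (negative-exponential
intensity statistics for beta=1, speckle diameter ``speckle_diameter``
pixels) whose field autocorrelation between frame 1 and frame k follows
the single-cosine-exponential law

    g1_bar(k) = exp{ -((2*pi*m)^2 / 6) * [1 - cos( (pi/2)*(k-1)/(f_N-1) )] }

with the decorrelation parameter ``m`` chosen so that g1_bar equals 0.5 at
the frame index corresponding to the decorrelation time tau_c.

Mechanism: each object-plane pixel carries a zero-mean circular-complex
Gaussian process over the frame index with covariance
C(dk) = exp(-sigma^2*[1 - cos(omega*dk)]), sigma = 2*pi*m/sqrt(6),
omega = (pi/2)/(f_N-1) — the stationary extension of the frame-1 law
above, so exposure integration keeps decorrelating at the same rate
throughout the stack.  C is periodic with period 4*(f_N-1) and positive
definite on that ring (its Fourier coefficients are modified Bessel
values), so frames are synthesized exactly by circulant spectral
synthesis: independent complex-Gaussian mode fields weighted by the
square roots of the FFT eigenvalues of C and mixed by an FFT along the
frame axis.  Every frame is exactly fully developed speckle (jointly
Gaussian fields), and the intensity correlation between frames j and k is
|C(j-k)|^2/C(0)^2 by the Siegert relation.  Imaging onto the detector is
a circular pupil filter in the Fourier plane whose diameter sets the
speckle size.  Partial coherence beta < 1 is emulated by
averaging ~1/beta independent speckle intensity patterns per frame, with
a fractional weight on the last pattern when 1/beta is not an integer so
that the zero-lag contrast is beta in expectation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import next_fast_len as scipy_next_fast_len

from .theory import ParameterError

__all__ = [
    "SpeckleOptics",
    "FrameStack",
    "ExperimentSet",
    "g1_bar",
    "m_from_tauc",
    "simulate_experiment",
    "simulate_integrated_exposure",
    "estimate_g1_from_frames",
]

#: pipeline ordering of the unit tags a stack passes through
UNITS_ORDER = ("copula-a.u.", "photons/s", "photons", "electrons")
NOISE_TAGS = ("~", "s", "sdr", "sd'r'")


@dataclass(frozen=True)
class SpeckleOptics:
    """Imaged speckle size and coherence/detection factor.

    ``speckle_diameter`` is the imaged speckle diameter in detector pixels
    (>= 2 so the speckle is Nyquist sampled); ``beta`` is the coherence
    factor, the T -> 0 limit of kappa^2.
    """

    speckle_diameter: float = 3.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.speckle_diameter < 2:
            raise ParameterError(
                "speckle_diameter must be >= 2 pixels (Nyquist sampling)"
            )
        if not 0.0 < self.beta <= 1.0:
            raise ParameterError("beta must lie in (0, 1]")

    def pixel_width_nm(self, wavelength_nm: float) -> float:
        """Physical width one pixel represents: lambda / speckle_diameter.

        The speckle diameter is ~ the wavelength, so imaging it over
        ``speckle_diameter`` pixels sets the physical pixel pitch.
        """
        return wavelength_nm / self.speckle_diameter

    def pixel_area_cm2(self, wavelength_nm: float) -> float:
        """Physical pixel area (lambda/diameter)^2 in cm^2."""
        return (self.pixel_width_nm(wavelength_nm) * 1e-7) ** 2


@dataclass
class FrameStack:
    """An (i, j, f) stack of speckle frames with units and noise provenance.

    ``units_tag`` walks the pipeline order copula-a.u. -> photons/s ->
    photons -> electrons; ``noise_tag`` is "~" until stochastic detector
    terms are applied.
    """

    data: np.ndarray
    units_tag: str = "copula-a.u."
    noise_tag: str = "~"
    t_frame: float = float("nan")
    rho: float = float("nan")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ParameterError("FrameStack data must be 3-D (i, j, f)")
        if self.units_tag not in UNITS_ORDER:
            raise ParameterError(f"unknown units_tag {self.units_tag!r}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def grid(self) -> tuple[int, int]:
        return self.data.shape[0], self.data.shape[1]

    def replace(self, data: np.ndarray, **kw) -> "FrameStack":
        """New stack with updated data/tags, inheriting metadata."""
        out = FrameStack(
            data=data,
            units_tag=kw.get("units_tag", self.units_tag),
            noise_tag=kw.get("noise_tag", self.noise_tag),
            t_frame=kw.get("t_frame", self.t_frame),
            rho=kw.get("rho", self.rho),
            meta=dict(self.meta),
        )
        return out


@dataclass
class ExperimentSet:
    """Repeated, independently seeded simulations of the same conditions."""

    stacks: list
    seed: object = None

    @property
    def epsilon_N(self) -> int:
        return len(self.stacks)


def g1_bar(k, m: float, f_N: int):
    """Closed-form frame autocorrelation between frame 1 and frame k."""
    k_arr = np.asarray(k, dtype=float)
    if np.any(k_arr < 1) or np.any(k_arr > f_N):
        raise ParameterError("frame index k must lie in [1, f_N]")
    phase = (math.pi / 2.0) * (k_arr - 1.0) / (f_N - 1.0)
    out = np.exp(-((2.0 * math.pi * m) ** 2 / 6.0) * (1.0 - np.cos(phase)))
    return float(out) if np.ndim(k) == 0 else out


def m_from_tauc(tau_c_frames: float, f_N: int) -> float:
    """Decorrelation parameter m such that g1_bar(tau_c_frames) = 0.5.

    Inverts the closed form at k = tau_c_frames:
        m = sqrt( 6 ln 2 / (4 pi^2 [1 - cos((pi/2)(tau_c-1)/(f_N-1))]) )
    """
    if not 1.0 < tau_c_frames < f_N:
        raise ParameterError("tau_c_frames must lie strictly inside (1, f_N)")
    bracket = 1.0 - math.cos(
        (math.pi / 2.0) * (tau_c_frames - 1.0) / (f_N - 1.0)
    )
    return math.sqrt(6.0 * math.log(2.0) / (4.0 * math.pi**2 * bracket))


def _beta_weights(beta: float) -> np.ndarray:
    """Intensity-averaging weights reproducing contrast beta at zero lag.

    Averaging independent unit-exponential intensities I with weights w
    gives kappa^2 = sum(w^2)/sum(w)^2; with n-1 unit weights plus one
    fractional weight the quadratic (n-1 + w^2) = beta*(n-1 + w)^2 is
    solved for w in (0, 1].
    """
    inv = 1.0 / beta
    n = math.ceil(inv - 1e-12)
    if abs(inv - round(inv)) < 1e-9:
        return np.ones(int(round(inv)))
    a = float(n - 1)
    # (beta - 1) w^2 + 2 a beta w + a^2 beta - a = 0
    disc = (2 * a * beta) ** 2 - 4 * (beta - 1) * (a**2 * beta - a)
    w = (-2 * a * beta + math.sqrt(disc)) / (2 * (beta - 1))
    return np.concatenate([np.ones(n - 1), [w]])


def _pupil(grid: tuple[int, int], diameter: float) -> np.ndarray:
    """Circular Fourier-plane pupil giving speckles ~``diameter`` px wide."""
    ny, nx = grid
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    # pupil radius in cycles/pixel: 1/(2*diameter) gives speckle ~ diameter px
    return (fy**2 + fx**2) <= (0.5 / diameter) ** 2


def _accumulate_pattern_intensity(
    rng: np.random.Generator,
    grid: tuple[int, int],
    diameter: float,
    m: float,
    f_N: int,
    out: np.ndarray,
    weight: float = 1.0,
    chunk: int = 256,
) -> None:
    """Add one speckle pattern's per-frame intensities into ``out``.

    ``out`` has shape (ny, nx, f_N) for a full stack, or (ny, nx) to
    accumulate the frame-summed (exposure-integrated) intensity without
    materializing the stack.  Draw order is identical in both modes so a
    given seed yields the same speckle realization.
    """
    ny, nx = grid
    npix = ny * nx
    sigma2 = (2.0 * math.pi * m) ** 2 / 6.0
    omega = (math.pi / 2.0) / (f_N - 1.0)
    # Circulant ring: the full period 4*(f_N-1) is exactly positive
    # definite, but when the covariance support is much shorter than f_N a
    # standard circulant embedding on a just-long-enough ring is
    # equivalent (wrapped lags carry ~0 covariance) and far cheaper.
    full = 4 * (f_N - 1)
    c_direct = np.exp(-sigma2 * (1.0 - np.cos(omega * np.arange(f_N))))
    support = int(np.argmax(c_direct < 1e-16)) or f_N
    L = min(full, int(scipy_next_fast_len(f_N + support)))
    dist = np.minimum(np.arange(L), L - np.arange(L))
    cov = np.exp(-sigma2 * (1.0 - np.cos(omega * dist)))
    lam = np.fft.fft(cov).real
    lam = np.clip(lam, 0.0, None)
    keep = np.flatnonzero(lam > 1e-14 * lam.max())
    amp = np.sqrt(lam[keep] / L)

    # object-plane frames: temporal FFT of weighted Gaussian mode fields
    obj = np.zeros((f_N, npix), dtype=complex)
    block = 4096
    for p0 in range(0, npix, block):
        nb = min(block, npix - p0)
        modes = np.zeros((L, nb), dtype=complex)
        draws = rng.standard_normal((keep.size, nb, 2))
        modes[keep] = amp[:, None] * (draws[..., 0] + 1j * draws[..., 1]) / math.sqrt(2.0)
        obj[:, p0 : p0 + nb] = np.fft.fft(modes, axis=0)[:f_N]
    obj = obj.reshape(f_N, ny, nx)

    pupil = _pupil(grid, diameter)
    integrate = out.ndim == 2
    for k0 in range(0, f_N, chunk):
        fields = np.fft.ifft2(
            np.fft.fft2(obj[k0 : k0 + chunk], axes=(1, 2)) * pupil, axes=(1, 2)
        )
        inten = np.abs(fields) ** 2
        if integrate:
            out += weight * inten.sum(axis=0)
        else:
            out[:, :, k0 : k0 + chunk] += weight * np.moveaxis(inten, 0, 2)


def simulate_experiment(
    tau_c: float,
    t_frame: float,
    f_N: int,
    grid: tuple[int, int],
    optics: SpeckleOptics,
    seed,
    rho: float = float("nan"),
) -> FrameStack:
    """Simulate one experiment: f_N correlated speckle frames (copula units).

    ``tau_c`` and ``t_frame`` are in seconds; the decorrelation time in
    frame-index units tau_c/t_frame must lie strictly inside (1, f_N).
    Identical seeds give bit-identical stacks.
    """
    rng = np.random.default_rng(seed)
    tau_c_frames = tau_c / t_frame
    m = m_from_tauc(tau_c_frames, f_N)
    ny, nx = grid
    if ny * nx < 25 * optics.speckle_diameter**2:
        warnings.warn(
            "grid holds fewer than 25 speckles; contrast statistics will be "
            "poorly sampled",
            stacklevel=2,
        )
    weights = _beta_weights(optics.beta)
    intensity = np.zeros((ny, nx, f_N))
    for w in weights:
        _accumulate_pattern_intensity(
            rng, grid, optics.speckle_diameter, m, f_N, intensity, weight=w
        )
    intensity /= weights.sum()
    return FrameStack(
        data=intensity,
        units_tag="copula-a.u.",
        noise_tag="~",
        t_frame=t_frame,
        rho=rho,
        meta={"tau_c": tau_c, "m": m, "seed": seed, "beta": optics.beta},
    )


def simulate_integrated_exposure(
    tau_c: float,
    t_frame: float,
    f_N: int,
    grid: tuple[int, int],
    optics: SpeckleOptics,
    seed,
    chunk: int = 512,
) -> np.ndarray:
    """Frame-summed intensity of one experiment, normalized to unit mean.

    Equivalent to summing the frames of :func:`simulate_experiment` (same
    seed, same draw order) and dividing by the stack mean, but accumulated
    in chunks so long exposures (large f_N) never materialize the full
    stack.  Returns an (i, j) array with mean 1 suitable for direct
    photometric rescaling.
    """
    rng = np.random.default_rng(seed)
    m = m_from_tauc(tau_c / t_frame, f_N)
    weights = _beta_weights(optics.beta)
    total = np.zeros(grid)
    for w in weights:
        _accumulate_pattern_intensity(
            rng, grid, optics.speckle_diameter, m, f_N, total,
            weight=w, chunk=chunk,
        )
    total /= weights.sum()
    return total / total.mean()


def intensity_correlation_curve(stack: FrameStack) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of intensity between frame 1 and each frame k.

    For speckle obeying the Siegert relation this equals |g1|^2, so it is
    the natural scale on which to average the decorrelation measurement
    over repeated experiments (its sampling noise is additive and
    symmetric, unlike after a square root).  Returns ``(k_indices, corr)``
    with corr = 1 at k = 1.
    """
    if stack.n_frames < 2:
        raise ParameterError("need at least 2 frames to estimate g1")
    data = stack.data.reshape(-1, stack.n_frames)
    ref = data[:, 0]
    ref_c = ref - ref.mean()
    denom_ref = math.sqrt((ref_c**2).mean())
    ks = np.arange(1, stack.n_frames + 1)
    out = np.empty(stack.n_frames)
    for idx in range(stack.n_frames):
        cur = data[:, idx]
        cur_c = cur - cur.mean()
        denom = denom_ref * math.sqrt((cur_c**2).mean())
        if denom == 0:
            out[idx] = 1.0 if np.array_equal(cur, ref) else 0.0
            continue
        corr = (ref_c * cur_c).mean() / denom
        out[idx] = corr
    out[0] = 1.0
    return ks, out


def estimate_g1_from_frames(stack: FrameStack) -> tuple[np.ndarray, np.ndarray]:
    """Measured field autocorrelation between frame 1 and each frame k.

    Signed square root of the intensity correlation (Siegert relation);
    the sign keeps sampling noise about zero symmetric so it averages out
    over repeated experiments.  Value 1 at k = 1.
    """
    ks, corr = intensity_correlation_curve(stack)
    return ks, np.copysign(np.sqrt(np.abs(corr)), corr)
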