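"""Closed-form semi-infinite correlation-diffusion-equation (CDE) quantities.

The electric-field autocorrelation of diffuse speckle measured at a
source-detector separation ``rho`` on a semi-infinite, multiply scattering
medium is given by the Green's function of the correlation diffusion
equation with an extrapolated-boundary image source.  From it this module
derives the decorrelation time ``tau_c`` (the lag at which g1 decays to
0.5), the detected photon current rate ``Phi(rho)`` from photon-diffusion
theory, and the theoretical squared speckle contrast ``kappa2_hat(T)``
obtained by integrating g1**2 over the camera exposure.

All lengths are in cm, times in seconds, ``wavelength`` in nm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "OpticalMedium",
    "Geometry",
    "TheoryCurve",
    "effective_reflection_coefficient",
    "semi_infinite_g1",
    "decorrelation_time",
    "photon_current_rate",
    "kappa2_from_g1",
    "kappa2_hat",
]

#: speed of light in vacuum (cm/s)
C_VACUUM_CM_S = 2.99792458e10
#: Planck constant (J s)
PLANCK_J_S = 6.62607015e-34


class ParameterError(ValueError):
    """Raised when a physical parameter violates its domain."""


@dataclass(frozen=True)
class OpticalMedium:
    """Tissue-like optical and dynamic properties feeding the CDE.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient (1/cm).
    mu_s_prime : float
        Reduced scattering coefficient (1/cm).
    n_index : float
        Refractive index of the medium.
    alpha_Db : float
        Effective Brownian diffusion coefficient of the moving scatterers
        weighted by the moving fraction, alpha*Db (cm^2/s). Acts as the
        blood-flow index.
    wavelength : float
        Source wavelength (nm).
    """

    mu_a: float
    mu_s_prime: float
    n_index: float
    alpha_Db: float
    wavelength: float

    def __post_init__(self) -> None:
        if self.mu_a <= 0 or self.mu_s_prime <= 0:
            raise ParameterError("mu_a and mu_s_prime must be positive")
        if self.wavelength <= 0:
            raise ParameterError("wavelength must be positive")
        if self.alpha_Db < 0:
            raise ParameterError("alpha_Db must be nonnegative")
        if self.n_index <= 0:
            raise ParameterError("n_index must be positive")
        if self.mu_s_prime < 10 * self.mu_a:
            warnings.warn(
                "mu_s_prime < 10*mu_a: photon-diffusion approximation is "
                "of questionable validity for this medium",
                stacklevel=2,
            )

    # -- derived quantities -------------------------------------------------
    @property
    def ltr(self) -> float:
        """Transport mean free path 1/(mu_a + mu_s_prime) (cm)."""
        return 1.0 / (self.mu_a + self.mu_s_prime)

    @property
    def k0(self) -> float:
        """Optical wavenumber in the medium, 2*pi*n/lambda (1/cm)."""
        return 2.0 * math.pi * self.n_index / (self.wavelength * 1e-7)

    @property
    def v(self) -> float:
        """Speed of light in the medium (cm/s)."""
        return C_VACUUM_CM_S / self.n_index

    @property
    def D(self) -> float:
        """Photon diffusion coefficient v/(3*(mu_a + mu_s_prime)) (cm^2/s)."""
        return self.v / (3.0 * (self.mu_a + self.mu_s_prime))

    @property
    def mu_eff(self) -> float:
        """Effective attenuation coefficient sqrt(3*mu_a*(mu_a+mu_s_prime))."""
        return math.sqrt(3.0 * self.mu_a * (self.mu_a + self.mu_s_prime))

    @property
    def zb(self) -> float:
        """Extrapolated-boundary distance (cm)."""
        reff = effective_reflection_coefficient(self.n_index)
        return 2.0 * self.ltr * (1.0 + reff) / (3.0 * (1.0 - reff))


@dataclass(frozen=True)
class Geometry:
    """Source-detector geometry and photometric scale factors."""

    rho: float  # source-detector separation (cm)
    source_irradiance: float  # S, source term (W/cm^3)
    pixel_area: float  # A, physical pixel area (cm^2)

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ParameterError("rho must be positive")
        if self.source_irradiance <= 0:
            raise ParameterError("source_irradiance must be positive")
        if self.pixel_area <= 0:
            raise ParameterError("pixel_area must be positive")


@dataclass
class TheoryCurve:
    """A g1 decay sampled on a lag grid, with its decorrelation time."""

    tau_grid: np.ndarray
    g1_values: np.ndarray
    tau_c: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.tau_grid = np.asarray(self.tau_grid, dtype=float)
        self.g1_values = np.asarray(self.g1_values, dtype=float)
        if self.tau_grid.shape != self.g1_values.shape:
            raise ParameterError("tau_grid and g1_values must share shape")


def effective_reflection_coefficient(n: float) -> float:
    """Effective Fresnel reflection coefficient for a tissue/air boundary.

    Standard polynomial approximation in the relative refractive index
    n = n_in/n_out; used to place the extrapolated boundary.
    """
    return -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n


def _source_distances(medium: OpticalMedium, rho: float) -> tuple[float, float]:
    """Distances from the detector to the real and image isotropic sources."""
    ltr, zb = medium.ltr, medium.zb
    r1 = math.hypot(ltr, rho)
    rb = math.hypot(ltr + 2.0 * zb, rho)
    return r1, rb


def semi_infinite_g1(medium: OpticalMedium, rho: float, tau) -> np.ndarray | float:
    """Normalized field autocorrelation g1(rho, tau) for a semi-infinite medium.

    The unnormalized G1 is the two-term (real + extrapolated-boundary image
    source) Green's function with dynamic attenuation

        K(tau)^2 = 3*mu_a*mu_s' + 6*mu_s'^2*k0^2*alpha_Db*tau,

    and the returned value is G1(rho, tau)/G1(rho, 0), which is 1 at tau=0
    and decays monotonically.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ParameterError("tau must be nonnegative")
    r1, rb = _source_distances(medium, rho)

    k2 = (
        3.0 * medium.mu_a * medium.mu_s_prime
        + 6.0 * medium.mu_s_prime**2 * medium.k0**2 * medium.alpha_Db * tau_arr
    )
    k = np.sqrt(k2)

    def _g(kk):
        return np.exp(-kk * r1) / r1 - np.exp(-kk * rb) / rb

    g0 = _g(math.sqrt(3.0 * medium.mu_a * medium.mu_s_prime))
    out = _g(k) / g0
    if np.ndim(tau) == 0:
        return float(out)
    return out


def decorrelation_time(
    medium: OpticalMedium,
    rho: float,
    bracket: tuple[float, float] = (1e-12, 10.0),
) -> float:
    """Lag tau_c at which g1(rho, tau_c) = 0.5.

    g1 is strictly monotone in tau so a sign-changing bracket is refined by
    Brent's method to |g1 - 0.5| < 1e-9.
    """
    lo, hi = bracket
    f = lambda t: semi_infinite_g1(medium, rho, t) - 0.5
    if f(lo) <= 0 or f(hi) >= 0:
        raise ParameterError(
            f"g1 does not cross 0.5 inside the search bracket {bracket}"
        )
    return float(brentq(f, lo, hi, xtol=1e-18, rtol=1e-12))


def photon_current_rate(medium: OpticalMedium, geom: Geometry) -> float:
    """Detected photon current rate Phi(rho) in photons/second per pixel.

    Photon-diffusion fluence for a semi-infinite medium (real source at
    depth ltr, image source behind the extrapolated boundary), attenuated
    with mu_eff, scaled by the source term S, converted from watts to
    photons/second by dividing by the photon energy h*c/lambda, and
    multiplied by the pixel area.
    """
    r1, rb = _source_distances(medium, geom.rho)
    mu_eff = medium.mu_eff
    fluence = (
        medium.v
        * geom.source_irradiance
        / (4.0 * math.pi * medium.D)
        * (math.exp(-mu_eff * r1) / r1 - math.exp(-mu_eff * rb) / rb)
    )
    photon_energy = PLANCK_J_S * C_VACUUM_CM_S / (medium.wavelength * 1e-7)
    return fluence * geom.pixel_area / photon_energy


def kappa2_from_g1(g1_func, T: float, beta: float) -> float:
    """Squared speckle contrast from an arbitrary g1(tau) decay.

        kappa2(T) = (2*beta/T) * Integral_0^T (1 - tau/T) * g1(tau)^2 dtau

    ``g1_func`` maps a lag in seconds to the normalized field correlation.
    """
    if T <= 0:
        raise ParameterError("exposure T must be positive")
    if not 0.0 < beta <= 1.0:
        raise ParameterError("beta must lie in (0, 1]")
    integrand = lambda t: (1.0 - t / T) * g1_func(t) ** 2
    val, err = quad(integrand, 0.0, T, epsabs=0.0, epsrel=1e-10, limit=200)
    if not math.isfinite(val) or (val > 0 and err > 1e-6 * val):
        raise RuntimeError("exposure-integral quadrature did not converge")
    return 2.0 * beta / T * val


def kappa2_hat(medium: OpticalMedium, rho: float, T: float, beta: float) -> float:
    """Theoretical kappa^2 for the semi-infinite CDE g1 at exposure T."""
    return kappa2_from_g1(lambda t: semi_infinite_g1(medium, rho, t), T, beta)
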