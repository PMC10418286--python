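"""Structured simulation configuration and strict YAML loading.

One config drives the full six-step workflow: decorrelation source
(either a semi-infinite optical medium or a directly specified tau_c),
camera spec or preset, speckle optics, geometry/acquisition lists, the
sampling windows, and the master seed every stochastic stage derives its
seed from.  Unknown keys anywhere in the file are rejected.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .contrast import Window
from .copula import SpeckleOptics
from .noise import DetectorSpec
from .presets import get_detector
from .theory import OpticalMedium, ParameterError

__all__ = ["SimulationConfig", "load_config", "config_from_dict"]


@dataclass
class SimulationConfig:
    """Everything needed to run (and exactly reproduce) a simulation."""

    detector: DetectorSpec
    optics: SpeckleOptics
    rho_values: list = field(default_factory=lambda: [2.0])
    exposures: list = field(default_factory=lambda: [5e-3])
    medium: OpticalMedium | None = None
    tau_c: float | None = None
    phi: float | None = None  # photons/s, overrides diffusion-theory Phi
    source_irradiance: float = 1.0  # S (W/cm^3) for diffusion-theory Phi
    frames_per_tauc: int = 10  # time resolution of the g1 decay
    grid: tuple[int, int] = (100, 100)
    window: Window | None = None
    epsilon_N: int = 100
    n_draws: int = 500
    master_seed: int = 0
    gamma_convention: str = "as-printed"

    def __post_init__(self) -> None:
        if (self.medium is None) == (self.tau_c is None):
            raise ParameterError(
                "exactly one of 'medium' and 'tau_c' must be given"
            )
        if self.medium is None and self.phi is None:
            # without a medium there is no diffusion theory to supply Phi
            raise ParameterError(
                "a direct tau_c requires an explicit phi (photons/s)"
            )
        if not self.rho_values or not self.exposures:
            raise ParameterError("rho_values and exposures must be nonempty")
        if self.epsilon_N < 2:
            raise ParameterError("epsilon_N must be >= 2")

    def hash(self) -> str:
        """Stable digest of the configuration for output provenance."""
        def _enc(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return asdict(obj)
            return str(obj)

        payload = json.dumps(asdict(self), default=_enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _strict_build(cls, d: dict, context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise ParameterError(
            f"unknown key(s) {sorted(unknown)} in {context}; "
            f"allowed: {sorted(allowed)}"
        )
    return cls(**d)


def config_from_dict(raw: dict) -> SimulationConfig:
    """Build a config from a parsed mapping, rejecting unknown keys."""
    top_allowed = {
        "medium", "tau_c", "phi", "detector", "optics", "geometry",
        "sampling", "master_seed", "gamma_convention",
    }
    unknown = set(raw) - top_allowed
    if unknown:
        raise ParameterError(
            f"unknown top-level key(s) {sorted(unknown)}; "
            f"allowed: {sorted(top_allowed)}"
        )

    medium = None
    if "medium" in raw:
        medium = _strict_build(OpticalMedium, dict(raw["medium"]), "medium")

    det_raw = raw.get("detector")
    if det_raw is None:
        raise ParameterError("config requires a 'detector' (preset or mapping)")
    if isinstance(det_raw, str):
        detector = get_detector(det_raw)
    else:
        detector = _strict_build(DetectorSpec, dict(det_raw), "detector")

    optics = _strict_build(
        SpeckleOptics, dict(raw.get("optics", {})), "optics"
    )

    geom = dict(raw.get("geometry", {}))
    geom_allowed = {"rho", "exposures", "source_irradiance", "frames_per_tauc"}
    unknown = set(geom) - geom_allowed
    if unknown:
        raise ParameterError(f"unknown key(s) {sorted(unknown)} in geometry")

    samp = dict(raw.get("sampling", {}))
    samp_allowed = {"grid", "window", "epsilon_N", "n_draws"}
    unknown = set(samp) - samp_allowed
    if unknown:
        raise ParameterError(f"unknown key(s) {sorted(unknown)} in sampling")
    window = None
    if samp.get("window") is not None:
        window = Window(kind="spatial", extent=tuple(samp["window"]))

    return SimulationConfig(
        detector=detector,
        optics=optics,
        rho_values=list(geom.get("rho", [2.0])),
        exposures=list(geom.get("exposures", [5e-3])),
        medium=medium,
        tau_c=raw.get("tau_c"),
        phi=raw.get("phi"),
        source_irradiance=float(geom.get("source_irradiance", 1.0)),
        frames_per_tauc=int(geom.get("frames_per_tauc", 10)),
        grid=tuple(samp.get("grid", (100, 100))),
        window=window,
        epsilon_N=int(samp.get("epsilon_N", 100)),
        n_draws=int(samp.get("n_draws", 500)),
        master_seed=int(raw.get("master_seed", 0)),
        gamma_convention=raw.get("gamma_convention", "as-printed"),
    )


def load_config(path) -> SimulationConfig:
    """Load a YAML configuration file (strict schema)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParameterError("config file must contain a mapping")
    return config_from_dict(raw)
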