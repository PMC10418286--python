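"""Bundled camera and study presets.

Detector values are the manufacturer/measured specification numbers for
three cameras commonly used in speckle-contrast instruments; the study
presets additionally carry the speckle/sampling settings each camera was
characterized with (decorrelation time, speckle size, coherence factor,
number of repeated experiments, spatial window).
"""

from __future__ import annotations

from dataclasses import dataclass

from .copula import SpeckleOptics
from .noise import DetectorSpec

__all__ = ["DETECTOR_PRESETS", "STUDY_PRESETS", "get_detector", "StudyPreset"]

DETECTOR_PRESETS = {
    # Hamamatsu Orca Fusion-C14440-20UP. QE for this camera is folded into
    # the measured electron rate (supply Phi directly as e-/s), hence 1.0.
    "orca_fusion": DetectorSpec(
        QE=1.0,
        dsnu_mean=0.0025,
        dsnu_var=0.16,
        read_mean=0.93,
        read_var=0.24,
        rate_mode=False,
        name="orca_fusion",
    ),
    # Hamamatsu Orca Flash4.0 v3; DSNU mean is specified as a rate (e-/s).
    "orca_flash": DetectorSpec(
        QE=0.542,
        dsnu_mean=0.06,
        dsnu_var=0.16,
        read_mean=2.9,
        read_var=0.1,
        rate_mode=True,
        name="orca_flash",
    ),
    # Basler daA1920-160um.
    "basler_daA1920": DetectorSpec(
        QE=0.29,
        dsnu_mean=130.9,
        dsnu_var=0.8,
        read_mean=2.15,
        read_var=2.28,
        rate_mode=False,
        name="basler_daA1920",
    ),
}


@dataclass(frozen=True)
class StudyPreset:
    """Speckle/sampling conditions a camera was characterized with."""

    detector: DetectorSpec
    optics: SpeckleOptics
    tau_c: float | None  # directly specified decorrelation time (s), if any
    epsilon_N: int
    window: tuple[int, int]


STUDY_PRESETS = {
    "orca_fusion": StudyPreset(
        detector=DETECTOR_PRESETS["orca_fusion"],
        optics=SpeckleOptics(speckle_diameter=4, beta=0.2),
        tau_c=4.18e-5,
        epsilon_N=100,
        window=(32, 32),
    ),
    "orca_flash": StudyPreset(
        detector=DETECTOR_PRESETS["orca_flash"],
        optics=SpeckleOptics(speckle_diameter=3, beta=0.5),
        tau_c=None,  # derived from the semi-infinite CDE medium
        epsilon_N=100,
        window=(100, 100),
    ),
    "basler_daA1920": StudyPreset(
        detector=DETECTOR_PRESETS["basler_daA1920"],
        optics=SpeckleOptics(speckle_diameter=5, beta=0.2),
        tau_c=1.46e-5,
        epsilon_N=100,
        window=(100, 100),
    ),
}


def get_detector(name_or_spec) -> DetectorSpec:
    """Resolve a preset name or pass a DetectorSpec through."""
    if isinstance(name_or_spec, DetectorSpec):
        return name_or_spec
    try:
        return DETECTOR_PRESETS[name_or_spec]
    except KeyError:
        raise KeyError(
            f"unknown detector preset {name_or_spec!r}; "
            f"available: {sorted(DETECTOR_PRESETS)}"
        ) from None
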