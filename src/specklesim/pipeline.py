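"""Config-driven orchestration of the full speckle-contrast workflow.

For every swept (rho, exposure) pair: derive tau_c from the semi-infinite
CDE (or take it directly), simulate ``epsilon_N`` independent experiments
of correlated speckle frames, scale them photometrically, integrate the
exposure, convert to electrons, apply the detector noise states, estimate
kappa^2 in each state, and aggregate the bias, model-corrected kappa^2,
accuracy, precision and SNR metrics into one table row.

Every stochastic call derives its seed deterministically from the master
seed plus (sweep index, exposure index, experiment index, stage), so an
identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import contrast as ct
from .config import SimulationConfig
from .copula import (FrameStack, SpeckleOptics, simulate_experiment,
                     simulate_integrated_exposure)
from .noise import (DetectorSpec, add_detector_noise, apply_shot_noise,
                    make_dark_frame)
from .photometry import ExposurePlan, integrate_exposure, scale_to_photon_rate, to_electrons
from .presets import STUDY_PRESETS
from .theory import (Geometry, ParameterError, decorrelation_time,
                     kappa2_from_g1, kappa2_hat, photon_current_rate)

__all__ = [
    "SweepResult",
    "run_pipeline",
    "run_count_rate_study",
    "validate_against_reference",
    "full_frame_acquisition_rate",
]

# stage identifiers folded into the seed derivation
_STAGE_SPECKLE, _STAGE_SHOT, _STAGE_DARK_ADD, _STAGE_DARK_CORR, _STAGE_MODEL = range(5)


@dataclass
class SweepResult:
    """Tabulated accuracy/precision/SNR over the swept parameter."""

    table: pd.DataFrame
    master_seed: int
    config_hash: str = ""
    threshold_rate: float | None = None  # count-rate studies only

    def to_csv(self, path) -> None:
        """Write the table with a provenance header comment."""
        with open(path, "w") as fh:
            fh.write(f"# specklesim sweep result\n")
            fh.write(f"# master_seed={self.master_seed} config_hash={self.config_hash}\n")
            if self.threshold_rate is not None:
                fh.write(f"# threshold_rate_e_per_px_s={self.threshold_rate}\n")
            self.table.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "SweepResult":
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                body_start = i + 1
                for token in line[1:].split():
                    if "=" in token:
                        k, v = token.split("=", 1)
                        meta[k] = v
            else:
                break
        from io import StringIO

        table = pd.read_csv(StringIO("".join(lines[body_start:])))
        thr = meta.get("threshold_rate_e_per_px_s")
        return cls(
            table=table,
            master_seed=int(meta.get("master_seed", -1)),
            config_hash=meta.get("config_hash", ""),
            threshold_rate=float(thr) if thr not in (None, "None") else None,
        )


def full_frame_acquisition_rate(n_sources: int, T: float) -> float:
    """Full kappa^2 acquisition rate (Hz) cycling n source positions.

    One full frame requires one exposure of length T at each source
    position, so the rate is 1/(n_sources * T); e.g. nine positions at
    T = 5 ms give 22.2 Hz.
    """
    if n_sources < 1 or T <= 0:
        raise ParameterError("need n_sources >= 1 and T > 0")
    return 1.0 / (n_sources * T)


def _seed(cfg_seed: int, *path: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(cfg_seed), *map(int, path)])


def _theory_kappa2(config: SimulationConfig, rho: float, tau_c: float, T: float) -> float:
    """Theoretical kappa^2: semi-infinite CDE if a medium is given, else a
    single-exponential decay pinned to g1(tau_c) = 0.5."""
    if config.medium is not None:
        return kappa2_hat(config.medium, rho, T, config.optics.beta)
    lam = math.log(2.0) / tau_c
    return kappa2_from_g1(lambda t: math.exp(-lam * t), T, config.optics.beta)


def _frame_plan(tau_c: float, T: float, frames_per_tauc: int) -> tuple[float, ExposurePlan, int]:
    """Pick t_frame, the exposure plan, and the number of frames to simulate.

    t_frame = tau_c/frames_per_tauc resolves the decay; the simulated
    frame count covers one exposure and always extends past the 0.5
    crossing so the copula parameter is well defined.
    """
    t_frame = tau_c / frames_per_tauc
    plan = ExposurePlan.from_exposure(T, t_frame)
    f_N = max(plan.n_summed, frames_per_tauc + 2)
    return t_frame, plan, f_N


def run_pipeline(config: SimulationConfig) -> SweepResult:
    """Execute the six-step workflow for every (rho, exposure) pair."""
    rows = []
    for r_idx, rho in enumerate(config.rho_values):
        if config.tau_c is not None:
            tau_c = float(config.tau_c)
        else:
            tau_c = decorrelation_time(config.medium, rho)
        if config.phi is not None:
            phi = float(config.phi)
        else:
            geom = Geometry(
                rho=rho,
                source_irradiance=config.source_irradiance,
                pixel_area=config.optics.pixel_area_cm2(config.medium.wavelength),
            )
            phi = photon_current_rate(config.medium, geom)
        for t_idx, T in enumerate(config.exposures):
            rows.append(
                _simulate_condition(config, r_idx, t_idx, rho, tau_c, phi, T)
            )
    return SweepResult(
        table=pd.DataFrame(rows),
        master_seed=config.master_seed,
        config_hash=config.hash(),
    )


def _simulate_condition(
    config: SimulationConfig,
    r_idx: int,
    t_idx: int,
    rho: float,
    tau_c: float,
    phi: float,
    T: float,
) -> dict:
    det = config.detector
    t_frame, plan, f_N = _frame_plan(tau_c, T, config.frames_per_tauc)
    window = config.window

    k2 = {state: [] for state in ("~", "s", "sdr", "s'd'r'")}
    mean_e = []
    for eps in range(config.epsilon_N):
        stack = simulate_experiment(
            tau_c, t_frame, f_N, config.grid, config.optics,
            _seed(config.master_seed, r_idx, t_idx, eps, _STAGE_SPECKLE),
            rho=rho,
        )
        rate = scale_to_photon_rate(stack, phi)
        photons = integrate_exposure(rate, plan)
        electrons = to_electrons(photons, det.QE)
        shot = apply_shot_noise(
            electrons, _seed(config.master_seed, r_idx, t_idx, eps, _STAGE_SHOT)
        )
        dark_add = make_dark_frame(
            det, config.grid, plan.T_x,
            _seed(config.master_seed, r_idx, t_idx, eps, _STAGE_DARK_ADD),
        )
        sdr = add_detector_noise(shot, dark_add)
        dark_corr = make_dark_frame(
            det, config.grid, plan.T_x,
            _seed(config.master_seed, r_idx, t_idx, eps, _STAGE_DARK_CORR),
        )
        sdpr = ct.subtract_dark_offset(sdr, dark_corr)

        k2["~"].append(ct.spatial_kappa2(electrons, window).values[0])
        k2["s"].append(ct.spatial_kappa2(shot, window).values[0])
        k2["sdr"].append(ct.spatial_kappa2(sdr, window).values[0])
        k2["s'd'r'"].append(
            ct.corrected_kappa2(sdpr, dark_corr, window).values[0]
        )
        sel = sdr.data[:, :, 0] if window is None else window.slice_of(sdr.data[:, :, 0])
        mean_e.append(sel.mean())

    sets = {
        state: ct.ContrastSet(np.array(vals), noise_state=state, window=window)
        for state, vals in k2.items()
    }
    k2_hat = _theory_kappa2(config, rho, tau_c, plan.T_x)
    bias = ct.bias_gamma(sets["~"], sets["s'd'r'"])
    model = ct.model_corrected_kappa2(
        k2_hat,
        bias,
        sigma2=sets["s'd'r'"].values.var(),
        n_draws=config.n_draws,
        seed=_seed(config.master_seed, r_idx, t_idx, 0, _STAGE_MODEL),
        convention=config.gamma_convention,
    )
    return {
        "rho_cm": rho,
        "T_s": plan.T_x,
        "tau_c_s": tau_c,
        "t_frame_s": t_frame,
        "f_N": f_N,
        "phi_photons_s": phi,
        "mean_e_per_pixel": float(np.mean(mean_e)),
        "kappa2_hat": k2_hat,
        "k2_ideal_mean": sets["~"].mean(),
        "k2_ideal_std": sets["~"].std(),
        "k2_s_mean": sets["s"].mean(),
        "k2_s_std": sets["s"].std(),
        "k2_sdr_mean": sets["sdr"].mean(),
        "k2_sdr_std": sets["sdr"].std(),
        "k2_corr_mean": sets["s'd'r'"].mean(),
        "k2_corr_std": sets["s'd'r'"].std(),
        "gamma": bias.gamma,
        "k2_model_mean": model.mean(),
        "k2_model_std": model.std(),
        "percent_error": ct.accuracy_percent_error(model, k2_hat),
        "cv_percent": ct.precision_cv(model),
        "snr": ct.snr(model),
    }


def run_count_rate_study(
    rates,
    preset: str = "basler_daA1920",
    T: float = 5e-3,
    grid: tuple[int, int] = (33, 33),
    epsilon_N: int | None = None,
    frames_per_tauc: int = 10,
    master_seed: int = 0,
    error_threshold: float = 5.0,
    tau_c: float | None = None,
    optics: SpeckleOptics | None = None,
    detector: DetectorSpec | None = None,
) -> SweepResult:
    """Minimum detected count rate for accurate kappa^2 (design study).

    The mean detected electron count rate (e-/pixel/s) is set directly —
    as with an attenuator in front of the detector — bypassing the
    diffusion-theory Phi.  Because the photometric chain is linear, each
    experiment's copula exposure pattern is simulated once and rescaled
    per rate before the stochastic detector stages.  Accuracy is judged
    against the kappa^2 at the highest rate; the reported
    ``threshold_rate`` is the lowest rate from which the noise-corrected
    percent error stays within ``error_threshold``.
    """
    study = STUDY_PRESETS[preset]
    det = detector if detector is not None else study.detector
    opt = optics if optics is not None else study.optics
    tc = tau_c if tau_c is not None else study.tau_c
    n_eps = epsilon_N if epsilon_N is not None else study.epsilon_N
    if tc is None:
        raise ParameterError("count-rate study needs a direct tau_c")

    t_frame = tc / frames_per_tauc
    f_N = max(1, round(T / t_frame))
    T_x = f_N * t_frame
    rates = np.sort(np.asarray(rates, dtype=float))

    patterns = [
        simulate_integrated_exposure(
            tc, t_frame, f_N, grid, opt,
            _seed(master_seed, 0, 0, eps, _STAGE_SPECKLE),
        )
        for eps in range(n_eps)
    ]

    rows = []
    for rate_idx, rate in enumerate(rates):
        mean_e_target = rate * T_x
        vals_corr, vals_ideal, vals_sdr = [], [], []
        for eps, pattern in enumerate(patterns):
            electrons = FrameStack(
                (pattern * mean_e_target)[:, :, None],
                units_tag="electrons",
                t_frame=t_frame,
            )
            shot = apply_shot_noise(
                electrons,
                _seed(master_seed, rate_idx, 1, eps, _STAGE_SHOT),
            )
            dark_add = make_dark_frame(
                det, grid, T_x,
                _seed(master_seed, rate_idx, 1, eps, _STAGE_DARK_ADD),
            )
            sdr = add_detector_noise(shot, dark_add)
            dark_corr = make_dark_frame(
                det, grid, T_x,
                _seed(master_seed, rate_idx, 1, eps, _STAGE_DARK_CORR),
            )
            sdpr = ct.subtract_dark_offset(sdr, dark_corr)
            vals_ideal.append(ct.spatial_kappa2(electrons).values[0])
            vals_sdr.append(ct.spatial_kappa2(sdr).values[0])
            vals_corr.append(ct.corrected_kappa2(sdpr, dark_corr).values[0])
        rows.append(
            {
                "count_rate_e_px_s": rate,
                "mean_e_per_pixel": mean_e_target,
                "k2_ideal_mean": float(np.mean(vals_ideal)),
                "k2_sdr_mean": float(np.mean(vals_sdr)),
                "k2_corr_mean": float(np.mean(vals_corr)),
                "k2_corr_std": float(np.std(vals_corr)),
            }
        )

    table = pd.DataFrame(rows)
    table["percent_error"] = ct.percent_error_vs_attenuation(
        table["k2_corr_mean"].to_numpy(), table["count_rate_e_px_s"].to_numpy()
    )
    ok = np.abs(table["percent_error"].to_numpy()) <= error_threshold
    threshold = None
    for i in range(len(ok)):
        if ok[i:].all():
            threshold = float(table["count_rate_e_px_s"].iloc[i])
            break
    if threshold is None:
        import warnings

        warnings.warn("no count rate on the grid reaches the error threshold")
    return SweepResult(
        table=table, master_seed=master_seed, threshold_rate=threshold
    )


# column -> comparison rule for validate_against_reference
_DETERMINISTIC_COLS = {
    "rho_cm", "T_s", "tau_c_s", "t_frame_s", "f_N", "phi_photons_s",
    "kappa2_hat", "count_rate_e_px_s",
}


def validate_against_reference(
    result: SweepResult,
    reference,
    n_sigma: float = 3.0,
    rtol_deterministic: float = 1e-9,
    epsilon_N: int = 100,
) -> pd.DataFrame:
    """Compare a sweep against a stored reference, column by column.

    Deterministic columns must agree to ``rtol_deterministic`` relative;
    stochastic kappa^2 means must agree within ``n_sigma`` standard errors
    (reference std / sqrt(epsilon_N)); remaining stochastic columns within
    5% relative.  Returns one row per (column, sweep row) with pass/fail.
    """
    ref = reference if isinstance(reference, SweepResult) else SweepResult.from_csv(reference)
    a, b = result.table, ref.table
    if len(a) != len(b):
        raise ParameterError("sweep length differs from reference")
    records = []
    for col in b.columns:
        if col not in a.columns or not np.issubdtype(b[col].dtype, np.number):
            continue
        for i in range(len(b)):
            x, y = float(a[col].iloc[i]), float(b[col].iloc[i])
            if col in _DETERMINISTIC_COLS:
                tol = rtol_deterministic * max(abs(y), 1e-300)
            elif col.endswith("_mean") and col.replace("_mean", "_std") in b.columns:
                tol = n_sigma * float(b[col.replace("_mean", "_std")].iloc[i]) / math.sqrt(epsilon_N)
            else:
                tol = 0.05 * max(abs(y), 1e-12)
            records.append(
                {"column": col, "row": i, "value": x, "reference": y,
                 "tolerance": tol, "passed": abs(x - y) <= tol}
            )
    return pd.DataFrame(records)
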