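"""kappa^2 estimators, noise corrections, bias transfer and metrics."""

import math

import numpy as np
import pytest

from specklesim import (
    BiasRecord,
    ContrastSet,
    DetectorSpec,
    ExperimentSet,
    FrameStack,
    SpeckleOptics,
    Window,
    accuracy_percent_error,
    add_detector_noise,
    apply_shot_noise,
    bias_gamma,
    corrected_kappa2,
    make_dark_frame,
    model_corrected_kappa2,
    percent_error_vs_attenuation,
    precision_cv,
    simulate_experiment,
    snr,
    spatial_kappa2,
    subtract_dark_offset,
    temporal_kappa2,
)
from specklesim.theory import ParameterError


def electron_stack(values):
    return FrameStack(np.asarray(values, dtype=float), units_tag="electrons")


class TestSpatialKappa2:
    def test_constant_frame_is_zero(self):
        out = spatial_kappa2(electron_stack(np.full((8, 8, 1), 3.0)))
        assert out.values[0] == 0.0

    def test_hand_computed_window(self):
        # values {1,2,3}: population var 2/3, mean 2 -> kappa^2 = 1/6
        frame = np.array([[1.0, 2.0, 3.0]]).reshape(1, 3, 1)
        out = spatial_kappa2(FrameStack(frame, units_tag="electrons"))
        assert out.values[0] == pytest.approx(1.0 / 6.0, rel=1e-14)

    def test_window_restricts_pixels(self):
        data = np.zeros((4, 4, 1))
        data[:2, :2, 0] = [[1, 2], [3, 4]]
        data[2:, 2:, 0] = 100.0
        win = Window(kind="spatial", extent=(0, 0, 2, 2))
        out = spatial_kappa2(electron_stack(data), win)
        vals = np.array([1, 2, 3, 4], dtype=float)
        assert out.values[0] == pytest.approx(vals.var() / vals.mean() ** 2)

    def test_window_out_of_bounds(self):
        win = Window(kind="spatial", extent=(0, 0, 10, 10))
        with pytest.raises(ParameterError):
            spatial_kappa2(electron_stack(np.ones((4, 4, 1))), win)

    def test_scale_invariance(self):
        stack = simulate_experiment(2e-5, 1e-5, 3, (48, 48),
                                    SpeckleOptics(3, 1.0), 0)
        a = spatial_kappa2(stack).values
        b = spatial_kappa2(stack.replace(stack.data * 77.7)).values
        assert np.allclose(a, b, rtol=1e-12)


class TestTemporalKappa2:
    def test_identical_repeats_are_zero(self):
        frame = np.random.default_rng(0).random((6, 6, 1)) + 1.0
        exps = ExperimentSet([FrameStack(frame, units_tag="electrons")] * 4)
        out = temporal_kappa2(exps)
        assert np.allclose(out.values, 0.0)
        assert out.values.size == 36  # one value per pixel

    def test_needs_two_experiments(self):
        exps = ExperimentSet([FrameStack(np.ones((4, 4, 1)))])
        with pytest.raises(ParameterError):
            temporal_kappa2(exps)

    def test_ergodicity_spatial_vs_temporal(self):
        # same process: per-pixel temporal kappa^2 over many experiments
        # matches the spatial estimate
        stacks, spatial = [], []
        for s in range(60):
            st = simulate_experiment(2e-5, 1e-5, 3, (32, 32),
                                     SpeckleOptics(3, 1.0), s)
            one = st.replace(st.data[:, :, :1])
            one.units_tag = "electrons"
            stacks.append(one)
            spatial.append(spatial_kappa2(one).values[0])
        temporal = temporal_kappa2(ExperimentSet(stacks)).values
        assert np.mean(temporal) == pytest.approx(np.mean(spatial), rel=0.1)


@pytest.fixture()
def noisy_chain():
    """A shot+dark noised stack with matched dark frames (small grid)."""
    spec = DetectorSpec(QE=0.5, dsnu_mean=10.0, dsnu_var=0.5,
                        read_mean=2.0, read_var=0.3)
    stack = simulate_experiment(2e-5, 1e-5, 3, (64, 64), SpeckleOptics(3, 1.0), 1)
    electrons = stack.replace(stack.data[:, :, :1] * 5e3 / stack.data.mean(),
                              units_tag="electrons")
    shot = apply_shot_noise(electrons, 2)
    dark_add = make_dark_frame(spec, (64, 64), 5e-3, 3)
    sdr = add_detector_noise(shot, dark_add)
    dark_corr = make_dark_frame(spec, (64, 64), 5e-3, 4)
    return electrons, shot, sdr, dark_add, dark_corr


class TestDarkSubtractionAndCorrection:
    def test_zero_noise_detector_identity(self):
        spec = DetectorSpec(QE=0.5, dsnu_mean=0.0, dsnu_var=0.0,
                            read_mean=0.0, read_var=0.0)
        shot = apply_shot_noise(electron_stack(np.full((16, 16, 1), 100.0)), 0)
        sdr = add_detector_noise(shot, make_dark_frame(spec, (16, 16), 1e-3, 1))
        out = subtract_dark_offset(sdr, make_dark_frame(spec, (16, 16), 1e-3, 2))
        assert np.array_equal(out.data, shot.data)
        assert out.noise_tag == "sd'r'"

    def test_reusing_added_dark_rejected(self, noisy_chain):
        _, _, sdr, dark_add, _ = noisy_chain
        with pytest.raises(ParameterError, match="independent"):
            subtract_dark_offset(sdr, dark_add)

    def test_offset_restored(self, noisy_chain):
        electrons, shot, sdr, _, dark_corr = noisy_chain
        out = subtract_dark_offset(sdr, dark_corr)
        assert out.data.mean() == pytest.approx(shot.data.mean(), rel=0.01)

    def test_noise_free_stack_correction_is_uncorrected(self):
        stack = electron_stack(np.random.default_rng(0).random((16, 16, 1)) + 1)
        assert corrected_kappa2(stack).values == pytest.approx(
            spatial_kappa2(stack).values
        )

    def test_corrected_recovers_ideal_at_high_counts(self):
        # mean 1e5 e-/pixel: corrected kappa^2 within 2% of noise-free
        spec = DetectorSpec(QE=0.5, dsnu_mean=5.0, dsnu_var=0.5,
                            read_mean=2.9, read_var=0.3)
        ideal, corrected = [], []
        for s in range(40):
            st = simulate_experiment(2e-5, 1e-5, 3, (64, 64),
                                     SpeckleOptics(3, 1.0), s)
            el = st.replace(st.data[:, :, :1] * 1e5 / st.data[:, :, :1].mean(),
                            units_tag="electrons")
            shot = apply_shot_noise(el, 100 + s)
            sdr = add_detector_noise(
                shot, make_dark_frame(spec, (64, 64), 5e-3, 200 + s)
            )
            dc = make_dark_frame(spec, (64, 64), 5e-3, 300 + s)
            corr = corrected_kappa2(subtract_dark_offset(sdr, dc), dc)
            ideal.append(spatial_kappa2(el).values[0])
            corrected.append(corr.values[0])
        assert np.mean(corrected) == pytest.approx(np.mean(ideal), rel=0.02)

    def test_shot_only_variant(self):
        el = electron_stack(np.random.default_rng(1).random((64, 64, 1)) * 1e4)
        shot = apply_shot_noise(el, 5)
        out = corrected_kappa2(shot)
        assert out.noise_state == "s'"
        assert out.values[0] == pytest.approx(
            spatial_kappa2(el).values[0], rel=0.2
        )


class TestBiasAndModelCorrection:
    def test_gamma_zero_for_identical_sets(self):
        ref = ContrastSet(np.array([0.1, 0.2, 0.3]), noise_state="~")
        rec = bias_gamma(ref, ContrastSet(ref.values.copy(), noise_state="~"))
        assert rec.gamma == 0.0

    def test_gamma_negative_when_noise_inflates(self):
        ref = ContrastSet(np.array([0.1, 0.1]), noise_state="~")
        noisy = ContrastSet(np.array([0.3, 0.3]), noise_state="sdr")
        assert bias_gamma(ref, noisy).gamma < 0

    def test_gamma_permutation_invariant(self):
        rng = np.random.default_rng(0)
        ref = ContrastSet(rng.random(50), noise_state="~")
        noisy_vals = rng.random(50)
        g1 = bias_gamma(ref, ContrastSet(noisy_vals, noise_state="sdr")).gamma
        g2 = bias_gamma(
            ref, ContrastSet(noisy_vals[::-1].copy(), noise_state="sdr")
        ).gamma
        assert g1 == pytest.approx(g2, rel=1e-14)

    def test_degenerate_model_draws(self):
        rec = BiasRecord(gamma=0.0, source_states=("~", "sdr"))
        out = model_corrected_kappa2(0.25, rec, sigma2=0.0, n_draws=20, seed=0)
        assert np.allclose(out.values, 0.25)

    def test_model_mean_and_spread(self):
        rec = BiasRecord(gamma=-0.02, source_states=("~", "s'd'r'"))
        out = model_corrected_kappa2(0.25, rec, sigma2=1e-4, n_draws=10**6,
                                     seed=1)
        assert out.values.mean() == pytest.approx(0.23, abs=3e-5)
        assert out.values.std() == pytest.approx(1e-2, rel=0.01)

    def test_bias_added_convention(self):
        rec = BiasRecord(gamma=-0.02, source_states=("~", "s'd'r'"))
        out = model_corrected_kappa2(0.25, rec, sigma2=0.0, n_draws=5, seed=0,
                                     convention="bias-added")
        assert np.allclose(out.values, 0.27)


class TestMetrics:
    def test_percent_error_identities(self):
        vals = ContrastSet(np.full(10, 0.2))
        assert accuracy_percent_error(vals, 0.2) == pytest.approx(0.0)
        vals2 = ContrastSet(np.full(10, 0.21))
        assert accuracy_percent_error(vals2, 0.2) == pytest.approx(5.0)

    def test_cv_hand_computed(self):
        vals = ContrastSet(np.array([1.0, 1.0, 1.0, 3.0]))
        # population std of {1,1,1,3} = sqrt(0.75), mean 1.5
        assert precision_cv(vals) == pytest.approx(
            100 * math.sqrt(0.75) / 1.5, rel=1e-12
        )
        assert precision_cv(ContrastSet(np.full(5, 0.3))) == 0.0

    def test_snr_is_reciprocal_cv(self):
        vals = ContrastSet(np.array([1.0, 1.0, 1.0, 3.0]))
        assert snr(vals) == pytest.approx(100.0 / precision_cv(vals), rel=1e-12)

    def test_attenuation_series(self):
        out = percent_error_vs_attenuation([1.0, 1.1], rates=[10.0, 1.0])
        assert out[0] == pytest.approx(0.0)
        assert out[1] == pytest.approx(10.0)
        out2 = percent_error_vs_attenuation([0.9, 1.0])
        assert out2[1] == 0.0

    def test_negative_corrected_values_flagged(self):
        vals = ContrastSet(np.array([0.1, -0.05]), noise_state="s'd'r'")
        assert vals.has_negative


def test_cv_follows_square_root_sampling_law():
    """CV(kappa^2) vs number of sampled speckles: log-log slope -0.5.

    CV is computed over repeated experiments for every non-overlapping
    window of each size and averaged over window positions, which keeps
    the estimate stable at the smaller sizes.
    """
    frames = [
        simulate_experiment(2e-5, 1e-5, 3, (96, 96),
                            SpeckleOptics(3, 1.0), s).data[:, :, 0]
        for s in range(600)
    ]
    sizes = np.array([24, 48, 96])
    cvs = []
    for w in sizes:
        tile_cvs = []
        for i0 in range(0, 96, w):
            for j0 in range(0, 96, w):
                k2 = ContrastSet(np.array([
                    f[i0:i0 + w, j0:j0 + w].var()
                    / f[i0:i0 + w, j0:j0 + w].mean() ** 2
                    for f in frames
                ]))
                tile_cvs.append(precision_cv(k2))
        cvs.append(np.mean(tile_cvs))
    n_speckles = (sizes / 3.0) ** 2
    slope = np.polyfit(np.log(n_speckles), np.log(cvs), 1)[0]
    assert slope == pytest.approx(-0.5, abs=0.1)
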