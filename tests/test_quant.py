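"""Intensity measurement, background, depth QC, normalization, decay fits."""

import numpy as np
import pandas as pd
import pytest

import germaquant as gq
from germaquant.quant import NormalizationError, SamplingError

from conftest import single_nucleus_stack


def _cores_from_truth(truth, diameter=1.75):
    df = truth.nuclei
    return gq.SpotSet(
        pd.DataFrame({"id": df["id"], "z_um": df["z_um"], "y_um": df["y_um"],
                      "x_um": df["x_um"], "diameter_um": diameter, "score": 1.0}),
        "core", "nuclear", diameter)


class TestMeasureIntensities:
    def test_uniform_channel_returns_that_value(self):
        data = np.full((2, 10, 30, 30), 7.0)
        data[1] = 3.0
        stack = gq.VoxelStack(data, (0.43, 0.14, 0.14), ["a", "b"])
        cores = gq.SpotSet(
            pd.DataFrame({"id": [0], "z_um": [2.0], "y_um": [2.0], "x_um": [2.0],
                          "diameter_um": [1.75], "score": [1.0]}),
            "core", "a", 1.75)
        out = gq.measure_intensities(stack, cores)
        assert out["a_raw"][0] == pytest.approx(7.0)
        assert out["b_raw"][0] == pytest.approx(3.0)
        assert not out["edge"][0]

    def test_noiseless_phantom_tracks_truth(self, clean_phantom):
        _, truth, stack = clean_phantom
        out = gq.measure_intensities(stack, _cores_from_truth(truth))
        for ch in ("eya", "cas", "reporter"):
            r = np.corrcoef(out[f"{ch}_raw"], truth.channel_truth(ch))[0, 1]
            assert r**2 > 0.99, ch

    def test_edge_core_flagged_and_measured_in_bounds(self):
        data = np.full((1, 10, 30, 30), 5.0)
        stack = gq.VoxelStack(data, (0.43, 0.14, 0.14), ["a"])
        cores = gq.SpotSet(
            pd.DataFrame({"id": [0], "z_um": [0.2], "y_um": [0.5], "x_um": [0.5],
                          "diameter_um": [1.75], "score": [1.0]}),
            "core", "a", 1.75)
        out = gq.measure_intensities(stack, cores)
        assert out["edge"][0]
        assert out["a_raw"][0] == pytest.approx(5.0)


class TestBackground:
    def test_uniform_background_exact(self):
        data = np.full((1, 24, 60, 60), 11.0)
        stack = gq.VoxelStack(data, (0.43, 0.14, 0.14), ["a"])
        bg = gq.estimate_background(stack, np.zeros((0, 3)), n_spots=10,
                                    rng=np.random.default_rng(0))
        assert bg.mean["a"] == pytest.approx(11.0)
        assert bg.sd["a"] == pytest.approx(0.0, abs=1e-12)
        assert bg.n_spots == 10
        assert len(bg.z_planes) == 2

    def test_noisy_background_within_three_se(self):
        rng = np.random.default_rng(5)
        data = rng.normal(10.0, 1.0, size=(1, 24, 80, 80)).clip(0)
        stack = gq.VoxelStack(data, (0.43, 0.14, 0.14), ["a"])
        bg = gq.estimate_background(stack, np.zeros((0, 3)), n_spots=12,
                                    rng=np.random.default_rng(1))
        assert bg.mean["a"] == pytest.approx(10.0, abs=1.0)

    def test_manual_spot_overlapping_nucleus_rejected(self):
        data = np.full((1, 24, 60, 60), 1.0)
        stack = gq.VoxelStack(data, (0.43, 0.14, 0.14), ["a"])
        nuclei = np.array([[5.0, 4.0, 4.0]])
        with pytest.raises(SamplingError):
            gq.estimate_background(stack, nuclei,
                                   manual_centers_um=[[5.0, 4.5, 4.0], [7.0, 4.0, 4.0]])

    def test_manual_spots_must_span_two_planes(self):
        data = np.full((1, 24, 60, 60), 1.0)
        stack = gq.VoxelStack(data, (0.43, 0.14, 0.14), ["a"])
        with pytest.raises(SamplingError):
            gq.estimate_background(stack, np.zeros((0, 3)),
                                   manual_centers_um=[[5.0, 2, 2], [5.0, 6, 6]])

    @pytest.mark.parametrize("raw, bg, expected", [(100.0, 10.0, 90.0), (5.0, 10.0, 0.0),
                                                   (42.0, 0.0, 42.0)])
    def test_subtraction_floored_at_zero(self, raw, bg, expected):
        table = pd.DataFrame({"a_raw": [raw]})
        est = gq.BackgroundEstimate({"a": bg}, {"a": 0.0}, 8, np.zeros((8, 3)), (1.0, 2.0))
        out = gq.subtract_background(table, est)
        assert out["a_bgsub"][0] == pytest.approx(expected)

    def test_background_subtraction_unbiased_across_seeds(self):
        """Mean residual (bgsub - truth) is centred at 0 across 20 seeds."""
        residuals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            truth_val = 30.0
            raw = truth_val + 10.0 + rng.normal(0, 0.5, 50)  # signal + bg + noise
            bg_meas = 10.0 + rng.normal(0, 0.5 / np.sqrt(10))
            est = gq.BackgroundEstimate({"a": bg_meas}, {"a": 0.5}, 10,
                                        np.zeros((10, 3)), (1.0, 2.0))
            out = gq.subtract_background(pd.DataFrame({"a_raw": raw}), est)
            residuals.append(out["a_bgsub"].mean() - truth_val)
        se = np.std(residuals, ddof=1) / np.sqrt(len(residuals))
        assert abs(np.mean(residuals)) < 2 * se + 1e-9


class TestDepthQC:
    def test_flat_intensities_pass(self):
        rng = np.random.default_rng(0)
        z = rng.uniform(0, 20, 30)
        v = np.full(30, 50.0) + rng.normal(0, 0.5, 30)
        qc = gq.depth_bias_qc(z, v)
        assert qc.passed is True
        assert qc.max_ratio == pytest.approx(1.0, abs=0.1)

    def test_residual_attenuation_fails(self):
        """Uncorrected e^(-0.01 z) over 40 um exceeds the 15% tolerance.

        Band means average within each z tercile, so the expected ratio is
        exp(0.01 * (mean bottom-tercile z - mean top-tercile z)) ~ e^0.27.
        """
        z = np.linspace(0, 40, 60)
        v = 50.0 * np.exp(-0.01 * z)
        qc = gq.depth_bias_qc(z, v)
        assert qc.passed is False
        top = np.mean(z[z <= np.quantile(z, 1 / 3)])
        bottom = np.mean(z[z > np.quantile(z, 2 / 3)])
        assert qc.max_ratio == pytest.approx(np.exp(0.01 * (bottom - top)), rel=0.02)

    def test_too_few_cells_not_evaluable(self):
        qc = gq.depth_bias_qc([1, 2, 3, 4, 5, 6, 7, 8], np.ones(8))
        assert qc.passed is None


class TestNormalizeMax:
    def test_basic_scaling(self):
        out = gq.normalize_max([2.0, 4.0, 8.0])
        np.testing.assert_allclose(out, [0.25, 0.5, 1.0])

    def test_per_sample_independence(self):
        v = np.array([1.0, 2.0, 10.0, 5.0])
        s = np.array(["a", "a", "b", "b"])
        out = gq.normalize_max(v, s)
        np.testing.assert_allclose(out, [0.5, 1.0, 1.0, 0.5])
        # perturbing sample b never changes sample a
        v2 = v.copy()
        v2[2:] *= 7.0
        np.testing.assert_allclose(gq.normalize_max(v2, s)[:2], out[:2])

    def test_excluded_cells_do_not_set_the_max(self):
        out = gq.normalize_max([2.0, 4.0, 100.0], exclude=[False, False, True])
        np.testing.assert_allclose(out[:2], [0.5, 1.0])

    def test_scale_invariance_and_idempotence(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 50, 40)
        out = gq.normalize_max(v)
        np.testing.assert_allclose(gq.normalize_max(3.7 * v), out, rtol=1e-12)
        np.testing.assert_allclose(gq.normalize_max(out), out, rtol=1e-12)
        assert out.max() == 1.0
        assert np.all((out >= 0) & (out <= 1))

    def test_all_zero_sample_warns(self):
        with pytest.warns(UserWarning):
            out = gq.normalize_max([0.0, 0.0, 0.0])
        np.testing.assert_array_equal(out, 0.0)


class TestNormalizeToControlMean:
    def test_mutant_fold_change_reads_directly(self):
        """Controls at 10, mutant at 18.3 -> normalized mutant value 1.83."""
        v = np.array([10.0, 10.0, 10.0, 18.3])
        ctrl = np.array([True, True, True, False])
        out = gq.normalize_to_control_mean(v, ctrl)
        assert out[3] == pytest.approx(1.83)
        np.testing.assert_allclose(out[:3], 1.0)

    def test_all_control_mean_is_one(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(5, 50, 30)
        out = gq.normalize_to_control_mean(v, np.ones(30, dtype=bool))
        assert out.mean() == pytest.approx(1.0)

    def test_too_few_controls_raise(self):
        with pytest.raises(NormalizationError):
            gq.normalize_to_control_mean([1.0, 2.0, 3.0], [True, True, False])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(1, 10, 20)
        ctrl = rng.random(20) < 0.5
        ctrl[:3] = True
        out = gq.normalize_to_control_mean(v, ctrl)
        perm = rng.permutation(20)
        np.testing.assert_allclose(gq.normalize_to_control_mean(v[perm], ctrl[perm]),
                                   out[perm], rtol=1e-12)


class TestDecayFit:
    def test_noiseless_exact_recovery(self):
        x = np.arange(0, 41, 5, dtype=float)
        y = 0.1 + 0.9 * np.exp(-0.08 * x)
        fit = gq.fit_one_phase_decay(x, y)
        assert fit.plateau == pytest.approx(0.1, abs=1e-6)
        assert fit.y0 == pytest.approx(1.0, abs=1e-6)
        assert fit.K == pytest.approx(0.08, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.converged

    def test_constant_data_degenerate_convention(self):
        fit = gq.fit_one_phase_decay([0, 5, 10, 15.0], [3.0, 3.0, 3.0, 3.0])
        assert fit.plateau == fit.y0 == 3.0
        assert fit.K == 0.0
        assert fit.r_squared == 0.0

    def test_noisy_k_within_ten_percent(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0, 40, 200)
        y = np.clip(0.1 + 0.9 * np.exp(-0.08 * x) + rng.normal(0, 0.05, 200), 0, None)
        fit = gq.fit_one_phase_decay(x, y)
        assert fit.K == pytest.approx(0.08, rel=0.10)

    def test_k_bias_small_across_seeds(self):
        """K-hat bias < 5% at n = 200, noise 5% of y0 (100 seeds)."""
        x = np.linspace(0, 40, 200)
        mean_y = 0.1 + 0.9 * np.exp(-0.08 * x)
        ks = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = np.clip(mean_y + rng.normal(0, 0.05, 200), 0, None)
            ks.append(gq.fit_one_phase_decay(x, y).K)
        assert abs(np.mean(ks) - 0.08) / 0.08 < 0.05

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            gq.fit_one_phase_decay([0, 1, 2.0], [1, 1, 1.0])


class TestNormalizeToDecay:
    def _fit(self):
        x = np.linspace(0, 40, 50)
        return gq.fit_one_phase_decay(x, 10.0 + 90.0 * np.exp(-0.08 * x))

    def test_control_cells_self_normalize_to_one(self):
        """Control cells on the fitted curve map to ~1 in every AP decile."""
        rng = np.random.default_rng(11)
        ap = rng.uniform(0, 40, 400)
        vals = (10.0 + 90.0 * np.exp(-0.08 * ap)) * rng.lognormal(0, 0.05, 400)
        fit = gq.fit_one_phase_decay(ap, vals)
        out, floored = gq.normalize_to_decay_prediction(vals, ap, fit)
        for lo in range(0, 40, 4):
            sel = (ap >= lo) & (ap < lo + 4)
            assert np.median(out[sel]) == pytest.approx(1.0, abs=0.05)
        assert not floored.any()

    def test_injected_fold_change_recovered(self):
        rng = np.random.default_rng(12)
        ap = rng.uniform(0, 40, 200)
        ctrl_fit = self._fit()
        vals = 1.5 * ctrl_fit.predict(ap) * rng.lognormal(0, 0.05, 200)
        out, _ = gq.normalize_to_decay_prediction(vals, ap, ctrl_fit)
        assert np.median(out) == pytest.approx(1.5, rel=0.03)

    def test_floor_clamps_small_predictions(self):
        fit = gq.DecayFit(plateau=0.0, y0=100.0, K=0.5, r_squared=1.0,
                          n_points=10, converged=True)
        out, floored = gq.normalize_to_decay_prediction([1.0], [100.0], fit)
        assert floored[0]
        assert out[0] == pytest.approx(1.0 / 5.0)  # divisor clamped to 5% of y0

    def test_unconverged_fit_rejected_unless_accepted(self):
        fit = gq.DecayFit(0.0, 1.0, 0.1, -np.inf, 10, converged=False)
        with pytest.raises(NormalizationError):
            gq.normalize_to_decay_prediction([1.0], [0.0], fit)
        out, _ = gq.normalize_to_decay_prediction([1.0], [0.0], fit,
                                                  accept_unconverged=True)
        assert out[0] == pytest.approx(1.0)
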