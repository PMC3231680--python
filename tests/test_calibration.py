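"""Calibration fits (proportional, linear, exponential), prediction and
validation statistics."""

import json

import numpy as np
import pandas as pd
import pytest

from rededge import (
    CalibrationResults,
    DegenerateDataError,
    IndexCalibration,
    IndexMap,
    UsageError,
    fit_exponential,
    fit_linear,
    fit_proportional,
    map_agreement,
    preset,
    validate,
)


def flat_map(value, shape=(2, 3), index=None):
    meta = {"index": index} if index else {}
    return IndexMap(np.full(shape, float(value)), np.zeros(shape, bool), meta)


class TestProportional:
    def test_exact_proportionality(self):
        res = fit_proportional([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert res.coefficients["slope"] == pytest.approx(2.0)
        assert res.r == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # slope = sum(xy)/sum(x^2) = 28.5/14
        res = fit_proportional([1, 2, 3], [2.1, 3.9, 6.2])
        assert res.coefficients["slope"] == pytest.approx(28.5 / 14)

    def test_constant_y_gives_undefined_r(self):
        res = fit_proportional([1.0, 2.0, 4.0], [3.0, 3.0, 3.0])
        assert res.coefficients["slope"] == pytest.approx(21.0 / 21.0)
        assert np.isnan(res.r)

    def test_all_zero_x_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_proportional([0.0, 0.0], [1.0, 2.0])

    def test_slope_recovery_within_three_se(self):
        """y = s*x + noise: the through-origin estimator covers s at ~3 SE."""
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            x = rng.uniform(0.05, 0.5, 200)
            y = 5.0 * x + rng.normal(0, 0.3, 200)
            res = fit_proportional(x, y)
            if abs(res.coefficients["slope"] - 5.0) <= 3 * res.bse["slope"]:
                hits += 1
        assert hits >= 95


class TestLinear:
    def test_exact_line_recovery(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        y = -3.8868 + 101.94 * x
        res = fit_linear(x, y)
        assert res.coefficients["intercept"] == pytest.approx(-3.8868)
        assert res.coefficients["slope"] == pytest.approx(101.94)
        assert res.r == pytest.approx(1.0)

    def test_two_point_line(self):
        res = fit_linear([0.0, 1.0], [1.0, 3.0])
        assert res.coefficients["intercept"] == pytest.approx(1.0)
        assert res.coefficients["slope"] == pytest.approx(2.0)

    def test_noisy_line_within_three_se(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, 1000)
        y = 1.5 + 4.0 * x + rng.normal(0, 0.5, 1000)
        res = fit_linear(x, y)
        assert abs(res.coefficients["slope"] - 4.0) <= 3 * res.bse["slope"]
        assert abs(res.coefficients["intercept"] - 1.5) <= 3 * res.bse["intercept"]

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_linear([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestExponential:
    def test_noiseless_recovery(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        y = 0.0219 * np.exp(10.02 * x)
        res = fit_exponential(x, y)
        assert res.coefficients["amplitude"] == pytest.approx(0.0219)
        assert res.coefficients["rate"] == pytest.approx(10.02)
        assert res.r == pytest.approx(1.0)

    def test_two_points_rejected(self):
        with pytest.raises(UsageError):
            fit_exponential([0.1, 0.2], [1.0, 2.0])

    def test_nonpositive_y_rejected(self):
        with pytest.raises(UsageError, match="offending"):
            fit_exponential([0.1, 0.2, 0.3], [1.0, 0.0, 2.0])

    def test_lognormal_noise_recovery_within_5pct(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0.0, 0.7, 500)
        y = 0.0219 * np.exp(10.02 * x) * np.exp(rng.normal(0, 0.2, 500))
        res = fit_exponential(x, y)
        assert res.coefficients["amplitude"] == pytest.approx(0.0219, rel=0.05)
        assert res.coefficients["rate"] == pytest.approx(10.02, rel=0.05)


class TestPredict:
    def test_proportional_on_constant_map(self):
        lai = preset("s2_lai_ndi").predict(flat_map(0.5, index="NDI"))
        assert np.allclose(lai.values, 4.226)

    def test_exponential_at_origin(self):
        chlai = preset("naoc_chlai_exponential").predict(flat_map(0.0, index="NAOC"))
        assert np.allclose(chlai.values, 0.0219)

    def test_mask_propagates(self):
        m = IndexMap(np.full((2, 2), np.nan), np.ones((2, 2), bool))
        out = preset("s2_lai_ndi").predict(m)
        assert out.mask.all()

    def test_index_kind_mismatch_rejected(self):
        with pytest.raises(UsageError):
            preset("naoc_ch_linear").predict(flat_map(0.5, index="NDI"))

    def test_scalar_predict(self):
        assert preset("naoc_ch_linear").predict(0.0) == pytest.approx(-3.8868)

    def test_training_r_matches_stored_r(self):
        """Pearson is affine-invariant, so r(pred, y) == r(x, y) for the
        proportional and linear forms."""
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 50)
        y = 3.0 * x + rng.normal(0, 0.2, 50)
        res = fit_proportional(x, y)
        pred = res.predict(x)
        assert np.corrcoef(pred, y)[0, 1] == pytest.approx(res.r)


class TestModelObjects:
    def test_from_dataframe_and_summary(self):
        df = pd.DataFrame({"ndi": [0.1, 0.3, 0.5], "lai": [0.8, 2.5, 4.2]})
        res = IndexCalibration.from_dataframe(df, "ndi", "lai", "proportional").fit()
        text = res.summary()
        assert "proportional" in text and "lai" in text

    def test_json_roundtrip(self, tmp_path):
        res = fit_linear([0.0, 0.5, 1.0], [1.0, 2.1, 2.9], y_units="ug/cm2")
        path = tmp_path / "model.json"
        res.to_json(path)
        back = CalibrationResults.from_json(path)
        assert back.kind == "linear"
        assert back.coefficients == pytest.approx(res.coefficients)
        assert back.y_units == "ug/cm2"

    def test_unknown_preset(self):
        with pytest.raises(UsageError):
            preset("nope")


class TestValidate:
    def test_identity(self):
        pred = flat_map(2.0)
        truth = pd.DataFrame({"row": [0, 1], "col": [0, 2], "value": [2.0, 2.0]})
        report = validate(pred, truth)
        assert report.rmse == 0.0 and report.bias == 0.0 and report.n == 2

    def test_hand_arithmetic(self):
        pred = flat_map(1.0, shape=(1, 2))
        truth = pd.DataFrame({"row": [0, 0], "col": [0, 1], "value": [0.0, 2.0]})
        report = validate(pred, truth)
        assert report.rmse == pytest.approx(1.0)
        assert report.bias == pytest.approx(0.0)

    def test_all_masked_rejected(self):
        pred = IndexMap(np.full((2, 2), np.nan), np.ones((2, 2), bool))
        truth = pd.DataFrame({"row": [0], "col": [0], "value": [1.0]})
        with pytest.raises(UsageError):
            validate(pred, truth)

    def test_per_class_breakdown(self):
        pred = flat_map(1.0, shape=(1, 4))
        truth = pd.DataFrame(
            {
                "row": [0, 0, 0, 0],
                "col": [0, 1, 2, 3],
                "value": [1.0, 1.0, 2.0, 0.0],
                "class_label": ["wheat", "wheat", "corn", "corn"],
            }
        )
        report = validate(pred, truth)
        per = report.per_class.set_index("class_label")
        assert per.loc["wheat", "rmse"] == 0.0
        assert per.loc["corn", "rmse"] == pytest.approx(1.0)


class TestMapAgreement:
    def test_self_agreement(self, small_scene):
        cube, truth = small_scene
        m = IndexMap(truth.lai, np.zeros_like(truth.lai, bool))
        report, pairs = map_agreement(m, m)
        assert report.r == pytest.approx(1.0)
        assert report.rmse == 0.0
        assert len(pairs) == report.n

    def test_constant_offset(self, small_scene):
        _, truth = small_scene
        a = IndexMap(truth.lai + 0.4, np.zeros_like(truth.lai, bool))
        b = IndexMap(truth.lai, np.zeros_like(truth.lai, bool))
        report, _ = map_agreement(a, b)
        assert report.bias == pytest.approx(0.4)
        assert report.rmse == pytest.approx(0.4)
        assert report.r == pytest.approx(1.0)

    def test_shape_mismatch(self):
        with pytest.raises(UsageError):
            map_agreement(flat_map(1.0, (2, 2)), flat_map(1.0, (3, 3)))

    def test_joint_masking(self):
        a = flat_map(1.0, (2, 3))
        b = flat_map(1.0, (2, 3))
        a.mask[0, 0] = True
        b.mask[1, 2] = True
        report, _ = map_agreement(a, b)
        assert report.n == 4
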