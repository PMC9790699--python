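"""Error metrics, agreement analysis, Dice quality and nonparametric tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdti import evaluation

angles = st.floats(min_value=-360, max_value=360, allow_nan=False)


class TestAngularDistance:
    @pytest.mark.parametrize(
        "a,b,expected", [(89, -89, 2), (30, 30, 0), (45, -45, 90), (0, 180, 0)]
    )
    def test_examples(self, a, b, expected):
        assert evaluation.angular_distance(a, b) == pytest.approx(expected)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(a=angles, b=angles, c=angles)
    def test_metric_on_folded_half_circle(self, a, b, c):
        dab = evaluation.angular_distance(a, b)
        assert 0 <= dab <= 90
        assert dab == pytest.approx(evaluation.angular_distance(b, a))
        # zero iff equal modulo 180
        if abs((a - b) % 180.0) < 1e-9 or abs((a - b) % 180.0 - 180.0) < 1e-9:
            assert dab == pytest.approx(0, abs=1e-6)
        # triangle inequality
        assert dab <= (
            evaluation.angular_distance(a, c) + evaluation.angular_distance(c, b) + 1e-9
        )


class TestErrorMaps:
    def _maps(self, hw=(8, 8)):
        rng = np.random.default_rng(0)
        mask = np.zeros(hw, bool)
        mask[2:6, 2:6] = True
        ref = {
            "fa": np.where(mask, rng.uniform(0.2, 0.8, hw), np.nan),
            "md": np.where(mask, rng.uniform(0.8, 1.4, hw), np.nan),
            "ha": np.where(mask, rng.uniform(-90, 90, hw), np.nan),
            "e2a": np.where(mask, rng.uniform(-90, 90, hw), np.nan),
        }
        return ref, mask

    def test_identical_maps_give_zero_errors(self):
        ref, mask = self._maps()
        s = evaluation.error_maps(ref, ref, mask)
        assert s.fa_mae == 0 and s.md_mae == 0 and s.ha_maae == 0 and s.e2a_maae == 0

    def test_constant_fa_offset(self):
        ref, mask = self._maps()
        test = dict(ref)
        test["fa"] = ref["fa"] + 0.1
        s = evaluation.error_maps(test, ref, mask)
        assert s.fa_mae == pytest.approx(0.1)

    def test_ha_offset_by_180_is_zero_error(self):
        ref, mask = self._maps()
        test = dict(ref)
        test["ha"] = ref["ha"] + 180.0
        s = evaluation.error_maps(test, ref, mask)
        assert s.ha_maae == pytest.approx(0.0, abs=1e-9)

    def test_undefined_voxels_excluded_and_counted(self):
        ref, mask = self._maps()
        test = {k: v.copy() for k, v in ref.items()}
        test["fa"][2, 2] = np.nan
        s = evaluation.error_maps(test, ref, mask)
        assert s.n_excluded["fa"] == 1
        assert s.fa_mae == 0.0

    def test_disjoint_support_rejected(self):
        ref, mask = self._maps()
        test = {k: np.full(v.shape, np.nan) for k, v in ref.items()}
        with pytest.raises(ValueError):
            evaluation.error_maps(test, ref, mask)


class TestBlandAltman:
    def test_identity_has_no_significant_bias(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        ba = evaluation.bland_altman(x, x)
        assert ba.bias_median == 0.0
        assert ba.ci_low <= 0.0 <= ba.ci_high
        assert not ba.significant_bias

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        ba = evaluation.bland_altman(x, x + 0.5)
        assert ba.bias_median == pytest.approx(0.5, abs=1e-12)
        assert ba.significant_bias

    def test_quantiles_bracket_bias(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        ba = evaluation.bland_altman(x, x + rng.normal(0.2, 0.1, 500))
        assert ba.q05 < ba.bias_median < ba.q95

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluation.bland_altman([1, 2, 3], [1, 2])


class TestDice:
    def test_identical_and_disjoint(self):
        a = np.zeros((6, 6), bool)
        a[1:4, 1:4] = True
        b = np.zeros((6, 6), bool)
        b[4:6, 4:6] = True
        assert evaluation.dice(a, a) == 1.0
        assert evaluation.dice(a, b) == 0.0

    def test_both_empty_defined_as_one(self):
        assert evaluation.dice(np.zeros((3, 3), bool), np.zeros((3, 3), bool)) == 1.0

    def test_shifted_annulus_matches_brute_force(self):
        hw = 32
        rows, cols = np.mgrid[0:hw, 0:hw].astype(float)
        r = np.hypot(rows - 15.5, cols - 15.5)
        mask = (r >= 5) & (r <= 9)
        shift = (4, -2)  # about the annulus width
        shifted = evaluation._shift_mask(mask, shift)
        overlap = 0
        for rr in range(hw):
            for cc in range(hw):
                sr, sc = rr - shift[0], cc - shift[1]
                if mask[rr, cc] and 0 <= sr < hw and 0 <= sc < hw and mask[sr, sc]:
                    overlap += 1
        expected = 2 * overlap / (mask.sum() + shifted.sum())
        assert evaluation.dice(mask, shifted) == pytest.approx(expected)

    def test_mean_dice_perfect_registration(self):
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        assert evaluation.mean_dice_quality(mask, np.zeros((5, 2))) == 1.0

    def test_quality_regression_recovers_linear_relation(self):
        rng = np.random.default_rng(4)
        dice_scores = rng.uniform(0.6, 1.0, 30)
        errors = 0.5 - 0.4 * dice_scores
        slope, intercept, r = evaluation.quality_regression(errors, dice_scores)
        assert slope == pytest.approx(-0.4)
        assert intercept == pytest.approx(0.5)
        assert r == pytest.approx(-1.0)


class TestNonparametricTests:
    def test_identical_paired_groups_degenerate(self):
        res = evaluation.nonparametric_tests([[1, 2, 3], [1, 2, 3]], paired=True)
        assert res.degenerate and np.isnan(res.pvalue)

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 50)
        b = rng.normal(2, 1, 50)  # 2-sigma shift
        assert evaluation.nonparametric_tests([a, b]).pvalue < 0.05
        assert evaluation.nonparametric_tests([a, b - 2 + a * 0], paired=True).test == (
            "wilcoxon-signed-rank"
        )

    def test_three_groups_dispatch_kruskal_with_pairwise(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(size=20) for _ in range(3)]
        res = evaluation.nonparametric_tests(groups)
        assert res.test == "kruskal-wallis"
        assert set(res.pairwise) == {(0, 1), (0, 2), (1, 2)}

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluation.nonparametric_tests([[1, 2, 3], [1, 2]], paired=True)


class TestRegionMDCompare:
    def test_scaled_infarct_ratio(self):
        mask = np.ones((6, 6), bool)
        labels = {"remote": mask.copy(), "infarct": mask.copy()}
        labels["remote"][:, 3:] = False
        labels["infarct"][:, :3] = False
        md = np.where(labels["infarct"], 1.27, 1.0)
        out = evaluation.region_md_compare(md, labels)
        assert out["ratio"] == pytest.approx(1.27)
        assert out["difference"] == pytest.approx(0.27)

    def test_no_scaling_gives_zero_difference(self):
        mask = np.ones((4, 4), bool)
        labels = {"remote": mask.copy(), "infarct": mask.copy()}
        labels["remote"][:, 2:] = False
        labels["infarct"][:, :2] = False
        out = evaluation.region_md_compare(np.ones((4, 4)), labels)
        assert out["difference"] == 0.0

    def test_empty_region_raises_for_exclusion(self):
        labels = {"remote": np.ones((3, 3), bool), "infarct": np.zeros((3, 3), bool)}
        with pytest.raises(ValueError, match="excluded"):
            evaluation.region_md_compare(np.ones((3, 3)), labels)
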