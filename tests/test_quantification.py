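"""Aggregation chain, shift/proton-fold algebra, ECDF, correlations, t-tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lysoquant.calibration import CalibrationCurve
from lysoquant.quantification import (
    ConditionSummary,
    LysosomeMeasurement,
    ecdf,
    measure_lysosomes,
    ph_size_correlation,
    proton_fold,
    shift,
    summarize,
    two_sample_test,
)
from lysoquant.roi_pairing import RoiPair, pair_ratio

from conftest import make_roi


CURVE = CalibrationCurve(r_min=0.2, r_max=2.0, ph50=4.8, slope_h=1.0,
                         valid_range=(3.0, 7.0))


def make_pair(ratio: float, area_px: int = 25) -> RoiPair:
    r445 = make_roi(1, (5, 5), channel=445, area_px=area_px, mean_intensity=100.0)
    r488 = make_roi(1, (5, 5), channel=488, area_px=area_px,
                    mean_intensity=100.0 * ratio)
    return RoiPair(roi_445=r445, roi_488=r488, centroid_distance_px=0.0,
                   ratio=pair_ratio(r445, r488))


def measurement(ph: float, area: float = 0.3, cell_id: int = 1,
                lysosome_id: int = 1, condition: str = "c") -> LysosomeMeasurement:
    return LysosomeMeasurement(experiment_id="t", condition=condition,
                               cell_id=cell_id, lysosome_id=lysosome_id,
                               ratio=1.0, ph=ph, area_um2=area, clamped_flag=False)


class TestMeasure:
    def test_midpoint_pair(self):
        mid = (CURVE.r_min + CURVE.r_max) / 2
        recs = measure_lysosomes({1: [make_pair(mid, area_px=25)]}, CURVE,
                                 pixel_size_um=0.1, condition="c")
        assert len(recs) == 1
        assert recs[0].ph == pytest.approx(CURVE.ph50)
        assert recs[0].area_um2 == pytest.approx(0.25)
        assert not recs[0].clamped_flag

    def test_ratio_above_ceiling_clamped(self):
        recs = measure_lysosomes({1: [make_pair(CURVE.r_max * 2)]}, CURVE, 0.1)
        assert recs[0].clamped_flag
        assert recs[0].ph == CURVE.valid_range[1]

    def test_invalid_pixel_size(self):
        with pytest.raises(ValueError):
            measure_lysosomes({}, CURVE, 0.0)


class TestSummarize:
    def test_cell_mean(self):
        recs = [measurement(4.0, lysosome_id=i) for i in range(3)] + \
               [measurement(4.4, lysosome_id=i + 3) for i in range(3)]
        cells, summary = summarize(recs, min_lysosomes_per_cell=2)
        assert cells[0].mean_ph == pytest.approx(4.2)
        assert summary.n_cells == 1
        assert np.isnan(summary.sem_ph)

    def test_condition_mean_and_sem(self):
        recs = [measurement(4.1, cell_id=1, lysosome_id=i) for i in range(5)] + \
               [measurement(4.3, cell_id=2, lysosome_id=i + 5) for i in range(5)]
        _, summary = summarize(recs)
        assert summary.mean_ph == pytest.approx(4.2)
        # sd of {4.1, 4.3} = 0.1414..., / sqrt(2) = 0.1
        assert summary.sem_ph == pytest.approx(0.1)

    def test_cells_weighted_equally_despite_lysosome_counts(self):
        recs = [measurement(4.0, cell_id=1, lysosome_id=i) for i in range(50)] + \
               [measurement(4.4, cell_id=2, lysosome_id=100 + i) for i in range(5)]
        _, summary = summarize(recs)
        assert summary.mean_ph == pytest.approx(4.2)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        recs = [measurement(4.0 + 0.01 * i, cell_id=1 + i % 3, lysosome_id=i)
                for i in range(30)]
        shuffled = list(recs)
        rng.shuffle(shuffled)
        cells_a, cond_a = summarize(recs)
        cells_b, cond_b = summarize(shuffled)
        assert [c.cell_id for c in cells_a] == [c.cell_id for c in cells_b]
        for a, b in zip(cells_a, cells_b):
            assert a.mean_ph == pytest.approx(b.mean_ph, rel=1e-12)
        assert cond_a.mean_ph == pytest.approx(cond_b.mean_ph, rel=1e-12)
        assert cond_a.sem_ph == pytest.approx(cond_b.sem_ph, rel=1e-9)

    def test_small_cells_excluded_and_empty_errors(self):
        recs = [measurement(4.0, cell_id=1, lysosome_id=i) for i in range(3)]
        with pytest.raises(ValueError):
            summarize(recs, min_lysosomes_per_cell=5)


def condition(mean_ph: float, area: float = 1.0) -> ConditionSummary:
    return ConditionSummary(condition="x", n_cells=5, mean_ph=mean_ph,
                            sem_ph=0.02, mean_area_um2=area, sem_area=0.1)


class TestShift:
    def test_zero_shift_unity_fold(self):
        res = shift(condition(4.3), condition(4.3))
        assert res.delta_ph == 0.0 and res.proton_fold == 1.0

    def test_one_unit_acidification_tenfold(self):
        res = shift(condition(5.0), condition(4.0))
        assert res.delta_ph == pytest.approx(-1.0)
        assert res.proton_fold == pytest.approx(10.0)

    def test_reported_shift_matches_printed_fold(self):
        """A -0.31 pH shift implies a 10^0.31 = 2.04 fold rise in free [H+],
        within 1% of the reported per-experiment average of 2.03."""
        res = shift(condition(4.32), condition(4.01))
        assert res.delta_ph == pytest.approx(-0.31)
        assert res.proton_fold == pytest.approx(2.042, abs=1e-3)
        assert abs(res.proton_fold - 2.03) / 2.03 < 0.01

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(x=st.floats(min_value=-2.0, max_value=2.0))
    def test_fold_product_identity(self, x):
        assert proton_fold(x) * proton_fold(-x) == pytest.approx(1.0, rel=1e-12)


class TestEcdf:
    def test_hand_example(self):
        out = ecdf([4.0, 4.5, 4.5, 5.0])
        as_dict = {x: f for x, f in out}
        assert as_dict[4.5] == pytest.approx(0.75)
        assert as_dict[5.0] == 1.0

    def test_single_value_step(self):
        out = ecdf([4.2])
        assert out.shape == (1, 2)
        assert out[0, 1] == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ecdf([])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=3.0, max_value=7.5), min_size=1, max_size=40))
    def test_monotone_ending_at_one(self, values):
        out = ecdf(values)
        fractions = out[:, 1]
        assert np.all(np.diff(fractions) > 0)
        assert fractions[-1] == 1.0
        assert fractions[0] > 0


class TestCorrelation:
    def test_perfect_linear(self):
        recs = [measurement(4.0 + 0.1 * i, area=0.2 + 0.05 * i, lysosome_id=i)
                for i in range(10)]
        r, p = ph_size_correlation(recs)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_hand_computed_r(self):
        recs = [measurement(ph, area=a, lysosome_id=i)
                for i, (a, ph) in enumerate([(1, 1), (2, 2), (3, 2)])]
        r, _ = ph_size_correlation(recs)
        assert r == pytest.approx(0.866, abs=1e-3)

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(11)
        recs = [measurement(float(rng.normal(4.3, 0.2)),
                            area=float(rng.lognormal(0, 0.3)), lysosome_id=i)
                for i in range(1000)]
        r, _ = ph_size_correlation(recs)
        assert abs(r) < 0.08  # 2.5 / sqrt(n)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            ph_size_correlation([measurement(4.0, lysosome_id=i) for i in range(5)])


class TestTwoSampleTest:
    def test_identical_groups(self):
        t, p = two_sample_test([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_paired_zero_mean_difference(self):
        t, p = two_sample_test([1, 2], [2, 1], paired=True)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        t, p = two_sample_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=1e-3)

    def test_degenerate_variance_errors(self):
        with pytest.raises(ValueError):
            two_sample_test([1, 1], [2, 2])
        with pytest.raises(ValueError):
            two_sample_test([1, 2], [2, 3], paired=True)

    def test_welch_differs_with_unequal_variances(self):
        a = [1.0, 1.1, 0.9, 1.05, 0.95]
        b = [2.0, 4.0, 0.5, 3.5, 1.0]
        t_pooled, _ = two_sample_test(a, b)
        t_welch, _ = two_sample_test(a, b, welch=True)
        assert t_pooled == pytest.approx(t_welch, rel=1e-9)  # same t, different df
        _, p_pooled = two_sample_test(a, b)
        _, p_welch = two_sample_test(a, b, welch=True)
        assert p_pooled != p_welch
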