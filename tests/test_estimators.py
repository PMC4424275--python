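import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sprforest import (
    estimate_cfi,
    estimate_temporary,
    percent_standard_error,
    spr_change,
    spr_current,
    spr_fit,
)
from sprforest.errors import (
    DegenerateRegressionError,
    DesignError,
    InsufficientDataError,
    PairingError,
)

from .oracle import cfi_oracle, spr_oracle, temporary_oracle

X = [10.0, 20.0, 30.0]
Y = [12.0, 24.0, 30.0]


class TestTemporary:
    def test_hand_example(self):
        est = estimate_temporary(X, Y)
        assert est.change == pytest.approx(2.0)
        assert est.variance == pytest.approx(100 / 3 + 28.0)

    def test_constant_samples(self):
        est = estimate_temporary([5.0, 5.0], [5.0, 5.0])
        assert est.change == 0.0
        assert est.variance == 0.0

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            estimate_temporary([1.0], [1.0, 2.0])


class TestCFI:
    def test_hand_example(self):
        est = estimate_cfi(X, Y)
        assert est.change == pytest.approx(2.0)
        assert est.variance == pytest.approx(4.0 / 3.0, rel=1e-9)

    def test_identical_pairs(self):
        est = estimate_cfi(X, X)
        assert est.change == 0.0
        assert est.variance == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift_zero_variance(self):
        est = estimate_cfi(X, [x + 5 for x in X])
        assert est.change == pytest.approx(5.0)
        assert est.variance == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(PairingError):
            estimate_cfi(X, Y[:2])

    def test_zero_spread_falls_back_with_flag(self):
        with pytest.warns(UserWarning):
            est = estimate_cfi([3.0, 3.0, 3.0], Y)
        assert "r_undefined" in est.flags
        assert est.variance == pytest.approx(mean_var(Y))


def mean_var(v):
    v = np.asarray(v)
    return float(((v - v.mean()) ** 2).sum() / (len(v) * (len(v) - 1)))


class TestSPRWorkedExample:
    """The fully hand-computed chain on x12=(10,20,30), y12=(12,24,30),
    x1_all=(10,20,30,40), y_new=(20,30)."""

    @pytest.fixture()
    def comps(self):
        return spr_fit([10, 20, 30, 40], X, Y, [20.0, 30.0])

    def test_regression_update(self, comps):
        assert comps.beta_yx == pytest.approx(0.9)
        assert comps.yI == pytest.approx(26.5)
        assert comps.s2_yx == pytest.approx(6.0)
        assert comps.vI == pytest.approx(22.25)

    def test_new_plot_mean(self, comps):
        assert comps.yII == pytest.approx(25.0)
        assert comps.vII == pytest.approx(25.0)

    def test_combined_current(self, comps):
        cur = spr_current(comps)
        assert cur.mean == pytest.approx(25.7936507936, rel=1e-9)
        assert cur.variance == pytest.approx(29.3714, rel=1e-4)

    def test_change_and_corrected_variance(self, comps):
        est = spr_change(comps)
        assert est.change == pytest.approx(0.79365079, rel=1e-7)
        oracle = spr_oracle([10, 20, 30, 40], X, Y, [20.0, 30.0])
        assert est.variance == pytest.approx(oracle["change_variance"], rel=1e-12)

    def test_as_printed_goes_negative_with_flag(self, comps):
        est = spr_change(comps, mode="as_printed")
        assert est.variance < 0
        assert "negative_variance" in est.flags
        oracle = spr_oracle([10, 20, 30, 40], X, Y, [20.0, 30.0], mode="as_printed")
        assert est.variance == pytest.approx(oracle["change_variance"], rel=1e-12)

    def test_no_unmatched_time1_plots_collapses_update(self):
        comps = spr_fit(X, X, Y, [20.0, 30.0])
        assert comps.yI == pytest.approx(comps.ybar12)


class TestSPRContracts:
    def test_design_errors(self):
        with pytest.raises(DesignError):
            spr_fit([1, 2, 3], [1.0, 2.0], [1.0, 2.0], [1.0, 2.0])
        with pytest.raises(DesignError):
            spr_fit([1, 2, 3, 4], X, Y, [5.0])

    def test_constant_x12_rejected(self):
        with pytest.raises(DegenerateRegressionError):
            spr_fit([2, 2, 2, 3], [2.0, 2.0, 2.0], Y, [1.0, 2.0])

    def test_equal_component_variances_average(self):
        # symmetric toy data where vI == vII would average the means;
        # approximate: check the convex-combination invariant instead
        rng = np.random.default_rng(5)
        for _ in range(20):
            x12 = rng.normal(100, 20, 8)
            y12 = 0.9 * x12 + rng.normal(0, 10, 8)
            x1 = np.concatenate([x12, rng.normal(100, 20, 4)])
            ynew = rng.normal(110, 20, 5)
            comps = spr_fit(x1, x12, y12, ynew)
            cur = spr_current(comps)
            assert min(comps.yI, comps.yII) - 1e-9 <= cur.mean <= max(comps.yI, comps.yII) + 1e-9

    def test_zero_beta_reduces_corrected_variance(self, rng):
        x12 = np.array([10.0, 20.0, 30.0, 40.0])
        y12 = np.array([7.0, 7.0, 7.0, 7.0])  # flat: beta = 0
        comps = spr_fit(x12, x12, y12, [6.0, 8.0])
        est = spr_change(comps)
        expect = 1.0 / comps.w + comps.s2_x1 / comps.n1
        assert est.variance == pytest.approx(expect, rel=1e-12)


class TestOracleEquivalence:
    def test_random_instances_match_brute_force(self, rng):
        """Vectorised estimators agree with explicit-sum recomputation to
        1e-10 relative on random small designs."""
        for _ in range(300):
            n12 = int(rng.integers(3, 11))
            nm2 = int(rng.integers(2, 11))
            n1only = int(rng.integers(0, 6))
            x12 = rng.normal(120, 50, n12)
            y12 = x12 * rng.uniform(0.7, 1.3) + rng.normal(0, 25, n12)
            x1 = np.concatenate([x12, rng.normal(120, 50, n1only)])
            ynew = rng.normal(130, 50, nm2)

            comps = spr_fit(x1, x12, y12, ynew)
            ora = spr_oracle(list(x1), list(x12), list(y12), list(ynew))
            for f in ("xbar1", "xbar12", "ybar12", "ybar_minus2", "s_xy",
                      "s2_x12", "s2_y12", "s2_yx", "r", "beta_yx", "s2_x1",
                      "yI", "yII", "vI", "vII", "wI", "wII", "w"):
                assert getattr(comps, f) == pytest.approx(ora[f], rel=1e-10), f

            cur = spr_current(comps)
            assert cur.mean == pytest.approx(ora["current_mean"], rel=1e-10)
            assert cur.variance == pytest.approx(ora["current_variance"], rel=1e-10)

            t = estimate_temporary(x1, ynew)
            to = temporary_oracle(list(x1), list(ynew))
            assert t.change == pytest.approx(to["change"], rel=1e-10)
            assert t.variance == pytest.approx(to["variance"], rel=1e-10)

            c = estimate_cfi(x12, y12)
            co = cfi_oracle(list(x12), list(y12))
            assert c.change == pytest.approx(co["change"], rel=1e-10)
            assert c.variance == pytest.approx(co["variance"], rel=1e-10, abs=1e-12)


class TestEquivariance:
    @settings(max_examples=60, deadline=None)
    @given(
        c=st.floats(min_value=-50, max_value=50),
        k=st.floats(min_value=0.1, max_value=10),
        seed=st.integers(min_value=0, max_value=2**20),
    )
    def test_location_scale(self, c, k, seed):
        rng = np.random.default_rng(seed)
        x12 = rng.normal(100, 30, 6)
        y12 = x12 + rng.normal(5, 10, 6)
        x1 = np.concatenate([x12, rng.normal(100, 30, 3)])
        ynew = rng.normal(105, 30, 4)

        base = spr_change(spr_fit(x1, x12, y12, ynew))
        shifted = spr_change(spr_fit(x1, x12, y12 + c, ynew + c))
        assert shifted.change == pytest.approx(base.change + c, abs=1e-8 * max(1, abs(base.change)))
        assert shifted.variance == pytest.approx(base.variance, rel=1e-8)

        scaled = spr_change(spr_fit(k * x1, k * x12, k * y12, k * ynew))
        assert scaled.change == pytest.approx(k * base.change, rel=1e-8)
        assert scaled.variance == pytest.approx(k**2 * base.variance, rel=1e-8)

    def test_cfi_beats_temporary_under_positive_correlation(self, rng):
        for _ in range(50):
            x = rng.normal(120, 40, 30)
            y = x + rng.normal(10, 15, 30)
            if np.corrcoef(x, y)[0, 1] <= 0:
                continue
            assert estimate_cfi(x, y).variance < estimate_temporary(x, y).variance


class TestPercentSE:
    def test_basic_ratio(self):
        est = estimate_temporary([0.0, 20.0], [8.0, 12.0])
        # change 0 -> own-change reference undefined
        assert math.isnan(percent_standard_error(est))
        assert percent_standard_error(est, ref=10.0) == pytest.approx(10.0 * est.se)

    def test_explicit_reference(self):
        est = estimate_cfi(X, Y)
        assert percent_standard_error(est, ref=2.0) == pytest.approx(100 * est.se / 2.0)
        assert percent_standard_error(est, denominator="current_mean", ref=22.0) \
            == pytest.approx(100 * est.se / 22.0)

    def test_current_mean_needs_ref(self):
        est = estimate_cfi(X, Y)
        with pytest.raises(ValueError):
            percent_standard_error(est, denominator="current_mean")
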