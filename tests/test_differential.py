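import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_table
from oracles import quadrature_auc
from longomix.differential import (
    DifferentialCall,
    call_regulation,
    compute_auc,
    differential_analysis,
    fold_change,
    max_fold_change,
)


class TestComputeAuc:
    def test_constant_rectangle(self):
        days = np.arange(3.0, 18.0)  # D3..D17
        out = compute_auc(days, np.full((2, days.size), 7.0))
        assert out.auc == pytest.approx(14 * 7.0)

    def test_trapezoid_arithmetic(self):
        out = compute_auc([0.0, 2.0, 4.0], [2.0, 4.0, 6.0])
        assert out.auc == pytest.approx(16.0)

    @pytest.mark.parametrize("days", [
        (3.0, 5.0, 7.0, 10.0, 12.0, 14.0, 17.0),  # intracellular/protein grid
        (0.0, 3.0, 5.0, 7.0, 10.0, 12.0, 14.0, 17.0),  # extracellular grid
    ])
    def test_study_day_grids(self, days, rng):
        vals = rng.lognormal(size=(3, len(days)))
        out = compute_auc(days, vals)
        assert out.auc == pytest.approx(np.trapezoid(vals.mean(axis=0), days))

    def test_missing_replicates_skipped(self):
        vals = np.array([[2.0, np.nan, 6.0], [2.0, 4.0, np.nan]])
        out = compute_auc([0.0, 2.0, 4.0], vals)
        assert out.mean_abundance_per_day == pytest.approx([2.0, 4.0, 6.0])

    def test_all_missing_day_errors_with_day_named(self):
        vals = np.array([[2.0, np.nan, 6.0], [2.0, np.nan, 5.0]])
        with pytest.raises(ValueError, match="day 2"):
            compute_auc([0.0, 2.0, 4.0], vals)

    def test_replicate_order_invariance(self, rng):
        vals = rng.lognormal(size=(4, 5))
        days = [1.0, 2.0, 4.0, 7.0, 9.0]
        a = compute_auc(days, vals).auc
        b = compute_auc(days, vals[::-1]).auc
        assert a == pytest.approx(b)

    def test_zero_iff_all_zero(self):
        assert compute_auc([0, 1, 2], [0.0, 0.0, 0.0]).auc == 0.0
        assert compute_auc([0, 1, 2], [0.0, 1.0, 0.0]).auc > 0.0

    def test_rejects_single_day(self):
        with pytest.raises(ValueError):
            compute_auc([3.0], [1.0])

    @settings(max_examples=60, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_quadrature_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 9))
        days = np.sort(r.uniform(0, 20, size=n))
        while np.unique(days).size != n:
            days = np.sort(r.uniform(0, 20, size=n))
        means = r.lognormal(mean=8, size=n)
        ours = compute_auc(days, means).auc
        ref = quadrature_auc(days, means)
        assert ours == pytest.approx(ref, rel=1e-10)


class TestFoldChange:
    def test_basic_ratio(self):
        assert fold_change(3.0, 2.0) == pytest.approx(1.5)

    def test_equal_aucs_unity(self):
        assert fold_change(5.0, 5.0) == pytest.approx(1.0)

    def test_down_regulation_signed(self):
        assert fold_change(2.0, 3.0) == pytest.approx(-1.5)

    def test_infinite_increase(self):
        assert fold_change(9000.0, 0.0, floor=5000.0) == math.inf

    def test_infinite_decrease(self):
        assert fold_change(0.0, 9000.0, floor=5000.0) == -math.inf

    def test_both_below_floor_undefined(self):
        assert math.isnan(fold_change(100.0, 200.0, floor=5000.0))

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            fold_change(-1.0, 2.0)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(min_value=1e-3, max_value=1e6),
           st.floats(min_value=1e-3, max_value=1e6))
    def test_antisymmetry(self, a, b):
        fc = fold_change(a, b)
        rev = fold_change(b, a)
        assert fc == pytest.approx(-rev) or (fc == 1.0 and rev == 1.0)

    def test_range_excludes_open_interval(self, rng):
        for _ in range(200):
            fc = fold_change(float(rng.uniform(0.01, 10)), float(rng.uniform(0.01, 10)))
            assert abs(fc) >= 1.0


class TestMaxFoldChange:
    def test_identical_trajectories(self):
        fc, day = max_fold_change([3, 5, 7], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert fc == pytest.approx(1.0)

    def test_single_day_spike(self):
        fc, day = max_fold_change([3, 5, 7], [1.0, 4.0, 3.0], [1.0, 2.0, 3.0])
        assert fc == pytest.approx(2.0)
        assert day == 5.0

    def test_largest_magnitude_wins_with_sign(self):
        # ratio series (+1.2, -1.3, +1.1)
        test = [1.2, 1.0, 1.1]
        control = [1.0, 1.3, 1.0]
        fc, day = max_fold_change([3, 5, 7], test, control)
        # brute force over all days
        per_day = [fold_change(t, c) for t, c in zip(test, control)]
        expected = max(per_day, key=abs)
        assert fc == pytest.approx(expected) == pytest.approx(-1.3)
        assert day == 5.0

    def test_no_usable_day_undefined(self):
        fc, day = max_fold_change([3, 5], [1.0, 2.0], [3.0, 4.0], floor=100.0)
        assert math.isnan(fc) and day is None

    def test_one_sided_day_gives_infinity(self):
        fc, day = max_fold_change([3, 5], [1.0, 200.0], [1.0, 2.0], floor=100.0)
        assert fc == math.inf and day == 5.0


class TestCallRegulation:
    def _call(self, fc):
        return DifferentialCall("F0", 1.0, 1.0, signed_fc=fc)

    def test_metabolite_boundary_inclusive(self):
        out = call_regulation([self._call(1.5)], 1.5, {"F0"})
        assert out[0].regulated and out[0].direction == "up"

    def test_protein_vs_metabolite_threshold(self):
        up = call_regulation([self._call(1.15)], 1.1, {"F0"})[0]
        assert up.regulated and up.direction == "up"
        not_reg = call_regulation([self._call(1.15)], 1.5, {"F0"})[0]
        assert not not_reg.regulated

    def test_requires_opls_significance(self):
        out = call_regulation([self._call(3.0)], 1.5, set())[0]
        assert out.passes_threshold and not out.regulated
        assert out.direction == "none"

    def test_infinite_fc_passes(self):
        out = call_regulation([self._call(math.inf)], 1.5, {"F0"})[0]
        assert out.regulated and out.direction == "up"

    def test_nan_never_regulated(self):
        out = call_regulation([self._call(math.nan)], 1.5, {"F0"})[0]
        assert not out.passes_threshold and not out.regulated

    def test_down_direction(self):
        out = call_regulation([self._call(-2.0)], 1.5, {"F0"})[0]
        assert out.regulated and out.direction == "down"

    def test_rejects_threshold_below_one(self):
        with pytest.raises(ValueError):
            call_regulation([self._call(2.0)], 0.9, {"F0"})


class TestDifferentialAnalysis:
    def test_swapping_conditions_flips_sign_and_direction(self, tiny_table):
        sig = set(tiny_table.feature_ids)
        fwd = differential_analysis(tiny_table, sig, threshold=1.1)
        rev = differential_analysis(tiny_table, sig, threshold=1.1,
                                    test_condition="control",
                                    control_condition="test")
        for f, r in zip(fwd, rev):
            assert f.signed_fc == pytest.approx(-r.signed_fc) or (
                f.signed_fc == 1.0 and r.signed_fc == 1.0)
            if f.regulated and f.direction == "up":
                assert r.direction == "down"

    def test_exclusive_feature_infinite(self):
        ab = np.array([[8e4, 8e4, 8e4, np.nan, np.nan, np.nan]])
        table = make_table(ab)
        out = differential_analysis(table, {"F000"}, threshold=1.5, floor=5000.0)
        assert out[0].signed_fc == math.inf
        assert out[0].regulated

    def test_day_grid_mismatch_warns_and_intersects(self, tiny_table):
        meta = tiny_table.sample_meta.copy()
        meta.loc["test_r1_d3", "day"] = 4.0  # test grid now {4,5,7}
        table = make_table(tiny_table.abundances.to_numpy())
        table.sample_meta = meta
        with pytest.warns(UserWarning, match="intersection"):
            out = differential_analysis(table, set(), threshold=1.5)
        assert len(out) == tiny_table.n_features
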