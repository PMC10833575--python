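"""Dice schedules, ICC(A,k) against independent oracles, ratings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from fluoroquant.agreement import (
    DegenerateMatrixError,
    DscRecord,
    ICCResult,
    RaterMatrix,
    compare_by_ci_overlap,
    dice,
    icc_absolute_agreement,
    interobserver_dsc_schedule,
    interobserver_rater_matrix,
    intraobserver_dsc_schedule,
    intraobserver_rater_matrix,
    rate_icc,
)
from helpers import analytic_icc_a_k, anova_icc_a_k, simulate_rater_matrix


def _mask(shape, r0, r1, c0, c1):
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


class TestDice:
    def test_identical_masks_give_one(self, rng):
        for _ in range(5):
            m = rng.random((30, 30)) < 0.3
            m[0, 0] = True
            assert dice(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = _mask((20, 20), 0, 5, 0, 5)
        b = _mask((20, 20), 10, 15, 10, 15)
        assert dice(a, b) == 0.0

    def test_half_overlapping_squares(self):
        a = _mask((20, 30), 5, 15, 5, 15)  # 100 px
        b = _mask((20, 30), 5, 15, 10, 20)  # 100 px, overlap 50
        assert dice(a, b) == 0.5

    @settings(max_examples=30, deadline=None)
    @given(
        a=hnp.arrays(bool, (12, 12), elements=st.booleans()),
        b=hnp.arrays(bool, (12, 12), elements=st.booleans()),
    )
    def test_symmetric_and_bounded(self, a, b):
        if not (a.any() or b.any()):
            a[0, 0] = True
        d = dice(a, b)
        assert d == dice(b, a)
        assert 0.0 <= d <= 1.0

    def test_both_empty_undefined(self):
        z = np.zeros((5, 5), dtype=bool)
        with pytest.raises(ValueError, match="undefined DSC"):
            dice(z, z)


class TestDscSchedules:
    observers = ("obs1", "obs2", "obs3")
    sessions = ("s1", "s2")

    def _full_masks(self, rng, identical=False):
        base = _mask((40, 40), 10, 30, 10, 30)
        masks = {}
        for o in self.observers:
            for s in self.sessions:
                if identical:
                    masks[(o, s)] = base
                else:
                    m = base.copy()
                    m[rng.integers(10, 30), rng.integers(10, 30)] ^= True
                    masks[(o, s)] = m
        return masks

    def test_interobserver_yields_twelve_records(self, rng):
        records = interobserver_dsc_schedule(self._full_masks(rng), "loaf_00")
        assert len(records) == 12
        pairs = {r.observers for r in records}
        assert pairs == {("obs1", "obs2"), ("obs1", "obs3"), ("obs2", "obs3")}
        combos = {(r.observers, r.sessions) for r in records}
        assert len(combos) == 12  # all four session combinations per pair

    def test_intraobserver_yields_three_records(self, rng):
        records = intraobserver_dsc_schedule(self._full_masks(rng), "loaf_00")
        assert len(records) == 3
        assert {r.observers[0] for r in records} == set(self.observers)
        assert all(r.sessions == ("s1", "s2") for r in records)

    def test_identical_delineations_all_score_one(self, rng):
        masks = self._full_masks(rng, identical=True)
        assert all(r.dsc == 1.0 for r in interobserver_dsc_schedule(masks))
        assert all(r.dsc == 1.0 for r in intraobserver_dsc_schedule(masks))

    def test_missing_combination_reported(self, rng):
        masks = self._full_masks(rng)
        del masks[("obs2", "s2")]
        with pytest.raises(ValueError, match=r"obs2.*s2"):
            interobserver_dsc_schedule(masks)

    def test_wrong_observer_count_rejected(self, rng):
        masks = {k: v for k, v in self._full_masks(rng).items() if k[0] != "obs3"}
        with pytest.raises(ValueError, match="3 observers"):
            intraobserver_dsc_schedule(masks)

    def test_record_validates_range(self):
        with pytest.raises(ValueError, match="range"):
            DscRecord("l", "signal_or_tumor", "interobserver", ("a", "b"), ("s", "s"), 1.2)


class TestIccEstimate:
    def test_matches_bruteforce_anova_on_random_matrices(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 13))
            k = int(rng.integers(2, 5))
            x = simulate_rater_matrix(n, k, 1.0, 0.3, 0.5, rng)
            res = icc_absolute_agreement(RaterMatrix(x))
            assert res.estimate == pytest.approx(anova_icc_a_k(x), abs=1e-10)

    def test_perfect_agreement_is_exactly_one(self):
        col = np.array([1.0, 2.0, 5.0, 9.0])
        res = icc_absolute_agreement(RaterMatrix(np.stack([col, col, col], axis=1)))
        assert res.estimate == 1.0
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)
        assert res.rating_point == "excellent"

    def test_pure_rater_bias_lowers_absolute_agreement(self, rng):
        x = simulate_rater_matrix(10, 3, 1.0, 0.0, 0.1, rng)
        base = icc_absolute_agreement(RaterMatrix(x)).estimate
        biased = x.copy()
        biased[:, 1] += 1.5
        assert icc_absolute_agreement(RaterMatrix(biased)).estimate < base

    def test_matches_pingouin_point_and_interval(self, rng):
        pg = pytest.importorskip("pingouin")
        for seed in range(3):
            r = np.random.default_rng(seed)
            x = simulate_rater_matrix(15, 3, 1.0, 0.3, 0.4, r)
            res = icc_absolute_agreement(RaterMatrix(x))
            df = pd.DataFrame(
                {
                    "subj": np.repeat(np.arange(15), 3),
                    "rater": list(range(3)) * 15,
                    "y": x.ravel(),
                }
            )
            table = pg.intraclass_corr(df, targets="subj", raters="rater", ratings="y")
            row = table[table["Type"] == "ICC(A,k)"].iloc[0]
            assert res.estimate == pytest.approx(row["ICC"], abs=1e-10)
            lo, hi = row["CI95"]  # pingouin rounds the interval to 2 decimals
            assert res.ci_low == pytest.approx(lo, abs=0.005)
            assert res.ci_high == pytest.approx(hi, abs=0.005)

    def test_parameter_recovery_converges(self, rng):
        # additive model with known variance components, n large
        target = analytic_icc_a_k(1.0, 0.1, 0.1, k=3)
        estimates = [
            icc_absolute_agreement(RaterMatrix(simulate_rater_matrix(200, 3, 1.0, 0.1, 0.1, rng))).estimate
            for _ in range(100)
        ]
        sem = np.std(estimates) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - target) < max(4 * sem, 5e-4)

    def test_negative_estimate_flagged_not_truncated(self):
        # strong rater disagreement, no subject signal
        x = np.array([[0.0, 10.0], [0.1, 9.9], [0.05, 10.1], [0.0, 10.0]])
        res = icc_absolute_agreement(RaterMatrix(x))
        assert res.estimate < 0
        assert res.negative_estimate

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(DegenerateMatrixError):
            icc_absolute_agreement(RaterMatrix(np.full((4, 3), 2.0)))

    def test_small_designs_rejected(self):
        with pytest.raises(ValueError):
            RaterMatrix(np.ones((1, 3)))
        with pytest.raises(ValueError):
            RaterMatrix(np.ones((3, 1)))
        with pytest.raises(ValueError, match="complete"):
            RaterMatrix(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestRatings:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.49, "poor"),
            (0.5, "moderate"),
            (0.66, "moderate"),
            (0.75, "moderate"),
            (0.76, "good"),
            (0.9, "good"),
            (0.91, "excellent"),
            (0.98, "excellent"),
            (-0.2, "poor"),
        ],
    )
    def test_bands(self, value, expected):
        assert rate_icc(value) == expected

    def test_result_rating_range_spans_interval(self):
        res = ICCResult(estimate=0.66, ci_low=0.24, ci_high=0.86, alpha=0.05, n=20, k=3)
        assert res.rating_point == "moderate"
        assert res.rating_range == ("poor", "good")
        res2 = ICCResult(estimate=0.80, ci_low=0.57, ci_high=0.91, alpha=0.05, n=30, k=2)
        assert res2.rating_range == ("moderate", "excellent")

    def test_interval_must_bracket_estimate(self):
        with pytest.raises(ValueError, match="bracket"):
            ICCResult(estimate=0.9, ci_low=0.95, ci_high=0.99, alpha=0.05, n=10, k=3)


class TestCiOverlap:
    def _res(self, est, lo, hi):
        return ICCResult(estimate=est, ci_low=lo, ci_high=hi, alpha=0.05, n=20, k=3)

    def test_disjoint_intervals_significant(self):
        a = self._res(0.98, 0.95, 0.99)
        b = self._res(0.66, 0.24, 0.86)
        assert compare_by_ci_overlap(a, b) == "significant"
        assert compare_by_ci_overlap(b, a) == "significant"

    def test_overlapping_intervals_not_significant(self):
        a = self._res(0.93, 0.60, 0.98)
        b = self._res(0.96, 0.92, 0.98)
        assert compare_by_ci_overlap(a, b) == "not_significant"

    def test_identical_intervals_not_significant(self):
        a = self._res(0.8, 0.6, 0.9)
        assert compare_by_ci_overlap(a, a) == "not_significant"


class TestStacking:
    def _long_df(self):
        rows = []
        rng = np.random.default_rng(3)
        for loaf in range(4):
            for ses in ("s1", "s2"):
                for obs in ("o1", "o2", "o3"):
                    rows.append(
                        {
                            "loaf_id": f"loaf_{loaf}",
                            "session": ses,
                            "observer": obs,
                            "ratio": 5 + loaf + rng.normal(0, 0.1),
                        }
                    )
        return pd.DataFrame(rows)

    def test_interobserver_stacks_loaf_by_session(self):
        m = interobserver_rater_matrix(self._long_df())
        assert (m.n, m.k) == (8, 3)  # 4 loaves x 2 sessions, 3 observers

    def test_intraobserver_stacks_loaf_by_observer(self):
        m = intraobserver_rater_matrix(self._long_df())
        assert (m.n, m.k) == (12, 2)  # 4 loaves x 3 observers, 2 sessions

    def test_incomplete_design_reported(self):
        df = self._long_df().iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            interobserver_rater_matrix(df)
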