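"""Two-condition differential calling against an independent rule oracle."""

import numpy as np
import pytest
from scipy import stats

from diffshape.differential import compare_profiles, mg_differential_report, records_to_frame
from .conftest import make_replicate_set


def welch_p_oracle(x, y):
    """Hand-coded two-sided Welch t-test (Satterthwaite df)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return 2.0 * stats.t.sf(abs(t), df)


def rule_oracle(x, y, dr=0.2, rel=0.2, alpha=0.05):
    """Independent brute-force evaluation of the three-criterion rule."""
    r1, r2 = np.mean(x), np.mean(y)
    delta = abs(r1 - r2)
    total = r1 + r2
    if total <= 0:
        return False
    p = welch_p_oracle(x, y)
    return delta > dr and delta / total > rel and p < alpha


class TestCompareProfiles:
    def test_identical_sets_yield_no_calls(self):
        rows = [(0.1, 0.2, 0.3), (1.0, 1.1, 0.9)]
        recs = compare_profiles(make_replicate_set(rows), make_replicate_set(rows))
        assert [r.delta_r for r in recs] == [0.0, 0.0]
        assert not any(r.significant for r in recs)
        assert all(r.direction == "none" for r in recs)

    def test_worked_example_matches_hand_welch(self):
        a = make_replicate_set([(1.0, 1.1, 0.9)])
        b = make_replicate_set([(0.40, 0.50, 0.45)])
        (rec,) = compare_profiles(a, b)
        assert rec.delta_r == pytest.approx(0.55)
        assert rec.rel_change == pytest.approx(0.55 / 1.45)
        assert rec.p_value == pytest.approx(welch_p_oracle([1.0, 1.1, 0.9], [0.40, 0.50, 0.45]))
        assert rec.significant
        assert rec.direction == "down_in_2"

    def test_delta_exactly_at_threshold_is_not_significant(self):
        # deltaR = 0.2 exactly; zero variance makes p = 0, yet the strict
        # "exceeds 0.2" rule must reject the call.
        a = make_replicate_set([(0.5, 0.5, 0.5)])
        b = make_replicate_set([(0.7, 0.7, 0.7)])
        (rec,) = compare_profiles(a, b)
        assert rec.delta_r == pytest.approx(0.2)
        assert rec.p_value == 0.0
        assert rec.flag == "degenerate_variance"
        assert not rec.significant

    def test_rel_change_exactly_at_threshold_is_not_significant(self):
        # R1 = 0.8, R2 = 1.2: deltaR = 0.4 > 0.2 but rel = 0.4/2.0 = 0.2.
        a = make_replicate_set([(0.8, 0.8, 0.8)])
        b = make_replicate_set([(1.2, 1.2, 1.2)])
        (rec,) = compare_profiles(a, b)
        assert rec.delta_r == pytest.approx(0.4)
        assert rec.rel_change == pytest.approx(0.2)
        assert not rec.significant

    def test_symmetry_flips_direction_only(self):
        rng = np.random.default_rng(11)
        rows_a = [tuple(rng.normal(0.5, 0.2, 3)) for _ in range(50)]
        rows_b = [tuple(rng.normal(0.7, 0.2, 3)) for _ in range(50)]
        fwd = compare_profiles(make_replicate_set(rows_a), make_replicate_set(rows_b))
        rev = compare_profiles(make_replicate_set(rows_b), make_replicate_set(rows_a))
        flip = {"up_in_2": "down_in_2", "down_in_2": "up_in_2", "none": "none"}
        for f, r in zip(fwd, rev):
            assert f.delta_r == pytest.approx(r.delta_r)
            assert f.rel_change == pytest.approx(r.rel_change)
            assert f.p_value == pytest.approx(r.p_value)
            assert f.significant == r.significant
            assert flip[f.direction] == r.direction

    def test_rel_change_bounded_for_nonnegative_means(self):
        rng = np.random.default_rng(5)
        rows_a = [tuple(rng.uniform(0.0, 2.0, 3)) for _ in range(200)]
        rows_b = [tuple(rng.uniform(0.0, 2.0, 3)) for _ in range(200)]
        recs = compare_profiles(make_replicate_set(rows_a), make_replicate_set(rows_b))
        rels = np.array([r.rel_change for r in recs])
        assert np.all(rels[np.isfinite(rels)] >= 0)
        assert np.all(rels[np.isfinite(rels)] <= 1)

    def test_matches_bruteforce_rule_on_random_triplicates(self):
        rng = np.random.default_rng(123)
        rows_a = [tuple(rng.normal(rng.uniform(0, 1.5), 0.15, 3)) for _ in range(300)]
        rows_b = [tuple(rng.normal(rng.uniform(0, 1.5), 0.15, 3)) for _ in range(300)]
        recs = compare_profiles(make_replicate_set(rows_a), make_replicate_set(rows_b))
        for rec, x, y in zip(recs, rows_a, rows_b):
            assert rec.significant == rule_oracle(x, y), f"mismatch at {rec.position}"

    def test_nonpositive_sum_is_flagged_not_significant(self):
        a = make_replicate_set([(-0.5, -0.6, -0.4)])
        b = make_replicate_set([(0.1, 0.2, 0.15)])
        (rec,) = compare_profiles(a, b)
        assert rec.flag == "nonpositive_sum"
        assert not rec.significant

    def test_single_replicate_side_is_flagged(self):
        a = make_replicate_set([(0.9,)])
        b = make_replicate_set([(0.1, 0.2, 0.15)])
        (rec,) = compare_profiles(a, b)
        assert rec.flag == "insufficient_replicates"
        assert np.isnan(rec.p_value)
        assert not rec.significant

    def test_undetermined_positions_excluded(self):
        a = make_replicate_set([(0.1, 0.2, 0.3), ()])
        b = make_replicate_set([(0.9, 1.0, 1.1), (0.5, 0.5, 0.5)])
        recs = compare_profiles(a, b)
        assert [r.position for r in recs] == [1]

    def test_no_shared_positions_warns_and_returns_empty(self):
        a = make_replicate_set([(0.1, 0.2, 0.3)], start=1)
        b = make_replicate_set([(0.9, 1.0, 1.1)], start=100)
        with pytest.warns(UserWarning):
            assert compare_profiles(a, b) == []

    def test_bh_adjustment_is_more_conservative(self):
        rng = np.random.default_rng(3)
        rows_a = [tuple(rng.normal(0.3, 0.1, 3)) for _ in range(100)]
        rows_b = [tuple(rng.normal(0.75, 0.1, 3)) for _ in range(100)]
        raw = compare_profiles(make_replicate_set(rows_a), make_replicate_set(rows_b))
        adj = compare_profiles(make_replicate_set(rows_a), make_replicate_set(rows_b), adjust="bh")
        assert sum(r.significant for r in adj) <= sum(r.significant for r in raw)


class TestReport:
    def test_counts_per_class_and_direction(self):
        a = make_replicate_set([(0.1, 0.12, 0.11)] * 3)
        b = make_replicate_set([(0.9, 0.95, 0.85), (0.1, 0.12, 0.11), (0.9, 0.95, 0.85)])
        recs = compare_profiles(a, b)
        annotation = {1: "PK3", 2: "HELIX"}  # position 3 left unannotated
        rep = mg_differential_report(recs, annotation)
        assert rep.loc["PK3", "n_significant"] == 1
        assert rep.loc["PK3", "n_up_in_2"] == 1
        assert rep.loc["HELIX", "n_significant"] == 0
        assert rep.loc["unannotated", "n_significant"] == 1
        assert rep["n_compared"].sum() == 3

    def test_no_calls_gives_zero_counts(self):
        rows = [(0.5, 0.5, 0.52)]
        recs = compare_profiles(make_replicate_set(rows), make_replicate_set(rows))
        rep = mg_differential_report(recs, {1: "SS"})
        assert rep["n_significant"].sum() == 0

    def test_frame_has_expected_columns(self):
        rows = [(0.5, 0.5, 0.52)]
        recs = compare_profiles(make_replicate_set(rows), make_replicate_set(rows))
        frame = records_to_frame(recs)
        assert list(frame.columns)[:5] == ["position", "base", "R1", "R2", "deltaR"]
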