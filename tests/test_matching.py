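"""Panel normalization and the expression/activity concordance score Phi."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualscreen.matching import (
    CellLinePanel,
    aggregate_matching,
    drop_missing_pairs,
    match_panels,
    matching_score,
    normalize_pattern,
    round_half_up,
)


def panel(values, ids=None, **kwargs):
    values = np.asarray(values, dtype=float)
    if ids is None:
        ids = [f"CL{i}" for i in range(len(values))]
    return CellLinePanel(ids, values, **kwargs)


def two_level(n=60):
    """Balanced +1/-1 pattern: the maximally informative panel shape."""
    return np.where(np.arange(n) < n // 2, 1.0, -1.0)


class TestNormalizePattern:
    def test_simple_three_line_panel(self):
        out = normalize_pattern(panel([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.values, [-1.0, 0.0, 1.0])
        assert out.mu == pytest.approx(2.0)
        assert out.max_abs_dev == pytest.approx(1.0)

    def test_constant_panel_normalizes_to_zeros(self, caplog):
        with caplog.at_level("WARNING"):
            out = normalize_pattern(panel([5.0, 5.0, 5.0]))
        np.testing.assert_array_equal(out.values, np.zeros(3))
        assert any("constant" in r.message for r in caplog.records)

    def test_positive_affine_invariance(self):
        raw = np.array([3.0, -1.0, 7.0, 2.0])
        a = normalize_pattern(panel(raw))
        b = normalize_pattern(panel(3.0 * raw + 7.0))
        np.testing.assert_allclose(a.values, b.values)

    def test_single_line_fatal(self):
        with pytest.raises(ValueError):
            normalize_pattern(panel([1.0]))

    def test_negated_log10_orientation(self):
        # GI50 of 1 nM is "stronger" than 1 uM: after -log10, larger value
        p = panel([1e-9, 1e-6], orientation="negated_log10", kind="activity")
        v = p.oriented_values()
        assert v[0] > v[1]

    def test_negated_log10_requires_positive(self):
        p = panel([1e-9, 0.0], orientation="negated_log10", kind="activity")
        with pytest.raises(ValueError):
            p.oriented_values()

    @given(
        raw=st.lists(st.floats(min_value=-1e4, max_value=1e4), min_size=2, max_size=60)
        .filter(lambda v: max(v) - min(v) > 1e-2)
    )
    @settings(max_examples=100, deadline=None)
    def test_zero_sum_and_unit_max_abs(self, raw):
        out = normalize_pattern(panel(raw))
        assert out.values.sum() == pytest.approx(0.0, abs=1e-6)
        assert np.abs(out.values).max() == pytest.approx(1.0)


class TestMatchingScore:
    def test_identical_balanced_patterns_reach_panel_size(self):
        nep = normalize_pattern(panel(two_level(60)))
        res = matching_score(nep, nep)
        assert res.phi == pytest.approx(60.0)
        np.testing.assert_allclose(res.per_cell_delta, np.ones(60))

    def test_constant_activity_annihilates(self):
        nep = normalize_pattern(panel(two_level(60)))
        ngi = normalize_pattern(panel(np.full(60, 2.5)))
        assert matching_score(nep, ngi).phi == 0.0

    def test_anticorrelated_patterns(self):
        nep = normalize_pattern(panel(two_level(60)))
        ngi = normalize_pattern(panel(-two_level(60)))
        assert matching_score(nep, ngi).phi == pytest.approx(-60.0)
        assert matching_score(nep, ngi, clamp_negative=True).phi == 0.0

    def test_mismatched_ids_fatal(self):
        a = normalize_pattern(panel([1.0, 2.0, 3.0], ids=["x", "y", "z"]))
        b = normalize_pattern(panel([1.0, 2.0, 3.0], ids=["y", "x", "z"]))
        with pytest.raises(ValueError, match="reordered"):
            matching_score(a, b)

    def test_symmetry_and_line_permutation_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        a, b = normalize_pattern(panel(x)), normalize_pattern(panel(y))
        assert matching_score(a, b).phi == pytest.approx(matching_score(b, a).phi)
        perm = rng.permutation(30)
        ids = [f"CL{i}" for i in perm]
        ap = normalize_pattern(CellLinePanel(ids, x[perm]))
        bp = normalize_pattern(CellLinePanel(ids, y[perm]))
        assert matching_score(ap, bp).phi == pytest.approx(matching_score(a, b).phi)

    @given(
        x=st.lists(st.floats(min_value=-100, max_value=100), min_size=2, max_size=60)
        .filter(lambda v: max(v) - min(v) > 1e-6),
        seed=st.integers(min_value=0, max_value=1000),
    )
    @settings(max_examples=60, deadline=None)
    def test_phi_bounded_by_panel_size(self, x, seed):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(len(x))
        a, b = normalize_pattern(panel(x)), normalize_pattern(panel(y))
        assert abs(matching_score(a, b).phi) <= len(x) + 1e-9

    def test_permutation_null_centers_on_zero(self):
        rng = np.random.default_rng(11)
        x, y = rng.standard_normal(60), rng.standard_normal(60)
        a = normalize_pattern(panel(x))
        phis = []
        for _ in range(1000):
            perm = rng.permutation(60)
            b = normalize_pattern(panel(y[perm]))
            phis.append(matching_score(a, b).phi)
        se = np.std(phis) / np.sqrt(len(phis))
        assert abs(np.mean(phis)) <= 3 * se + 1e-9

    def test_missing_lines_dropped_pairwise(self):
        ids = ["a", "b", "c", "d"]
        act = CellLinePanel(ids, [1.0, np.nan, 3.0, 4.0], "activity")
        exp = CellLinePanel(ids, [1.0, 2.0, np.nan, 4.0], "expression")
        act2, exp2 = drop_missing_pairs(act, exp)
        assert act2.cell_line_ids == ["a", "d"]
        assert len(exp2) == 2


class TestAggregateMatching:
    # printed per-target maxima -> integer mean, from an eight-compound
    # dual-target matching table
    TABLE = [
        ((39, 41), 40),
        ((39, 30), 35),
        ((37, 33), 35),
        ((34, 33), 34),
        ((35, 33), 34),
        ((32, 31), 32),
        ((34, 25), 30),
        ((25, 28), 27),
    ]

    @pytest.mark.parametrize("maxima,display", TABLE)
    def test_reported_means_reproduced_with_round_half_up(self, maxima, display):
        summary = aggregate_matching({"CDK1": [maxima[0]], "PARP1": [maxima[1]]})
        assert summary.mean_matching == pytest.approx(sum(maxima) / 2)
        assert summary.mean_matching_display == display

    def test_max_over_experiments(self):
        summary = aggregate_matching({"CDK1": [10.0, 39.0, 12.0], "PARP1": [41.0, 2.0]})
        assert summary.per_target_max == {"CDK1": 39.0, "PARP1": 41.0}
        assert summary.mean_matching == pytest.approx(40.0)

    def test_single_target_identity(self):
        assert aggregate_matching({"X": [33.0]}).mean_matching == pytest.approx(33.0)

    def test_empty_experiment_list_fatal(self):
        with pytest.raises(ValueError, match="PARP1"):
            aggregate_matching({"CDK1": [1.0], "PARP1": []})

    @pytest.mark.parametrize("x,expected", [(26.5, 27), (29.5, 30), (31.5, 32),
                                            (33.5, 34), (34.5, 35), (40.0, 40), (2.4, 2)])
    def test_round_half_up(self, x, expected):
        assert round_half_up(x) == expected


class TestMatchPanels:
    def test_full_compound_analysis(self):
        ids = [f"CL{i}" for i in range(60)]
        z = two_level(60)
        activity = CellLinePanel(ids, z, "activity")
        expression = {
            "CDK1": {
                "exp1": CellLinePanel(ids, z, "expression"),
                "exp2": CellLinePanel(ids, -z, "expression"),
            },
            "PARP1": {"exp1": CellLinePanel(ids, z, "expression")},
        }
        summary, table = match_panels(activity, expression)
        assert summary.per_target_max == {"CDK1": pytest.approx(60.0),
                                          "PARP1": pytest.approx(60.0)}
        assert summary.mean_matching == pytest.approx(60.0)
        assert len(table) == 3
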