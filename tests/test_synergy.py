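"""Conditional-prevalence profiles, binned outlier flagging and overlap tests."""

import math

import numpy as np
import pytest

from cohortminer import (
    CohortFamily,
    CohortSummary,
    ConfigurationError,
    bin_and_flag,
    conditional_profile,
    overlap_significance,
    synergistic_terms,
)
from cohortminer.synergy import ConditionalRecord, hypergeom_overlap_p


def records_from(y_values, x=1.0):
    return [
        ConditionalRecord(term_id=f"T{i}", x=x, y=v, y_norm=v)
        for i, v in enumerate(y_values)
    ]


class TestBinAndFlag:
    def test_hand_computed_bin_statistics(self):
        recs = records_from([0.0, 0.0, 0.0, 0.0, 10.0])
        summaries = bin_and_flag(recs)
        assert len(summaries) == 1
        s = summaries[0]
        assert s.mean == pytest.approx(2.0)
        assert s.sd == pytest.approx(math.sqrt(20), rel=1e-12)
        assert s.upper == pytest.approx(2.0 + 1.6448536269514722 * math.sqrt(20), rel=1e-9)
        assert [r.flagged for r in recs] == [False] * 4 + [True]

    def test_degenerate_bin_flags_nothing(self):
        recs = records_from([1.5] * 6)
        bin_and_flag(recs)
        assert all(r.bin_sd == 0 and not r.flagged for r in recs)

    def test_small_bins_merge_leftward(self):
        rng = np.random.default_rng(2)
        xs = np.concatenate([rng.uniform(0, 0.5, 50), [5.0]])  # lone far-right point
        recs = [
            ConditionalRecord(term_id=f"T{i}", x=float(x), y=0.0, y_norm=float(rng.normal()))
            for i, x in enumerate(xs)
        ]
        summaries = bin_and_flag(recs, n_bins=10, min_bin_count=3)
        assert all(s.count >= 3 for s in summaries)
        assert sum(s.count for s in summaries) == len(recs)

    def test_needs_at_least_two_records(self):
        with pytest.raises(ConfigurationError):
            bin_and_flag(records_from([1.0]))

    def test_null_gaussian_flag_rate_near_five_percent(self):
        rng = np.random.default_rng(8)
        recs = [
            ConditionalRecord(term_id=f"T{i}", x=float(rng.uniform(0, 2)), y=0.0,
                              y_norm=float(rng.normal()))
            for i in range(4000)
        ]
        bin_and_flag(recs)
        rate = sum(r.flagged for r in recs) / len(recs)
        assert abs(rate - 0.05) <= 3 * math.sqrt(0.05 * 0.95 / len(recs))


class TestConditionalProfile:
    def test_no_conditional_enrichment_gives_zero_y(self, tiny_family):
        # term A sits in the intersection at exactly cohort X's rate
        recs, _ = conditional_profile(tiny_family, "X", "index_given_condition")
        rec = {r.term_id: r for r in recs}["A"]
        assert rec.y == pytest.approx(0.0, abs=1e-12)
        assert rec.y_norm == pytest.approx(0.0, abs=1e-12)

    def test_enriched_term_has_positive_normalised_score(self, tiny_family):
        recs, _ = conditional_profile(tiny_family, "X", "index_given_condition")
        rec = {r.term_id: r for r in recs}["B"]
        assert rec.y > 0 and rec.y_norm > 0

    def test_difference_normalization(self, tiny_family):
        recs, _ = conditional_profile(
            tiny_family, "X", "index_given_condition", normalization="difference"
        )
        for r in recs:
            assert r.y_norm == pytest.approx(r.y - r.x, rel=1e-12)

    def test_directions_use_different_marginals(self, tiny_family):
        d1, _ = conditional_profile(tiny_family, "X", "index_given_condition")
        d2, _ = conditional_profile(tiny_family, "X", "condition_given_index")
        x1 = {r.term_id: r.x for r in d1}
        x2 = {r.term_id: r.x for r in d2}
        assert x1["A"] != x2["A"]  # marginal LOR of index vs. of condition

    def test_low_marginal_terms_excluded_with_reason(self):
        background = CohortSummary("BG", 100_000, {"A": 1000})
        index = CohortSummary("IDX", 2000, {"A": 20})  # prevalence == background
        cond = CohortSummary("X", 1000, {"A": 100})
        inter = CohortSummary("I", 50, {"A": 10})
        family = CohortFamily(
            background=background, index=index, conditions=(cond,),
            intersections={"X": inter},
        )
        recs, exclusions = conditional_profile(family, "X", "index_given_condition")
        assert recs == []
        assert exclusions == [("A", "low_marginal_lor")]

    def test_missing_intersection_is_config_error(self, tiny_family):
        with pytest.raises(ConfigurationError):
            conditional_profile(tiny_family, "nope", "index_given_condition")

    def test_direction_asymmetry_exists_on_null_simulation(self):
        from cohortminer.synthetic import null_synergy_config, simulate_family

        family, _ = simulate_family(null_synergy_config(seed=3, n_terms=1500))
        flags = {}
        for direction in ("index_given_condition", "condition_given_index"):
            recs, _ = conditional_profile(family, "target", direction)
            bin_and_flag(recs)
            flags[direction] = {r.term_id for r in recs if r.flagged}
        assert flags["index_given_condition"] != flags["condition_given_index"]
        assert flags["index_given_condition"] - flags["condition_given_index"]


class TestSynergisticTerms:
    def test_intersection_of_directions(self):
        rep = synergistic_terms({"A", "B", "C"}, {"B", "C", "D"}, "X")
        assert rep.synergistic == {"B", "C"}
        assert rep.counts() == {
            "index_given_condition": 3,
            "condition_given_index": 3,
            "synergistic": 2,
        }

    def test_disjoint_directions(self):
        rep = synergistic_terms({"A"}, {"B"})
        assert rep.synergistic == set()


def enumeration_overlap_p(n_a, n_b, overlap, universe):
    total = math.comb(universe, n_b)
    favourable = sum(
        math.comb(n_a, k) * math.comb(universe - n_a, n_b - k)
        for k in range(overlap, min(n_a, n_b) + 1)
    )
    return favourable / total


class TestOverlapSignificance:
    def test_full_overlap_tiny_universe(self):
        p = overlap_significance({"a", "b", "c", "d", "e"},
                                 {"a", "b", "c", "d", "e"}, 10)
        assert p == pytest.approx(1 / 252, rel=1e-12)

    def test_no_overlap_in_huge_universe(self):
        p = overlap_significance({"a"}, {"b"}, 10_000)
        assert p == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("n_a,n_b,overlap,universe", [
        (5, 5, 3, 12), (4, 6, 2, 10), (7, 3, 3, 15), (2, 2, 0, 6),
    ])
    def test_matches_exhaustive_enumeration(self, n_a, n_b, overlap, universe):
        assert hypergeom_overlap_p(n_a, n_b, overlap, universe) == pytest.approx(
            enumeration_overlap_p(n_a, n_b, overlap, universe), rel=1e-12
        )

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ConfigurationError):
            hypergeom_overlap_p(5, 5, 6, 10)
        with pytest.raises(ConfigurationError):
            hypergeom_overlap_p(11, 5, 2, 10)
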