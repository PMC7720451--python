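"""Synthetic population generator: determinism, fidelity, consistency."""

import math

import numpy as np
import pytest

from cohortminer import (
    ConfigurationError,
    EffectModel,
    SimulationConfig,
    generate_population,
    simulate_family,
    summarize_cohorts,
    validate_family,
    write_cohort_summary,
)
from cohortminer.synthetic import _classify, plackett_joint_cell


def quick_config(**overrides):
    base = dict(
        n_patients=50_000,
        index_prob=0.02,
        condition_probs={"target": 0.05},
        n_terms=100,
        baseline_prevalence_range=(0.01, 0.05),
        seed=5,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("index_prob", 0.0),
        ("index_prob", 1.0),
        ("n_terms", 0),
        ("counts_rounded_to", 5),
        ("baseline_prevalence_range", (0.5, 0.1)),
        ("target_condition", "missing"),
    ])
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(ConfigurationError):
            quick_config(**{field: value})

    def test_planted_blocks_from_dict(self):
        config = SimulationConfig.from_dict(
            {
                "n_patients": 1000,
                "condition_probs": {"target": 0.05},
                "n_terms": 10,
                "planted": [
                    {"count": 3, "rr_index": 2.0, "rr_synergy": {"target": 4.0}}
                ],
            }
        )
        effects = config.resolved_effects()
        assert list(effects.rr_index[:4]) == [2.0, 2.0, 2.0, 1.0]
        assert list(effects.rr_synergy["target"][:4]) == [4.0, 4.0, 4.0, 1.0]


class TestPlackettConstruction:
    @pytest.mark.parametrize("p_i,q,orr", [
        (0.0075, 0.04, 4.0), (0.02, 0.06, 8.0), (0.1, 0.3, 0.5), (0.5, 0.5, 1.0),
    ])
    def test_cell_satisfies_margin_and_odds_ratio(self, p_i, q, orr):
        p11 = plackett_joint_cell(p_i, q, orr)
        p10, p01 = p_i - p11, q - p11
        p00 = 1 - p_i - q + p11
        assert min(p11, p10, p01, p00) >= 0
        if orr != 1.0:
            assert p11 * p00 / (p10 * p01) == pytest.approx(orr, rel=1e-9)
        else:
            assert p11 == pytest.approx(p_i * q, rel=1e-12)

    def test_empirical_co_membership_odds_ratio(self):
        config = quick_config(
            n_patients=200_000, joint_enrichment={"target": 4.0}, seed=9
        )
        pop = generate_population(config)
        i = pop.index_membership
        c = pop.condition_membership[:, 0]
        a = np.sum(i & c)
        b = np.sum(i & ~c)
        cc = np.sum(~i & c)
        d = np.sum(~i & ~c)
        log_or = math.log(a * d / (b * cc))
        se = math.sqrt(1 / a + 1 / b + 1 / cc + 1 / d)
        assert abs(log_or - math.log(4.0)) <= 3 * se


class TestDeterminism:
    def test_same_seed_same_family(self):
        f1, t1 = simulate_family(quick_config())
        f2, t2 = simulate_family(quick_config())
        assert f1 == f2 and t1 == t2

    def test_same_seed_byte_identical_files(self, tmp_path):
        contents = []
        for run in range(2):
            family, _ = simulate_family(quick_config())
            path = tmp_path / f"run{run}.tsv"
            write_cohort_summary(family.index, path)
            contents.append(path.read_bytes())
        assert contents[0] == contents[1]

    def test_different_seed_differs(self):
        f1, _ = simulate_family(quick_config())
        f2, _ = simulate_family(quick_config(seed=6))
        assert f1.index.term_freqs != f2.index.term_freqs


class TestStatisticalFidelity:
    def test_null_model_index_prevalence_matches_background(self):
        config = quick_config(n_patients=200_000, n_terms=50, seed=1)
        family, _ = simulate_family(config)
        # aggregate over terms: index-cohort prevalence tracks background
        n_idx = family.index.size
        deviations = []
        for term, f_bg in family.background.term_freqs.items():
            p = f_bg / family.background.size
            f_idx = family.index.freq(term)
            se = math.sqrt(p * (1 - p) / n_idx)
            deviations.append((f_idx / n_idx - p) / se)
        z = np.mean(deviations) * math.sqrt(len(deviations))
        assert abs(z) < 3

    def test_planted_index_risk_multiplier_recovered(self):
        effects = EffectModel.null(50, ["target"])
        effects.rr_index[:10] = 10.0
        config = quick_config(
            n_patients=200_000,
            n_terms=50,
            baseline_prevalence_range=(0.001, 0.001),
            effects=effects,
            seed=2,
        )
        family, _ = simulate_family(config)
        n_idx = family.index.size
        ratios = [
            (family.index.freq(f"T{i:05d}") / n_idx)
            / (family.background.freq(f"T{i:05d}") / family.background.size)
            for i in range(10)
        ]
        # expected count per planted term in the index cohort ~ 40; 3 MC SEs
        # on the mean of 10 prevalence ratios
        tol = 3 * 10 / math.sqrt(10 * 200_000 * 0.02 * 0.001 * 10)
        assert np.mean(ratios) == pytest.approx(10.0, abs=tol)


class TestSummaries:
    def test_exact_counts_satisfy_all_nesting_invariants(self, small_sim):
        _, family, _ = small_sim
        assert validate_family(family).ok
        for cid in family.condition_ids:
            inter = family.intersection(cid)
            cond = family.condition(cid)
            for term, f_i in inter.term_freqs.items():
                assert f_i <= min(family.index.freq(term), cond.freq(term))

    def test_rounded_mode_emits_multiples_of_ten(self):
        family, _ = simulate_family(quick_config(counts_rounded_to=10))
        for cohort in (family.background, family.index, *family.conditions,
                       *family.intersections.values()):
            assert cohort.size % 10 == 0
            assert all(f % 10 == 0 for f in cohort.term_freqs.values())
        assert validate_family(family).ok

    def test_empty_intersection_when_no_joint_members(self):
        config = quick_config(
            n_patients=2000, index_prob=0.005, condition_probs={"target": 0.005}, seed=3
        )
        pop = generate_population(config)
        if not np.any(pop.index_membership & pop.condition_membership[:, 0]):
            family, _ = summarize_cohorts(pop)
            inter = family.intersection("target")
            assert inter.size == 0 and inter.n_terms == 0

    def test_truth_labels_cover_every_term(self, small_sim):
        config, _, truths = small_sim
        assert len(truths) == config.n_terms
        assert {t.term_id for t in truths} == {f"T{i:05d}" for i in range(config.n_terms)}


class TestTruthClassification:
    @pytest.mark.parametrize("rr_index,rr_cond,rr_syn,expected", [
        (1.0, 1.0, 1.0, "null"),
        (2.0, 1.0, 1.0, "index_only"),
        (1.0, 2.0, 1.0, "condition_only"),
        (2.0, 2.0, 1.0, "commonly_prevalent"),
        (1.0, 1.0, 2.0, "synergistic"),
        (2.0, 1.0, 2.0, "synergistic"),
        (2.0, 2.0, 2.0, "commonly_and_synergistic"),
    ])
    def test_label_rules(self, rr_index, rr_cond, rr_syn, expected):
        assert _classify(rr_index, rr_cond, rr_syn) == expected
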