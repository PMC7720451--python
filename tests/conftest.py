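import pytest

from cohortminer import CohortFamily, CohortSummary


@pytest.fixture
def headline_cohorts():
    """Background and a large condition cohort with one term, using the
    published cohort sizes of a real EHR extraction (12.68M background,
    116,660-record condition, term frequencies 8,140 / 610)."""
    background = CohortSummary(
        cohort_id="BG", size=12_684_250, term_freqs={"D": 8140}
    )
    condition = CohortSummary(cohort_id="TBI", size=116_660, term_freqs={"D": 610})
    return condition, background


@pytest.fixture
def tiny_family():
    """Hand-built consistent family with arithmetic chosen to be checkable
    by eye: the intersection carries term A at exactly the cohort-size ratio
    of cohort X (no conditional enrichment) and term B enriched 4-fold."""
    background = CohortSummary("BG", 100_000, {"A": 2000, "B": 400, "C": 3000})
    index = CohortSummary("IDX", 2000, {"A": 400, "B": 80, "C": 60})
    cond = CohortSummary("X", 1000, {"A": 100, "B": 20, "C": 30})
    inter = CohortSummary("IDX&X", 50, {"A": 5, "B": 4})
    return CohortFamily(
        background=background,
        index=index,
        conditions=(cond,),
        intersections={"X": inter},
    )


@pytest.fixture(scope="session")
def small_sim():
    """A quick simulated family + truth labels shared across tests."""
    from cohortminer.synthetic import SimulationConfig, simulate_family

    config = SimulationConfig(
        n_patients=50_000,
        index_prob=0.02,
        condition_probs={"target": 0.05, "control_a": 0.03, "control_b": 0.03},
        n_terms=300,
        baseline_prevalence_range=(0.02, 0.1),
        seed=11,
    )
    family, truths = simulate_family(config)
    return config, family, truths
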