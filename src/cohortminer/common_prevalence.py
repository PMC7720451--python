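"""Shared-term counting and common-prevalence scoring with empirical FDR cut-offs.

A term is *shared* between the index condition and a condition X when it has
non-zero frequency in the index∩X intersection cohort. A term's *common
prevalence* score with respect to the index and X is

    CP_X(d) = min{ LOR(d, X|BG), LOR(d, index|BG) },

high only when the term is enriched in *both* cohorts. Significance cut-offs
are calibrated empirically from control conditions believed unrelated to the
index condition: for each control, the cut-off at level α is the smallest
observed CP value such that the fraction of that control's CP scores strictly
above it is at most α (the empirical upper-α quantile), and the operative
threshold is the maximum of the per-control cut-offs — a deliberately
conservative rule that mirrors using the most permissive control as the
yardstick. Selection is strict: a term passes at level α iff its CP exceeds
the operative threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .cohort_io import CohortSummary
from .errors import ConfigurationError
from .prevalence import build_prevalence_table, chi_square_p, log_odds_ratio

__all__ = [
    "CPRecord",
    "FdrThresholds",
    "shared_terms",
    "cp_scores",
    "fdr_thresholds",
    "select_commonly_prevalent",
]

DEFAULT_ALPHAS = (0.05, 0.01)


@dataclass(frozen=True)
class CPRecord:
    """Common-prevalence score of one term for an (index, other-cohort) pair."""

    term_id: str
    lor_index: float
    lor_other: float
    cp: float
    p_index: float
    p_other: float
    corrected: bool  # continuity correction used in either LOR
    passes_fdr_5: bool = False
    passes_fdr_1: bool = False


@dataclass(frozen=True)
class FdrThresholds:
    """Per-control empirical cut-offs and the operative (max) threshold per level."""

    per_control: Mapping[str, Mapping[float, float]]
    operative: Mapping[float, float]

    def threshold(self, alpha: float) -> float:
        return self.operative[alpha]


def shared_terms(
    cohort_a: CohortSummary, cohort_b: CohortSummary | None = None
) -> set[str]:
    """Terms shared between two cohorts.

    With a single argument the cohort is interpreted as an intersection
    cohort and its non-zero-frequency terms are returned; with two arguments
    the terms with non-zero frequency in both are returned.
    """
    if cohort_b is None:
        return cohort_a.terms()
    return cohort_a.terms() & cohort_b.terms()


def cp_scores(
    index: CohortSummary,
    other: CohortSummary,
    background: CohortSummary,
    term_universe: set[str] | None = None,
    counts_rounded_to: int = 1,
    yates: bool = False,
) -> list[CPRecord]:
    """Common-prevalence scores for every term present in both cohorts.

    ``term_universe`` defaults to the terms with non-zero frequency in both
    ``index`` and ``other``; supplying a universe restricts scoring to a
    subset of it. Records are sorted by term_id. Raw χ² p-values for the two
    constituent prevalence tests are carried along unadjusted; the caller
    owns the Bonferroni family.
    """
    universe = shared_terms(index, other) if term_universe is None else term_universe
    records: list[CPRecord] = []
    for term in sorted(universe):
        t_index = build_prevalence_table(term, index, background, counts_rounded_to)
        t_other = build_prevalence_table(term, other, background, counts_rounded_to)
        lor_i, corr_i = log_odds_ratio(t_index)
        lor_o, corr_o = log_odds_ratio(t_other)
        p_i, _ = chi_square_p(t_index, yates)
        p_o, _ = chi_square_p(t_other, yates)
        records.append(
            CPRecord(
                term_id=term,
                lor_index=lor_i,
                lor_other=lor_o,
                cp=min(lor_i, lor_o),
                p_index=p_i,
                p_other=p_o,
                corrected=corr_i or corr_o,
            )
        )
    return records


def empirical_upper_cutoff(scores: Sequence[float], alpha: float) -> float:
    """Smallest observed score with at most a fraction ``alpha`` strictly above it."""
    s = np.sort(np.asarray(scores, dtype=float))
    if s.size == 0:
        raise ConfigurationError("cannot compute a cut-off from an empty distribution")
    uniq = np.unique(s)
    n_above = s.size - np.searchsorted(s, uniq, side="right")
    ok = n_above / s.size <= alpha
    # ok is monotone non-decreasing in the value; the largest values always qualify
    return float(uniq[int(np.argmax(ok))])


def fdr_thresholds(
    control_cp_distributions: Mapping[str, Sequence[float]],
    alphas: Sequence[float] = DEFAULT_ALPHAS,
) -> FdrThresholds:
    """Empirical FDR cut-offs from control-cohort CP distributions.

    For each control and level α the cut-off is the empirical upper-α
    quantile of that control's CP scores; the operative threshold at each
    level is the maximum across controls.
    """
    if not control_cp_distributions:
        raise ConfigurationError("at least one control CP distribution is required")
    per_control: dict[str, dict[float, float]] = {}
    for control_id, scores in sorted(control_cp_distributions.items()):
        per_control[control_id] = {
            alpha: empirical_upper_cutoff(scores, alpha) for alpha in alphas
        }
    operative = {
        alpha: max(cuts[alpha] for cuts in per_control.values()) for alpha in alphas
    }
    return FdrThresholds(per_control=per_control, operative=operative)


def select_commonly_prevalent(
    records: Sequence[CPRecord], thresholds: FdrThresholds
) -> tuple[list[CPRecord], dict[float, set[str]]]:
    """Flag records whose CP strictly exceeds the operative threshold per level.

    Returns the records with their ``passes_fdr_*`` flags set (when the 0.05
    and 0.01 levels are present) and a mapping level → selected term set.
    The smaller-α selection is nested in the larger-α selection because its
    threshold is at least as large.
    """
    selected: dict[float, set[str]] = {
        alpha: {r.term_id for r in records if r.cp > cut}
        for alpha, cut in thresholds.operative.items()
    }
    flagged = [
        replace(
            r,
            passes_fdr_5=r.term_id in selected.get(0.05, set()),
            passes_fdr_1=r.term_id in selected.get(0.01, set()),
        )
        for r in records
    ]
    return flagged, selected
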