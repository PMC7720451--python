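"""2×2 contingency tables, log-odds ratios and χ² significance.

Two table constructions are used throughout the pipeline. The *prevalence*
table compares a term's frequency in a cohort X against the background
population BG:

    a = f_X(d)                          (in cohort, has term)
    b = f_BG(d) − f_X(d)                (outside cohort, has term)
    c = N_X − f_X(d)                    (in cohort, no term)
    d = N_BG − N_X − f_BG(d) + f_X(d)   (outside cohort, no term)

The *conditional prevalence* table restricts the reference population to a
parent cohort Y and compares the intersection cohort X∩Y against Y, with the
same cell algebra (the intersection plays the role of X, the parent the role
of BG).

The association measure is the natural-log odds ratio LOR = ln(ad/bc), with a
Haldane–Anscombe +0.5 continuity correction applied to all four cells when
any cell is zero (flagged in the output). Significance is the 1-df Pearson χ²
independence test; p-values are Bonferroni-adjusted across the hypothesis
family of all (term, cohort) pairs scored in a run. χ² p-values are reported
for completeness, but with cohort sizes in the millions they saturate and are
unsuitable for ranking — the LOR is the ranking statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Sequence

import numpy as np
from scipy.stats import chi2_contingency

from .cohort_io import CohortSummary
from .errors import ConsistencyError

__all__ = [
    "TwoByTwoTable",
    "PrevalenceRecord",
    "build_prevalence_table",
    "build_conditional_table",
    "log_odds_ratio",
    "chi_square_p",
    "bonferroni",
]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Contingency table with rows = term present/absent, cols = in/out of cohort."""

    a: int
    b: int
    c: int
    d: int
    clamped: bool = False  # a negative cell within rounding slack was clamped to 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ConsistencyError(f"negative cell in table {self.cells()}")
        if self.total == 0:
            raise ConsistencyError("empty 2x2 table")

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class PrevalenceRecord:
    """Scored association of one term with one cohort."""

    term_id: str
    lor: float
    p_raw: float
    p_adj: float = float("nan")
    corrected: bool = False  # +0.5 continuity correction was applied
    degenerate: bool = False  # a zero margin made the chi-square test vacuous

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.lor))


def _make_table(
    cells: dict[str, int], counts_rounded_to: int = 1
) -> TwoByTwoTable:
    """Build a table, clamping small negative cells in rounded-count mode.

    Each computed cell combines up to two independently rounded counts, so in
    rounded mode a deficit of at most twice the granularity is attributable to
    rounding and is clamped to zero (flagged); larger deficits are genuine
    inconsistencies.
    """
    slack = 2 * counts_rounded_to if counts_rounded_to > 1 else 0
    clamped = False
    fixed: dict[str, int] = {}
    for name, value in cells.items():
        if value < 0:
            if -value <= slack:
                fixed[name] = 0
                clamped = True
            else:
                raise ConsistencyError(
                    f"cell {name!r} is negative ({value}); inconsistent input counts"
                )
        else:
            fixed[name] = value
    return TwoByTwoTable(fixed["a"], fixed["b"], fixed["c"], fixed["d"], clamped=clamped)


def build_prevalence_table(
    term: str,
    cohort: CohortSummary,
    background: CohortSummary,
    counts_rounded_to: int = 1,
) -> TwoByTwoTable:
    """Prevalence of ``term`` in ``cohort`` relative to the background population."""
    f_x = cohort.freq(term)
    f_bg = background.freq(term)
    return _make_table(
        {
            "a": f_x,
            "b": f_bg - f_x,
            "c": cohort.size - f_x,
            "d": background.size - cohort.size - f_bg + f_x,
        },
        counts_rounded_to,
    )


def build_conditional_table(
    term: str,
    cohort_x: CohortSummary,
    intersection: CohortSummary,
    counts_rounded_to: int = 1,
) -> TwoByTwoTable:
    """Conditional prevalence of ``term`` in the intersection relative to its parent.

    ``cohort_x`` is the parent cohort to which the reference population is
    restricted; ``intersection`` is the index∩parent cohort.
    """
    f_i = intersection.freq(term)
    f_x = cohort_x.freq(term)
    return _make_table(
        {
            "a": f_i,
            "b": f_x - f_i,
            "c": intersection.size - f_i,
            "d": cohort_x.size - intersection.size - f_x + f_i,
        },
        counts_rounded_to,
    )


def log_odds_ratio(table: TwoByTwoTable) -> tuple[float, bool]:
    """Natural-log odds ratio of a 2×2 table.

    Returns ``(lor, corrected)`` where ``corrected`` indicates the
    Haldane–Anscombe +0.5 correction was applied (any zero cell).
    """
    a, b, c, d = table.cells()
    corrected = 0 in (a, b, c, d)
    if corrected:
        af, bf, cf, df = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        af, bf, cf, df = float(a), float(b), float(c), float(d)
    return log(af) + log(df) - log(bf) - log(cf), corrected


def chi_square_p(table: TwoByTwoTable, yates: bool = False) -> tuple[float, bool]:
    """Pearson χ² independence p-value (1 df).

    Returns ``(p, degenerate)``; a zero row or column margin makes the test
    vacuous and yields ``(1.0, True)``.
    """
    a, b, c, d = table.cells()
    if min(a + b, c + d, a + c, b + d) == 0:
        return 1.0, True
    _, p, _, _ = chi2_contingency(table.as_array(), correction=yates)
    return float(p), False


def bonferroni(p_values: Sequence[float], family_size: int) -> list[float]:
    """Bonferroni adjustment ``min(1, m·p)`` with an explicit family size.

    ``family_size`` may exceed ``len(p_values)``: the family is every
    (term, cohort) hypothesis tested in the run, not just the ones in this
    batch.
    """
    if family_size < len(p_values):
        raise ValueError(
            f"family_size {family_size} smaller than number of p-values {len(p_values)}"
        )
    return [min(1.0, family_size * p) for p in p_values]
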