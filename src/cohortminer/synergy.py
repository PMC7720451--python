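"""Synergistic-prevalence detection via binned one-sided Gaussian outliers.

A term is *synergistically* prevalent with respect to the index condition and
a condition X when its frequency among records carrying both conditions is
unusually high in *both* conditional directions:

* direction index|X — enrichment of the term in the index cohort among
  records already in X, i.e. LOR computed from the intersection vs. X table;
* direction X|index — enrichment in X among records already in the index
  cohort.

Because conditional prevalence scales with a term's marginal prevalence (the
parent cohort is a subsample of the background), raw conditional LORs are not
comparable across terms. Each direction therefore plots, per term,

    x = LOR(d, A|BG)        (marginal prevalence of the enriched cohort A)
    y = LOR(d, A|parent)    (conditional prevalence)
    y_norm = y / x          (conditional prevalence normalised by marginal)

and asks whether y_norm is an outlier *given* x: terms are split into
equal-width bins on x, each bin's mean and sample standard deviation of
y_norm define a one-sided 95% Gaussian bound mean + 1.645·sd, and terms
strictly above their bin's bound are flagged. Terms flagged in both
directions form the synergistic set. Overlap between two synergistic sets is
assessed with a one-sided Fisher's exact (hypergeometric upper-tail) test.

Terms with near-zero marginal LOR (x ≤ ε, default 0.1) are excluded before
normalisation: the ratio y/x is numerically meaningless there, and the
procedure targets terms with clearly positive marginal enrichment. Division
(`ratio`) is the default reading of "normalised by"; subtraction is available
as ``normalization="difference"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.stats import hypergeom

from .cohort_io import CohortFamily
from .errors import ConfigurationError
from .prevalence import build_conditional_table, build_prevalence_table, log_odds_ratio

__all__ = [
    "ConditionalRecord",
    "BinSummary",
    "SynergyReport",
    "conditional_profile",
    "bin_and_flag",
    "synergistic_terms",
    "overlap_significance",
    "hypergeom_overlap_p",
]

Direction = Literal["index_given_condition", "condition_given_index"]
DIRECTIONS: tuple[Direction, Direction] = (
    "index_given_condition",
    "condition_given_index",
)

ONE_SIDED_95_Z = 1.6448536269514722  # standard normal 95th percentile


@dataclass
class ConditionalRecord:
    """One term's point in the conditional-prevalence scatter of a direction."""

    term_id: str
    x: float  # LOR(d, A|BG)
    y: float  # LOR(d, A|parent)
    y_norm: float
    bin_index: int = -1
    bin_mean: float = float("nan")
    bin_sd: float = float("nan")
    bin_upper: float = float("nan")
    flagged: bool = False


@dataclass(frozen=True)
class BinSummary:
    """Per-bin summary backing the mean and upper-CI curves of the scatter."""

    bin_index: int
    x_low: float
    x_high: float
    count: int
    mean: float
    sd: float
    upper: float


@dataclass(frozen=True)
class SynergyReport:
    """Flagged sets per direction and their intersection for one condition."""

    condition_id: str
    flagged_index_given_condition: frozenset[str]
    flagged_condition_given_index: frozenset[str]
    synergistic: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "synergistic",
            frozenset(
                self.flagged_index_given_condition & self.flagged_condition_given_index
            ),
        )

    def counts(self) -> dict[str, int]:
        return {
            "index_given_condition": len(self.flagged_index_given_condition),
            "condition_given_index": len(self.flagged_condition_given_index),
            "synergistic": len(self.synergistic),
        }


def conditional_profile(
    family: CohortFamily,
    condition_id: str,
    direction: Direction,
    epsilon: float = 0.1,
    normalization: Literal["ratio", "difference"] = "ratio",
) -> tuple[list[ConditionalRecord], list[tuple[str, str]]]:
    """Compute (x, y, y_norm) for every eligible term of one direction.

    Eligible terms have non-zero frequency in the index∩condition
    intersection cohort; terms absent from the enriched cohort or the
    background (possible only with rounded counts) or with marginal LOR
    x ≤ ``epsilon`` are excluded, each with a logged reason. Returns
    ``(records, exclusions)`` with records sorted by term_id.
    """
    if condition_id not in family.intersections:
        raise ConfigurationError(
            f"no intersection cohort for condition {condition_id!r}"
        )
    if direction not in DIRECTIONS:
        raise ConfigurationError(f"unknown direction {direction!r}")
    inter = family.intersection(condition_id)
    cond = family.condition(condition_id)
    if direction == "index_given_condition":
        enriched, parent = family.index, cond
    else:
        enriched, parent = cond, family.index

    rt = family.counts_rounded_to
    records: list[ConditionalRecord] = []
    exclusions: list[tuple[str, str]] = []
    for term in sorted(inter.term_freqs):
        if enriched.freq(term) == 0:
            exclusions.append((term, "absent_from_enriched_cohort"))
            continue
        if family.background.freq(term) == 0:
            exclusions.append((term, "absent_from_background"))
            continue
        x, _ = log_odds_ratio(build_prevalence_table(term, enriched, family.background, rt))
        if x <= epsilon:
            exclusions.append((term, "low_marginal_lor"))
            continue
        y, _ = log_odds_ratio(build_conditional_table(term, parent, inter, rt))
        y_norm = y / x if normalization == "ratio" else y - x
        records.append(ConditionalRecord(term_id=term, x=x, y=y, y_norm=y_norm))
    return records, exclusions


def _merge_small_bins(counts: list[int], min_count: int) -> list[int]:
    """Map raw bin indices to merged group ids so every group has ≥ min_count.

    Under-populated bins merge into their left neighbour; a leading
    under-populated run merges rightward. Returns a group id per raw bin.
    """
    n = len(counts)
    group = list(range(n))
    changed = True
    while changed and len(set(group)) > 1:
        changed = False
        group_counts: dict[int, int] = {}
        for g, c in zip(group, counts):
            group_counts[g] = group_counts.get(g, 0) + c
        ordered = sorted(group_counts)
        for pos, g in enumerate(ordered):
            if group_counts[g] < min_count:
                target = ordered[pos - 1] if pos > 0 else ordered[pos + 1]
                group = [target if x == g else x for x in group]
                changed = True
                break
    # renumber groups consecutively from 0, preserving order
    remap = {g: i for i, g in enumerate(sorted(set(group)))}
    return [remap[g] for g in group]


def bin_and_flag(
    records: Sequence[ConditionalRecord],
    n_bins: int = 10,
    z: float = ONE_SIDED_95_Z,
    min_bin_count: int = 3,
) -> list[BinSummary]:
    """Assign equal-width x bins, compute per-bin Gaussian bounds, flag outliers.

    Bins are equal-width over the observed x range; bins with fewer than
    ``min_bin_count`` terms are merged with their left neighbour so the
    sample standard deviation is defined. Each record is annotated in place
    with its (merged) bin index, the bin's mean/sd/upper bound, and the flag
    ``y_norm > mean + z·sd`` (strict inequality: a degenerate bin with zero
    spread flags nothing). Returns the per-bin summaries.
    """
    if len(records) < 2:
        raise ConfigurationError("binning requires at least 2 records")
    xs = np.array([r.x for r in records])
    ys = np.array([r.y_norm for r in records])
    x_min, x_max = float(xs.min()), float(xs.max())
    if x_max == x_min:
        raw = np.zeros(len(records), dtype=int)
        n_bins = 1
        edges = np.array([x_min, x_max])
    else:
        edges = np.linspace(x_min, x_max, n_bins + 1)
        raw = np.clip(
            ((xs - x_min) / (x_max - x_min) * n_bins).astype(int), 0, n_bins - 1
        )

    counts = [int((raw == b).sum()) for b in range(n_bins)]
    group_of_raw = _merge_small_bins(counts, min_bin_count)
    groups = np.array([group_of_raw[b] for b in raw])

    summaries: list[BinSummary] = []
    for g in sorted(set(group_of_raw)):
        members = groups == g
        vals = ys[members]
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        upper = mean + z * sd
        raw_bins = [b for b in range(n_bins) if group_of_raw[b] == g]
        summaries.append(
            BinSummary(
                bin_index=g,
                x_low=float(edges[raw_bins[0]]),
                x_high=float(edges[raw_bins[-1] + 1]),
                count=int(members.sum()),
                mean=mean,
                sd=sd,
                upper=upper,
            )
        )
        for i in np.nonzero(members)[0]:
            rec = records[i]
            rec.bin_index = g
            rec.bin_mean = mean
            rec.bin_sd = sd
            rec.bin_upper = upper
            rec.flagged = rec.y_norm > upper
    return summaries


def synergistic_terms(
    flags_dir1: Iterable[str], flags_dir2: Iterable[str], condition_id: str = ""
) -> SynergyReport:
    """Intersect the two directions' flagged sets into the synergistic set."""
    return SynergyReport(
        condition_id=condition_id,
        flagged_index_given_condition=frozenset(flags_dir1),
        flagged_condition_given_index=frozenset(flags_dir2),
    )


def hypergeom_overlap_p(n_a: int, n_b: int, overlap: int, universe_size: int) -> float:
    """One-sided Fisher's exact p-value for observing at least ``overlap``."""
    if not (0 <= n_a <= universe_size and 0 <= n_b <= universe_size):
        raise ConfigurationError("set sizes must lie within the universe")
    if overlap > min(n_a, n_b):
        raise ConfigurationError("overlap exceeds the smaller set")
    return float(hypergeom.sf(overlap - 1, universe_size, n_a, n_b))


def overlap_significance(
    set_a: Iterable[str], set_b: Iterable[str], universe_size: int
) -> float:
    """One-sided Fisher's exact test of the overlap between two term sets."""
    a, b = set(set_a), set(set_b)
    return hypergeom_overlap_p(len(a), len(b), len(a & b), universe_size)
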