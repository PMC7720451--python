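"""Cohort summary data model, TSV serialisation and cross-cohort validation.

A *cohort summary* is the de-identified export this pipeline works from: a
cohort identifier, the number of records in the cohort, and the frequency of
every clinical term that appears in at least one record. Term identifiers are
opaque strings; an optional human-readable label is carried along but never
interpreted. Zero-frequency terms are never stored — "present in the cohort"
is synonymous with "present in the term map".

The on-disk format is a tab-separated table with a commented key=value header:

    # cohort_id=IPV
    # size=8140
    term_id<TAB>term_label<TAB>frequency
    T0001<TAB>domestic abuse<TAB>8140

A :class:`CohortFamily` bundles the background population, the index-condition
cohort, the comparison-condition cohorts and the index∩condition intersection
cohorts, together with the de-identification rounding granularity (EHR exports
commonly round all counts to multiples of 10). :func:`validate_family` checks
the nesting arithmetic that must hold between these cohorts; with rounding
declared, the checks are relaxed by the rounding granularity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ConsistencyError, ParseError

__all__ = [
    "CohortSummary",
    "CohortFamily",
    "Violation",
    "ValidationReport",
    "read_cohort_summary",
    "write_cohort_summary",
    "validate_family",
]

_HEADER_KEYS = ("cohort_id", "size")
_COLUMNS = ("term_id", "term_label", "frequency")


@dataclass(frozen=True)
class CohortSummary:
    """One cohort's de-identified export: size plus term → frequency map."""

    cohort_id: str
    size: int
    term_freqs: Mapping[str, int] = field(default_factory=dict)
    term_labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ConsistencyError(
                f"cohort {self.cohort_id!r}: size must be non-negative, got {self.size}"
            )
        for term, freq in self.term_freqs.items():
            if freq <= 0:
                raise ConsistencyError(
                    f"cohort {self.cohort_id!r}, term {term!r}: "
                    f"frequency must be positive, got {freq}"
                )
            if freq > self.size:
                raise ConsistencyError(
                    f"cohort {self.cohort_id!r}, term {term!r}: "
                    f"frequency {freq} exceeds cohort size {self.size}"
                )

    @property
    def n_terms(self) -> int:
        """Number of terms with non-zero frequency."""
        return len(self.term_freqs)

    def freq(self, term: str) -> int:
        """Frequency of ``term`` in this cohort (0 if absent)."""
        return self.term_freqs.get(term, 0)

    def terms(self) -> set[str]:
        return set(self.term_freqs)


@dataclass(frozen=True)
class CohortFamily:
    """Background + index + condition cohorts with their intersections.

    ``intersections`` maps a condition's cohort_id to the summary of the
    index∩condition cohort. ``counts_rounded_to`` declares the
    de-identification rounding granularity (1 = exact counts); nesting
    invariants are relaxed by this amount when > 1.
    """

    background: CohortSummary
    index: CohortSummary
    conditions: tuple[CohortSummary, ...]
    intersections: Mapping[str, CohortSummary] = field(default_factory=dict)
    counts_rounded_to: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if self.counts_rounded_to < 1:
            raise ConsistencyError("counts_rounded_to must be >= 1")

    @property
    def condition_ids(self) -> list[str]:
        return [c.cohort_id for c in self.conditions]

    def condition(self, cohort_id: str) -> CohortSummary:
        for c in self.conditions:
            if c.cohort_id == cohort_id:
                return c
        raise KeyError(f"no condition cohort {cohort_id!r} in family")

    def intersection(self, cohort_id: str) -> CohortSummary:
        try:
            return self.intersections[cohort_id]
        except KeyError:
            raise KeyError(f"no intersection cohort for condition {cohort_id!r}")


@dataclass(frozen=True, order=True)
class Violation:
    """One breached validation rule, identified by cohort, term and rule name."""

    cohort_id: str
    term_id: str
    rule: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation]

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "cohort_id": v.cohort_id,
                    "term_id": v.term_id,
                    "rule": v.rule,
                    "message": v.message,
                }
                for v in self.violations
            ],
            indent=2,
        )


def read_cohort_summary(path: str | Path, format: str = "tsv") -> CohortSummary:
    """Read a cohort summary table.

    The only supported dialect is ``"tsv"`` (the format documented in the
    module docstring). Raises :class:`ParseError` with a line number for
    malformed content and :class:`ConsistencyError` for count violations.
    """
    if format != "tsv":
        raise ParseError(f"unknown cohort summary format {format!r}")
    path = Path(path)
    meta: dict[str, str] = {}
    freqs: dict[str, int] = {}
    labels: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body_start = i + 1
            entry = line.lstrip("#").strip()
            if "=" not in entry:
                raise ParseError(f"{path}:{i + 1}: malformed header line {line!r}")
            key, _, value = entry.partition("=")
            meta[key.strip()] = value.strip()
        else:
            break

    for key in _HEADER_KEYS:
        if key not in meta:
            raise ParseError(f"{path}: header is missing '# {key}=...'")
    try:
        size = int(meta["size"])
    except ValueError:
        raise ParseError(f"{path}: size {meta['size']!r} is not an integer")
    cohort_id = meta["cohort_id"]

    rows = lines[body_start:]
    if rows and tuple(rows[0].split("\t")) == _COLUMNS:
        rows = rows[1:]
        body_start += 1
    for offset, line in enumerate(rows):
        lineno = body_start + offset + 1
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(
                f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
            )
        term_id, label, freq_text = parts
        try:
            freq = int(freq_text)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: frequency {freq_text!r} is not an integer")
        if term_id in freqs:
            raise ParseError(f"{path}:{lineno}: duplicate term_id {term_id!r}")
        if freq <= 0:
            raise ConsistencyError(
                f"{path}:{lineno}: term {term_id!r} has non-positive frequency {freq}"
            )
        if freq > size:
            raise ConsistencyError(
                f"{path}:{lineno}: term {term_id!r} frequency {freq} "
                f"exceeds cohort size {size}"
            )
        freqs[term_id] = freq
        if label:
            labels[term_id] = label

    return CohortSummary(cohort_id=cohort_id, size=size, term_freqs=freqs, term_labels=labels)


def write_cohort_summary(summary: CohortSummary, path: str | Path) -> None:
    """Write ``summary`` in the TSV dialect; rows sorted by term_id."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# cohort_id={summary.cohort_id}\n")
        fh.write(f"# size={summary.size}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for term in sorted(summary.term_freqs):
            label = summary.term_labels.get(term, "")
            fh.write(f"{term}\t{label}\t{summary.term_freqs[term]}\n")


def _check_size(
    child: CohortSummary, bound: int, rule: str, message: str, out: list[Violation]
) -> None:
    if child.size > bound:
        out.append(Violation(child.cohort_id, "", rule, message))


def validate_family(family: CohortFamily) -> ValidationReport:
    """Check the nesting invariants of a cohort family.

    Violations are data, not exceptions: the report lists every breached rule,
    deterministically sorted by (cohort_id, term_id, rule). With
    ``counts_rounded_to > 1`` every count comparison is relaxed by the
    rounding granularity, since independently rounded counts can disagree by
    up to one granule in each operand.
    """
    tol = family.counts_rounded_to if family.counts_rounded_to > 1 else 0
    out: list[Violation] = []
    bg = family.background

    for cohort in (family.index, *family.conditions, *family.intersections.values()):
        _check_size(
            cohort,
            bg.size + tol,
            "size_vs_background",
            f"cohort size {cohort.size} exceeds background size {bg.size}",
            out,
        )

    for cond_id, inter in sorted(family.intersections.items()):
        try:
            cond = family.condition(cond_id)
        except KeyError:
            out.append(
                Violation(
                    inter.cohort_id,
                    "",
                    "orphan_intersection",
                    f"intersection declared for unknown condition {cond_id!r}",
                )
            )
            continue
        bound = min(family.index.size, cond.size)
        if inter.size > bound + tol:
            out.append(
                Violation(
                    inter.cohort_id,
                    "",
                    "intersection_size",
                    f"intersection size {inter.size} exceeds "
                    f"min(index={family.index.size}, {cond_id}={cond.size})",
                )
            )
        for term in sorted(inter.term_freqs):
            f_i = inter.term_freqs[term]
            cap = min(family.index.freq(term), cond.freq(term))
            if f_i > cap + tol:
                out.append(
                    Violation(
                        inter.cohort_id,
                        term,
                        "nesting_frequency",
                        f"intersection frequency {f_i} exceeds "
                        f"min(f_index={family.index.freq(term)}, "
                        f"f_{cond_id}={cond.freq(term)})",
                    )
                )

    for cohort in (family.index, *family.conditions):
        for term in sorted(cohort.term_freqs):
            if cohort.term_freqs[term] > bg.freq(term) + tol:
                out.append(
                    Violation(
                        cohort.cohort_id,
                        term,
                        "background_frequency",
                        f"frequency {cohort.term_freqs[term]} exceeds background "
                        f"frequency {bg.freq(term)}",
                    )
                )

    return ValidationReport(sorted(out))


def family_term_universe(cohorts: Iterable[CohortSummary]) -> set[str]:
    """Terms with non-zero frequency in *every* supplied cohort."""
    result: set[str] | None = None
    for cohort in cohorts:
        terms = cohort.terms()
        result = terms if result is None else result & terms
    return result or set()
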