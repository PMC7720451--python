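"""Pipeline orchestration, term classification and report serialisation.

:func:`run_all` executes the three analyses — shared-term counting,
common-prevalence scoring with control-calibrated FDR thresholds, and
bidirectional conditional-prevalence (synergy) detection — for the index
condition against a target condition and a set of controls, then classifies
the target's terms by the three resulting flags:

===========================  ======  ==========  ==========
category                     CP(5%)  index|X     X|index
===========================  ======  ==========  ==========
strongly_associated_with_
both_and_co_occurrence        yes     yes         yes
screen_in_co_occurrence       no      yes         yes
indicator_of_index_in_X       yes     yes         no
indicator_of_X_in_index       yes     no          yes
none                          anything else
===========================  ======  ==========  ==========

Terms in no intersection category are still reported with their raw flags.
All outputs are plain TSV/JSON with sorted rows and keys, so re-running the
same manifest reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import common_prevalence as cp_mod
from . import synergy as syn_mod
from .cohort_io import CohortFamily, read_cohort_summary, validate_family
from .errors import ConfigurationError, ConsistencyError
from .prevalence import bonferroni

__all__ = [
    "TermClassification",
    "RunManifest",
    "classify_terms",
    "run_all",
    "write_family_bundle",
    "CATEGORIES",
]

CATEGORIES = (
    "indicator_of_index_in_X",
    "indicator_of_X_in_index",
    "screen_in_co_occurrence",
    "strongly_associated_with_both_and_co_occurrence",
    "none",
)


@dataclass(frozen=True)
class TermClassification:
    term_id: str
    in_cp_set: bool
    in_dir_index_given_X: bool
    in_dir_X_given_index: bool
    category: str


def classify_terms(
    cp_set: set[str],
    flags_index_given_x: set[str],
    flags_x_given_index: set[str],
    universe: set[str] | None = None,
) -> list[TermClassification]:
    """Deterministic category per term from the three membership flags."""
    terms = (
        universe
        if universe is not None
        else cp_set | flags_index_given_x | flags_x_given_index
    )
    out: list[TermClassification] = []
    for term in sorted(terms):
        cp = term in cp_set
        d1 = term in flags_index_given_x
        d2 = term in flags_x_given_index
        if cp and d1 and d2:
            category = "strongly_associated_with_both_and_co_occurrence"
        elif d1 and d2:
            category = "screen_in_co_occurrence"
        elif cp and d1:
            category = "indicator_of_index_in_X"
        elif cp and d2:
            category = "indicator_of_X_in_index"
        else:
            category = "none"
        out.append(TermClassification(term, cp, d1, d2, category))
    return out


@dataclass(frozen=True)
class RunManifest:
    """Everything a reproducible run needs: input paths plus parameters."""

    background: str
    index: str
    conditions: Mapping[str, str]  # condition id -> cohort TSV path
    intersections: Mapping[str, str]  # condition id -> intersection TSV path
    target_condition: str
    controls: tuple[str, ...]
    alphas: tuple[float, ...] = (0.05, 0.01)
    n_bins: int = 10
    z: float = syn_mod.ONE_SIDED_95_Z
    epsilon_x: float = 0.1
    min_bin_count: int = 3
    normalization: str = "ratio"
    counts_rounded_to: int = 1
    yates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "controls", tuple(self.controls))
        object.__setattr__(self, "alphas", tuple(self.alphas))
        if self.target_condition not in self.conditions:
            raise ConfigurationError(
                f"target_condition {self.target_condition!r} has no cohort path"
            )
        for ctrl in self.controls:
            if ctrl not in self.conditions:
                raise ConfigurationError(f"control {ctrl!r} has no cohort path")
        missing = set(self.conditions) - set(self.intersections)
        if missing:
            raise ConfigurationError(f"conditions without intersection paths: {missing}")
        if self.normalization not in ("ratio", "difference"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunManifest":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        raw["conditions"] = dict(raw["conditions"])
        raw["intersections"] = dict(raw["intersections"])
        raw["controls"] = tuple(raw["controls"])
        if "alphas" in raw:
            raw["alphas"] = tuple(raw["alphas"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["conditions"] = dict(data["conditions"])
        data["intersections"] = dict(data["intersections"])
        data["controls"] = list(data["controls"])
        data["alphas"] = list(data["alphas"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def load_family(self) -> CohortFamily:
        background = read_cohort_summary(self.background)
        index = read_cohort_summary(self.index)
        conditions = tuple(
            read_cohort_summary(self.conditions[cid]) for cid in sorted(self.conditions)
        )
        intersections = {
            cid: read_cohort_summary(self.intersections[cid])
            for cid in sorted(self.intersections)
        }
        return CohortFamily(
            background=background,
            index=index,
            conditions=conditions,
            intersections=intersections,
            counts_rounded_to=self.counts_rounded_to,
        )


def write_family_bundle(
    family: CohortFamily,
    outdir: str | Path,
    target_condition: str,
    controls: Sequence[str],
    seed: int = 0,
    **manifest_overrides,
) -> RunManifest:
    """Write every cohort of a family as TSV and return a ready manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .cohort_io import write_cohort_summary

    write_cohort_summary(family.background, outdir / "background.tsv")
    write_cohort_summary(family.index, outdir / "index.tsv")
    conditions: dict[str, str] = {}
    intersections: dict[str, str] = {}
    for cond in family.conditions:
        path = outdir / f"condition_{cond.cohort_id}.tsv"
        write_cohort_summary(cond, path)
        conditions[cond.cohort_id] = str(path)
        ipath = outdir / f"intersection_{cond.cohort_id}.tsv"
        write_cohort_summary(family.intersection(cond.cohort_id), ipath)
        intersections[cond.cohort_id] = str(ipath)
    return RunManifest(
        background=str(outdir / "background.tsv"),
        index=str(outdir / "index.tsv"),
        conditions=conditions,
        intersections=intersections,
        target_condition=target_condition,
        controls=tuple(controls),
        counts_rounded_to=family.counts_rounded_to,
        seed=seed,
        **manifest_overrides,
    )


def _fmt(x: float) -> str:
    return format(x, ".10g")


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write(
                "\t".join(_fmt(v) if isinstance(v, float) else str(v) for v in row)
                + "\n"
            )


def _write_json(path: Path, payload) -> None:
    with path.open("w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _cp_stage(
    family: CohortFamily, manifest: RunManifest
) -> tuple[dict[str, list[cp_mod.CPRecord]], cp_mod.FdrThresholds, dict[float, set[str]], int]:
    """CP records per condition, thresholds from controls, target selection."""
    records: dict[str, list[cp_mod.CPRecord]] = {}
    for cid in sorted(family.condition_ids):
        records[cid] = cp_mod.cp_scores(
            family.index,
            family.condition(cid),
            family.background,
            counts_rounded_to=family.counts_rounded_to,
            yates=manifest.yates,
        )

    # Bonferroni family: every distinct (term, cohort) prevalence hypothesis.
    index_terms: set[str] = set()
    family_size = 0
    for cid, recs in records.items():
        family_size += len(recs)
        index_terms.update(r.term_id for r in recs)
    family_size += len(index_terms)

    thresholds = cp_mod.fdr_thresholds(
        {cid: [r.cp for r in records[cid]] for cid in manifest.controls},
        alphas=manifest.alphas,
    )
    flagged, selected = cp_mod.select_commonly_prevalent(
        records[manifest.target_condition], thresholds
    )
    records[manifest.target_condition] = flagged
    return records, thresholds, selected, family_size


def run_all(manifest: RunManifest, outdir: str | Path) -> dict:
    """Run the full pipeline and write the report bundle into ``outdir``.

    Returns the JSON summary (also written to ``summary.json``). Raises with
    the offending stage on any input inconsistency.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    family = manifest.load_family()
    report = validate_family(family)
    if not report.ok:
        (outdir / "validation.json").write_text(report.to_json() + "\n", encoding="utf-8")
        raise ConsistencyError(
            f"stage validate: cohort family has {len(report.violations)} violations "
            f"(first: {report.violations[0]})"
        )

    # stage 1: shared terms
    shared_counts = {
        cid: len(cp_mod.shared_terms(family.intersection(cid)))
        for cid in sorted(family.condition_ids)
    }
    _write_tsv(
        outdir / "shared_terms.tsv",
        ("condition_id", "condition_size", "n_shared_terms"),
        [
            (cid, family.condition(cid).size, shared_counts[cid])
            for cid in sorted(shared_counts)
        ],
    )

    # stage 2: common prevalence
    cp_records, thresholds, cp_selected, family_size = _cp_stage(family, manifest)
    for cid, recs in sorted(cp_records.items()):
        adj = bonferroni([p for r in recs for p in (r.p_index, r.p_other)], family_size)
        _write_tsv(
            outdir / f"cp_scores_{cid}.tsv",
            (
                "term_id",
                "lor_index",
                "lor_other",
                "cp",
                "p_adj_index",
                "p_adj_other",
                "corrected",
                "passes_fdr_5",
                "passes_fdr_1",
            ),
            [
                (
                    r.term_id,
                    r.lor_index,
                    r.lor_other,
                    r.cp,
                    adj[2 * i],
                    adj[2 * i + 1],
                    int(r.corrected),
                    int(r.passes_fdr_5),
                    int(r.passes_fdr_1),
                )
                for i, r in enumerate(recs)
            ],
        )
    _write_json(
        outdir / "thresholds.json",
        {
            "per_control": {
                c: {str(a): t for a, t in cuts.items()}
                for c, cuts in thresholds.per_control.items()
            },
            "operative": {str(a): t for a, t in thresholds.operative.items()},
            "rule": "empirical upper-alpha quantile per control; operative = max over controls",
        },
    )

    # stage 3: synergy, for every condition (per-control counts mirror the
    # target analysis and feed the overlap tests)
    synergy_reports: dict[str, syn_mod.SynergyReport] = {}
    eligible_counts: dict[str, dict[str, int]] = {}
    for cid in sorted(family.condition_ids):
        flags: dict[str, frozenset[str]] = {}
        eligible_counts[cid] = {}
        for direction in syn_mod.DIRECTIONS:
            records, exclusions = syn_mod.conditional_profile(
                family,
                cid,
                direction,
                epsilon=manifest.epsilon_x,
                normalization=manifest.normalization,  # type: ignore[arg-type]
            )
            if len(records) < 2:
                raise ConfigurationError(
                    f"stage synergy: condition {cid!r} direction {direction!r} "
                    f"has {len(records)} eligible terms"
                )
            syn_mod.bin_and_flag(
                records,
                n_bins=manifest.n_bins,
                z=manifest.z,
                min_bin_count=manifest.min_bin_count,
            )
            flags[direction] = frozenset(r.term_id for r in records if r.flagged)
            eligible_counts[cid][direction] = len(records)
            _write_tsv(
                outdir / f"conditional_{cid}_{direction}.tsv",
                (
                    "term_id",
                    "x",
                    "y",
                    "y_norm",
                    "bin_index",
                    "bin_upper",
                    "flagged",
                ),
                [
                    (r.term_id, r.x, r.y, r.y_norm, r.bin_index, r.bin_upper, int(r.flagged))
                    for r in records
                ]
                + [(term, "", "", "", "", "", f"excluded:{reason}") for term, reason in exclusions],
            )
        synergy_reports[cid] = syn_mod.synergistic_terms(
            flags["index_given_condition"], flags["condition_given_index"], cid
        )

    target = manifest.target_condition
    target_report = synergy_reports[target]
    overlaps = {}
    for cid in sorted(family.condition_ids):
        if cid == target:
            continue
        universe = len(
            cp_mod.shared_terms(family.intersection(target))
            | cp_mod.shared_terms(family.intersection(cid))
        )
        other = synergy_reports[cid].synergistic
        overlaps[cid] = {
            "n_target": len(target_report.synergistic),
            "n_other": len(other),
            "overlap": len(target_report.synergistic & other),
            "universe": universe,
            "p_value": syn_mod.overlap_significance(
                target_report.synergistic, other, universe
            ),
        }
    _write_json(
        outdir / "synergy_report.json",
        {
            "per_condition": {
                cid: {
                    **rep.counts(),
                    "eligible": eligible_counts[cid],
                    "synergistic_terms": sorted(rep.synergistic),
                }
                for cid, rep in sorted(synergy_reports.items())
            },
            "overlap_with_target": overlaps,
        },
    )

    # stage 4: classification of the target condition's terms
    cp_set = cp_selected[0.05] if 0.05 in cp_selected else cp_selected[max(cp_selected)]
    classifications = classify_terms(
        cp_set,
        set(target_report.flagged_index_given_condition),
        set(target_report.flagged_condition_given_index),
        universe=cp_mod.shared_terms(family.intersection(target))
        | {r.term_id for r in cp_records[target]},
    )
    _write_tsv(
        outdir / "classification.tsv",
        ("term_id", "in_cp_set", "in_dir_index_given_X", "in_dir_X_given_index", "category"),
        [
            (c.term_id, int(c.in_cp_set), int(c.in_dir_index_given_X), int(c.in_dir_X_given_index), c.category)
            for c in classifications
        ],
    )

    category_counts = {cat: 0 for cat in CATEGORIES}
    for c in classifications:
        category_counts[c.category] += 1

    summary = {
        "parameters": {
            "target_condition": target,
            "controls": list(manifest.controls),
            "alphas": list(manifest.alphas),
            "n_bins": manifest.n_bins,
            "z": manifest.z,
            "epsilon_x": manifest.epsilon_x,
            "min_bin_count": manifest.min_bin_count,
            "normalization": manifest.normalization,
            "counts_rounded_to": manifest.counts_rounded_to,
            "yates": manifest.yates,
            "seed": manifest.seed,
        },
        "decisions": {
            "fdr_rule": "empirical upper-alpha quantile of control CP scores; operative threshold = max over controls; strict inequality",
            "normalization": manifest.normalization,
            "zero_cell_handling": "Haldane-Anscombe +0.5 on all cells, flagged",
            "bonferroni_family_size": family_size,
        },
        "shared_terms": shared_counts,
        "thresholds": {str(a): t for a, t in thresholds.operative.items()},
        "n_commonly_prevalent": {str(a): len(s) for a, s in cp_selected.items()},
        "synergy": {cid: rep.counts() for cid, rep in sorted(synergy_reports.items())},
        "overlap_with_target": overlaps,
        "category_counts": category_counts,
    }
    _write_json(outdir / "summary.json", summary)
    return summary
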