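"""Synthetic patient populations with planted association structure.

Real inputs to this pipeline are proprietary EHR exports; this module stands
in for them with a generative model whose ground truth is known per term, so
every downstream stage can be tested end to end.

Model
-----
A population of ``n_patients`` records (one record = one patient). Each
patient independently carries the index condition with probability
``index_prob``. Conditionally on index membership, each condition ``c`` is
drawn so that its marginal probability equals ``condition_probs[c]`` while
the odds ratio of co-membership with the index condition equals
``joint_enrichment[c]`` (Plackett 2×2 construction; closed-form cell
probability below). Conditions are independent of each other given index
membership.

Each term ``d`` has a baseline carriage probability ``p_d`` drawn
log-uniformly from ``baseline_prevalence_range``. A patient carries term
``d`` with probability

    clip( p_d · rr_index^[I] · Π_c rr_condition[c]^[C_c] · Π_c rr_synergy[c]^[I·C_c], 0, 1 )

— a multiplicative risk model: at small p_d the realised cohort odds ratio
for a term equals the configured risk multiplier (rare-disease
approximation), which makes planted effects directly comparable to the
pipeline's log-odds-ratio outputs.

Sampling is stratified: patients fall into 2^(k+1) membership strata, and
per-term counts per stratum are drawn from the exact binomial law by
inverse-CDF transform of uniforms. This is equal in distribution to
per-patient Bernoulli draws, and — because the uniforms depend only on the
seed — couples runs that differ only in effect multipliers monotonically
(common random numbers), which parameter-recovery experiments rely on.

Counts can be rounded to multiples of 10 to emulate de-identified exports;
rounding is applied after exact counting and is monotone, so nesting
invariants hold up to the declared granularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .cohort_io import CohortFamily, CohortSummary
from .errors import ConfigurationError

__all__ = [
    "EffectModel",
    "SimulationConfig",
    "TermTruth",
    "Population",
    "generate_population",
    "summarize_cohorts",
    "simulate_family",
    "desk_preset",
    "null_common_prevalence_config",
    "null_synergy_config",
    "planted_recovery_config",
]

TRUTH_LABELS = (
    "null",
    "index_only",
    "condition_only",
    "commonly_prevalent",
    "synergistic",
    "commonly_and_synergistic",
)


def term_ids(n_terms: int) -> list[str]:
    return [f"T{i:05d}" for i in range(n_terms)]


@dataclass(frozen=True)
class EffectModel:
    """Per-term risk multipliers: index, per-condition, per-condition synergy."""

    rr_index: np.ndarray
    rr_condition: Mapping[str, np.ndarray]
    rr_synergy: Mapping[str, np.ndarray]

    @classmethod
    def null(cls, n_terms: int, condition_ids: Sequence[str]) -> "EffectModel":
        ones = np.ones(n_terms)
        return cls(
            rr_index=ones.copy(),
            rr_condition={c: ones.copy() for c in condition_ids},
            rr_synergy={c: ones.copy() for c in condition_ids},
        )

    def validate(self, n_terms: int, condition_ids: Sequence[str]) -> None:
        arrays = [self.rr_index, *self.rr_condition.values(), *self.rr_synergy.values()]
        for arr in arrays:
            if arr.shape != (n_terms,):
                raise ConfigurationError(
                    f"effect array has shape {arr.shape}, expected ({n_terms},)"
                )
            if np.any(arr < 0):
                raise ConfigurationError("risk multipliers must be non-negative")
        for mapping in (self.rr_condition, self.rr_synergy):
            missing = set(condition_ids) - set(mapping)
            if missing:
                raise ConfigurationError(f"effect model missing conditions {missing}")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic cohort family.

    The default preset is a desk-scale echo of a large EHR extraction:
    200,000 records; an index cohort of ~1,500 (0.75%); one large target
    condition of ~8,000 (4%); three mid-size control conditions of ~4,000
    (2%) each — the proportions, not the absolute sizes, of a
    multi-million-record database.
    """

    n_patients: int = 200_000
    index_prob: float = 0.0075
    condition_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "target": 0.04,
            "control_a": 0.02,
            "control_b": 0.02,
            "control_c": 0.02,
        }
    )
    joint_enrichment: Mapping[str, float] = field(default_factory=dict)
    n_terms: int = 2000
    baseline_prevalence_range: tuple[float, float] = (5e-3, 5e-2)
    effects: EffectModel | None = None
    seed: int = 0
    counts_rounded_to: int = 1
    index_id: str = "index"
    background_id: str = "background"
    target_condition: str = "target"

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_terms <= 0:
            raise ConfigurationError("n_patients and n_terms must be positive")
        if not 0 < self.index_prob < 1:
            raise ConfigurationError("index_prob must be in (0, 1)")
        for cid, p in self.condition_probs.items():
            if not 0 < p < 1:
                raise ConfigurationError(f"condition_probs[{cid!r}] must be in (0, 1)")
        for cid, orr in self.joint_enrichment.items():
            if cid not in self.condition_probs:
                raise ConfigurationError(f"joint_enrichment for unknown condition {cid!r}")
            if orr <= 0:
                raise ConfigurationError("joint_enrichment must be positive")
        lo, hi = self.baseline_prevalence_range
        if not 0 < lo <= hi < 1:
            raise ConfigurationError("baseline_prevalence_range must satisfy 0 < lo <= hi < 1")
        if self.counts_rounded_to not in (1, 10):
            raise ConfigurationError("counts_rounded_to must be 1 or 10")
        if self.target_condition not in self.condition_probs:
            raise ConfigurationError(
                f"target_condition {self.target_condition!r} not in condition_probs"
            )
        if self.effects is not None:
            self.effects.validate(self.n_terms, sorted(self.condition_probs))

    @property
    def condition_ids(self) -> list[str]:
        return sorted(self.condition_probs)

    def enrichment(self, cid: str) -> float:
        return self.joint_enrichment.get(cid, 1.0)

    def resolved_effects(self) -> EffectModel:
        return self.effects or EffectModel.null(self.n_terms, self.condition_ids)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        """Build a config from plain data (e.g. a YAML document).

        An optional ``planted`` list assigns effect multipliers to blocks of
        terms, front to back:

            planted:
              - count: 20
                rr_index: 2.0
                rr_condition: {target: 2.0}
                rr_synergy: {target: 8.0}
        """
        raw = dict(raw)
        planted = raw.pop("planted", [])
        if "baseline_prevalence_range" in raw:
            raw["baseline_prevalence_range"] = tuple(raw["baseline_prevalence_range"])
        config = cls(**raw)
        if planted:
            effects = EffectModel.null(config.n_terms, config.condition_ids)
            start = 0
            for block in planted:
                count = int(block["count"])
                sl = slice(start, start + count)
                if start + count > config.n_terms:
                    raise ConfigurationError("planted blocks exceed n_terms")
                if "rr_index" in block:
                    effects.rr_index[sl] = float(block["rr_index"])
                for key, target in (
                    ("rr_condition", effects.rr_condition),
                    ("rr_synergy", effects.rr_synergy),
                ):
                    for cid, value in block.get(key, {}).items():
                        target[cid][sl] = float(value)
                start += count
            config = replace(config, effects=effects)
        return config


@dataclass(frozen=True)
class TermTruth:
    """Planted ground-truth label of one synthetic term (w.r.t. the target condition)."""

    term_id: str
    label: str
    baseline_p: float
    rr_index: float
    rr_condition: Mapping[str, float]
    rr_synergy: Mapping[str, float]


def _classify(rr_index: float, rr_cond: float, rr_syn: float) -> str:
    common = rr_index > 1 and rr_cond > 1
    if rr_syn > 1:
        return "commonly_and_synergistic" if common else "synergistic"
    if common:
        return "commonly_prevalent"
    if rr_index > 1:
        return "index_only"
    if rr_cond > 1:
        return "condition_only"
    return "null"


def plackett_joint_cell(p_row: float, p_col: float, odds_ratio: float) -> float:
    """P(row ∧ col) for given margins and 2×2 odds ratio.

    Solves OR = p11·p00 / (p10·p01) with p10 = p_row − p11, p01 = p_col − p11,
    p00 = 1 − p_row − p_col + p11; a quadratic in p11 whose admissible root is

        p11 = (S − sqrt(S² − 4·OR·(OR−1)·p_row·p_col)) / (2·(OR−1)),
        S = 1 + (p_row + p_col)(OR − 1).
    """
    if odds_ratio == 1.0:
        return p_row * p_col
    s = 1.0 + (p_row + p_col) * (odds_ratio - 1.0)
    disc = s * s - 4.0 * odds_ratio * (odds_ratio - 1.0) * p_row * p_col
    return (s - math.sqrt(disc)) / (2.0 * (odds_ratio - 1.0))


@dataclass(frozen=True)
class Population:
    """Latent population: per-patient memberships plus per-stratum term counts.

    Strata are indexed by the bit pattern ``I·2^k + Σ_j C_j·2^j`` where bit
    ``j`` corresponds to ``condition_ids[j]`` and the index condition holds
    the top bit. ``stratum_term_counts[s, t]`` is the number of stratum-``s``
    patients carrying term ``t``.
    """

    config: SimulationConfig
    term_ids: tuple[str, ...]
    baseline_p: np.ndarray
    condition_ids: tuple[str, ...]
    index_membership: np.ndarray  # (n_patients,) bool
    condition_membership: np.ndarray  # (n_patients, k) bool
    stratum_sizes: np.ndarray  # (2^(k+1),)
    stratum_term_counts: np.ndarray  # (2^(k+1), n_terms)
    stratum_probs: np.ndarray  # (2^(k+1), n_terms) realised per-stratum term probability

    def _index_bit(self) -> int:
        return len(self.condition_ids)

    def _strata_mask(self, require_index: bool, condition: str | None) -> np.ndarray:
        n_strata = self.stratum_sizes.size
        codes = np.arange(n_strata)
        mask = np.ones(n_strata, dtype=bool)
        if require_index:
            mask &= (codes >> self._index_bit()) & 1 == 1
        if condition is not None:
            j = self.condition_ids.index(condition)
            mask &= (codes >> j) & 1 == 1
        return mask

    def cohort_counts(
        self, require_index: bool = False, condition: str | None = None
    ) -> tuple[int, np.ndarray]:
        """(cohort size, per-term frequency vector) for a membership query."""
        mask = self._strata_mask(require_index, condition)
        size = int(self.stratum_sizes[mask].sum())
        freqs = self.stratum_term_counts[mask].sum(axis=0)
        return size, freqs


def generate_population(config: SimulationConfig) -> Population:
    """Draw one population; the seed fully determines the output."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    cids = config.condition_ids
    k = len(cids)
    effects = config.resolved_effects()

    lo, hi = config.baseline_prevalence_range
    baseline_p = np.exp(rng.uniform(math.log(lo), math.log(hi), size=config.n_terms))

    index_member = rng.random(n) < config.index_prob
    cond_member = np.empty((n, k), dtype=bool)
    for j, cid in enumerate(cids):
        q = config.condition_probs[cid]
        p11 = plackett_joint_cell(config.index_prob, q, config.enrichment(cid))
        p_given_index = p11 / config.index_prob
        p_given_not = (q - p11) / (1.0 - config.index_prob)
        if not (0 <= p_given_index <= 1 and 0 <= p_given_not <= 1):
            raise ConfigurationError(
                f"joint_enrichment for {cid!r} incompatible with its marginal probability"
            )
        u = rng.random(n)
        cond_member[:, j] = np.where(index_member, u < p_given_index, u < p_given_not)

    codes = index_member.astype(np.int64) << k
    for j in range(k):
        codes |= cond_member[:, j].astype(np.int64) << j
    n_strata = 1 << (k + 1)
    stratum_sizes = np.bincount(codes, minlength=n_strata)

    # per-stratum term probabilities
    probs = np.tile(baseline_p, (n_strata, 1))
    for s in range(n_strata):
        has_index = (s >> k) & 1
        mult = effects.rr_index if has_index else 1.0
        row = probs[s] * mult
        for j, cid in enumerate(cids):
            if (s >> j) & 1:
                row = row * effects.rr_condition[cid]
                if has_index:
                    row = row * effects.rr_synergy[cid]
        probs[s] = np.clip(row, 0.0, 1.0)

    # inverse-CDF binomial sampling: monotone in p under common random numbers
    u = rng.random((n_strata, config.n_terms))
    counts = np.zeros((n_strata, config.n_terms), dtype=np.int64)
    for s in range(n_strata):
        if stratum_sizes[s] > 0:
            counts[s] = binom.ppf(u[s], stratum_sizes[s], probs[s]).astype(np.int64)

    return Population(
        config=config,
        term_ids=tuple(term_ids(config.n_terms)),
        baseline_p=baseline_p,
        condition_ids=tuple(cids),
        index_membership=index_member,
        condition_membership=cond_member,
        stratum_sizes=stratum_sizes,
        stratum_term_counts=counts,
        stratum_probs=probs,
    )


def _round_counts(values: np.ndarray, granularity: int) -> np.ndarray:
    if granularity == 1:
        return values
    return (np.rint(values / granularity) * granularity).astype(np.int64)


def _to_summary(
    cohort_id: str, size: int, freqs: np.ndarray, ids: Sequence[str], granularity: int
) -> CohortSummary:
    size_r = int(_round_counts(np.array([size]), granularity)[0])
    freqs_r = _round_counts(freqs, granularity)
    np.minimum(freqs_r, size_r, out=freqs_r)  # rounding up past a rounded size
    term_map = {ids[t]: int(freqs_r[t]) for t in np.nonzero(freqs_r)[0]}
    return CohortSummary(cohort_id=cohort_id, size=size_r, term_freqs=term_map)


def summarize_cohorts(population: Population) -> tuple[CohortFamily, list[TermTruth]]:
    """Aggregate a population into a cohort family plus per-term truth labels.

    Frequencies are exact counts from the population, then rounded per
    ``counts_rounded_to``; zero-frequency terms are dropped. Truth labels are
    a deterministic function of the configured multipliers with respect to
    the target condition.
    """
    config = population.config
    ids = population.term_ids
    g = config.counts_rounded_to

    bg_size, bg_freqs = population.cohort_counts()
    background = _to_summary(config.background_id, bg_size, bg_freqs, ids, g)
    idx_size, idx_freqs = population.cohort_counts(require_index=True)
    index = _to_summary(config.index_id, idx_size, idx_freqs, ids, g)

    conditions: list[CohortSummary] = []
    intersections: dict[str, CohortSummary] = {}
    for cid in population.condition_ids:
        c_size, c_freqs = population.cohort_counts(condition=cid)
        conditions.append(_to_summary(cid, c_size, c_freqs, ids, g))
        i_size, i_freqs = population.cohort_counts(require_index=True, condition=cid)
        intersections[cid] = _to_summary(f"{config.index_id}&{cid}", i_size, i_freqs, ids, g)

    family = CohortFamily(
        background=background,
        index=index,
        conditions=tuple(conditions),
        intersections=intersections,
        counts_rounded_to=g,
    )

    effects = config.resolved_effects()
    target = config.target_condition
    truths = [
        TermTruth(
            term_id=ids[t],
            label=_classify(
                float(effects.rr_index[t]),
                float(effects.rr_condition[target][t]),
                float(effects.rr_synergy[target][t]),
            ),
            baseline_p=float(population.baseline_p[t]),
            rr_index=float(effects.rr_index[t]),
            rr_condition={c: float(effects.rr_condition[c][t]) for c in population.condition_ids},
            rr_synergy={c: float(effects.rr_synergy[c][t]) for c in population.condition_ids},
        )
        for t in range(config.n_terms)
    ]
    return family, truths


def simulate_family(config: SimulationConfig) -> tuple[CohortFamily, list[TermTruth]]:
    """Convenience wrapper: generate a population and summarise it."""
    return summarize_cohorts(generate_population(config))


# ---------------------------------------------------------------------------
# Experiment presets. These fix the study conditions used by the package's own
# calibration and recovery experiments; rationale in docs/methods.md.
# ---------------------------------------------------------------------------


def desk_preset(seed: int = 0, **overrides) -> SimulationConfig:
    """Default desk-scale configuration with no planted effects."""
    return SimulationConfig(seed=seed, **overrides)


def _spread(rng: np.random.Generator, n: int, log_low: float, log_high: float) -> np.ndarray:
    return np.exp(rng.uniform(log_low, log_high, size=n))


def null_common_prevalence_config(seed: int = 0, n_terms: int = 3000) -> SimulationConfig:
    """Exchangeable null for CP-selection calibration.

    All risk multipliers are 1 and the single control condition has the same
    marginal probability as the target, so per term the (target, control) CP
    pair is exchangeable and selection against the control-derived cut-off
    should fire at the nominal rate. A single control is used deliberately:
    the max-over-controls rule is conservative by construction and cannot
    calibrate exactly to α.
    """
    return SimulationConfig(
        n_patients=200_000,
        index_prob=0.02,
        condition_probs={"target": 0.04, "control_a": 0.04},
        n_terms=n_terms,
        baseline_prevalence_range=(0.01, 0.1),
        seed=seed,
    )


def null_synergy_config(seed: int = 0, n_terms: int = 3000) -> SimulationConfig:
    """Null (no planted synergy) family for flag-rate calibration.

    Terms carry marginal index- and condition-risk spreads (log-uniform,
    ln rr in [0.3, 1.5]) so the conditional-prevalence scatter has a genuine
    x-axis, but rr_synergy ≡ 1. The intersection is enriched
    (joint_enrichment 8 on a 4,000-record index cohort) and baseline
    prevalence kept in [0.005, 0.02] so per-stratum probabilities stay well
    below 1 and per-term intersection counts are large enough for the
    normalised conditional LOR to be roughly Gaussian within bins — the
    regime in which the mean + 1.645·sd rule has its nominal 5% level.
    """
    rng = np.random.default_rng(seed + 1_000_003)
    condition_ids = ["target"]
    effects = EffectModel.null(n_terms, condition_ids)
    effects.rr_index[:] = _spread(rng, n_terms, 0.3, 1.5)
    effects.rr_condition["target"][:] = _spread(rng, n_terms, 0.3, 1.5)
    return SimulationConfig(
        n_patients=200_000,
        index_prob=0.02,
        condition_probs={"target": 0.06},
        joint_enrichment={"target": 8.0},
        n_terms=n_terms,
        baseline_prevalence_range=(0.005, 0.02),
        effects=effects,
        seed=seed,
    )


def planted_recovery_config(
    seed: int = 0,
    rr_synergy_level: float = 8.0,
    n_terms: int = 2000,
    n_synergistic: int = 20,
    n_commonly_prevalent: int = 20,
) -> SimulationConfig:
    """Desk-scale family with planted synergistic and commonly-prevalent terms.

    Background terms carry shared marginal spreads (identical rr_condition
    across the target and all controls, so control CP distributions remain
    exchangeable with the target's null terms). The first ``n_synergistic``
    terms get rr_index = rr_condition(target) = 2 plus rr_synergy =
    ``rr_synergy_level`` on the target only; the next ``n_commonly_prevalent``
    terms get rr_index = rr_condition(target) = 6 with no synergy. Varying
    only ``rr_synergy_level`` under the same seed yields monotonically
    coupled runs (common random numbers).

    Index and condition memberships are independent (no joint enrichment)
    and the cohorts are sized so the index∩target intersection is a small
    (~2%) share of either parent cohort: a planted term's intersection
    enrichment then barely moves its marginal LOR, so planted terms land in
    x-bins dominated by null terms rather than by each other, and the
    normalised conditional prevalence y/x responds to rr_synergy through y
    alone. The ~200-record expected intersection keeps every planted term's
    expected intersection frequency above 50, the regime where saturation of
    the flagging rule is meaningful.
    """
    rng = np.random.default_rng(seed + 2_000_003)
    condition_ids = ["target", "control_a", "control_b", "control_c"]
    effects = EffectModel.null(n_terms, condition_ids)
    effects.rr_index[:] = _spread(rng, n_terms, 0.3, 1.5)
    shared_cond = _spread(rng, n_terms, 0.3, 1.5)
    for cid in condition_ids:
        effects.rr_condition[cid][:] = shared_cond

    syn = slice(0, n_synergistic)
    effects.rr_index[syn] = 2.0
    effects.rr_condition["target"][syn] = 2.0
    for cid in condition_ids[1:]:
        effects.rr_condition[cid][syn] = 1.0
    effects.rr_synergy["target"][syn] = rr_synergy_level

    cp = slice(n_synergistic, n_synergistic + n_commonly_prevalent)
    effects.rr_index[cp] = 6.0
    effects.rr_condition["target"][cp] = 6.0
    for cid in condition_ids[1:]:
        effects.rr_condition[cid][cp] = 1.0

    return SimulationConfig(
        n_patients=500_000,
        index_prob=0.02,
        condition_probs={"target": 0.02, "control_a": 0.01, "control_b": 0.01, "control_c": 0.01},
        n_terms=n_terms,
        baseline_prevalence_range=(0.01, 0.025),
        effects=effects,
        seed=seed,
    )
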