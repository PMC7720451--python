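# Methods

`cohortminer` mines the adverse-health correlates of a pair of clinical
conditions from de-identified EHR cohort *term-frequency summaries*: for each
cohort, only its record count and the number of records referencing each
clinical term are available. One condition is designated the *index*
condition; every other condition is compared against it. The pipeline has
three stages — shared-term counting, common-prevalence scoring, and
synergistic-prevalence detection — plus a synthetic cohort generator that
stands in for proprietary EHR exports.

## Data model

A `CohortSummary` is a cohort id, a record count `N_X`, and a map
`d → f_X(d)` of term frequencies; terms with zero frequency are never stored.
A `CohortFamily` bundles the background population (all records meeting the
demographic constraints), the index cohort, the condition cohorts, and the
index∩condition intersection cohorts. Families may declare
`counts_rounded_to = 10`, the de-identification convention in which every
exported count is rounded to a multiple of 10; all nesting checks and cell
constructions then tolerate deficits attributable to rounding (one granule
per independently rounded operand) instead of raising.

Terms are opaque identifiers. A free-text label column is carried through
serialisation but never interpreted — ontology navigation is explicitly out
of scope.

## Stage 1 — shared terms

`S_X` is the set of terms with non-zero frequency in the index∩X
intersection cohort; `|S_X|` as a function of `N_X` is the first-stage
statistic. No modelling is involved; the stage exists to contextualise a
condition's overlap with the index against same-sized controls.

## Stage 2 — common prevalence

For a term `d` and cohort `X`, prevalence relative to the background is
summarised by the natural-log odds ratio of the 2×2 table

|                | in X            | not in X                          |
|----------------|-----------------|-----------------------------------|
| **has d**      | `f_X(d)`        | `f_BG(d) − f_X(d)`                |
| **no d**       | `N_X − f_X(d)`  | `N_BG − N_X − f_BG(d) + f_X(d)`   |

`LOR(d, X|BG) = ln(ad/bc)`. When any cell is zero, all four cells receive
the Haldane–Anscombe +0.5 correction and the record is flagged. A Pearson
1-df χ² p-value is computed per table and Bonferroni-adjusted over the
family of all (term, cohort) hypotheses tested in the run; with cohort sizes
in the millions these p-values saturate, so they are reported but never used
for ranking (a regression test pins a fixture where LOR- and p-orderings
disagree).

The *common prevalence* score of `d` for the pair (index, X) is

    CP_X(d) = min{ LOR(d, X|BG), LOR(d, index|BG) },

computed for every term with non-zero frequency in both cohorts: CP is high
only when the term is enriched in *both*. No pre-filtering on χ²
significance is applied by default (a toggle exists); adjusted p-values are
reported alongside.

**Control-calibrated cut-offs.** Significance thresholds come from the CP
distributions of control conditions chosen to be biologically unrelated to
the index condition: for each control and level α, the cut-off is the
*empirical upper-α quantile* — the smallest observed CP value such that the
fraction of that control's scores strictly above it is ≤ α. The operative
threshold is the **maximum across controls** and selection uses strict
inequality. The max rule is deliberately conservative: it treats the most
permissive control as the yardstick. Consequently the selection rate on
exchangeable null data equals α only when calibrating against a single
control of the same size as the target; the package's calibration experiment
is designed that way (below), while production runs keep the conservative
max rule.

## Stage 3 — synergistic prevalence

*Conditional prevalence* restricts the reference population to a parent
cohort: `LOR(d, A|Y)` is computed from the table comparing the intersection
A∩Y against Y (same cell algebra, with the intersection as the "cohort" and
the parent as the "background"). Because the parent is a subsample of the
background, conditional prevalence scales with marginal prevalence; raw
conditional LORs are therefore not comparable across terms. Each direction
(index|X and X|index) builds, per eligible term,

    x = LOR(d, A|BG),   y = LOR(d, A|parent),   y_norm = y / x,

and flags terms whose `y_norm` is an outlier *given* `x`: terms are split
into 10 equal-width bins on `x`; each bin's mean and sample (n−1) standard
deviation of `y_norm` define the one-sided 95% Gaussian bound
`mean + 1.645·sd`; terms strictly above their bin's bound are flagged. Bins
with fewer than 3 terms merge into their left neighbour (leftward
under-populated runs merge rightward) so the standard deviation is defined.
Terms flagged in **both** directions are *synergistically prevalent*.
Overlap between two conditions' synergistic sets is tested with a one-sided
Fisher's exact (hypergeometric upper-tail) test; the default universe is the
union of the two analyses' shared-term sets, recorded in the output since
the choice is interpretive.

Numerical choices, all echoed into the run summary for audit:

* **Eligibility.** Only terms with non-zero intersection frequency enter a
  direction; terms with `x ≤ ε = 0.1` are excluded (ratio normalisation is
  meaningless near `x = 0`, and the procedure targets terms with clearly
  positive marginal enrichment). Exclusions are logged per term with a
  reason.
* **Normalisation.** "Normalised by" is read as division; subtraction is
  available via `normalization="difference"` and the choice is recorded in
  the output metadata.
* **Equal-width bins** over the observed x-range (equal-count binning is the
  natural alternative; equal-width is the default and the bin edges are part
  of the output).
* Strict inequality at the bound: a degenerate bin (zero spread) flags
  nothing.

## Classification

Terms of the target condition are classified from three flags — membership
in the 5%-FDR commonly-prevalent set, and the two directional conditional
flags: all three ⇒ *strongly associated with both conditions and their
co-occurrence*; both directional flags without CP ⇒ *screen in
co-occurrence*; CP plus exactly one directional flag ⇒ an *indicator*
category for the corresponding direction; anything else ⇒ *none*, reported
with its raw flags rather than forced into a category.

## Synthetic cohort generator

Real inputs are proprietary, so the generator produces populations whose
ground truth is known per term.

* **Memberships.** Each of `n_patients` records (one record ≡ one patient)
  carries the index condition with probability `index_prob`; each condition
  `c` is drawn conditionally on index membership so that its marginal equals
  `condition_probs[c]` while the co-membership odds ratio equals
  `joint_enrichment[c]` (Plackett construction; the joint cell is the
  admissible root of the quadratic `OR = p11·p00/(p10·p01)` under fixed
  margins). Conditions are mutually independent given index membership.
* **Terms.** Term `d` has baseline probability `p_d`, log-uniform on
  `baseline_prevalence_range`; a patient carries `d` with probability
  `clip(p_d · rr_index^[I] · Π_c rr_condition[c]^[C_c] ·
  Π_c rr_synergy[c]^[I·C_c], 0, 1)`. The model is multiplicative on
  probability rather than logistic: at small `p_d` the realised cohort odds
  ratio equals the configured risk multiplier (rare-disease approximation),
  so planted effects are directly comparable to the pipeline's LOR outputs
  and trivially brute-forceable.
* **Sampling.** Patients fall into `2^(k+1)` membership strata; per-term
  counts per stratum are drawn from the exact binomial law by inverse-CDF
  transform of seed-determined uniforms. This is equal in distribution to
  per-patient Bernoulli draws, and makes runs that differ only in effect
  multipliers monotonically coupled (common random numbers) — the property
  the recovery experiments rely on. The per-patient term-indicator matrix is
  never materialised; membership flags are.
* **Truth labels** are a deterministic function of the multipliers with
  respect to the target condition: `commonly_prevalent` ⇔ `rr_index > 1` and
  `rr_condition > 1` with no synergy; `synergistic` ⇔ `rr_synergy > 1`
  without the former; both ⇔ `commonly_and_synergistic`; single-sided
  effects are `index_only`/`condition_only`.
* **Rounding** (optional, off for unit tests): counts rounded to the nearest
  multiple of 10 after exact counting; rounding is monotone, so nesting
  holds up to the granularity.

The generator emulates frequency structure only. It has no time dimension
(the summaries it mimics have none), no demographic covariates beyond
implicit eligibility, no term–term correlation beyond that induced by shared
memberships, and no coding bias or under-reporting. Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under the
stated generative law — not that real EHR extractions satisfy that law.

### Preset study conditions

The default (*desk-scale*) preset echoes the proportions of a large EHR
extraction at 200,000 records: index cohort ≈ 1,500 (0.75%), one large
target condition ≈ 8,000 (4%), three mid-size controls ≈ 4,000 (2%) each,
2,000 terms with baselines in [0.005, 0.05].

Three experiment presets fix the package's own validation conditions; each
was designed from the power analysis below, not tuned.

* **CP null calibration** (`null_common_prevalence_config`): all multipliers
  1, a 4,000-record index and a single 8,000-record control sized equal to
  the target, 3,000 terms. Per term, the target and control CP scores are
  then exchangeable, so selection against the control-derived cut-off fires
  at the nominal rate; a single control is used because the max-over-controls
  rule is conservative by construction and cannot calibrate exactly to α.
* **Synergy null calibration** (`null_synergy_config`): marginal index and
  condition risk spreads (ln rr uniform on [0.3, 1.5]) with `rr_synergy ≡ 1`,
  a joint-enrichment-8 intersection (~1,300 of 500,000-scale memberships on
  a 4,000-record index cohort) and baselines in [0.005, 0.02]. The spreads
  give the scatter a genuine x-axis; the bounds keep every per-stratum
  probability far from 1 (clipping would fabricate synergy) and per-term
  intersection counts large enough that binned `y_norm` is approximately
  Gaussian and homoscedastic — the regime in which the `mean + 1.645·sd`
  rule has its nominal 5% level.
* **Planted recovery** (`planted_recovery_config`): 500,000 records, 10,000-
  record index and target cohorts with independent co-membership
  (intersection ≈ 200 records, ~2% of either parent — the same order as the
  share seen in real extractions), 5,000-record controls, baselines in
  [0.01, 0.025]. Twenty synergistic terms are planted with
  `rr_index = rr_condition(target) = 2` and `rr_synergy ∈ {2, 4, 8}`; twenty
  commonly-prevalent terms with `rr_index = rr_condition(target) = 6`.
  Background terms share identical `rr_condition` across the target and all
  controls, keeping the control CP distributions exchangeable with the
  target's null terms. The small intersection share matters: it makes a
  planted term's marginal LOR nearly invariant to `rr_synergy`, so `y/x`
  responds through `y` alone (monotone recovery) and planted terms land in
  x-bins dominated by null terms rather than by each other (no
  self-masking). Recovery is measured as each planted term's rank within
  the null population — invariant under common random numbers — which is
  the statement "more synergy never ranks a planted term lower" free of
  planted-vs-planted jostling at saturation.

## Degenerate inputs and tie-breaking

* All-zero 2×2 tables are rejected at construction; zero margins make χ²
  vacuous (`p = 1`, flagged degenerate).
* An empty control CP distribution is a configuration error; a constant one
  yields that constant as the cut-off at every level.
* If all eligible terms share one x value, binning degenerates to a single
  bin and proceeds.
* Ties at a threshold (CP equal to the cut-off, `y_norm` equal to the bin
  bound) are excluded — strict inequalities throughout.
* The 1%-level selection is nested within the 5%-level selection by
  construction (the 1% cut-off is never smaller).

## Reproducibility

A run is fully determined by its manifest (input paths plus every analysis
parameter and seed): all outputs are sorted TSV/JSON with fixed float
formatting, and re-running a manifest reproduces byte-identical files. The
simulator is fully determined by its config's seed. Problem sizes of the
shipped experiments (200k–500k records, 2,000–3,000 terms) keep any single
experiment under ~15 seconds on one CPU; they are the package's chosen desk
scale, echoing the proportions rather than the absolute sizes of
multi-million-record databases.

## Known limitations

* The FDR cut-off is an empirical quantile of control scores — an
  interpretive operationalisation of "FDR based on the control distribution";
  fitted-tail alternatives would differ in the extreme tail.
* Ratio normalisation amplifies noise at small marginal LORs; the ε-guard
  excludes that region rather than modelling it.
* With rounded counts, arithmetic consistency is only guaranteed up to the
  rounding granularity; cells clamped to zero are flagged but still enter
  continuity-corrected LORs.
* χ² p-values (even Bonferroni-adjusted) are reported for completeness but
  are uninformative at EHR scale; no inference in the pipeline depends on
  them.
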