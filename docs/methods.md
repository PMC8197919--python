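# Methods

This note documents the models, numerical choices and limitations of the
package. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Prioritization cascade

Variants pass three sequential stages; exclusion reasons accumulate in
stage order and a variant is retained iff every stage retains it.

**Call quality.** A call is excluded when the upstream pipeline flagged it,
read depth is below `min_depth` (default 10), heterozygous allele balance
(ABHet = alternate reads / total reads) falls outside `abhet_bounds`
(default [0.2, 0.8], bounds inclusive-retained), or fewer than
`min_callers` (default 2 of 3) variant callers support it. ABHet applies
only to heterozygous calls; homozygous-alternate calls carry no ABHet and
skip the rule. Negative depth is an input error, not an exclusion.

**Consequence.** Only potentially protein-altering classes are studied:
frameshift, stop gained/lost, canonical splice site, in-frame indel,
missense, and structural-interaction calls (variants predicted to disrupt
internal polypeptide interactions; treated as high-impact throughout).
Compound printed classes such as "frameshift & stop_gained" or "missense &
splice region" are stored under a single primary type chosen by severity
(frameshift > stop_gained > stop_lost > splice_site >
structural_interaction > inframe_indel > missense > splice_region), with
the full printed string preserved, so each record is counted exactly once.
Non-canonical splice-region changes alone do not qualify as high impact;
the one compound missense-and-splice-region record in the bundled tables
is retained through its missense in-silico evidence, which is consistent
with that reading. The single consequence reason code covers every
non-qualifying class.

**Frequency and specificity.** Criterion A fires when the maximum minor
allele frequency over the in-scope (database, population) entries exceeds
`maf_threshold` (default 0.001). Absent entries contribute nothing:
absence from a population database is the strongest rarity evidence the
design uses, and is deliberately distinct from an explicit frequency of
zero. Criterion B fires when the variant recurs in more than
`max_inhouse_families` (default 2) families of an internal reference
database; that count is an annotation supplied with the input (the
internal database itself is not distributed), and the synthetic generator
plants it. Two combinators are provided because the design is genuinely
ambiguous: `any_criterion_excludes` (default — every retained variant in
the bundled tables is consistent with an effective disjunction) and the
literal conjunctive `both_criteria_exclude`. Under the conjunctive mode
the retained set is provably a superset of the disjunctive mode's. Two
population scopes mirror the two cohort dialects: `ancestry_matched`
consults only configured ancestry tags (default NFE/EUR/EA), while
`any_population` consults every entry, including East-Asian frequencies,
as the replication analysis requires.

**Pre-passed stages.** The bundled tables print only variants that already
survived QC and frequency screening in the source pipelines, whose
consulted-database set is wider than the two gnomAD evidence columns the
tables print. Fixture loads therefore mark both stages pre-passed, and
downstream tabulation starts at the pathogenicity classification; the
gnomAD columns are carried as reported evidence. This keeps the recomputed
counts independent of databases the package cannot consult.

## Pathogenicity classification

Four independent branches; a variant is retained iff at least one fires:

1. **High impact** — the consequence class itself (see above).
2. **In-silico triple** — MetaSVM = D and MetaLR = D and phred-scaled
   CADD ≥ 20 (inclusive), all three present; applies to missense variants
   only. The ensemble calls are consumed as printed D/T categories, never
   recomputed from their nine constituent algorithms.
3. **ClinVar** — pathogenic or likely-pathogenic assertion (exact P/LP;
   anything else maps to a non-triggering class).
4. **HGMD** — disease-causing mutation (exact DM).

Missing components fail their branch rather than defaulting. The clinical
branches rescue benign-scored missense variants (the bundled discovery
table contains one such record: tolerated ensemble calls and CADD 0.004,
retained via ClinVar P + HGMD DM). Classification is monotone in evidence:
adding a satisfied branch can only grow the criteria set.

## Tabulation and replication

Summaries count retained records by primary consequence class, distinct
carrier identifiers (a compound printed identifier such as "1048/5320" is
conservatively one carrier), distinct genes, and distinct genes per
functional category. Category attribution uses each record's single
printed pathway label when present; records without a label contribute to
every category of their gene in the panel and multi-category genes are
flagged in the summary. The carrier fraction is held as an exact rational
so that fraction × cohort size equals the carrier count identically.

Replication restricts the second cohort to genes with retained variants in
the discovery cohort before classification. Case-only tabulation returns
the variant keys with zero carriers among control samples; keys absent
from the control matrix count as zero-carrier columns.

## Burden / variance-component testing

### Statistic

See the README for the definition of Q_ρ. The null model is an
intercept-only logistic regression by default (the analysis design reports
no covariate adjustment); with covariates the null means come from a
statsmodels binomial GLM and the score covariance projects out the design
in the sqrt(variance)-weighted space. Missing dosages contribute nothing
to scores. Default weights are the Beta(1,25) density at the sample-
estimated minor allele frequency (zero frequencies replaced by the
pseudo-count estimate 0.5/(2n+1)); a flat scheme is available. The default
ρ grid is {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}, dense near the kernel
end where the optimum typically lies for mixed-direction effects; grid,
weights and every threshold are configurable.

### Null distribution and tail evaluation

Each Q_ρ is asymptotically Σ_k λ_k χ²₁ with λ_k the eigenvalues of
R_ρ^{1/2} Φ R_ρ^{1/2}, where Φ = (GW)ᵀ P (GW) is the null covariance of
the weighted score vector and R_ρ = (1−ρ)I + ρ11ᵀ. Tails are evaluated by
a hybrid:

* **Imhof characteristic-function inversion**, vectorized over dyadic
  panels with node counts proportional to the local phase change (arctan
  terms plus oscillation) and Simpson integration per panel; truncation
  where the oscillation-damped envelope falls below ~3×10⁻⁸. Absolute
  accuracy ~10⁻⁷; the default evaluator.
* **Lugannani–Rice saddlepoint** on the cumulant generating function
  K(t) = −½Σ log(1−2tλ_k); small relative error far into the tail. Used
  when the inversion's node budget explodes (severely ill-conditioned
  spectra) and whenever the inversion returns below 10⁻⁶, where its
  absolute tolerance is no longer informative.
* **Liu–Tang–Zhang moment matching** (modified variant): closed-form and
  vectorized; used inside the grid-combination integrand, over permutation
  batches, near the distribution centre, and as a general fallback.

A one-component mixture is evaluated exactly as a scaled χ²₁. Q ≤ 0 gives
p = 1; spectra are cleaned of eigenvalues below 10⁻¹⁰ of the maximum; a
unit with no genotype variance returns p = 1 with a warning; constant
phenotype is an input error.

The optimal test takes T = min_ρ p_ρ and computes
P(min_ρ p_ρ ≤ T | H₀) by the standard one-dimensional integral over the
shared burden-direction χ²₁ component, with per-ρ quantiles of T from the
moment match and the remainder moment-matched per evaluation point
(ρ capped at 0.999 inside the integral; m = 1 or a degenerate burden
direction reduces to the Bonferroni bound). The result is clamped to
[T, grid size × T]: the exact combination probability is bracketed by the
single best grid point and its Bonferroni bound.

### Permutation oracle

Phenotype-label permutation (equivalently residual permutation under the
intercept-only null) recomputes the full grid per permutation; per-ρ
p-values use the moment match with the spectra held fixed, so observed and
permuted statistics pass through the same monotone transform, and the
permutation p of the min-p statistic is (1 + #{T_b ≤ T_obs})/(B + 1).
Permutations require an explicit seed; the suite derives a distinct
sub-seed per unit so units do not share permutation streams. The
permutation p-value is exact by construction and is the package's
ground-truth oracle.

### Small-sample behaviour

With unbalanced case-control ratios and low minor allele counts the
asymptotic mixture understates the skewness of binary-trait scores, so
analytic p-values are mildly anti-conservative deep in the tail. At the
default study geometry (138 cases / 598 controls, gene-level minor allele
counts in the tens) the analytic optimal-test rejection rate is within the
binomial 95% CI of the nominal level at α = 0.05 but roughly threefold
inflated at α = 0.01 (both measured by the test suite on the generator's
null). Exact small-sample moment and kurtosis corrections are deliberately
out of scope; for stringent thresholds use the permutation p-value, which
is calibrated at all levels. Multiplicity correction is Bonferroni over
the units actually tested (none as alternative).

### Analysis modes

`all_rare` tests every variant of a gene; `pathogenic_only` restricts the
columns to classifier-retained variants (a subset of the former);
`pathway` pools all rare variants of every panel gene in a functional
category. Pathway mode deliberately uses all rare variants (mode-1
semantics at category level); empty units are skipped with a log entry.

## Synthetic cohorts

The generator emulates the assumed study design: default 138 cases versus
598 controls; per-gene variant counts Poisson with mean 3; MAFs log-uniform
on a configurable spectrum within (0, 0.01], default [10⁻⁵, 10⁻³] matching
a discovery pipeline's rarity regime; unlinked variants (rare-variant
linkage disequilibrium is negligible at these frequencies and the analysis
treats variants independently); Hardy–Weinberg genotype sampling with a
carrier-scale odds ratio applied to cases of enriched genes or categories
(carrier status is Bernoulli in the enriched odds; homozygous-alternate
status follows conditional Hardy–Weinberg). Gene-level enrichment settings
override category-level ones. Case-only genes set the control carrier
probability to zero. Every random draw flows from one required seed
through named sub-streams (structure / genotypes / annotations / QC), so
identical configurations are bit-identical and stages can be regenerated
independently.

Annotations are deterministic-by-branch: each variant receives a planted
pathogenicity branch (high-impact / in-silico triple / ClinVar / HGMD /
none) and the exact annotation profile that triggers it, which makes the
planted retained set exactly recoverable by the cascade + classifier — the
end-to-end correctness check. Planted filter failures (low depth, ABHet
out of range, single caller, pipeline flag, synonymous, common-in-
population, recurrent-in-house) are assigned either randomly by configured
fractions or in a deterministic cycle that guarantees every exclusion
reason appears. Only observed variants (≥ 1 carrier) are emitted, like a
real call set; the truth object covers every emitted variant and records
the realized case-only key set (planted case-only genes plus any variant
whose realized control carrier count is zero), so exact-set recovery is
well-defined.

**Calibration scenarios.** The null, enrichment and
analytic-vs-permutation scenarios draw MAFs log-uniformly from
[10⁻³, 10⁻²] — the upper part of the admissible spectrum — because at 736
samples the discovery-regime spectrum leaves most sites monomorphic
in-sample and every score test degenerates; calibration requires
polymorphic units. The null scenario uses a 500-gene synthetic panel
(~470 tested units after Poisson gene sizes and monomorphic drops; the
calibration checks pool two seeds to exceed 500 units). The enrichment
scenario plants a carrier odds ratio of 5 on the notochord category of the
bundled panel. Power and calibration checks use 40-replicate and
two-cohort problem sizes respectively, chosen to keep the suite fast while
leaving the binomial confidence bounds meaningful.

**What the generator does not model.** Population structure, relatedness,
linkage disequilibrium, sequencing error, genotype missingness and phasing
are all absent. Passing tests therefore demonstrate correctness of the
implemented statistics under the assumed sampling model, not robustness of
the study design to confounding; on real cohorts the usual ancestry
matching and kinship screening remain the analyst's responsibility.

## Known limitations

* The exclusion logic's combinator (disjunctive vs conjunctive) is
  configurable because the design statement is ambiguous; neither mode is
  asserted as "the" study's.
* The discovery table prints 30 distinct carrier identifiers (compound
  identifier counted once) against a published carrier total of 32; the
  package preserves the printed identifiers and reports, but does not
  resolve, the discrepancy.
* The published pathway-level association values for the notochord
  category are not reproducible here: they require the control-cohort
  genotypes, which are not publicly distributable, and the original
  weighting/grid/covariate choices are unstated. The burden machinery is
  validated by simulation instead.
* Analytic tails are approximate at low minor allele counts (see
  small-sample behaviour above).
* The bundled panel covers the genes of the two packaged cohorts; the full
  literature-curated candidate panel is study-specific and must be
  supplied as a panel document for panel-wide screens.
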