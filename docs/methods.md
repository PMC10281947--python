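# Methods

## Data model and preprocessing

Peak areas from untargeted LC–MS are relative abundances: strictly
positive when present, with non-detects as explicit missing values. A `0`
in an input table is rejected rather than silently treated as missing,
because normalized peak areas cannot be zero and Metabolon-style exports
use blanks for non-detects. Metabolite and sample identifiers are matched
exactly (case-sensitive) after stripping surrounding whitespace, since
metabolite names carry meaningful punctuation and case.

**Median normalization** divides each value by the median of its
metabolite within its batch, computed over non-missing values (even counts
use the midpoint mean). The operation is idempotent and leaves the missing
mask untouched. A metabolite never observed within a batch has no defined
scale factor; `normalizable_subset` removes such metabolites before
normalization (they could not survive the presence filter anyway) and the
pipeline normalizes the microdialysate and CSF blocks separately, since
they are separate platform runs with disjoint detection profiles.

**Presence filter.** A metabolite is analyzable when observed in at least
`ceil(min_fraction × n_samples)` samples; the default `min_fraction=0.90`
gives the ≥40-of-44-catheters rule at the cohort size this analysis is
designed around, and behaves predictably at other sizes. Survivors keep
their input order.

**Perfusate exclusions** (e.g. a lactate-containing perfusion fluid in
some cases) mask the affected (metabolite, case) cells rather than
deleting rows, so paired statistics skip those cases while the metabolite
universe for ranked lists is preserved. With two of nine cases excluded, a
paired E/B test runs on the remaining seven pairs.

Handling of a missing value inside an otherwise-present metabolite: a
catheter pair contributes to a fold change only when both members are
observed; the pair is otherwise reported unavailable (no imputation for
ranked lists or tests).

## Ranked lists

`rank_score = log2(FC)` rather than raw FC: the ordering is identical (a
monotone transform), but the weighted enrichment statistic depends on hit
magnitudes, and the log scale is symmetric about zero so positive and
negative enrichment are weighted comparably. The choice is recorded in
every ranked list's provenance. Ties in FC break by ascending metabolite
name — deterministic and seed-free. Reversing a contrast exactly reverses
the ordering and negates every score.

## Enrichment

The running-sum statistic follows the preranked convention: walking the
list, a hit at position *i* adds `|s_i|^p / N_R` (`N_R` = the sum of
`|s|^p` over hits), a miss subtracts `1/(N − N_H)`; ES is the signed
maximum-magnitude deviation (first position attaining it, in case of
exact ties). Defaults and their rationale:

- `weighting_exponent p = 1` (the classic weighted statistic and the
  default of the software family this reimplements); `p = 0` is available,
  and the acceptance suite checks that sign-level conclusions on the
  synthetic cohort are identical across `p ∈ {0, 1}`, since the exponent
  used for the original analyses is not documented.
- **Metabolite-label permutation null** (1000 permutations, seed
  mandatory): ranked lists come from single catheter pairs, so no
  phenotype/sample permutation exists. Each permutation redraws the `N_H`
  hit positions uniformly without replacement.
- `NES = ES / mean(|ES_null| of the same sign)` — same-sign normalization
  so positive and negative enrichment are separately calibrated. If no
  same-sign null value exists, the pooled `|ES_null|` mean is used and the
  result flagged.
- Nominal p is the same-sign tail fraction. FDR q is the ratio-of-tails
  estimate over all results sharing a null family (pooled null NES tail /
  observed NES tail, clipped to [0, 1]), monotonized so q never decreases
  as |NES| grows within a sign family.
- Estimates of exactly 0 are floored at `1e-5` for display (`<1e-05`);
  raw estimates are retained on the result object.
- Set members absent from a ranked list are dropped and counted, never
  imputed. If every hit has score 0 under `p > 0` (all-tied centre of a
  degenerate list), the set falls back to `p = 0`, flagged in provenance.

## Paired exact differential abundance

Zero differences are discarded before ranking (the convention under which
the attainable minimum two-sided p at full n is `2/2^n` — matching the
0.0039/0.0156 floors of nine- and seven-pair cohorts); tied magnitudes
receive midranks. The exact null pmf of the signed-rank sum is built by
convolution over sign flips on doubled (integer) midranks — equivalent to
enumerating all 2^n assignments but O(n³) — and the two-sided p doubles
the smaller tail, capped at 1. No normal approximation is used at any n.

The test operates on paired differences of normalized values, while the
significance class uses the ratio scale: `up` iff `p ≤ 0.05` and mean FC
≥ 2, `down` iff `p ≤ 0.05` and mean FC ≤ 0.5. `mean_fc` is the arithmetic
mean of per-case ratios (a "mean of fold-changes"), not a ratio of means;
both are emitted, the former drives classification. No multiple-testing
correction is applied in this module — the FC cutoff plus raw p mirrors
the volcano-style reporting convention; BH adjustment can be added as a
column but never changes the class.

Cross-platform concordance (targeted concentrations vs untargeted peak
areas) is ordinary least squares on untransformed values with r² the
squared Pearson correlation, intended for wide-dynamic-range checks.

## Clustering

Spearman correlations are computed per sample pair over pairwise-complete
metabolites (≥3 shared required, else the cell is undefined and flagged).
For Ward clustering, remaining missing values are filled with half the
metabolite's minimum observed value — a conventional detection-floor
surrogate, recorded here because the upstream tool's treatment is
undocumented; autoscaling (mean 0, sd 1 per metabolite) drops
zero-variance metabolites with a warning. Clipping of autoscaled values at
±6 affects only the display matrix, never distances. Samples enter the
linkage in lexicographic order, making the dendrogram invariant to input
column order with deterministic tie resolution. The linkage is Ward on
Euclidean distances (scipy); the test suite verifies the heights against a
naive Lance–Williams agglomeration.

## CSF bloodiness and plasma contamination

The paired list uses one subject's simultaneously drawn bloody and clean
CSF: universe = metabolites observed in both samples ∩ the microdialysate
presence-filtered set; FC = bloody/clean. The pooled list ranks CSF
samples by heme content (arbitrary units — only rank order matters),
takes the top and bottom `ceil(n/4)` as bloody/clean pools (7 each from
26), filters to metabolites observed in >90% of microdialysate samples
and >85% of CSF samples, and uses the ratio of pool arithmetic means.
Heme ties are broken by sample id, with a warning when a tie straddles a
pool boundary. A case is scored plasma-positive when the bloody top-35
set is positively enriched (FDR ≤ 0.05) in its tumour-contrast list, or
the clean bottom-35 set negatively enriched.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with ground truth for recovery testing. Values follow a log-normal
multiplicative model,

    value(m, s) = 2^( μ_m + patient_{m,case} + effect_{m,location} + ε ),

with `μ_m ~ N(10, 2²)` (log2 peak-area scale), patient effects
`N(0, τ²)`, `τ = 1` per (metabolite, case) shared across a case's
catheters — so patient heterogeneity cancels in within-case fold changes,
the property the paired design exploits — and residual `ε ~ N(0, σ²)`,
`σ = 0.5`. Default geometry: 9 cases (7 with E/NE/B, 2 with E/B; 25
catheters), 200 metabolites, 28 CSF samples; two batches split by
enrolment order, with IDH-mutant cases interleaved across the enrolment so
genotype is not confounded with batch.

Metabolite classes and default log2 location effects (relative to brain):
plasma-derived 20% (E +3, NE +0.5 — barrier-disruption influx),
tumour-produced 10% (E +5, NE +3; one designated GAA-like member at E +7,
NE +3.75, i.e. ~128× and ~13× — the extreme reported for that compound
family), brain-associated 10% (E −3, NE −1), one 2-HG-like oncometabolite
(+4.4 ≈ 21× in tumour catheters of IDH-mutant cases only), background the
rest. One background metabolite is flagged perfusate-excluded in two
cases (the lactate-in-perfusate situation).

Missingness is intensity-dependent by default: a logistic in
log2-abundance centred at the configured rate's quantile (default rate
0.05), emulating non-detects; realized missingness approximates the
nominal rate. The designated marquee metabolites' baselines are pinned one
sd above the mean so they belong to the ≥90%-presence universe, as their
real counterparts do. CSF samples mix a plasma profile (plasma-derived
class boosted +4 log2) into a clean-CSF profile (brain-flavoured; tumour
products scarce at −4 log2) proportionally to a contamination fraction;
heme is monotone in that fraction. The first two CSF samples form the
designated paired bloody/clean pair (fractions 0.8 and 0.005); the
remaining 26 span [0, 0.9] evenly.

Because tumour products are scarce in clean CSF, their blood carryover
inflates bloody/clean ratios: the bloodiness list's top decile is
plasma-dominated but includes trace tumour products — the same pattern
reported for the GAA-like compound (low in bloody CSF, undetected in
clean).

All randomness derives from a single seed through named substreams
(classes, baselines, patient effects, noise, missingness, CSF), so any
block regenerates in isolation.

**What the generator does not emulate:** chromatography artefacts,
adducts or compound-identification ambiguity; batch-specific
intensity drift beyond the per-batch median scale; correlated metabolite
modules (pathway structure); heavy-tailed single-metabolite outliers.
Passing recovery tests therefore show that the pipeline's inference is
correct under the assumed multiplicative model at study-scale effect
sizes, not that those effects are detectable in any real cohort.

## Problem sizes and numerical choices

The test suite and acceptance script use the 9-case/200-metabolite
cohort, 1000 permutations per enrichment, 20 generator seeds for recovery
rates, 10,000 replicates for the type-I error of the exact test, and 1000
random instances for the ES oracle bound — sizes chosen so the full
acceptance run completes in well under a minute per block on one CPU
while keeping Monte-Carlo error far below the margins asserted.
Tolerances: ES oracle agreement 1e-12; Ward heights 1e-8 (accumulated
Lance–Williams rounding); normalized-median invariant 1e-9. Degenerate
inputs are first-class: all-zero difference vectors (p = 1, flagged),
identical bloody/clean CSF pairs (degenerate list, warned), zero-variance
metabolites under autoscale (dropped, warned), empty universes (errors).

## Known limitations

- The exact signed-rank convolution is exact for midranks on the doubled
  integer scale; pathological non-half-integer rank patterns cannot occur.
- FDR by ratio-of-tails is the convention of the tool family this
  reimplements; it is not a Benjamini–Hochberg guarantee and can be
  conservative for small set families.
- Spearman maps are pairwise-complete; under strongly
  intensity-dependent missingness this can bias correlations upward for
  bright samples.
- The cohort-scale headline numbers of any real dataset (universe size,
  up/down counts, specific fold changes) depend on the supplied data
  files; the package reproduces them only when those inputs are provided.
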