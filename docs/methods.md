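# Methods

This note documents the statistical procedures `scapa` implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish.

## Input model

The pipeline consumes a gene × cell APA score matrix in one of two
dialects — `dapars` (ΔPDUI, the change in distal polyA-site usage, in
[−1, 1], shortening negative) or `roar` (a positive ratio-of-ratios,
shortening > 1) — a complete gene × cell TPM matrix, a per-cell annotation
(patient, cell type, optional tumor type), gene sets in GMT, a
term → parent-GO-term table, and a patient survival table. Gene identifiers
are opaque strings; any symbol/Entrez harmonisation belongs to input
preparation. APA matrices may be sparse: a missing entry means the gene's
3'UTR usage could not be estimated in that cell.

Both dialects are mapped onto one **shortening score** where larger means
shorter: `s = −ΔPDUI` for dapars and `s = log2(ratio)` for roar. This
orientation is a package decision — it makes "positive correlation between
shortening and expression" well defined regardless of the upstream
quantifier. Expression enters as log2(TPM + 1).

## ssGSEA scoring

Per cell, genes with observed values are ranked by decreasing score, ties
broken by ascending gene id for determinism. With N observed genes and a
set overlapping m of them, the enrichment score is the sum over all N
ranked positions of (P_in − P_out), where P_in accumulates
|rank score|^τ / Σ_in-set |rank score|^τ (rank score N…1 from the top) and
P_out accumulates 1/(N − m) on out-of-set genes. This is the running-sum
integral of single-sample GSEA, not the maximum-deviation statistic.

Choices:

* **τ = 0.25** by default, the exponent of the original single-sample
  formulation as shipped by the standard R implementation; exposed as a
  parameter. At τ = 0 the score depends on ranks only (verified by a
  property test) and is antisymmetric between a set and its complement.
* **Normalisation on** by default: all scores divided by the global
  max − min of the score matrix, for cross-cell comparability.
* **Missing data**: a cell's ranking universe is only its observed genes;
  sets with fewer than `min_overlap = 3` observed members (or covering the
  whole universe, which leaves no out-of-set step) get a missing score in
  that cell. ssGSEA needs a complete ranking, and per-cell universe
  shrinkage is the smallest assumption that provides one.
* Gene-level analyses bypass ssGSEA entirely: a gene's own oriented
  shortening and log-expression values serve as its scores.

The implementation is checked against an independent brute-force
double-loop oracle to 1e−9 on random instances.

## Filters and variable components

Cells are kept when at least 10 % of genes carry an APA estimate
(inclusive boundary); gene-level analyses additionally require a gene to be
estimated in at least 30 % of cells. Components are scored for variation
as the sample (n−1) standard deviation across cells, missing entries
excluded pairwise; the selection baseline is mean + 1 × s.d. of the
variation-level distribution, with strict exceedance required. The
multiplier is configurable because "the mean and s.d." admits other
combinations; 1 is the most literal reading. The variance selection feeds
clustering/ordination views; the signature statistic below is evaluated on
all components.

## The signature statistic

For each component and candidate cell type:

* **Median-split flags.** A cell is flagged when both its shortening and
  expression scores strictly exceed the component's medians, computed
  globally over cells with both scores observed (global medians put every
  type on a common scale against "the others"). Cells missing either score
  are excluded from the table entirely.
* **Odds ratio.** From the 2×2 table (in-type/out × flagged/unflagged):
  OR = AD/BC with the Haldane–Anscombe 0.5 correction only when some cell
  is zero; significance by a two-sided Fisher exact test on the
  uncorrected counts (minimum-likelihood convention, checked against exact
  rational enumeration to 1e−12).
* **Within-type correlation.** Pearson r between the two scores across the
  candidate type's cells; p from the Fisher Z-transformation (needs n ≥ 4
  and non-degenerate variance; |r| = 1 reports p = 0 with a warning). An
  all-cells correlation scope is available behind `pcc_scope="all"`.
* **Hit rule.** PCC > 0 with p < 0.05 AND OR > 2 with p < 0.01, strict
  inequalities, applied to every (component, type) pair with no
  multiplicity correction (the raw-cutoff design is kept; a
  Benjamini–Hochberg option exists but is off by default). A component may
  legitimately hit several types. Ineligible pairs (too few cells,
  degenerate variance) carry missing statistics and are never hits.

## Tumor-type contrasts

Restricted to cells annotated as tumor cells with a tumor-type label.
delta = mean(in-type) − mean(other tumor cells) on the gene-set shortening
enrichment; significance by a two-sided **Welch** t-test (chosen over the
pooled-variance Student t because tumor-type group sizes are typically
very unbalanced; pooled is available behind `equal_var=True`). The top-k
report ranks significant sets by delta toward shortening, ties by smaller
p then set id. Degenerate designs (a group of two identical values) yield
missing statistics rather than infinite ones.

## GO-parent network

Edges between hit gene sets require Jaccard similarity of their parent-term
sets strictly above 0.5; clusters are **connected components** of the
thresholded graph (no community algorithm is implied by a force-directed
display, so components are the minimal faithful construction), with
deterministic cluster ids (smallest member id) and retention only for
components holding strictly more than 9 sets. The parent table is used
as supplied — direct parents only, no ancestor closure.

## Survival

Follow-up is administratively censored at 10 years (a death after the
horizon counts as a survivor at 10 years), the horizon being configurable.
Patients are classed low (≤ 25th percentile) / high (≥ 75th) / excluded on
a gene's expression, percentiles by linear interpolation between order
statistics; the middle half never enters the two-group tests. Kaplan–Meier
and the two-group log-rank test are implemented in-house (they are the
package's validation surface) and cross-checked against lifelines in the
test suite; the multivariate Cox model delegates to lifelines
(partial likelihood, Efron ties) behind a thin contract that refuses
constant covariates and designs with more covariates than events, and
reports collinearity or non-convergence as an explicit fit failure.
Times are expected in years at the I/O boundary; any day/month conversion
is the caller's responsibility.

## Synthetic cohorts

The generator draws one latent per-entry ΔPDUI (truncated Gaussian in
[−1, 1], s.d. `noise_sd = 0.15`) and emits either dialect from it
(roar = 2^(−ΔPDUI)), so both file dialects share one ground truth. Log2
expression is a per-gene baseline (uniform 1–8) plus a per-patient random
intercept (s.d. 0.2) plus noise; TPM is the exponentiated matrix with
columns rescaled to 10^6.

For each cell type, `planted_sets_per_type` gene sets are planted: in
cells of that type their member genes shift by `−shortening_effect` on
ΔPDUI and `+expression_effect` on log2 expression, both multiplied by a
per-cell activity factor (truncated normal around 1, s.d. 0.3). The shared
activity factor is what couples shortening to over-expression *within* the
type — a constant shift would separate the type from the rest but leave
the within-type correlation at zero, which is not the phenomenon the
statistic targets. Planted sets draw members from a reserved gene pool per
type and background sets from the remaining genes, mirroring the largely
disjoint marker programs of distinct cell types; same-type planted sets
share an identical parent pool (Jaccard 1) so network clusters can form.
Default effects are 0.45, i.e. three noise standard deviations. APA
entries drop out independently at rate 0.3.

What the simulator does **not** model: read-level sampling noise,
expression-dependent APA estimability (dropout is independent of
expression), batch structure beyond the patient intercept, correlated
background gene sets, and DaPars/Roar estimation bias. Passing recovery
tests therefore demonstrate the statistics behave as designed under their
own assumptions, not that the upstream quantifiers are accurate on real
reads.

Survival simulation: exponential event times with hazard
λ0·exp(β·group), independent exponential censoring, administrative cutoff
at `max_followup`; defaults λ0 = 0.1/year, censoring 0.05/year, 15-year
follow-up.

## Validation sizes and numerical conventions

The test suite and `scripts/acceptance.py` validate at these problem
sizes, chosen to give stable binomial/recovery estimates at desk scale:
signature recovery on default cohorts (5 types × 40 cells, 2,000 genes,
300 sets, 3 planted sets/type) over 10 seeds in the suite and 5 in the
acceptance script; null calibration from 200 (suite) or 100 (script)
replicates per statistic; tumor top-10 recovery over 20 seeds; log-rank
power over 60–100 replicates at 200 patients/group. Oracle comparisons use
50 ssGSEA instances (20 genes × 5 cells) and 200 Fisher tables of total
≤ 40.

Numerical conventions collected in one place: sample (n−1) standard
deviations; strict inequalities at all cutoffs, medians and baselines;
ties in rankings broken by ascending identifier; detection thresholds
inclusive with a 1e−9 float guard at fraction × count boundaries; all
randomness through `numpy.random.Generator` streams spawned from a single
seed, one stream per simulated matrix.
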