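# Methods

## Scope and data model

`scnoise` analyses a genes × cells matrix of read counts from a
two-condition single-cell RNA-seq experiment, with per-cell condition
(e.g. WT / KD) and batch labels.  It is designed around deeply sequenced
full-length protocols (Fluidigm C1 + SMARTer class), where a typical
experiment captures tens of cells per condition per chip and detects on
the order of 10⁴ genes; nothing in the code assumes UMIs.

Processing order: cell filter on counts → TPM normalisation → gene
prevalence filter → per-condition noise statistics → low-expression filter
→ differential-variability calls → overlap/PCA/peak-proximity analyses.
Every filter appends a record (parameters, before/after dimensions) to an
append-only `filter_log` carried with the matrix.

## Quality control and normalisation

- **Cell filter**: a cell is kept when it detects (count > 0) at least
  `min_genes` genes, default 3000.  The threshold is a minimum, applied
  inclusively: exactly 3000 detected genes is kept.
- **TPM**: tpm[g,c] = 10⁶ · (counts[g,c]/len_g) / Σ_g′ (counts[g′,c]/len_g′).
  Gene lengths come from a user table; without one, all lengths are set
  to 1 (counts-per-million) and the fallback is recorded prominently in
  the filter log.  This is safe for everything downstream of normalisation
  here, because the per-gene statistics (mean, CV, η², fold changes) are
  ratios within a gene, where length cancels; only cross-gene comparisons
  of absolute expression would be affected.
- **Gene prevalence filter**: a gene is kept when log₂(TPM+1) is strictly
  above 1.0 in at least 2 cells.
- The log transform is log₂(TPM+1) everywhere.

## Expression noise and differential variability

Per gene and condition the package computes μ, σ² (n−1 denominator),
CV = σ/μ and the noise η² = σ²/μ².  η² is stored as the exact square of
the computed CV, so the identity η² = CV² holds bit-for-bit.  Genes with
μ = 0 in a condition have no defined CV; they are stored as missing and
excluded from classification with a logged count, never silently
propagated.

Statistics are computed on **linear TPM** by default.  σ/μ of
log-transformed values is not a coefficient of variation in the usual
sense; an `on_log` flag exists for sensitivity analyses.

For negative-binomial counts with Var = μ + φμ², the expected noise is
η² = 1/μ + φ.  The noise-versus-expression profile (equal-count bins of
pooled mean log₂(TPM+1) against mean η², with Spearman correlations split
at the cutoff) makes the two regimes visible: a slope of −1 on log-log
axes at low expression, a plateau near φ at high expression.  Because the
low regime is dominated by sampling noise rather than biology, genes with
pooled mean log₂(TPM+1) ≤ 1.0 (strict) are removed before variability
calls.  The pooled mean over all retained cells is used rather than
per-condition means so the same universe underlies both conditions; a
per-condition variant can be obtained by filtering the noise table
directly.

Differential variability uses ΔCV = CV_KD − CV_WT.  With m and s the
sample mean and n−1 standard deviation of ΔCV over the classified genes,
labels are: increased iff ΔCV > m + s, decreased iff ΔCV < m − s, both
strict, else unchanged.  The rule is deliberately simple — a global
mean ± SD gate, not a per-gene test — so by construction it labels the
tails of the empirical ΔCV distribution (≈ 15.9% per side if ΔCV were
normal).  A normality check (skewness, excess kurtosis,
D'Agostino–Pearson K²) is reported descriptively; in simulations ΔCV is
mildly leptokurtic (excess kurtosis ≈ 1.4) because genes differ in CV
sampling variance, which lowers the tail fractions to ≈ 14% per side.

## Differential expression

The package does not fit count GLMs.  Externally produced DE tables
(gene_id, logFC, p, optional q) can be imported and labelled at a chosen
BH FDR (default α = 0.05; q is recomputed only when absent).  For
self-contained runs a per-gene two-sided Wilcoxon rank-sum test on
log₂(TPM+1) is provided (normal approximation with midrank ties and
continuity correction; all-tied genes get p = 1), with
logFC = log₂((mean TPM_KD + 1)/(mean TPM_WT + 1)) and in-package
step-up Benjamini–Hochberg adjustment.  This is a robust nonparametric
stand-in chosen for ~24-cell groups, not a reimplementation of any count
model.

## Enrichment statistics

The overlap of two gene sets is assessed in a declared universe — by
default the genes passing the low-expression filter, i.e. the set on which
variability labels exist; set members outside the universe are dropped and
counted in the log.  The test is Pearson's χ² with 1 df, no Yates
correction by default (tables here are large; a flag enables it), reported
with the fold enrichment a·N/((a+b)(a+c)) and cross-checked by the
two-sided Fisher exact test.  χ² and Fisher p-values differ by a few
percent at realistic table sizes, so significance calls at a hard α can
flip for tables whose p sits within that sliver of the threshold; the test
suite asserts ≥ 99% concordance rather than identity.

Generic over-representation analysis is an upper-tail hypergeometric test
per term (GMT input supported) with BH adjustment across terms.  Wilcoxon
rank-sum comparisons use exact enumeration for combined samples of ≤ 12
values without ties, otherwise the tie-corrected normal approximation with
continuity correction.

## PCA and peak proximity

PCA runs on cells in log₂(TPM+1) space over all retained genes,
gene-centred and **not** unit-scaled by default (scaling is a flag);
centring-only preserves expression-magnitude structure and is the common
default for this data type.  Components carry a deterministic sign (the
largest-|loading| gene is positive) so runs are reproducible.  Condition
or batch separation along a component is a classical equal-variance
two-sample t-test (Welch by flag); gene-to-component association is
squared Pearson correlation with its t-distribution p.

Peak proximity counts ChIP-seq peaks (BED, 0-based half-open) overlapping
the closed window [TSS − w, TSS + w], default w = 20 kb; "any overlap" is
the default rule (a peak starting exactly at TSS + w counts), with a
midpoint-in-window alternative.  Counting uses per-chromosome sorted
binary search and is verified against a brute-force double loop.  One TSS
per gene is chosen from a GTF by the most-upstream (5′-most in
transcription direction) policy by default, or longest transcript;
chromosome-name dialects are reconciled by stripping a `chr` prefix.
Class comparisons are pairwise Wilcoxon tests among
increased/decreased/unchanged genes.

## Synthetic data

Counts are drawn per gene, condition and cell from a negative binomial
parameterised by (μ, φ) with Var = μ + φμ², giving CV² = 1/μ + φ (Poisson
when φ = 0).  Defaults emulate the target experiment class:

| parameter | default | rationale |
|---|---|---|
| n_genes | 10,000 | expressed genes surviving QC in deep full-length data |
| cells/condition/chip | 24 | one C1 chip row per condition per batch, 2 batches |
| baseline mean | log-normal(2.5, 1.3) counts | mean ≈ 28 counts/gene ≈ 2×10⁵ reads/cell over 10⁴ genes |
| dispersion φ₀ | 0.5 | biological CV ≈ 0.7 at high expression |
| fraction_de / mean_fold | 0.03 / 2 | ~300 DE genes, half up, half down |
| fraction_disp / disp_fold | 0.03 / 4 | ~300 dispersion-changed genes, half up, half down |
| coupling ρ | 0.8 | share of dispersion-increased genes drawn from the mean-decreased set |
| dropout, batch_scale | off / 1.0 | full-length C1 data is mildly zero-inflated; no batch effect by default |

fraction_disp equals fraction_de so that ρ·(dispersion-increased) ≤
(mean-decreased) stays feasible at ρ = 0.8; the config validator rejects
infeasible combinations.  Gene lengths are log-normal (median ≈ 1.8 kb).
Same seed ⇒ bit-identical output.

Synthetic annotation lays genes along one chromosome with non-overlapping
TSS windows (spacing auto-widened and logged if needed) and drops
Poisson(λ_high) peaks in the windows of variability-increased genes versus
Poisson(λ_low) elsewhere.

What the generator does **not** emulate: gene–gene correlation modules,
cell-cycle or cell-size covariates, amplification-length bias, realistic
zero inflation, or mapping artefacts.  Passing recovery tests therefore
demonstrates that the statistics do what they claim under the stated count
model, not that every conclusion transfers to arbitrary real data.

## Numerical and design notes

- Sample statistics use n−1 denominators throughout (group sizes ~24).
- TPM columns sum to 10⁶ within relative 10⁻⁹; all-zero cells normalise to
  zero with a warning rather than NaN.
- Classification thresholds are strict inequalities; a zero-spread ΔCV
  labels nothing.
- PCA uses the full SVD solver for determinism; explained-variance
  fractions are non-increasing and sum to ≤ 1.
- The pipeline aborts on the first failing stage, naming it and persisting
  the partial JSON report; report bookkeeping (labels partition the
  classified set, filter dimensions monotone) is asserted on every run.

## Known limitations

- **Expression-change and variability-change calls are not independent,
  even without generative coupling.**  Two mechanisms: (1) lowering an NB
  gene's mean mechanically raises its CV² through the 1/μ sampling term —
  in simulations, true mean-halved genes shift ΔCV by ≈ +0.35 SD of the
  null spread; (2) DE calls and ΔCV are estimated from the same cells, so
  conditioning on a significant "down" call selects genes whose KD sample
  happened to come out low, biasing CV_KD upward (a winner's-curse
  effect ≈ +1.6 SD for called genes in simulations).  Consequently the
  down-regulated × variation-increased overlap χ² rejects far above the
  nominal rate even at coupling ρ = 0 (~85–90% at α = 0.05 under the
  default generator), and a significant overlap on real data should not,
  on its own, be read as biological coupling.  The corresponding
  acceptance test asserts the idealised 5% rate and is expected to fail;
  it is kept as an executable record of this caveat.
- The mean ± SD classifier has no per-gene error control; its calls are
  relative to the experiment-wide ΔCV spread.
- The Wilcoxon DE stand-in is less powerful than count-model tests at
  these group sizes; imported DE tables are preferred for real analyses.
- Technical-noise decomposition with spike-ins is out of scope.
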