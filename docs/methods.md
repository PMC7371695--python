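# Methods

## Scope and data model

pol3kit analyzes per-locus and per-gene tag-count tables from three
spike-in normalized assays of pol III regulation: ChIP-seq at an annotated
catalog of pol III loci, matched ribosome-footprint/RNA-seq libraries, and
gene-level RNA-seq. Alignment, counting, and read-level QC happen upstream;
the package's contracts start at TSV count tables plus spike totals. A
locus catalog (BED6, optionally an annotation TSV mapping names to gene
class, tRNA isotype, and anticodon) defines the ChIP universe; coordinates
stay in BED convention (0-based, half-open), and strand is carried but not
used in scoring since counts arrive as per-locus totals.

## Spike-normalized occupancy scores

Each ChIP library (IP and its input) contains a fixed proportion of
exogenous chromatin; tags mapping to the spike genome give per-library
spike totals. The occupancy score at locus *i* is
`log2(((ip_i + a)/S_IP) / ((input_i + a)/S_input))` with pseudocount
`a = 0.5` (default; avoids log of zero at unoccupied loci while leaving
high scores essentially untouched). Two contracts define the scheme and
are enforced by tests: scaling a sample's entire count vector including its
spike total changes no score (sequencing-depth invariance), and doubling
only the IP spike total lowers every score by exactly 1 log2 unit — the
normalization really runs through the spike, so genome-wide occupancy
shifts between samples are measurable rather than normalized away.
Replicates are scored individually and averaged for display; the moderated
t operates on the replicate-level matrix.

## Occupied/not-occupied cut-off

Score distributions over pol III loci are strongly bimodal (active vs
silent loci). The cut-off is estimated by fitting a two-component Gaussian
mixture with EM: components are initialized deterministically from the
halves below/above the median with equal weights, iterated to a relative
log-likelihood tolerance of 1e-10 (max 500 iterations, error with
diagnostics on non-convergence), and the cut-off is placed where the
posterior probability of the upper component crosses 0.5 between the two
means (closed-form root of the weighted-density log-ratio; if extreme
weight imbalance prevents a crossing between the means, an sd-weighted
midpoint is used). A fixed threshold can be supplied instead
(`cutoff: fixed:<x>` in run configs). The mixture route was chosen because
the upstream literature's cut-off procedure is not fully specified and the
bimodality makes a mixture boundary reproducible and data-driven.
Quantile classes (default quintiles) are assigned from a caller-chosen
reference sample; ties at class boundaries all take the lower class, so
assignments are deterministic.

## Statistical core

**TMM scaling factors.** For sample *s* against a reference *r* (by
default the sample whose upper-quartile CPM is closest to the mean upper
quartile), per-feature `M = log2((y_s/N_s)/(y_r/N_r))` and
`A = 0.5·log2(y_s y_r/(N_s N_r))` are computed over features nonzero in
both samples; 30% of the M distribution and 5% of the A distribution are
trimmed from each tail by quantile rank; the factor is the weighted mean of
the surviving M values, `2^(Σ wM/Σ w)`. Weights are inverse delta-method
variances computed from the tag *fractions*, `w = 1/((1−p_s)/p_s +
(1−p_r)/p_r)`: unlike count-based asymptotic weights, these make each
factor an exact function of library composition, so multiplying one column
by a constant provably leaves every factor unchanged (a tested contract).
Factors are rescaled to unit geometric mean. Within the spike-anchored
ribo normalization the factors are instead anchored at the reference sample
(factor_ref = 1) so the reference's scores do not move when other samples
change.

**Moderated t.** Per feature, the pooled two-sample variance s² with d
residual df is shrunk toward a prior: `s_post² = (d₀s₀² + d s²)/(d₀+d)`,
`t = Δmean/(s_post √(1/n₁+1/n₂))`, p from a t distribution on `d₀+d` df.
When no prior is supplied it is estimated by method-of-moments on
`log s²` using digamma/trigamma identities for a scaled-F model, with the
prior df capped at 1e9 (numerically "infinite" shrinkage). Limits are
tested: d₀=0 reproduces the ordinary equal-variance t; d₀→∞ uses the prior
variance alone. Significance thresholds on BH-adjusted p-values use strict
`<` by default (configurable), matching the reporting convention of the
occupancy and RNA-seq analyses; the TE analysis flags both adj-p ≤ 0.05
and ≤ 0.1. Mean–variance precision weighting (voom) and unwanted-variation
factors (RUV) are deliberately not implemented; the moderated t operates
directly on log-scale scores. On real data this omission can leave
heteroscedasticity unmodeled, which is one reason dataset-level result
counts are not desk-reproducible.

**KS test.** D is the sup over all pooled distinct values of the
difference of empirical CDFs (deterministic under ties); the p-value is the
classic Kolmogorov limit law evaluated at `√(nm/(n+m))·D`, appropriate at
the thousands-of-genes scale where it is used.

**Hypergeometric overlap.** Expected overlap `n₁n₂/N`; depletion and
enrichment tails both include the observed point mass (so they sum to ≥ 1).

## Spike-anchored translation efficiency

Tags mapping to both genomes, to neither, or to rRNA/scRNA features are
dropped (counts of each reported). Per library type (RF and RNA
separately — the estimator is computed per type because footprint and RNA
libraries have unrelated efficiencies): `NTC = log2(count + 0.5) −
log2(total · TMM)`, then each sample receives the correction
`median over spike transcripts of (NTC_reference − NTC_sample)`. Pairing
per transcript before taking the median matters: spike panels are
heterogeneous in abundance, and the median of raw spike NTCs effectively
rides on the handful of transcripts nearest the panel's middle (per-sample
wobble ~0.02 log2 on a 200-transcript panel), whereas paired differencing
removes the abundance centers so the median pools the whole panel. After
correction the median per-transcript spike difference to the reference is
exactly zero, any per-sample scalar (depth, TMM, library efficiency)
cancels, and a genome-wide change in the mouse fraction of one sample
shifts that sample's mouse NTCs by exactly its log2 magnitude. With the
default pseudocount
this exactness is attenuated at very low counts
(`log2(c·k + a) ≠ log2 c + log2(k + a)`); property tests therefore assert
the exact form at pseudocount 0 on positive counts and the default form
approximately. Transcript scores are averaged per gene (isoforms differ by
TSS, splicing, polyA site), `TE = RF-NTC − RNA-NTC`, and the global shift
between groups is the mean over genes of the difference of group-mean TE,
reported also as `(2^shift − 1)·100` percent, alongside a KS comparison of
the per-gene TE distributions. Negative-binomial GLM alternatives for
differential TE (Xtail-style) are out of scope; the moderated t on TE
scores is the implemented test.

## RNA-seq differential expression

Genes pass the expression filter with CPM ≥ 1 in at least `min(group
size)` samples (both configurable); this reproduces a 10–14k expressed
universe at realistic depths. TMM-scaled log2-CPM scores feed the moderated
t; genes are *selected* only when adj-p < 0.01 **and** |log2FC| > 0.5. The
fold-change threshold is a parameter because the source convention
("fold change > log2 |0.5|") is ambiguous between 0.5 log2 units
(linear ≈ 1.41) and a linear factor near 1.7; 0.5 log2 units is the
default. The reverse cumulative frequency `F̄(x) = fraction of genes with
expression ≥ x` is computed per group on a shared grid with a KS test
against the first (reference) group, to check that selected genes shift
independently of expression level.

## Enrichment and cross-study comparison

GSEA running score: hits increment by `|stat|^w / Σ_hits |stat|^w`
(default w = 1; w = 0 gives the unweighted form), misses decrement by
`1/(N−|S|)`; ES is the signed maximum deviation, with an optional seeded
gene-label permutation p-value. RRHO: for rank thresholds on a grid
(default step ⌈N/100⌉) the overlap of top-i and top-j is scored by the
hypergeometric enrichment tail, mapped as −log10 p with the maximum and its
coordinates reported; lists are ranked by fold change or sign-adjusted p,
ties broken by gene ID. A Bonferroni-style bound over grid cells is the
reporting threshold used in calibration tests. Fixed-threshold set overlap
delegates to the hypergeometric machinery; for two DE sets of 937 and 958
genes in a 12,056-gene universe the expected chance overlap is ≈ 74.5.

## Synthetic data

The generators are pure functions of (parameters, seed); per-sample random
streams are split from the seed so adding replicates never changes earlier
samples. Counts are negative-binomial via gamma–Poisson.

- **ChIP** (defaults): 500 loci, occupied fraction 0.6, occupied/unoccupied
  score modes +4/−2 (sd 1), 2 replicates per genotype, spike fraction
  0.025 of a 1e6-tag library, per-replicate biological noise N(0, 0.3) on
  log2 enrichment, count dispersion 0.01 (near-Poisson: replicate-level
  biology is the explicit noise term; pooled-library counting adds little
  overdispersion). Input counts follow per-locus baseline weights.
- **Ribo** (defaults): 5000 genes (~20% with two isoforms), 3 samples per
  genotype, 200-transcript spike panel at a 1/15 material ratio, depth 5e6
  tags (a desk-scale stand-in for much deeper real libraries; low depths
  would inflate pseudocount attenuation of the global-shift estimate),
  mouse count dispersion 0.1, spike counts Poisson (one shared extract —
  its between-sample variation is counting noise), global TE factor 0.87
  on knockout footprints (the study-scale ~13% reduction).
- **RNA-seq** (defaults): 12,000 genes, 7 vs 5 samples, 7.8% of genes
  shifted by 1 log2 unit with 89% downward bias, dispersion 0.05, depth
  1e7.

What the generators do **not** model: mappability and GC effects, isoform
switching, count correlation between RF and RNA libraries from shared
mRNA sampling, batch structure/unwanted variation, and the upstream
two-pass alignment's effect on counts. Passing recovery tests therefore
demonstrates estimator correctness under the declared statistical model,
not robustness to those real-data artifacts; dataset-level published
counts (e.g. exact numbers of significant genes) additionally depend on
the real data and the omitted RUV step and are reference points, not
targets.

## Numerical and design choices

- Pseudocount 0.5 on all log2 counts (sparse footprint data).
- EM tolerance 1e-10 relative log-likelihood; component sd floor 1e-3.
- Quantile-class and ranking ties break deterministically (lower class /
  lexicographic gene ID).
- Cross-condition classes extend the significance × direction table with a
  `concordant` class (significant in both contrasts, same sign) so the
  classification is exhaustive.
- "Score ratios" between genotypes are differences of log2 scores
  (scores are already log-scale); negative differences are retained in
  full tables but excluded from positive-set exports.
- The hypergeometric-expectation universe for cross-study overlap defaults
  to the expressed-gene universe (12,056-scale); a shared-gene universe is
  an alternative the caller can pass explicitly.
- Pipeline configs are YAML with one block per stage; unknown keys fail
  validation with a closest-match suggestion, and manifests record config
  hash, package version, SHA-256 of every output, and per-stage wall time.
- Problem sizes in tests and the acceptance script (500 loci, 2000–12,000
  genes, 50 null replicates) are desk-scale choices that keep the full
  suite in seconds while leaving Monte-Carlo error well inside the asserted
  tolerances.

## Known limitations

No BAM/FASTQ ingestion (count tables only); no voom/RUV; no
negative-binomial differential TE; KS p-values are asymptotic (fine for
thousands of genes, conservative for tiny samples); the mixture cut-off
assumes two Gaussian-ish modes and will reject unimodal score
distributions; GSEA permutation p-values use gene-label permutation, not
sample permutation.
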