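# Methods

## The analysis model

`coldatlas` analyses a gene × sample matrix of RNA-seq read counts from a
factorial design: organs × {control, cold 3 h, cold 27 h} × replicates. The
statistical units are *contrasts* — one organ's cold-vs-control comparison at
one duration — and the package's summaries are built on the per-contrast DE
calls.

### Normalization

Library size is estimated by median-of-ratios: for sample *j*,
s_j = median over genes of count[g,j] / geometric-mean_g, using only genes
with nonzero counts in every sample, then rescaled so the size factors have
geometric mean 1 (so "normalized counts" stay on the raw-count scale).
Expression values for QC, clustering and entropy use RPKM,
count · 10⁹ / (length_bp · total assigned reads of the sample); the
per-million denominator is the column sum of the count matrix, since
original mapped-read totals are not recoverable from a count matrix alone.

### The NB Wald test

Counts are modelled as negative binomial with Var = μ + αμ² (dispersion α).
For a contrast with groups A (control) and B (cold):

1. Gene-wise α is estimated by method of moments on normalized counts,
   pooling the within-group sums of squares of both groups
   (residual df = n_A + n_B − 2) and flooring at α_min = 10⁻⁸.
2. Gene-wise estimates on 2–3 replicates are extremely noisy, so they are
   moderated: each α is shrunk toward the dataset-wide median dispersion of
   reasonably expressed genes (pooled normalized mean > 20) with a prior
   weight of 10 residual df, a lightweight analogue of the empirical-Bayes
   moderation used throughout the RNA-seq literature. Without moderation
   the Wald test is either anti-conservative (normal reference, ~10%
   rejection under the null at nominal 5%) or powerless (t reference on 4 df).
3. log2FC = log₂(mean_B + 0.5) − log₂(mean_A + 0.5) on normalized group
   means; the 0.5 pseudocount stabilises fold changes at zero counts.
4. The standard error comes from the delta method:
   SE² = [(μ_A + αμ_A²)/n_A/(μ_A+0.5)² + (μ_B + αμ_B²)/n_B/(μ_B+0.5)²] / ln²2.
5. Two-sided p-values use a t reference with df = (n_A + n_B − 2) + 10
   (residual plus prior df). Measured on null simulations at 3+3
   replicates the raw-p rejection rate at 0.05 is ≈ 0.04–0.06; a plain
   normal reference gives ≈ 0.10.
6. q-values are Benjamini–Hochberg over the tested genes. Genes with zero
   counts across the whole contrast are excluded from testing and from the
   BH family.
7. Status: up if q ≤ fdr_max and log2FC ≥ log₂(min_fold_change); down
   symmetric; ns otherwise. Ties at the FDR threshold count as significant.
   Defaults fdr_max = 0.05, min_fold_change = 2 — the thresholds of the
   study design this package follows. Fold-change filtering is applied to
   raw (unshrunken) fold changes.

This is a deliberately simple, fully documented test — not a DESeq2 clone:
there is no dispersion trend fitting, no fold-change shrinkage, no outlier
(Cook's) filtering, no covariates. On data that match its assumptions it is
well calibrated and powerful (see the acceptance suite); on real data with
batch structure or outlier replicates a full GLM framework will be more
robust.

### Cross-organ classes

Over a *scope* of contrasts (e.g. all six organs at 3 h, or all twelve
contrasts), a gene DE in at least one contrast is classified **Down** (down
somewhere, up nowhere), **Up** (symmetric) or **Mix** (both directions).
The classes partition the DE-anywhere set by construction. Commonality
tables count genes DE in exactly *k* contrasts of the scope — for Down/Up
genes, contrasts with that direction; for Mix genes, contrasts DE in either
direction. The scope is an explicit argument because both per-timepoint and
pooled analyses are meaningful. The down/up ratio of a contrast is reported
rounded half-up at two decimals, with a one-decimal variant for comparison
against one-decimal reports.

Direction concordance against a signed reference list (e.g. a regulon with
known induction directions) compares only reference genes actually called
DE; the match percentage is undefined (None) when nothing is comparable.

### Expression specificity

Shannon entropy H = −Σ pᵢ log₂ pᵢ with pᵢ = xᵢ/Σx is computed on
replicate-averaged RPKM per sample group, without pseudocount; a gene with
zero total expression has no pattern and is reported as NaN rather than 0.
H is invariant to rescaling, 0 for a single-group pattern and log₂N for a
uniform one. The histogram bin width defaults to 0.3, making the first bin
the "organ-specific" stratum. Note the stratum is resolution-dependent: on
an organ-level map (one group per organ) an organ-specific gene has H ≈ 0,
whereas with each organ split into three condition groups the same gene
sits near log₂3 ≈ 1.58. Atlas-style low-entropy analyses therefore use
organ-level groups.

The DE Score runs the same NB Wald test (same thresholds, for internal
consistency) over all C(S,2) unordered pairs of sample groups and counts
the significant pairs per gene; with 79 groups the maximum is 3081. Every
group needs ≥ 2 replicates.

### Gene-set enrichment

Each gene set is reduced to a 2×2 table (target vs non-target) × (DE vs
non-DE) over a declared universe — by default the genes actually tested for
DE, the standard enrichment practice. The p-value is the right tail of the
hypergeometric distribution (Fisher exact, one-sided), the headline score
log₂(%target(DE)/%target(non-DE)) with ±∞ sentinels flagged at empty cells,
and fold enrichment (a/(a+b))/((a+c)/N) is reported for category-style
thresholds (q ≤ 0.05 and fold ≥ 2). BH runs over exactly the tested sets;
sets with fewer than 2 genes in the universe are skipped and excluded from
the family. This is plain Fisher, not the EASE-adjusted (a−1) variant some
annotation servers use.

### QC and clustering

Replicate quality is the mean squared Pearson correlation over within-group
sample pairs on log₂(RPKM+1); constant columns yield undefined correlations,
flagged as NaN and excluded from the mean. Samples are clustered
agglomeratively with average linkage on distance 1 − r; merge heights are
non-decreasing and the tree is emitted as Newick with branch lengths equal
to merge-height increments. Distance and linkage are parameters of record:
the upstream description names only generic hierarchical clustering, so
these defaults are explicit package choices.

## The synthetic-data generator

The generator emulates the study's count structure, not its reads: no
FASTQ, alignment or positional coverage. Defaults:

| parameter | default | meaning |
|---|---|---|
| organs | 6 labels | cotyledons, hypocotyl, leaf, flower, young_flower, seeds |
| timepoints_h | 3, 27 | cold durations |
| n_replicates | 3 | per (organ, condition); 2 supported |
| baseline_log_mean / sd | 4.0 / 1.5 | ln-scale log-normal control expression (median ≈ 55 counts) |
| dispersion | 0.05 | NB α, Var = μ + αμ² |
| frac_de_per_contrast | 0.1 | genes with a true effect per contrast |
| effect_log2fc_range | [1.5, 4] | true \|log2FC\| of DE genes (≥1 so effects clear 2-fold) |
| frac_sign_flip | 0.05 | DE genes forced to opposite directions in two organs |
| frac_organ_specific | 0.1 | genes expressed in exactly one organ |
| size_factor_range | [0.5, 2] | per-sample library-size factors, log-uniform |
| n_tf_sets / n_active_tfs | 219 / 20 | regulons; active ones oversample DE genes 4× |

Organ baselines share a two-block structure (photosynthetic:
cotyledons/hypocotyl/leaf vs reproductive: flower/young_flower/seeds) via a
per-gene class effect (sd 0.8 in log space) plus per-organ jitter (sd 0.2),
which is what makes the clustering stage's organ grouping testable. The
real study used 2 replicates; the default here is 3 so that the simplified
DE test has usable power for parameter-recovery checks, with 2 fully
supported. All randomness flows from one integer seed through a single
`numpy.random.Generator`, so outputs are bitwise reproducible.

What the simulator does **not** model: batch effects, GC/length biases,
correlated genes (co-regulation beyond the planted regulon memberships),
outlier replicates, isoform structure, circadian variation. Passing the
recovery suites therefore shows the pipeline is correct and calibrated
under its stated assumptions — not that it is robust to every artefact of
real libraries.

## Numerical choices and degenerate inputs

* Dispersion floor α_min = 10⁻⁸; constant-replicate genes get the floor.
* All-zero genes in a contrast: untested, NaN p/q, status ns, excluded from
  the BH family.
* Size factors require ≥1 gene nonzero in every sample; otherwise the error
  advises filtering.
* BH on an empty vector returns an empty vector; p outside [0,1] is a
  ValueError.
* Entropy underflow (a positive fraction rounding to 0) is guarded before
  the log.
* Clustering ties resolve deterministically to the lowest-index pair
  (scipy's ordering); reruns are byte-identical.
* Ratio and percentage rounding is decimal half-up, not banker's.

## Problem sizes in the validation suites

The test and acceptance suites run entirely on generated data at desk
scale: 5 000 genes × 3+3 replicates for DE recovery, 2 000 genes for null
calibration, 10 × 1 500 genes for regulon recovery, an 8-group map of 300
genes for the DE-Score oracle, and 4 000 genes for the entropy-histogram
shapes. Published organ-level DE counts enter only as arithmetic inputs to
the summary functions; the original 79-sample atlas and raw sequencing data
are not required anywhere.

## Known limitations

* The DE test assumes independent NB counts with a common dispersion per
  gene across the two groups; severe outliers or batch structure are not
  handled.
* The enrichment universe default (tested genes) matters: switching to a
  whole-genome universe changes %target(non-DE) and every p-value.
* RPKM's per-million denominator uses assigned gene reads, which differs
  from mapped-read totals when many reads fall outside annotated genes.
* DE Score is threshold-dependent; scores from maps computed with other
  tests/thresholds are not directly comparable.
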