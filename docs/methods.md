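# Methods

## Data model

Probes are keyed by id and annotated with chromosome (1–22, X, Y), a 1-based
point coordinate, Infinium design type (I/II), colour channel (Grn/Red for
type I, Both for type II), associated gene symbols, one gene-feature category
and one CpG-island-relation category, plus a SNP flag. Gene association is
symbol-level: Infinium annotation is per transcript and multi-valued, so
transcript duplicates collapse to unique symbols and a multi-gene probe
counts once toward each of its symbols. Coordinates are never converted to
0-based. Sample metadata carries pair id, lesion role (Early/Late/Normal),
WHO grade, IDH1/IDH2 genotype and cohort; validation enforces one Early and
one Late lesion per pair and non-decreasing grade within a pair.

## Preprocessing

Type I probes read both bead types on one colour channel, and the two dyes
differ in brightness, so raw Red-channel intensities are biased relative to
Grn. Per array, the pooled type I Red intensities (M and U) are mapped onto
the Grn quantile function through a monotone PCHIP interpolation of the
empirical quantile map evaluated on 1000 probability anchors
(`smooth_grid_points`). A smoothed map is used rather than the exact
order-statistic map so the correction generalizes across the two channels'
different probe sets; monotonicity guarantees rank preservation within the
Red channel. Grn is the reference (left unchanged) because mapping the
biased channel onto the unbiased one is the usual convention for dye-bias
correction; type II probes have a single effective channel and bypass this
step. The exact smoothing kernel of array-processing toolchains varies by
implementation and version, so numeric reproduction of any particular
processed dataset is not promised — the contract is distributional
(corrected Red matches Grn quantiles within the smoothing tolerance).

Between-array quantile normalization replaces each column's sorted values
with the column-wise mean of order statistics (ties averaged). It is applied
to the stacked (M over U) intensity matrix so each array is normalized as a
single intensity vector and the M/U pairing within an array is preserved.
β = M / (M + U + α) with α = 100 by default (the standard Infinium offset;
configurable, and α = 0 with M = U = 0 is defined as β = 0 with a warning).
When a precomputed β matrix is supplied, normalization is skipped with a
notice.

## Hypermethylation calling

Boundary semantics are fixed exactly: a probe is removed when detection
*p* > 0.01 in **any** sample of the run (tumours and normals alike), when it
lies on X or Y, or when β ≥ 0.25 in **any** normal; a surviving probe is
called in a grade group when β ≥ 0.5 in strictly more than 30% of that
group's tumours (exact rational comparison, normals never in the
denominator); a gene is kept when ≥ 3 of its annotated probes are called.
Grade groups pool early and late lesions by WHO grade. The exclusion log
records each removed probe's first failing stage, so removed plus surviving
probes always partition the input. The three pure probe filters commute; the
cascade order only determines provenance attribution. SNP-flagged probes are
retained by default and excludable via config. Normal-based exclusion uses
the normalized β by default (the alternative is exposed as a flag, since
either choice is defensible).

Cross-grade analysis intersects the gene-associated called probes of all
grades and re-applies the ≥3-probe gene filter; the Venn partition counts
called probes restricted to each grade's ≥3-probe genes, so the regions sum
to the union of those sets. Cohort comparisons (e.g. secondary vs primary
GBM) use the same cascade per cohort and an exact three-way symbol partition
of the resulting gene lists; following the unadjusted-data convention for
cross-cohort work, that mode runs on β computed without the type I/II
correction.

## CIMP classification

The 2000 loci with the greatest across-sample SD (n−1 denominator, ties
broken by probe id) feed agglomerative clustering of samples on Euclidean
distance. Average linkage is the default — the common choice for methylation
heatmaps and stable on this data shape — with single/complete/Ward
available. The tree's top split defines the two major clusters; each major
cluster is cut again at its own top split into two sub-clusters (singletons
permitted with a warning; fewer than 4 samples gives a major cut only).
Major clusters are numbered so cluster 1 has the lower mean β, and the
higher-mean cluster is labelled CIMP+. Cluster means are unweighted means
over all (probe, sample) cells restricted to the selected loci. The
between-cluster ANOVA runs on per-sample mean β (one observation per sample)
to avoid pseudo-replication from treating probes as replicates; a per-cell
mode is available. Zero within-group variance with differing means is
reported as p = 0 with a degeneracy flag rather than NaN.

Retention: a pair retains CIMP when both lesions carry the same label;
additionally a pair is flagged "profile-similar" when its early–late
Euclidean distance over the selected loci falls below the 0.25 quantile of
all inter-sample distances (a descriptive flag; the quantile is
configurable).

## Genomic context

Context tables count a probe set over the seven gene-feature categories and
the six island-relation categories, against the analyzed-array background:
probes associated with a gene, autosomal, and not SNP-flagged. Each probe
carries a single pre-collapsed feature annotation (multi-valued manifest
rows collapse by promoter-first priority: TSS200 > TSS1500 > 5'UTR >
1stExon > Body > 3'UTR). Enrichment is the simple ratio of set fraction to
background fraction, undefined (flagged None) for empty background
categories. A chi-square goodness-of-fit against the background is available
but not default, since the primary readout is descriptive fractions.

## Clone sequencing

The methylation index is 100 × methylated CpGs / CpGs observed across all
clones of an amplicon (at most 12 clones per the cloning protocol).
Ambiguous calls are missing values and excluded from numerator and
denominator — "CpGs sequenced" means observed cells — which makes MI of a
concatenation the cell-weighted mean of the parts. Concordance with array β
reuses the pipeline's own thresholds (0.5 call bound, 0.25 normal-exclusion
bound): agree when β > 0.5 ∧ MI > 50% or β < 0.25 ∧ MI < 25%, otherwise
indeterminate.

## Synthetic cohorts

The generator emulates the study design rather than a generic array: 4
normals and 20 pairs with the 5×II→III / 5×II→IV / 10×III→IV transition mix
(grade groups 10/15/15), 14 of 20 pairs IDH1-mutant. Mutant pairs carry the
CIMP shift (`cimp_delta` = 0.4) at 5% of loci in the early lesion; 4 mutant
pairs (configurable) lose it on progression, so 24 of 44 samples are CIMP+
and the expected retention is 16/20. CIMP loci are drawn 80% from island and
20% from shore probes (autosomal, SNP-free, outside planted genes),
reflecting island-centred methylator phenotypes. Each grade receives 50
planted hypermethylated genes (β mean 0.8 at 3 probes per gene in that
grade's tumours), and 30 further genes are planted in **all** tumours to
emulate methylation conserved through progression, which is what the
conserved-list derivation is for. Everything else sits at β mean 0.1.

Numeric choices, fixed once from field realism: β noise is
Beta(mean·ν, (1−mean)·ν) with concentration ν = 80, giving within-group SDs
of ~0.03–0.06 as seen between array replicates, and keeping values in (0, 1)
without clipping; detection failures are i.i.d. per cell at 10⁻⁴ so the
"any sample" removal is exercised (~0.4% of probes) without dominating gene
recovery; the default array is 40,000 probes / 4,000 genes of 3–9 probes —
large enough that 5% CIMP loci outweigh the planted grade structure in the
top-2000 selection, as island-wide CIMP does on the real array, while
keeping a full pipeline run to seconds. The manifest's island/open-sea mix
(35.6% / 31.4%) matches the analyzed-array background composition.

What the generator does **not** model: batch effects, copy-number
contamination, probe cross-hybridization, spatially correlated noise, and
raw IDAT-level artifacts. Passing recovery tests therefore demonstrate the
pipeline's correctness and calibration under the assumed noise model, not
robustness to those real-data pathologies.

Recovery scoring: sensitivity is recall of the genes planted for a grade
(including the conserved set); specificity is computed over genes with no
planted signal of any kind — a gene that received planted CIMP methylation
and gets called is a true detection, not a false positive.

## Determinism and problem sizes

A single integer seed determines every cohort byte-for-byte. All list
outputs are sorted and tie-breaks use ascending probe/sample ids, so reruns
produce identical files (checksummed in the run report). The test suite and
the acceptance script use the default 40k-probe cohort (seconds per run) and
scaled-down cohorts for structural tests, chosen so the whole suite runs in
well under a minute of simulation time per module.

## Known limitations

- The colour-bias step corrects distributions, not probe-level chemistry;
  type I/type II β-distribution differences beyond quantile location are out
  of scope (no BMIQ-style within-type correction).
- The conserved-list and Venn logic assume the three grade groups share one
  normal panel; per-grade normal panels are not supported.
- Retention's profile-similarity flag depends on the chosen distance
  quantile and is reported descriptively, never tested against a null.
- File inputs must fit in memory as dense matrices; no chunked I/O.
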