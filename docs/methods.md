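# Methods

## Overview

`crosstrait` implements a comorbidity-genetics workflow that asks whether
two disorders — the motivating case is Alzheimer's disease and depression —
share more regulatory biology than chance predicts. The workflow has five
stages:

1. **Locus selection.** GWAS-catalog association rows are filtered to the
   exact trait labels of each disorder (case-insensitive, whitespace
   collapsed) and to suggestive significance, p < 5×10⁻⁵ strictly.
   Duplicate SNP reports across studies collapse to one entry keeping the
   minimum p and the union of proximity-mapped gene symbols.
2. **eQTL mapping.** The SNP sets are joined to a brain eQTL summary table;
   pairs with FDR < 0.05 (strict, FDR consumed as provided) are kept,
   classified cis (same chromosome, |SNP − TSS| < 1 Mb), trans (different
   chromosome, or > 5 Mb on the same one) or ambiguous (the 1–5 Mb gap,
   which neither definition covers), and collapsed to unique gene sets on
   version-stripped stable gene ids. A `found_in_proximity` flag marks
   genes already proximity-mapped in the catalog, i.e. not novel.
3. **Overlap null.** The overlap of the two gene sets is summarised by the
   sum-normalised statistic J = |A∩B| / (|A| + |B|), whose maximum is 0.5
   for identical sets (it is not the classical Jaccard |A∩B|/|A∪B|, which
   is provided separately). Draw sizes default to the unique-gene counts
   but may follow the SNP–gene *pair* counts ("pairs" convention, the
   pipeline default), in which the denominator is the summed pair counts
   while the numerator stays the unique-gene overlap. The null resamples
   `reps_a` and `reps_b` (default 1000 each) uniform without-replacement
   gene sets from an explicit universe — all genes with any eQTL effect —
   and evaluates J for every pairwise combination (10⁶ comparisons by
   default, computed as one membership-matrix product and stored as
   integer overlap counts). The empirical exceedance is the raw fraction
   of null values *strictly* greater than the observed J, with no
   (n+1)-style smoothing. Under this null the overlap count is
   hypergeometric, giving the closed form E[J] = (n_a·n_b/N)/(n_a+n_b)
   used as a validation oracle; the Monte-Carlo standard error of the grid
   mean is estimated from the variances of row and column means, the
   replicate-level projections of the two-sample U-statistic.
4. **Co-expression expansion.** Each disorder's eQTL genes (seeds) are
   correlated against every gene in a hippocampal expression matrix
   (Pearson by default, Spearman optional); two-sided p-values come from
   the exact transform t = r·√((n−2)/(1−r²)) on n−2 df. Partners passing a
   Bonferroni gate — family m = the number of (seed, partner) tests
   actually performed, adjusted p < 0.05 strictly — join the network;
   self-edges are excluded and seed–seed pairs are tested once. Modules
   are connected components of the retained-edge graph (deterministic;
   greedy modularity refinement available), ordered by size then smallest
   member id.
5. **Enrichment clustering.** Both expanded gene lists are tested against a
   GMT collection with the hypergeometric upper tail P(X ≥ k); the
   background defaults to all genes appearing in the collection (a
   supplied list, e.g. all expressed genes, overrides it). A term is
   significant under the express convention p < 0.01, k ≥ 3, enrichment
   factor k/(n·K/N) ≥ 1.5; BH q-values are emitted alongside for
   transparency but do not gate. Significant terms are linked when their
   Cohen's-kappa membership agreement — computed over a reference set
   defaulting to the union of the significant terms' members — exceeds
   0.3; clusters are the single-linkage transitive closure, named by the
   minimum-p member (ties broken by term id), and flagged *shared* when
   they contain at least one significant term for each disorder.
   Per-cluster per-disorder gene counts and their overlap are reported for
   pie-chart-style visualisation, and the term similarity graph is
   exported as GraphML for Cytoscape.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `p_threshold` | 5×10⁻⁵ | suggestive GWAS association cut (strict <) |
| `fdr_threshold` | 0.05 | eQTL significance cut (strict <) |
| cis / trans bounds | 1 Mb / 5 Mb | SNP–TSS distance windows (fixed) |
| `overlap_reps_a/b` | 1000 / 1000 | null replicates per disorder (10⁶ comparisons) |
| `overlap_size_convention` | pairs | denominator of J: pair counts vs unique genes |
| `coexpression_alpha` | 0.05 | Bonferroni family-wise level |
| `enrichment_p_threshold` / `min_overlap` / `min_factor` | 0.01 / 3 / 1.5 | term significance gates |
| `similarity_threshold` | 0.3 | kappa linkage cut for term clustering |

All thresholds surface as named fields of `PipelineConfig` (YAML/JSON).

## Numerical choices

- Strict inequalities throughout (p <, FDR <, adjusted p <, kappa >), so
  boundary values are excluded everywhere, consistently.
- Exceedance compares null and observed J after identical division, so an
  observed value lying exactly on a grid point ties rather than being
  counted as exceeded through rounding.
- Distance gene anchor is the TSS; distance = |SNP pos − TSS|. Pairs with
  missing coordinates classify as ambiguous with a warning.
- Gene identity is the version-stripped stable id, so set overlap is
  insensitive to annotation-version suffixes.
- The master seed spawns a fixed-label substream per consumer (two for the
  null grid, one per synthetic generator), so changing one replicate count
  or adding a generator never perturbs other draws. All partitions and
  written tables are sorted, making reports byte-identical across reruns.
- Degenerate inputs: empty gene sets, empty queries/backgrounds and empty
  networks raise domain errors; constant-expression genes and seeds absent
  from the matrix are skipped with warnings; kappa with degenerate
  marginals (chance agreement 1) is defined as 1 for identical memberships
  and 0 otherwise.

## The synthetic-data generator

The generator emulates the four inputs with known planted structure so
every stage has an exact recovery target:

- **Association table** — per trait, `n_snps_per_trait` rows with exactly
  `round(frac_significant · n)` p-values below 5×10⁻⁵ (significant rows
  log-uniform on [10⁻³⁰, 5×10⁻⁵), the rest log-uniform on [5×10⁻⁵, 1]),
  plus a decoy trait and duplicate re-reports of a few significant SNPs
  under a second study accession. Duplicates carry non-significant p, so
  the per-trait sub-threshold row count stays exact while still
  exercising the unique-SNP collapse.
- **eQTL table** — planted significant pair sets of 101 and 487 pairs
  collapsing to 70 and 278 unique genes with exactly 6 genes shared (the
  default study-scale configuration), on one synthetic genome of 22
  autosomes. Genes receive coordinates first; cis SNPs are placed within
  1 Mb of their gene's TSS, trans SNPs on another chromosome, so the
  intended label is exactly recoverable. Noise rows are either
  non-significant (FDR ≥ 0.05) on real SNPs or significant on decoy SNPs
  absent from every disorder set, so neither survives both gates.
- **Universe** — 17,000 genes by default, the scale of genome-wide
  brain eQTL resources. At this size the closed form gives an expected
  null J of 0.0049 for 101- and 487-gene draws, and six shared genes sit
  at the ~2.6% exceedance point of the hypergeometric null — a realistic
  regime in which a genuine shared signal is detectable but not trivial.
- **Expression matrix** — 192 samples by default. Each planted module is
  one shared latent factor: gene = √ρ·f + √(1−ρ)·ε, giving exact pairwise
  population correlation ρ; background genes and non-module seeds are
  independent standard normals. Module anchors are taken by interleaving
  the two disorders' gene lists, so both disorders' screens have planted
  modules to recover.
- **Annotations** — terms draw members uniformly from a universe of
  expression genes, expanded disease lists, and 4,000 background genes
  (wide enough that a disease list stays a small background fraction, as
  with genome-scale collections). Planted enriched terms draw 80% of
  their members evenly from the two disease lists and take sizes from the
  top third of `term_size_range`: a small term with a handful of planted
  genes is not reliably above chance for a ~300-gene query, so planting
  small terms would not constitute an enrichment plant at all.

What the generator does **not** emulate: linkage disequilibrium, allele
frequencies, genotype-level effects, expression normalisation artefacts,
correlated annotation structure (real GO terms overlap hierarchically),
and realistic p-value/FDR joint distributions. Passing recovery tests
therefore demonstrates that the pipeline's filters, statistics and
clustering behave as specified — not that the biological findings of any
real analysis are correct.

## Problem sizes in the test suite

Unit tests run a scaled-down configuration (hundreds of genes, tens of
SNPs); the recovery and calibration checks run at study scale: the full
10⁶-comparison null grid, a 17,000-gene universe, 192-sample expression
matrices, 100-seed enrichment recovery, 200-run FWER simulation, and a
500-repetition exceedance calibration at reduced replicate counts
(40×40) with draw sizes (1000, 1200 from 4000) chosen so the discrete
overlap distribution is wide enough for the continuous
probability-integral-transform approximation the calibration test relies
on. Monte-Carlo assertions use explicit error bounds: 3 standard errors
for means, Fisher-combined goodness-of-fit replicates, and a 1% binomial
bound for the family-wise error rate.

## Known limitations

- Published hippocampal co-expression resources rarely document their
  correlation statistic or module-detection rule; connected components is
  the simplest deterministic default here, and module *counts* are
  structural outputs, not quantities with a single right value.
- Cohen's kappa over the significant-term reference is one defensible
  reading of "more than 30% similarity"; the reference set and the
  measure are configurable because the cited tool's exact choices are not
  public.
- The Bonferroni family is the per-disorder set of performed tests;
  other families (e.g. genome-wide) would be stricter.
- The classical hypergeometric FDR of the eQTL resource is consumed, not
  re-estimated.
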