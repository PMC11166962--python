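# crosstrait

Comorbidity genetics of two disorders through shared brain eQTL genes.

Two common disorders — the motivating case is Alzheimer's disease and
depression — can co-occur because their risk loci regulate the same genes
in the brain. `crosstrait` implements that analysis as a tested, seedable
pipeline for anyone with a GWAS-catalog-style association table, a brain
eQTL summary table, an expression matrix and a GMT annotation collection:

1. **Locus selection** — filter associations to each disorder's trait
   labels and to suggestive significance (p < 5×10⁻⁵), collapsing
   duplicate SNP reports.
2. **eQTL mapping** — join SNPs to significant eQTL effects (FDR < 0.05),
   classify cis (< 1 Mb) / trans (> 5 Mb or another chromosome), collapse
   to unique gene sets, and flag genes already proximity-mapped in the
   catalog.
3. **Overlap null** — quantify the gene-set overlap with

   *J* = |A ∩ B| / (|A| + |B|)

   and compare it with a Monte-Carlo null built from 1000 random gene
   sets per disorder drawn from the eQTL gene universe — all 10⁶ pairwise
   comparisons — reporting the mean null *J* and the fraction of null
   comparisons exceeding the observed value. The closed form
   E[*J*] = (n_A·n_B/N)/(n_A+n_B) validates the simulation.
4. **Co-expression expansion** — guilt-by-association: correlate each
   disorder's eQTL genes against a hippocampal expression matrix, keep
   partners with Bonferroni-adjusted p < 0.05, and partition the network
   into modules.
5. **Enrichment clustering** — hypergeometric enrichment of both expanded
   lists against GMT terms (significant at p < 0.01, overlap ≥ 3,
   enrichment factor ≥ 1.5), single-linkage clustering of terms with
   Cohen's kappa similarity > 0.3, clusters named by their most
   significant term and flagged when enriched in **both** disorders.

A synthetic-data module generates all four inputs with planted structure
(shared genes, co-expression modules, doubly-enriched terms) so the whole
pipeline can be exercised and validated without any external download.

## Worked example

Run the pipeline end-to-end on study-scale synthetic data (two disorders
with planted eQTL pair sets of 101 and 487 pairs, 70 and 278 unique genes,
6 of them shared, over a 17,000-gene universe):

```python
from crosstrait import PipelineConfig, run_pipeline, SimulationConfig
from crosstrait.pipeline import DisorderConfig

config = PipelineConfig(
    disorders=(
        DisorderConfig("AD", ("disorder A",)),
        DisorderConfig("depression", ("disorder B",)),
    ),
    synthetic=SimulationConfig(seed=0),
    seed=0,
)
report, art = run_pipeline(config)
print(art.overlap.summary())
```

```
Gene-set overlap Monte-Carlo test
==========================================
Set AD: 70 genes (draw size 101)
Set depression: 278 genes (draw size 487)
Universe: 17000 genes
Overlap: 6 genes
Observed J = |A∩B|/(|A|+|B|): 0.01020
Null mean J (1000000 comparisons): 0.00492
Analytic E[J]: 0.00492
Exceedance P(J_null > J_obs): 0.0258
```

Reading this: the six genes shared by the two disorders give an observed
overlap statistic of 0.01020 (six shared genes over the 101 + 487 summed
pair counts), roughly double the null mean of 0.00492, and only ~2.6% of
the million null comparisons overlap more — the shared regulatory signal
is unlikely to arise by chance at these set sizes. `art.enrichment.summary()`
then lists the term clusters enriched in both disorders:

```
Enrichment analysis
==========================================
Query 'AD': 60 terms tested, 3 significant
Query 'depression': 60 terms tested, 3 significant
Clusters: 3 (3 shared)
  shared cluster 1: planted shared pathway 2 (best p = 2.78e-22)
  shared cluster 2: planted shared pathway 0 (best p = 1.17e-20)
  shared cluster 3: planted shared pathway 1 (best p = 3.33e-15)
```

On synthetic data the three planted doubly-enriched pathways are exactly
the three shared clusters recovered.

With `out_dir` set, the run writes per-stage TSVs, an overlap JSON, GraphML
networks (Cytoscape-importable), a machine-readable run report and a file
manifest. The same stages are available from the shell:

```bash
crosstrait simulate --seed 0 --out inputs/
crosstrait run config.yaml --seed 0 --out results/
```

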