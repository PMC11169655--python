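# leukattr

Attribute age-associated whole-blood gene expression changes to leukocyte
subtypes.

## The problem

Differential expression studies of human whole blood report genes whose
expression changes with donor age, and a common reading is that these
reflect changed transcription inside blood cells.  But whole blood is a
mixture: its composition shifts with age — most prominently, naïve T cells
decline — so a gene highly specific to a shrinking cell population will
*appear* down-regulated in bulk data even if no cell changes its
transcription.  `leukattr` quantifies this composition signal.  Given

1. a **reference expression atlas** of sorted leukocyte subtypes (18 immune
   cell populations, normalized transcripts per million, nTPM), and
2. a **ranked list of age-associated genes** (rank, association Z-score,
   direction of change from a bulk meta-analysis),

it computes for every protein-coding gene *i* and cell type *j* the
**attribution fraction**

```
x[i, j] = nTPM[i, j] / Σ_j nTPM[i, j]
```

the share of the gene's atlas expression contributed by that cell type
(row-stochastic, scale-invariant), and then asks whether the
age-associated gene sets are unusual in where their expression comes from:

- **Enrichment tests** — per cell type, a Wilcoxon comparison of the gene
  set's attribution fractions against the genome-wide background, with
  Benjamini–Hochberg adjustment across the 18 cell types.  Two variants
  are provided: a one-sample signed-rank test against the background
  median, and a two-sample rank-sum test against the full background
  distribution (see `docs/methods.md` for when each is appropriate).
- **Cumulative median curves** — median combined naïve-T attribution of
  the top-*k* ranked genes as *k* grows.
- **Direction-of-change tests** — exact two-tailed binomial test of the
  decrease/increase split against a null proportion of 0.5.

A synthetic-data generator produces atlases and ranked lists with the same
statistical structure (Dirichlet cell-type compositions, a planted set of
naïve-T-specific genes enriched in the top ranks and biased toward
decreasing with age), so the entire pipeline runs and is tested without
any download.

## Worked example

```python
from leukattr import (CellTypeAttribution, EnrichmentConfig, RANK_SUM,
                      SimulationConfig)
from leukattr.synthetic_data import generate_atlas, generate_ranked_list

cfg = SimulationConfig()                       # default study conditions
atlas, truth = generate_atlas(cfg, seed=7)
genes = generate_ranked_list(cfg, truth, seed=7)

model = CellTypeAttribution(atlas, genes)
res = model.fit("frac:0.5", config=EnrichmentConfig(test_variant=RANK_SUM))
print(res.summary())
```

prints

```
Gene set: frac0.5 (20 genes, 20 mapped)
Test variant: rank_sum_vs_background
List mapping: mapped 200 of 200 listed genes (100.0%); 0 unmapped

Cell type                Background %    Set %         p     p_adj  sig direction
Naive CD8 T-cell                 4.23    42.50   4.5e-09   8.0e-08  *** elevated
Naive CD4 T-cell                 4.09    42.50   1.5e-08   1.4e-07  *** elevated
Memory CD8 T-cell                3.90     1.41   7.2e-04   8.6e-04  *** depleted
...
Basophil                         3.92     0.55   1.8e-06   1.1e-05  *** depleted

Direction of change: 18 of 20 (90%) had decreased expression with age, p = 4.0e-04
Elevated: Naive CD8 T-cell, Naive CD4 T-cell
```

Reading this: the `frac:0.5` rule selects the genes whose Z-score is at
least half the top gene's (here the top 20).  A random gene's expression
is ~4% attributable to each cell type (Background %), but the top ageing
genes put a median 42.5% of their expression on each naïve T column —
both flagged as significantly elevated after BH adjustment (`***` means
p_adj ≤ 0.001) — while every myeloid column is depleted.  18 of the 20
genes decrease with age (binomial p = 4.0e-4), the pattern expected if
the bulk ageing signal tracks a declining naïve-T compartment.

The same analysis runs from the shell:

```sh
leukattr simulate --out sim --seed 7
leukattr run --atlas sim/atlas.tsv --genes sim/ranked_genes.tsv --out results \
    --set frac:0.5 --set all --variant rank_sum_vs_background
```

writing the attribution table, one enrichment TSV per gene set, the
cumulative median curve, direction tests, the gene-mapping report, a run
log with input checksums, and a plain-text summary.  To analyze real
data, point `--atlas` at a long-format TSV with columns
`Gene / Gene name / Immune cell / nTPM` and `--genes` at a
`rank / symbol / id / score / direction` TSV.

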