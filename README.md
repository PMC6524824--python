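# scapa

Cell-type-specific **alternative polyadenylation (APA)** signatures from
single-cell RNA-seq, combined with gene expression.

Shortening of 3'UTRs through APA is a hallmark of proliferating cells:
losing microRNA/RBP binding sites tends to stabilise transcripts and raise
protein output. In a tumor biopsy, however, tumor cells, lymphocytes,
myeloid and stromal cells each run their own APA program, and bulk RNA-seq
averages them away. `scapa` works at single-cell resolution: given per-cell
3'UTR-length-change scores (DaPars-style ΔPDUI or Roar-style usage ratios)
and a matched TPM expression matrix, it finds the gene sets and genes whose
**3'UTR shortening and over-expression co-occur specifically in one cell
type**, contrasts APA programs between tumor types, organises the hits into
functional clusters via shared parent GO terms, and asks whether signature
genes stratify patient survival.

## The statistic at the core

For every component *g* (a gene set scored by ssGSEA, or a single gene) and
candidate cell type *k*, two measures must agree:

1. **Within-type coupling.** The Pearson correlation *r* between the
   component's shortening score *s_g(c)* and expression score *e_g(c)*
   across the cells *c* of type *k*, tested with the Fisher
   Z-transformation: *z* = atanh(*r*), *p* = 2Φ(−|z|·√(n−3)).
2. **Type specificity.** Cells are flagged when both scores exceed the
   component's global medians; the 2×2 table
   (in-type / out-of-type × flagged / unflagged) gives an odds ratio
   OR = AD/BC (Haldane–Anscombe 0.5 when a cell is zero) with a two-sided
   Fisher exact *p*.

A pair (*g*, *k*) is a signature hit when **PCC > 0 with p < 0.05 and
OR > 2 with p < 0.01** (strict inequalities, no multiplicity correction by
default).

Around this sit the supporting stages: ssGSEA enrichment (the running-sum
integral, weight |rank score|^τ with τ = 0.25, per-cell universe shrinkage
for missing APA values), detection filters (cells need ≥ 10 % of genes
estimated; gene-level runs drop genes estimated in < 30 % of cells),
variance-baseline selection of variable components (s.d. across cells above
mean + s.d. of all components), Welch-t tumor-type contrasts with per-type
top-k reporting, connected-component clustering of hits at parent-GO-term
Jaccard > 0.5 with clusters > 9 kept, and 25th/75th-percentile expression
stratification with Kaplan–Meier/log-rank (in-house) plus multivariate Cox
regression (lifelines, Efron ties) under 10-year administrative censoring.

A synthetic-cohort generator plants concordant shortening/over-expression
signals per cell type, so the entire pipeline is testable end to end
without any external data.

## Worked example

```python
from scapa import SimConfig, simulate_cohort, signature_pipeline

cohort = simulate_cohort(SimConfig(n_cell_types=3, cells_per_type=25,
                                   n_genes=600, n_gene_sets=60,
                                   planted_sets_per_type=2, seed=11))
res = signature_pipeline(cohort.apa, cohort.expression,
                         cohort.annotation, cohort.gene_sets)
print(res.summary())
```

```
Cell-type signature selection
  cutoffs: PCC > 0 (p < 0.05), OR > 2.0 (p < 0.01); PCC scope: within
  pairs tested: 180   hits: 6
  B: 2 hit(s): GS0002_B, GS0003_B
  T: 2 hit(s): GS0004_T, GS0005_T
  tumor: 2 hit(s): GS0000_tumor, GS0001_tumor
```

All six planted gene sets (two per cell type) are recovered with no false
positives; `res.hits` holds the per-pair statistics — for instance
`GS0002_B` in B cells has within-type PCC 0.686 (p = 8.1e-5) and odds ratio
1.7e3 (Fisher p = 4.9e-19). `res.stats` lists every tested
(component, cell type) pair.

The same stages are scriptable from a shell:

```sh
scapa simulate --out cohort/ --seed 11
scapa enrich --channel apa --apa cohort/apa.tsv --gmt cohort/gene_sets.gmt --out apa_es.tsv
scapa enrich --channel expression --expr cohort/expression.tsv --gmt cohort/gene_sets.gmt --out expr_es.tsv
scapa signatures --apa-scores apa_es.tsv --expr-scores expr_es.tsv \
      --annot cohort/annotation.tsv --out stats.tsv --hits-out hits.tsv
scapa go-network --hits hits.tsv --parents cohort/parents.tsv \
      --edges-out edges.tsv --nodes-out nodes.tsv
```

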