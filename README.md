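# aireclass

Classification of Aire target genes from single-cell data.

The transcription factor Aire drives *promiscuous gene expression* in
medullary thymic epithelial cells (mTECs): thousands of tissue-restricted
antigen genes are transcribed in the thymus so that self-reactive T cells
can be eliminated. Genes that drop in Aire-knockout mTECs ("Aire-induced"
genes from bulk RNA-seq) are, however, a mixture of two very different
regulatory classes, because Aire also reshapes the composition of the mTEC
compartment:

* **Aire-driven** genes — direct targets, expressed *only* in the
  Aire-expressing mature cluster, stochastically (each gene fires in a
  small minority, about 13% of cells, as an independent per-cell event);
* **Aire-enhanced** genes — expressed Aire-independently in other mature
  (mimetic) mTEC clusters, in coordinated co-expression modules, and merely
  amplified by Aire-dependent development.

This package implements, as a tested and reusable pipeline, the
computational procedures that make that distinction and characterize the
two classes — exercised on synthetic single-cell data with recorded ground
truth, for tool validation, benchmarking and method study.

## What is implemented

| module | contents |
| --- | --- |
| `simdata` | synthetic count matrices, genomes, spike-in libraries, peaks and tracks with the assumed statistical structure and recorded truth |
| `normx` | per-cell log-normalization ln(1 + 10⁴·c/total); gene-length-corrected TMM (GeTMM); group z-scores |
| `rankstats` | Wilcoxon rank-sum (exact ≤ 8 per group, else normal approx. with tie/continuity corrections), auROC, Bonferroni/BH, Yates 2×2 χ², one-way ANOVA + Tukey HSD, SMA regression, permutation Z-test |
| `degattr` | two-group DEG tables, the four-branch gene-to-cluster attribution rule (adj. p < 10⁻⁵ exclusivity → z-gap > 1 → z > 0 → "not lower than significant"), Aire-driven/enhanced class labels, maturation dynamics, Aire-neutral calls |
| `stochastic` | expressing-cell fractions (cell expresses a gene when its value exceeds 25% of the gene's 97.5th percentile), top-5% expression means, group comparisons |
| `coexpr` | ≥5 reads in ≥5 cells filtering, gene–gene Pearson matrices, affinity-propagation micro-clusters, r > 0.6 connection lists with intra/inter-chromosomal contingency and TSS-distance statistics |
| `crossmatch` | auROC-selected signatures (top 2,000 by abs(AUC − 0.5), adj. p < 0.05), Pearson cell-to-cluster assignment (unassigned at r ≤ 0.2), matching matrices |
| `tfcorr` | TF expression vs motif-activity correlation with the dual permutation null (shuffled cluster labels and substituted TFs; p = max of the two) |
| `bulkcontrib` | bulk Aire-induced calls (FC < 0.5, FDR < 0.05), cluster contribution = mean expression × relative size, TRA calls (expressed in ≤ 3 organs) |
| `epigenome` | spike-in scaling: FrSpike from genome-size-normalized read counts, Eff = RiP/RQC, Sfabs = 1/[RQC·(1 − FrSpike)]/Eff, Sfrel = Sfabs/max; track scaling, locus densities (±10 kb), strand-aware TSS profiles, peak proximity (20-kb window) |
| `pipeline`, `cli` | YAML-configured orchestration with a JSON manifest; `aireclass` console script |

## Worked example

```python
import aireclass as ac

adata = ac.simulate_dataset(ac.SimParams(seed=1))   # 2000 cells x 1700 genes
result = ac.classify_dataset(adata)

truth = adata.var.set_index("gene_id")["truth_class"]
classes = result["classes"]
print(classes.value_counts().to_dict())
pred = set(classes.index[classes == "aire_driven"])
true = set(truth.index[truth == "aire_driven"])
print("precision", len(pred & true) / len(pred), "recall", len(pred & true) / len(true))
```

prints

```
{'none': 700, 'aire_driven': 500, 'aire_enhanced': 500}
precision 1.0 recall 1.0
```

i.e. on default study conditions every one of the 500 simulated Aire-driven
and 500 Aire-enhanced genes enters the Aire-DEG set (significantly up in
the WT Aire cluster vs its knockout counterpart) and is attributed to the
correct class; the 500 neutral and 200 marker genes stay out. The
worked-example contingency of high-correlation connections —
23 intra-chromosomal/1 inter for driven vs 79/1078 for enhanced — gives
4.2% vs 93.2% inter-chromosomal connections and a Yates chi-square
p = 7.7 × 10⁻⁵¹:

```python
from aireclass.rankstats import chi_square_2x2
print(chi_square_2x2([[23, 1], [79, 1078]]).p)   # 7.698e-51
```

The same classification is available from a shell:

```sh
aireclass run-all --outdir run1 --seed 1
```

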