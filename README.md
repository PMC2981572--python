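# enrichmap

Headless construction of **enrichment maps**: similarity networks over
the results of gene-set enrichment analysis.

## The problem

Enrichment analysis asks which predefined gene-sets (GO terms, pathways,
signatures) are over-represented in an experiment's gene list, and
routinely returns hundreds of significant sets that are heavily
redundant — GO children overlap their parents by definition. A flat
table of such results is hard to interpret. An enrichment map organises
the significant sets as a network: each set is a node, and two sets are
connected when they share enough genes. A force-directed layout then
groups redundant sets into visible clusters that correspond to
functional themes.

Given sets *A* and *B*, similarity is measured by the Jaccard
coefficient

    JC(A, B) = |A ∩ B| / |A ∪ B|

or the overlap coefficient

    OC(A, B) = |A ∩ B| / min(|A|, |B|).

OC ≥ JC always; OC equals 1 for any subset relation, so with the OC
metric every parent–child pair in a hierarchical collection receives an
edge at any cutoff ≤ 1 (the threshold is inclusive, default 0.5).
Sets enter the map if they pass strict significance thresholds
(nominal p < 0.001 and FDR q < 0.05 by default), after discarding sets
annotating fewer than 10 or more than 500 genes. Node colour encodes
signed significance, `direction × (1 − p)`: red for enrichment in one
phenotype, blue for the other, white for not significant; node size
encodes the number of genes in the set; edge thickness encodes the
coefficient.

The package also provides:

* **two-dataset comparison** — one map whose nodes carry two enrichment
  slots (centre/border in a viewer), the node set being the union of
  sets significant in either dataset;
* **query-set post-analysis** — a user gene list (e.g. known disease
  genes) is linked to map nodes by a one-tailed Fisher's exact test
  (nominal p < 10⁻⁴ by default, edge width −log₁₀ p);
* **a Fisher enrichment mode** for discrete gene lists, with
  Benjamini–Hochberg FDR;
* **gene scoring** (Welch t statistic or ratio of class means) and
  **heat-map data extraction** for the expression values underlying any
  gene-set;
* **synthetic fixtures** with planted cluster structure, so the whole
  pipeline is testable without downloads.

Inputs are the standard exchange formats: GMT gene-set collections,
GSEA report tables or generic `id / pvalue / fdr / direction` TSV,
GCT/CLS expression data. Outputs are GraphML (lossless,
re-importable), SIF, and node/edge TSV — ready for Cytoscape or any
graph viewer.

## Worked example

```python
from enrichmap import build_map, layout, style_attributes
from enrichmap.synth import SynthSpec, make_collection, make_enrichment

spec = SynthSpec(k_clusters=3, seed=7)          # 3 planted themes
collection, labels = make_collection(spec)
result = make_enrichment(spec, collection, labels)[0]

network = build_map(result, collection, metric="overlap", cutoff=0.5)
style_attributes(network)
layout(network, seed=42)

print(f"{len(collection)} gene-sets, {len(result.records)} enrichment records")
print(f"map: {len(network.nodes)} nodes, {len(network.edges)} edges")
```

prints

```
24 gene-sets, 24 enrichment records
map: 24 nodes, 84 edges
```

The 24 sets are three gene-disjoint clusters of eight sets each
(six overlapping sets built on a shared 20-gene core, plus a strict
parent/child pair). Within a cluster every pair shares its core, so
the overlap coefficient is at least 0.8 and all 3 × C(8,2) = 84 edges
pass the 0.5 cutoff; between clusters the coefficient is exactly 0, so
the map's three connected components recover the planted themes:

```
component 1: 8 sets, e.g. ['C1_CHILD', 'C1_PARENT', 'C1_S1']
component 2: 8 sets, e.g. ['C2_CHILD', 'C2_PARENT', 'C2_S1']
component 3: 8 sets, e.g. ['C3_CHILD', 'C3_PARENT', 'C3_S1']
```

A node's attributes carry the encodings, e.g.

```
C1_S1: size=25, p=9.08e-05, color_score=-0.9999
```

— a 25-gene set, highly significant (p ≈ 9×10⁻⁵) in the −1 phenotype,
hence an intensely blue node (`color_score = −(1 − p) ≈ −1`).

The same pipeline from the shell:

```sh
emk simulate --seed 7 -o fixtures/
emk build --gmt fixtures/sets.gmt --generic fixtures/enrichment1.tsv \
    --metric overlap --cutoff 0.5 --pval 0.001 --fdr 0.05 --seed 42 -o out/
emk post --map out/ --gmt fixtures/sets.gmt --query disease.txt --alpha 1e-4 -o out_post/
emk heatmap --set C1_S1 --gmt fixtures/sets.gmt --expr fixtures/expr.gct \
    --cls fixtures/expr.cls --norm row_zscore -o heat.tsv
```

## Documentation

See `docs/methods.md` for the model, parameter defaults, numerical
choices, what the synthetic generator does and does not emulate, and
known limitations.
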