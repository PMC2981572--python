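# Methods

## The enrichment-map model

An enrichment map is a weighted, undirected network over the gene-sets
that pass a significance filter. The pipeline is:

1. **Gene-set pre-processing.** A GMT collection is optionally
   restricted to the experiment's gene universe, then filtered by size:
   sets with fewer than `min_size` (default 10) or more than `max_size`
   (default 500) genes are discarded, bounds inclusive. Very large
   sets rarely convey specific biology; very small ones are prone to
   spurious enrichment.
2. **Significance filtering.** Each dataset's enrichment records are
   filtered with *strict* inequalities: kept iff `p < p_max` (default
   0.001) and, when a q-value is present, `q < q_max` (default 0.05).
   A record lying exactly on a threshold is removed. GSEA reports
   print an empty p-value cell when the permutation p falls below the
   test's resolution (p < 1/#permutations); such cells are parsed as
   0.0 so they always pass.
3. **Similarity edges.** For every unordered pair of included sets the
   Jaccard coefficient `|A∩B| / |A∪B|` or overlap coefficient
   `|A∩B| / min(|A|,|B|)` is computed on the post-filtering set
   definitions (not on leading-edge subsets). Pairs at or above the
   cutoff (default 0.5, *inclusive*) become edges. Inclusivity
   matters: a strict subset scores OC exactly 1, so with the OC metric
   every hierarchical parent–child pair is connected at any cutoff ≤ 1.
   The implementation prefilters candidate pairs with an inverted
   gene→set index; since the cutoff is strictly positive this is
   provably output-equivalent to the all-pairs scan (which the tests
   verify directly).
4. **Visual encodings.** Node colour score is `direction × (1 − p)` in
   [−1, +1]; a non-significant or absent slot is forced to 0 (white),
   and one-class records (direction 0) are treated as +1 (the
   white-to-red gradient). The bounded, linear `1 − p` form keeps the
   gradient well defined; a −log p intensity would be unbounded. Node
   display size and edge width are monotone affine maps of set size
   and coefficient onto fixed pixel ranges ([20, 65] and [1, 8] by
   default); degenerate ranges (all sizes equal; cutoff = 1) collapse
   to a single value.
5. **Layout.** A Fruchterman–Reingold spring embedding
   (`networkx.spring_layout`) with the similarity coefficient as edge
   weight, so strongly overlapping sets attract each other more.
   Deterministic given `(seed, iterations)`; defaults 42 and 100.
   Nodes without edges are legitimate map members and are placed on a
   grid below the connected part's bounding box instead of drifting
   under pure repulsion; a single-node map sits at the origin.

### Two-dataset comparison

Both datasets are filtered independently; the node set is the **union**
of sets significant in either. Each node carries two slots: the
dataset's unfiltered record (kept for tables and tooltips) plus a
significance flag; the colour score of a non-significant slot is 0.
Viewers render slot 1 as the node centre and slot 2 as the border.
Swapping the input order exchanges the slots and nothing else.

### Query-set post-analysis

A query gene list is tested against every gene-set node with the
one-tailed Fisher's exact test: with universe size `N`, restricted set
size `n`, query size `m` and overlap `k`,

    p = Σ_{i=k}^{min(n,m)} C(n,i) C(N−n, m−i) / C(N, m),

computed as the hypergeometric survival function
(`scipy.stats.hypergeom.sf(k−1, N, n, m)`). Edges appear for nominal
`p < alpha` (default 10⁻⁴, deliberately unadjusted — the threshold is
conservative and the analysis exploratory) with width `−log₁₀ p`
(natural log available via `log_base`). The default universe is the
union of genes across the collection; overriding it with the
expression platform's gene list is recommended when available. The
query becomes a triangle-shaped "signature" node; signature edges never
modify similarity edges or node attributes.

### Fisher enrichment mode

For discrete input gene lists the same hypergeometric tail serves as a
stand-alone enrichment test over a whole collection, with
Benjamini–Hochberg q-values (`statsmodels.stats.multitest`) across the
tested sets; filtering then uses the same strict p/q rule as the
GSEA-sourced path.

### Gene scoring and heat maps

The two-class scoring statistics are the Welch (unequal-variance) t,
with per-class variances floored at 1e-8 so constant genes score 0
rather than NaN (a pooled-variance variant is available), and the
ratio of class means computed on the values as given — for log2-scale
data this is a ratio of log means; genes with a zero control mean are
excluded with a warning. Rankings sort descending by score with ties
broken by gene id for determinism.

Heat-map extraction returns the set ∩ matrix submatrix with rows
ordered by descending t statistic when the sample classes permit
scoring (otherwise matrix order — the ordering rule is a documented
choice), columns grouped by class in input order, and optional
normalisation: `row_zscore` (population moments; constant rows become
all-zero) or `log2`. Genes of the set absent from the matrix are
reported, never fabricated.

## Parameters that matter

| parameter | default | units / range | why |
|---|---|---|---|
| `min_size`, `max_size` | 10, 500 | genes, inclusive | the routine pre-processing bounds for annotation-derived sets |
| `p_max` | 0.001 | nominal p, strict | conservative inclusion of sets in the map |
| `q_max` | 0.05 | FDR q, strict | ditto |
| `metric` | overlap | {overlap, jaccard} | OC keeps hierarchical relations in the network; JC groups similar-size sets |
| `cutoff` | 0.5 | coefficient, inclusive | sparse enough to reveal clusters, dense enough to connect themes |
| `alpha` | 1e-4 | nominal Fisher p, strict | post-analysis threshold |
| `seed`, `iterations` | 42, 100 | — | layout reproducibility |

## The synthetic generator

`SynthSpec` defaults describe a small GO-like study: a 2000-gene
universe; 3 planted clusters of 6 sets, each set a shared 20-gene core
plus 5 private genes (within-cluster OC exactly 20/25 = 0.8, clusters
gene-disjoint so between-cluster OC is exactly 0); one strict
parent/child pair per cluster (child = core, parent = core + 5 genes;
OC exactly 1); all sets significant (`frac_significant = 1`) with
p ~ U(0, 0.0005) and q ~ U(0, 0.04), non-significant sets drawing
p ~ U(0.01, 1) — both with deliberate margins around the thresholds so
boundary flakiness cannot occur; directions constant within a cluster
(`mixed` flips a fair coin per cluster). Expression matrices use
Normal(7, 0.5) baselines (a log2-like scale) with 3 samples per class
and a +5 shift for genes of the designated DE sets in the case class —
an effect large enough that planted genes separate completely from the
null, which is what the separation tests assert. A second enrichment
dataset demotes each planted set with probability 0.1, emulating a
two-time-point contrast.

What the generator does **not** emulate: a realistic GO DAG topology
(clusters here are disjoint by construction, real collections overlap
across themes), correlated genes, permutation-based p-value
distributions, or probe-level artefacts. Passing tests therefore
demonstrate the algebraic and structural correctness of the pipeline —
coefficients, thresholds, union semantics, cluster recovery under
designed separation — not recovery performance on noisy, entangled
real collections.

## Numerical choices

* Hypergeometric tails via `scipy.stats.hypergeom.sf`, clipped into
  (0, 1]; the test suite cross-checks against exhaustive enumeration of
  all C(N, m) draws for universes up to 25 genes.
* File round trips are exact: floats are serialised with `repr` and
  parsed with `float_precision="round_trip"`, so GMT, generic TSV, GCT
  and GraphML exports re-import to equal objects.
* Problem sizes in the test suite are deliberately small (collections
  of tens of sets, universes ≤ 2000 genes, enumeration universes ≤ 25);
  they are chosen to make the oracles exact, and the full suite runs in
  a few seconds.
* Edge lists are canonicalised (lexicographic pair order, sorted
  output) so results are independent of collection iteration order.
* Tie-breaks everywhere are deterministic (gene id, set id ascending).

## Limitations

* At most two datasets per map; multi-condition comparison would need a
  different visual encoding.
* Similarity is set-definition overlap only; co-expression-weighted or
  leading-edge-restricted similarities are out of scope.
* The `1 − p` colour intensity is one reasonable choice among several;
  it is documented, not canonical.
* The tool is headless: it computes coordinates and style attributes
  but delegates actual rendering to external viewers.
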