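"""Synthetic fixtures with planted, recoverable structure.

Real enrichment maps are built from GO-derived collections (heavily
overlapping, hierarchically organised) and enrichment tables from
microarray contrasts.  This module generates self-contained stand-ins
with known ground truth:

* a gene-set collection organised into ``k`` planted clusters whose
  sets share a cluster core (so within-cluster overlap coefficients are
  provably >= core/(core+peripheral)) while clusters are gene-disjoint
  (between-cluster coefficients exactly 0), plus one strict
  parent/child pair per cluster (overlap coefficient exactly 1);
* enrichment results in which planted-significant sets draw
  p ~ U(0, 0.0005) and q ~ U(0, 0.04) — safely inside the default
  p < 0.001 / q < 0.05 filter — and the rest draw p ~ U(0.01, 1),
  safely outside, so threshold-boundary flakiness cannot occur;
* a two-class expression matrix with Normal(7, noise_sd) baselines and
  a mean shift of ``effect_size`` in the case class for genes of chosen
  DE sets, emulating a set induced in one condition.

All generators are pure functions of ``(spec, seed)``: the same spec
yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

import numpy as np

from .enrichment import EnrichmentRecord, EnrichmentResult
from .expression import ExpressionMatrix
from .genesets import GeneSet, GeneSetCollection

__all__ = ["SynthSpec", "make_collection", "make_enrichment", "make_expression",
           "write_fixture_dir"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic study.

    Defaults mirror a small GO-like analysis: a 2000-gene universe,
    three functional themes of six sets each built on 20-gene cores
    with 5 private genes per set, every set significant, three
    replicates per class, a 5-unit (log2-scale) induction of DE genes
    over noise_sd 0.5.
    """

    n_genes: int = 2000
    k_clusters: int = 3
    sets_per_cluster: int = 6
    core_size: int = 20
    peripheral_size: int = 5
    frac_significant: float = 1.0
    direction_scheme: str = "mixed"  # "all_up" or "mixed"
    n_samples_per_class: int = 3
    effect_size: float = 5.0
    noise_sd: float = 0.5
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("n_genes", "k_clusters", "sets_per_cluster", "core_size",
                     "peripheral_size", "n_samples_per_class"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 <= self.frac_significant <= 1.0:
            raise ValueError("frac_significant must be in [0, 1]")
        if self.direction_scheme not in ("all_up", "mixed"):
            raise ValueError("direction_scheme must be 'all_up' or 'mixed'")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def make_collection(spec: SynthSpec) -> tuple[GeneSetCollection, dict[str, int]]:
    """Generate the planted-cluster collection and its truth labels.

    Each cluster occupies a disjoint block of the gene universe.  Its
    ``sets_per_cluster`` sets share the cluster core and add
    ``peripheral_size`` private genes each (private genes are disjoint
    across sets, so within-cluster overlap coefficients equal
    core/(core+peripheral) exactly).  Two extra sets per cluster form a
    strict parent/child pair: the child is the core, the parent the
    core plus ``peripheral_size`` further genes.

    Returns the collection and a map from set id to 0-based cluster
    label.
    """
    block = spec.n_genes // spec.k_clusters
    need = spec.core_size + (spec.sets_per_cluster + 1) * spec.peripheral_size
    if need > block:
        raise ValueError(
            f"infeasible sizes: each cluster needs {need} genes but only "
            f"{block} are available (n_genes={spec.n_genes}, "
            f"k_clusters={spec.k_clusters})"
        )
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)

    collection = GeneSetCollection(name="synthetic")
    labels: dict[str, int] = {}
    for c in range(spec.k_clusters):
        pool = genes[c * block:(c + 1) * block]
        picked = rng.choice(len(pool), size=need, replace=False)
        picked_genes = [pool[i] for i in picked]
        core = picked_genes[:spec.core_size]
        cursor = spec.core_size
        for s in range(spec.sets_per_cluster):
            private = picked_genes[cursor:cursor + spec.peripheral_size]
            cursor += spec.peripheral_size
            sid = f"C{c + 1}_S{s + 1}"
            collection.add(
                GeneSet(sid, frozenset(core) | frozenset(private),
                        description=f"cluster {c + 1} set {s + 1}")
            )
            labels[sid] = c
        parent_extra = picked_genes[cursor:cursor + spec.peripheral_size]
        parent_id, child_id = f"C{c + 1}_PARENT", f"C{c + 1}_CHILD"
        collection.add(
            GeneSet(parent_id, frozenset(core) | frozenset(parent_extra),
                    description=f"cluster {c + 1} parent term")
        )
        collection.add(
            GeneSet(child_id, frozenset(core),
                    description=f"cluster {c + 1} child term")
        )
        labels[parent_id] = c
        labels[child_id] = c
    return collection, labels


def _cluster_directions(spec: SynthSpec, rng: np.random.Generator) -> dict[int, int]:
    if spec.direction_scheme == "all_up":
        return {c: 1 for c in range(spec.k_clusters)}
    # mixed: per-cluster coin flip, consistent within a functional theme
    return {
        c: int(rng.choice([1, -1])) for c in range(spec.k_clusters)
    }


def make_enrichment(
    spec: SynthSpec,
    collection: GeneSetCollection,
    labels: dict[str, int],
    n_datasets: int = 1,
    perturb_frac: float = 0.1,
) -> list[EnrichmentResult]:
    """Generate one or two enrichment results with planted significance.

    A ``frac_significant`` fraction of sets is planted significant with
    p ~ U(0, 0.0005) and q ~ U(0, 0.04); the rest draw p ~ U(0.01, 1)
    and q ~ U(0, 1), guaranteed to fail the default p < 0.001 filter.
    Directions are +1 under ``all_up`` or a per-cluster coin flip under
    ``mixed`` (consistent within a cluster).  With ``n_datasets=2`` the
    second dataset independently demotes each planted set to
    non-significant with probability ``perturb_frac``, emulating a
    condition contrast in which some themes are enriched at only one
    time point.
    """
    if n_datasets not in (1, 2):
        raise ValueError("n_datasets must be 1 or 2")
    rng = np.random.default_rng(spec.seed + 1)
    set_ids = collection.set_ids
    n_sig = round(spec.frac_significant * len(set_ids))
    sig_ids = set(
        rng.choice(set_ids, size=n_sig, replace=False)
    ) if n_sig else set()
    directions = _cluster_directions(spec, rng)
    universe = collection.all_genes()

    def draw(sid: str, significant: bool) -> EnrichmentRecord:
        direction = directions.get(labels.get(sid, 0), 1)
        if significant:
            p = float(rng.uniform(0.0, 0.0005))
            q = float(rng.uniform(0.0, 0.04))
        else:
            p = float(rng.uniform(0.01, 1.0))
            q = float(rng.uniform(0.0, 1.0))
        return EnrichmentRecord(sid, p_value=p, q_value=q, direction=direction)

    results = []
    for d in range(n_datasets):
        res = EnrichmentResult(dataset_name=f"sim{d + 1}", universe=universe)
        for sid in set_ids:
            significant = sid in sig_ids
            if d == 1 and significant and rng.uniform() < perturb_frac:
                significant = False
            res.add(draw(sid, significant))
        results.append(res)
    return results


def make_expression(
    spec: SynthSpec,
    collection: GeneSetCollection,
    de_sets: list[str],
) -> ExpressionMatrix:
    """Generate a two-class matrix with planted differential expression.

    Baselines are Normal(7, noise_sd) per gene and sample (log2-like
    scale).  Genes belonging to any set in ``de_sets`` are shifted by
    ``+effect_size`` in the case class.  Samples are named
    ``case_1..n`` and ``control_1..n`` with matching class labels.
    """
    rng = np.random.default_rng(spec.seed + 2)
    genes = sorted(collection.all_genes())
    de_genes: set[str] = set()
    for sid in de_sets:
        de_genes |= collection[sid].genes
    n = spec.n_samples_per_class
    samples = [f"case_{i + 1}" for i in range(n)] + [
        f"control_{i + 1}" for i in range(n)
    ]
    values = rng.normal(7.0, spec.noise_sd, size=(len(genes), 2 * n))
    de_rows = np.array([g in de_genes for g in genes])
    values[de_rows, :n] += spec.effect_size
    classes = {s: ("case" if s.startswith("case") else "control") for s in samples}
    return ExpressionMatrix(genes, samples, values, classes)


def write_fixture_dir(
    spec: SynthSpec,
    outdir: str | PathLike[str],
    n_datasets: int = 1,
    de_sets: list[str] | None = None,
) -> dict[str, Path]:
    """Emit a complete fixture directory: GMT, enrichment TSV(s), GCT,
    CLS, and a truth JSON with the planted cluster labels.

    Returns a mapping of artifact kind to path.
    """
    from .enrichment import write_generic_table
    from .expression import write_cls, write_gct
    from .genesets import write_gmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collection, labels = make_collection(spec)
    results = make_enrichment(spec, collection, labels, n_datasets=n_datasets)
    if de_sets is None:
        de_sets = [sid for sid, c in labels.items() if c == 0]
    expr = make_expression(spec, collection, de_sets)

    paths = {"gmt": outdir / "sets.gmt"}
    write_gmt(collection, paths["gmt"])
    for i, res in enumerate(results, start=1):
        paths[f"enrichment{i}"] = outdir / f"enrichment{i}.tsv"
        write_generic_table(res, paths[f"enrichment{i}"])
    paths["gct"] = outdir / "expr.gct"
    write_gct(expr, paths["gct"])
    paths["cls"] = outdir / "expr.cls"
    write_cls(expr, paths["cls"])
    paths["truth"] = outdir / "truth.json"
    truth = {
        "labels": labels,
        "de_sets": de_sets,
        "spec": {k: getattr(spec, k) for k in spec.__dataclass_fields__},
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return paths
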