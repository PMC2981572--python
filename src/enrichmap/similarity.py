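"""Set-overlap coefficients and the thresholded similarity edge list.

Two coefficients quantify the overlap between gene-sets A and B:

* Jaccard coefficient, ``JC = |A ∩ B| / |A ∪ B|`` — penalises size
  mismatch, so it tends to connect sets of similar size.
* Overlap coefficient, ``OC = |A ∩ B| / min(|A|, |B|)`` — equals 1 for
  any subset relation, so hierarchical parent/child pairs (ubiquitous
  in GO-derived collections) always reach the maximal score.

``OC >= JC`` holds for every pair.  The enrichment map keeps only edges
whose coefficient meets a user-defined cutoff (default 0.5, inclusive:
with an inclusive threshold and OC, parent-child relations — scoring
exactly 1 — are guaranteed to be present at any cutoff <= 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .genesets import GeneSet, GeneSetCollection

__all__ = ["SimilarityEdge", "jaccard", "overlap_coeff", "build_similarity_edges", "METRICS"]

METRICS = ("jaccard", "overlap")


@dataclass(frozen=True)
class SimilarityEdge:
    """An undirected similarity link between two gene-sets.

    ``(a, b)`` is canonicalised to lexicographic order so each unordered
    pair appears at most once.
    """

    a: str
    b: str
    coefficient: float
    metric: str
    intersection_size: int

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-edge on {self.a!r}")
        if not 0.0 <= self.coefficient <= 1.0:
            raise ValueError(f"coefficient {self.coefficient} outside [0, 1]")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")


def jaccard(a: GeneSet, b: GeneSet) -> float:
    """Jaccard coefficient |A∩B| / |A∪B|.  Symmetric, in [0, 1]."""
    if a.size == 0 or b.size == 0:
        raise ValueError("coefficients are undefined for empty sets")
    inter = len(a.genes & b.genes)
    union = a.size + b.size - inter
    return inter / union


def overlap_coeff(a: GeneSet, b: GeneSet) -> float:
    """Overlap coefficient |A∩B| / min(|A|, |B|).  Symmetric, in [0, 1].

    Equals 1 whenever one set is a subset of the other, regardless of
    the size difference.
    """
    if a.size == 0 or b.size == 0:
        raise ValueError("coefficients are undefined for empty sets")
    inter = len(a.genes & b.genes)
    return inter / min(a.size, b.size)


_METRIC_FN = {"jaccard": jaccard, "overlap": overlap_coeff}


def build_similarity_edges(
    collection: GeneSetCollection,
    metric: str = "overlap",
    cutoff: float = 0.5,
) -> list[SimilarityEdge]:
    """All unordered pairs whose coefficient is >= ``cutoff``.

    The threshold is inclusive and ``cutoff`` must lie in (0, 1].  Pairs
    are canonicalised lexicographically and the returned list is sorted
    by ``(a, b)``, so the result does not depend on the collection's
    iteration order.

    An inverted gene-to-set index prefilters pairs with empty
    intersection; since the cutoff is strictly positive, such pairs can
    never pass, and the output is identical to the all-pairs scan.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if not (0.0 < cutoff <= 1.0):
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    if len(collection) == 0:
        raise ValueError("collection must contain at least one gene-set")

    fn = _METRIC_FN[metric]

    # gene -> ids of sets containing it; only co-annotated pairs can
    # have a nonzero coefficient.
    index: dict[str, list[str]] = {}
    for gs in collection:
        for g in gs.genes:
            index.setdefault(g, []).append(gs.set_id)
    candidates: set[tuple[str, str]] = set()
    for ids in index.values():
        if len(ids) > 1:
            for x, y in combinations(ids, 2):
                candidates.add((x, y) if x < y else (y, x))

    edges = []
    for x, y in sorted(candidates):
        a, b = collection[x], collection[y]
        coef = fn(a, b)
        if coef >= cutoff:
            edges.append(
                SimilarityEdge(
                    a=x,
                    b=y,
                    coefficient=coef,
                    metric=metric,
                    intersection_size=len(a.genes & b.genes),
                )
            )
    return edges
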