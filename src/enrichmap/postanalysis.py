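"""Query-set post-analysis: linking an external gene list to the map.

A query set (e.g. genes with known disease associations, or targets of
a regulator) is compared against every gene-set node with a one-tailed
Fisher's exact test over a declared gene universe.  Nodes whose overlap
p-value falls below a nominal threshold (default 1e-4, no
multiple-testing adjustment) receive a signature edge whose width is
−log10(p); the query itself becomes a triangle-shaped signature node,
visually distinct from the red/blue enrichment gradient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.stats import hypergeom

from .emap import EnrichmentMapNetwork
from .genesets import GeneSet, GeneSetCollection

__all__ = ["SignatureEdge", "query_overlap_test", "attach_signature"]


@dataclass(frozen=True)
class SignatureEdge:
    """A significant overlap between a query set and a map node."""

    query_id: str
    set_id: str
    p_fisher: float
    overlap_count: int
    overlap_genes: frozenset[str]
    width: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_fisher <= 1.0:
            raise ValueError(f"Fisher p must be in (0, 1], got {self.p_fisher}")
        if self.width < 0:
            raise ValueError("width must be non-negative")


def query_overlap_test(
    query: GeneSet,
    network: EnrichmentMapNetwork,
    collection: GeneSetCollection,
    universe=None,
    alpha: float = 1e-4,
    log_base: float = 10.0,
) -> list[SignatureEdge]:
    """One-tailed Fisher's exact overlap of ``query`` with every map node.

    ``universe`` defaults to the union of genes across the collection's
    sets (override with the experiment's gene list for more fidelity).
    The query is restricted to the universe first.  Edges are returned
    only for nominal ``p < alpha`` — no multiple-testing correction is
    applied, matching the post-analysis convention — with width
    ``−log10(p)`` (``log_base`` switches the logarithm).
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    universe = frozenset(universe) if universe is not None else collection.all_genes()
    if not universe:
        raise ValueError("universe must be non-empty")
    query_genes = query.genes & universe
    if not query_genes:
        raise ValueError(
            f"query set {query.set_id!r} is empty after universe restriction"
        )
    if len(query_genes) < query.size:
        warnings.warn(
            f"{query.size - len(query_genes)} query gene(s) outside the "
            f"universe were dropped",
            stacklevel=2,
        )

    N, m = len(universe), len(query_genes)
    edges = []
    for node in network.geneset_nodes():
        gs = collection.get(node.set_id)
        if gs is None:
            continue
        restricted = gs.genes & universe
        if not restricted:
            continue
        overlap = restricted & query_genes
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, len(restricted), m))
        p = min(max(p, 0.0), 1.0)
        if p < alpha:
            edges.append(
                SignatureEdge(
                    query_id=query.set_id,
                    set_id=node.set_id,
                    p_fisher=p,
                    overlap_count=k,
                    overlap_genes=frozenset(overlap),
                    width=-math.log(p, log_base),
                )
            )
    edges.sort(key=lambda e: e.set_id)
    return edges


def attach_signature(
    network: EnrichmentMapNetwork,
    query: GeneSet,
    edges: list[SignatureEdge],
) -> EnrichmentMapNetwork:
    """Add the query node and its signature edges to the map (in place).

    The query becomes a node with role ``signature`` and a triangle
    shape hint; edges carry role ``signature`` and a pink colour hint in
    exports.  Existing similarity edges and node significance
    attributes are never modified.  A query id colliding with an
    existing node id is an error; zero passing edges still add the node,
    with a warning.
    """
    from .emap import EMNode  # local import avoids a cycle at module load

    if query.set_id in network.nodes:
        raise ValueError(
            f"signature id {query.set_id!r} collides with an existing map node"
        )
    for e in edges:
        if e.query_id != query.set_id:
            raise ValueError(
                f"edge {e.query_id!r}->{e.set_id!r} does not belong to "
                f"query {query.set_id!r}"
            )
        if e.set_id not in network.nodes:
            raise ValueError(f"edge target {e.set_id!r} is not a map node")
    if not edges:
        warnings.warn(
            f"query set {query.set_id!r} has no significant overlap with any "
            f"map node; adding an isolated signature node",
            stacklevel=2,
        )
    network.nodes[query.set_id] = EMNode(
        set_id=query.set_id,
        label=query.description or query.set_id,
        size=query.size,
        role="signature",
        shape="triangle",
    )
    network.signature_edges.extend(edges)
    return network
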