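"""Enrichment-map assembly, visual encodings, layout, and export.

The enrichment map is a weighted similarity network over the gene-sets
that pass the significance filter: nodes are gene-sets, edges connect
pairs whose Jaccard or overlap coefficient meets the cutoff.  The
standard visual encodings are attached as plain attributes so any
viewer can render them:

* node size encodes the number of genes in the set;
* node colour encodes signed enrichment significance, from red
  (direction +1) through white (not significant) to blue (direction
  −1), with intensity ``1 − p``;
* edge thickness encodes the overlap coefficient.

Two datasets can share one map: each node carries two enrichment slots
(rendered as node centre and node border by viewers that support it),
and the node set is the union of sets significant in either dataset, so
condition-specific enrichment is visible.  A deterministic weighted
force-directed layout places overlapping sets close together.  Maps are
exported to GraphML (lossless, re-importable), SIF and node/edge TSV.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

import networkx as nx
import pandas as pd

from .enrichment import EnrichmentRecord, EnrichmentResult, filter_significant
from .genesets import GeneSetCollection
from .similarity import METRICS, SimilarityEdge, build_similarity_edges

logger = logging.getLogger(__name__)

__all__ = [
    "EMNode",
    "MapEdge",
    "EnrichmentMapNetwork",
    "EmptyMapError",
    "build_map",
    "color_score",
    "style_attributes",
    "layout",
    "export_graphml",
    "import_graphml",
    "export_tables",
]


class EmptyMapError(ValueError):
    """No gene-set passed the significance filter: there is nothing to map."""


@dataclass
class EMNode:
    """One map node: a gene-set with one or two enrichment slots.

    A slot keeps the dataset's *unfiltered* record (useful for tables
    and tooltips) together with a significance flag; the colour score of
    a non-significant slot is forced to 0 (white).  ``color_score`` is
    ``direction × (1 − p)`` in [−1, +1].
    """

    set_id: str
    label: str
    size: int
    slot1: EnrichmentRecord | None = None
    significant1: bool = False
    slot2: EnrichmentRecord | None = None
    significant2: bool = False
    color_score1: float = 0.0
    color_score2: float = 0.0
    x: float = 0.0
    y: float = 0.0
    display_size: float | None = None
    role: str = "geneset"
    shape: str = "ellipse"


@dataclass(frozen=True)
class MapEdge:
    """A similarity edge with its rendered width."""

    a: str
    b: str
    metric: str
    coefficient: float
    intersection_size: int
    width: float = 1.0


@dataclass
class EnrichmentMapNetwork:
    """Nodes, edges and provenance metadata of one enrichment map.

    Signature (query-set) nodes and edges added by post-analysis live
    beside the enrichment content: signature edges never alter the
    similarity edges or node significance attributes.
    """

    nodes: dict[str, EMNode] = field(default_factory=dict)
    edges: list[MapEdge] = field(default_factory=list)
    signature_edges: list = field(default_factory=list)  # list[SignatureEdge]
    metadata: dict = field(default_factory=dict)

    @property
    def n_datasets(self) -> int:
        return len(self.metadata.get("datasets", [])) or 1

    def geneset_nodes(self) -> list[EMNode]:
        return [n for n in self.nodes.values() if n.role == "geneset"]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EnrichmentMapNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and sorted(self.edges, key=lambda e: (e.a, e.b)) ==
            sorted(other.edges, key=lambda e: (e.a, e.b))
            and sorted(self.signature_edges, key=lambda e: (e.query_id, e.set_id)) ==
            sorted(other.signature_edges, key=lambda e: (e.query_id, e.set_id))
            and self.metadata == other.metadata
        )


def color_score(record: EnrichmentRecord | None, significant: bool = True) -> float:
    """Signed colour intensity ``direction × (1 − p)`` in [−1, +1].

    A missing or non-significant record maps to 0 (white); a one-class
    record (direction 0) is treated as direction +1, matching the
    white-to-red gradient of a single-phenotype analysis.
    """
    if record is None or not significant:
        return 0.0
    direction = record.direction if record.direction != 0 else 1
    return direction * (1.0 - record.p_value)


def build_map(
    results: EnrichmentResult | list[EnrichmentResult],
    collection: GeneSetCollection,
    metric: str = "overlap",
    cutoff: float = 0.5,
    p_max: float = 0.001,
    q_max: float = 0.05,
) -> EnrichmentMapNetwork:
    """Assemble the enrichment map for one or two datasets.

    The node set is the union over datasets of the gene-sets passing
    :func:`~enrichmap.enrichment.filter_significant` (union semantics:
    a set significant in only one dataset is included, its other slot
    marked not-significant).  Edges are the similarity edges among
    included nodes at the given metric and cutoff.  Significant ids
    that do not resolve in the collection are skipped with a warning
    and counted in the metadata.

    Raises :class:`EmptyMapError` when nothing is significant.
    """
    if isinstance(results, EnrichmentResult):
        results = [results]
    if not 1 <= len(results) <= 2:
        raise ValueError("build_map supports one or two datasets")
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")

    significant_ids: list[set[str]] = []
    unresolved: dict[str, int] = {}
    for res in results:
        sig = filter_significant(res, p_max=p_max, q_max=q_max)
        missing = [sid for sid in sig.records if sid not in collection]
        if missing:
            warnings.warn(
                f"{len(missing)} significant set id(s) from dataset "
                f"{res.dataset_name!r} not found in the collection; skipped",
                stacklevel=2,
            )
        unresolved[res.dataset_name] = len(missing)
        significant_ids.append(set(sig.records) - set(missing))

    union_ids = set().union(*significant_ids)
    # collection iteration order keeps the node ordering deterministic
    included = [gs.set_id for gs in collection if gs.set_id in union_ids]
    if not included:
        raise EmptyMapError(
            "no gene-set passed the significance filter "
            f"(p < {p_max}, q < {q_max}); nothing to map"
        )

    sub = GeneSetCollection(
        name=collection.name, sets=[collection[sid] for sid in included]
    )
    sim_edges = build_similarity_edges(sub, metric=metric, cutoff=cutoff)

    network = EnrichmentMapNetwork(
        metadata={
            "metric": metric,
            "cutoff": cutoff,
            "p_max": p_max,
            "q_max": q_max,
            "datasets": [res.dataset_name for res in results],
            "unresolved": unresolved,
        }
    )
    for sid in included:
        gs = collection[sid]
        node = EMNode(set_id=sid, label=gs.description or sid, size=gs.size)
        for i, res in enumerate(results, start=1):
            rec = res.records.get(sid)
            sig = rec is not None and sid in significant_ids[i - 1]
            setattr(node, f"slot{i}", rec)
            setattr(node, f"significant{i}", sig)
            setattr(node, f"color_score{i}", color_score(rec, sig))
        network.nodes[sid] = node
    network.edges = [
        MapEdge(
            a=e.a,
            b=e.b,
            metric=e.metric,
            coefficient=e.coefficient,
            intersection_size=e.intersection_size,
        )
        for e in sim_edges
    ]
    logger.info(
        "built map: %d node(s), %d edge(s) (metric=%s, cutoff=%s)",
        len(network.nodes),
        len(network.edges),
        metric,
        cutoff,
    )
    return network


def _affine(value: float, lo: float, hi: float, out_lo: float, out_hi: float) -> float:
    span = hi - lo
    if span <= 0:
        return (out_lo + out_hi) / 2.0
    return out_lo + (value - lo) / span * (out_hi - out_lo)


def style_attributes(
    network: EnrichmentMapNetwork,
    min_node_size: float = 20.0,
    max_node_size: float = 65.0,
    min_edge_width: float = 1.0,
    max_edge_width: float = 8.0,
) -> EnrichmentMapNetwork:
    """Attach display sizes and edge widths (monotone affine encodings).

    Node display size maps the map's gene-set size range onto
    [min_node_size, max_node_size]; edge width maps the coefficient from
    [cutoff, 1] onto [min_edge_width, max_edge_width].  Degenerate
    ranges (all nodes equal, or cutoff = 1) collapse to a single value.
    Signature-edge widths are −log p values owned by the post-analysis
    and are left untouched.
    """
    gnodes = network.geneset_nodes()
    if gnodes:
        sizes = [n.size for n in gnodes]
        lo, hi = min(sizes), max(sizes)
        for node in gnodes:
            node.display_size = _affine(node.size, lo, hi, min_node_size, max_node_size)
    cutoff = float(network.metadata.get("cutoff", 0.5))
    if cutoff >= 1.0:
        network.edges = [
            MapEdge(e.a, e.b, e.metric, e.coefficient, e.intersection_size,
                    width=max_edge_width)
            for e in network.edges
        ]
    else:
        network.edges = [
            MapEdge(
                e.a, e.b, e.metric, e.coefficient, e.intersection_size,
                width=_affine(e.coefficient, cutoff, 1.0,
                              min_edge_width, max_edge_width),
            )
            for e in network.edges
        ]
    return network


def layout(
    network: EnrichmentMapNetwork, seed: int = 42, iterations: int = 100
) -> EnrichmentMapNetwork:
    """Deterministic weighted force-directed layout.

    A Fruchterman–Reingold spring embedding in which the attractive
    force along an edge is scaled by its similarity coefficient, so
    strongly overlapping gene-sets are pulled together and clusters of
    related sets become spatially apparent.  Nodes without any edge
    (legitimate singleton map members) are placed on a grid below the
    connected component bounding box rather than being thrown around by
    pure repulsion.  Identical ``(seed, iterations)`` give identical
    coordinates.
    """
    if not network.nodes:
        raise ValueError("cannot lay out an empty network")
    graph = nx.Graph()
    graph.add_nodes_from(network.nodes)
    for e in network.edges:
        graph.add_edge(e.a, e.b, weight=e.coefficient)
    for se in network.signature_edges:
        graph.add_edge(se.query_id, se.set_id, weight=1.0)

    if len(graph) == 1:
        only = next(iter(network.nodes.values()))
        only.x, only.y = 0.0, 0.0
    else:
        connected = [n for n, d in graph.degree() if d > 0]
        singletons = [n for n, d in graph.degree() if d == 0]
        pos: dict[str, tuple[float, float]] = {}
        if connected:
            sub = graph.subgraph(connected)
            pos.update(
                nx.spring_layout(sub, weight="weight", seed=seed, iterations=iterations)
            )
        if singletons:
            if pos:
                xs = [p[0] for p in pos.values()]
                ys = [p[1] for p in pos.values()]
                x0, y0 = min(xs), min(ys) - 0.3
            else:
                x0, y0 = 0.0, 0.0
            cols = max(1, math.ceil(math.sqrt(len(singletons))))
            for i, sid in enumerate(singletons):
                pos[sid] = (x0 + 0.25 * (i % cols), y0 - 0.25 * (i // cols))
        for sid, (x, y) in pos.items():
            network.nodes[sid].x = float(x)
            network.nodes[sid].y = float(y)
    network.metadata["seed"] = int(seed)
    network.metadata["iterations"] = int(iterations)
    return network


# --- GraphML / table export ------------------------------------------------

_META_SCALARS = ("metric", "cutoff", "p_max", "q_max", "seed", "iterations")


def export_graphml(network: EnrichmentMapNetwork, path: str | PathLike[str]) -> None:
    """Write the map as GraphML 1.0 with all style and slot attributes.

    The export is lossless: :func:`import_graphml` reproduces the
    network exactly (missing q-values and empty slots are encoded by
    attribute absence).
    """
    graph = nx.Graph()
    for key in _META_SCALARS:
        if key in network.metadata:
            graph.graph[key] = network.metadata[key]
    for i, name in enumerate(network.metadata.get("datasets", []), start=1):
        graph.graph[f"dataset{i}"] = name
        graph.graph[f"unresolved{i}"] = int(
            network.metadata.get("unresolved", {}).get(name, 0)
        )

    for sid, node in network.nodes.items():
        attrs: dict = {
            "label": node.label,
            "size": int(node.size),
            "role": node.role,
            "shape": node.shape,
            "x": float(node.x),
            "y": float(node.y),
            "color_score1": float(node.color_score1),
            "color_score2": float(node.color_score2),
            "significant1": bool(node.significant1),
            "significant2": bool(node.significant2),
        }
        if node.display_size is not None:
            attrs["display_size"] = float(node.display_size)
        for i in (1, 2):
            rec: EnrichmentRecord | None = getattr(node, f"slot{i}")
            if rec is not None:
                attrs[f"p{i}"] = float(rec.p_value)
                attrs[f"direction{i}"] = int(rec.direction)
                if rec.q_value is not None:
                    attrs[f"q{i}"] = float(rec.q_value)
                if rec.score is not None:
                    attrs[f"score{i}"] = float(rec.score)
        graph.add_node(sid, **attrs)

    for e in network.edges:
        graph.add_edge(
            e.a,
            e.b,
            role="similarity",
            metric=e.metric,
            coefficient=float(e.coefficient),
            width=float(e.width),
            intersection_size=int(e.intersection_size),
        )
    for se in network.signature_edges:
        graph.add_edge(
            se.query_id,
            se.set_id,
            role="signature",
            color="pink",
            p_fisher=float(se.p_fisher),
            width=float(se.width),
            intersection_size=int(se.overlap_count),
            overlap_genes="|".join(sorted(se.overlap_genes)),
        )
    nx.write_graphml(graph, str(path))


def import_graphml(path: str | PathLike[str]) -> EnrichmentMapNetwork:
    """Read a map previously written by :func:`export_graphml`."""
    from .postanalysis import SignatureEdge  # local import avoids a cycle

    graph = nx.read_graphml(str(path))
    network = EnrichmentMapNetwork()
    meta = dict(graph.graph)
    datasets = []
    unresolved = {}
    for i in (1, 2):
        name = meta.pop(f"dataset{i}", None)
        count = meta.pop(f"unresolved{i}", None)
        if name is not None:
            datasets.append(name)
            unresolved[name] = int(count or 0)
    network.metadata = {k: meta[k] for k in _META_SCALARS if k in meta}
    network.metadata["datasets"] = datasets
    network.metadata["unresolved"] = unresolved

    for sid, attrs in graph.nodes(data=True):
        node = EMNode(
            set_id=sid,
            label=attrs.get("label", sid),
            size=int(attrs.get("size", 0)),
            color_score1=float(attrs.get("color_score1", 0.0)),
            color_score2=float(attrs.get("color_score2", 0.0)),
            significant1=bool(attrs.get("significant1", False)),
            significant2=bool(attrs.get("significant2", False)),
            x=float(attrs.get("x", 0.0)),
            y=float(attrs.get("y", 0.0)),
            display_size=(
                float(attrs["display_size"]) if "display_size" in attrs else None
            ),
            role=attrs.get("role", "geneset"),
            shape=attrs.get("shape", "ellipse"),
        )
        for i in (1, 2):
            if f"p{i}" in attrs:
                rec = EnrichmentRecord(
                    set_id=sid,
                    p_value=float(attrs[f"p{i}"]),
                    q_value=(
                        float(attrs[f"q{i}"]) if f"q{i}" in attrs else None
                    ),
                    direction=int(attrs[f"direction{i}"]),
                    score=(
                        float(attrs[f"score{i}"]) if f"score{i}" in attrs else None
                    ),
                )
                setattr(node, f"slot{i}", rec)
        network.nodes[sid] = node

    for a, b, attrs in graph.edges(data=True):
        if attrs.get("role") == "signature":
            query_id, set_id = (a, b) if network.nodes[a].role == "signature" else (b, a)
            genes = attrs.get("overlap_genes", "")
            network.signature_edges.append(
                SignatureEdge(
                    query_id=query_id,
                    set_id=set_id,
                    p_fisher=float(attrs["p_fisher"]),
                    overlap_count=int(attrs["intersection_size"]),
                    overlap_genes=frozenset(g for g in genes.split("|") if g),
                    width=float(attrs["width"]),
                )
            )
        else:
            x, y = (a, b) if a < b else (b, a)
            network.edges.append(
                MapEdge(
                    a=x,
                    b=y,
                    metric=attrs["metric"],
                    coefficient=float(attrs["coefficient"]),
                    intersection_size=int(attrs["intersection_size"]),
                    width=float(attrs["width"]),
                )
            )
    network.edges.sort(key=lambda e: (e.a, e.b))
    return network


def export_tables(network: EnrichmentMapNetwork, outdir: str | PathLike[str]) -> None:
    """Write node.tsv, edge.tsv and map.sif into ``outdir``.

    The SIF uses the relation ``overlaps`` for similarity edges and
    ``signature`` for query-set edges.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    node_rows = []
    for node in network.nodes.values():
        row = {
            "set_id": node.set_id,
            "label": node.label,
            "size": node.size,
            "role": node.role,
            "shape": node.shape,
            "x": node.x,
            "y": node.y,
            "display_size": node.display_size,
            "color_score1": node.color_score1,
            "color_score2": node.color_score2,
            "significant1": node.significant1,
            "significant2": node.significant2,
        }
        for i in (1, 2):
            rec = getattr(node, f"slot{i}")
            row[f"p{i}"] = rec.p_value if rec else None
            row[f"q{i}"] = rec.q_value if rec else None
            row[f"direction{i}"] = rec.direction if rec else None
        node_rows.append(row)
    pd.DataFrame(node_rows).to_csv(outdir / "node.tsv", sep="\t", index=False)

    edge_rows = [
        {
            "a": e.a,
            "b": e.b,
            "role": "similarity",
            "metric": e.metric,
            "coefficient": e.coefficient,
            "intersection_size": e.intersection_size,
            "width": e.width,
        }
        for e in network.edges
    ] + [
        {
            "a": se.query_id,
            "b": se.set_id,
            "role": "signature",
            "metric": "fisher",
            "coefficient": se.p_fisher,
            "intersection_size": se.overlap_count,
            "width": se.width,
        }
        for se in network.signature_edges
    ]
    pd.DataFrame(
        edge_rows,
        columns=["a", "b", "role", "metric", "coefficient",
                 "intersection_size", "width"],
    ).to_csv(outdir / "edge.tsv", sep="\t", index=False)

    with (outdir / "map.sif").open("w", encoding="utf-8") as fh:
        linked = set()
        for e in network.edges:
            fh.write(f"{e.a}\toverlaps\t{e.b}\n")
            linked.update((e.a, e.b))
        for se in network.signature_edges:
            fh.write(f"{se.query_id}\tsignature\t{se.set_id}\n")
            linked.update((se.query_id, se.set_id))
        for sid in network.nodes:
            if sid not in linked:
                fh.write(f"{sid}\n")
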