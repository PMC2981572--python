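"""Map assembly, visual encodings, layout, and export round trips."""

import itertools
import math
import xml.etree.ElementTree as ET

import numpy as np
import pytest

from enrichmap.emap import (
    EmptyMapError,
    build_map,
    color_score,
    export_graphml,
    export_tables,
    import_graphml,
    layout,
    style_attributes,
)
from enrichmap.enrichment import EnrichmentRecord
from enrichmap.genesets import GeneSetCollection

from .conftest import make_set, result_from


def components(network):
    """Connected components over similarity edges (frozensets of ids)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(n.set_id for n in network.geneset_nodes())
    g.add_edges_from((e.a, e.b) for e in network.edges)
    return {frozenset(c) for c in nx.connected_components(g)}


class TestBuildMap:
    def test_three_nodes_one_edge(self, small_collection, significant_result):
        net = build_map(significant_result, small_collection,
                        metric="overlap", cutoff=0.5)
        assert set(net.nodes) == {"S1", "S2", "S3"}
        assert [(e.a, e.b) for e in net.edges] == [("S1", "S2")]
        assert net.nodes["S1"].significant1

    def test_non_significant_records_excluded(self, small_collection):
        res = result_from(
            [
                EnrichmentRecord("S1", 1e-5, 0.01, 1),
                EnrichmentRecord("S2", 0.5, 0.8, 1),   # fails the filter
            ]
        )
        net = build_map(res, small_collection)
        assert set(net.nodes) == {"S1"}

    def test_zero_significant_raises_empty_map_error(self, small_collection):
        res = result_from([EnrichmentRecord("S1", 0.9, 0.9, 1)])
        with pytest.raises(EmptyMapError):
            build_map(res, small_collection)

    def test_unresolvable_ids_warned_and_counted(self, small_collection):
        res = result_from(
            [
                EnrichmentRecord("S1", 1e-5, 0.01, 1),
                EnrichmentRecord("GHOST", 1e-5, 0.01, 1),
            ]
        )
        with pytest.warns(UserWarning, match="not found"):
            net = build_map(res, small_collection)
        assert "GHOST" not in net.nodes
        assert net.metadata["unresolved"]["test"] == 1

    def test_two_dataset_union_semantics(self, small_collection):
        res1 = result_from([EnrichmentRecord("S1", 1e-5, 0.01, 1)], name="d1")
        res2 = result_from(
            [
                EnrichmentRecord("S1", 0.5, 0.9, 1),   # not significant in d2
                EnrichmentRecord("S3", 1e-4, 0.02, -1),
            ],
            name="d2",
        )
        net = build_map([res1, res2], small_collection)
        assert set(net.nodes) == {"S1", "S3"}
        node = net.nodes["S1"]
        assert node.significant1 and not node.significant2
        assert node.color_score2 == 0.0
        assert node.slot2 is not None  # unfiltered record kept for tables
        # S3 is significant only in dataset 2
        assert not net.nodes["S3"].significant1
        assert net.nodes["S3"].color_score2 == pytest.approx(-(1 - 1e-4))

    def test_swapping_datasets_exchanges_slots(self, small_collection):
        res1 = result_from([EnrichmentRecord("S1", 1e-5, 0.01, 1)], name="d1")
        res2 = result_from([EnrichmentRecord("S2", 1e-4, 0.02, -1)], name="d2")
        net_ab = build_map([res1, res2], small_collection)
        net_ba = build_map([res2, res1], small_collection)
        assert set(net_ab.nodes) == set(net_ba.nodes)
        assert [(e.a, e.b) for e in net_ab.edges] == [
            (e.a, e.b) for e in net_ba.edges
        ]
        for sid in net_ab.nodes:
            a, b = net_ab.nodes[sid], net_ba.nodes[sid]
            assert a.slot1 == b.slot2 and a.slot2 == b.slot1
            assert a.color_score1 == b.color_score2
            assert a.significant1 == b.significant2


class TestColorScore:
    @pytest.mark.parametrize(
        "p,direction,expected",
        [(0.0, 1, 1.0), (1.0, -1, 0.0), (0.001, -1, -0.999), (0.25, 0, 0.75)],
    )
    def test_formula(self, p, direction, expected):
        rec = EnrichmentRecord("S", p_value=p, direction=direction)
        assert color_score(rec) == pytest.approx(expected)

    def test_not_significant_maps_to_white(self):
        rec = EnrichmentRecord("S", p_value=0.5, direction=1)
        assert color_score(rec, significant=False) == 0.0
        assert color_score(None) == 0.0

    def test_odd_in_direction_and_decreasing_in_p(self):
        for p in np.linspace(0, 1, 11):
            up = color_score(EnrichmentRecord("S", p_value=float(p), direction=1))
            dn = color_score(EnrichmentRecord("S", p_value=float(p), direction=-1))
            assert up == -dn
        ps = np.linspace(0, 1, 11)
        scores = [
            color_score(EnrichmentRecord("S", p_value=float(p), direction=1))
            for p in ps
        ]
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestStyleAttributes:
    def _map_with_sizes(self, sizes, cutoff=0.5):
        sets = []
        pool = itertools.count()
        for i, n in enumerate(sizes):
            sets.append(make_set(f"S{i}", [f"g{next(pool)}" for _ in range(n)]))
        col = GeneSetCollection("c", sets)
        res = result_from(
            [EnrichmentRecord(f"S{i}", 1e-5, 0.01, 1) for i in range(len(sizes))]
        )
        return build_map(res, col, cutoff=cutoff)

    def test_node_size_endpoints(self):
        net = style_attributes(self._map_with_sizes([10, 100, 500]),
                               min_node_size=20, max_node_size=65)
        sizes = {n.set_id: n.display_size for n in net.geneset_nodes()}
        assert sizes["S0"] == 20 and sizes["S2"] == 65
        assert 20 < sizes["S1"] < 65

    def test_equal_sizes_degenerate_range(self):
        net = style_attributes(self._map_with_sizes([30, 30, 30]))
        display = {n.display_size for n in net.geneset_nodes()}
        assert len(display) == 1

    def test_edge_width_endpoints(self, parent_child):
        parent, child = parent_child
        other = make_set("OTHER", list(parent.genes)[:10])  # OC(other,parent)=1
        half = make_set(
            "HALF", list(child.genes)[:3] + ["h1", "h2", "h3"]
        )  # OC(half, child) = 3/6 = 0.5
        col = GeneSetCollection("c", [parent, child, other, half])
        res = result_from(
            [EnrichmentRecord(s, 1e-5, 0.01, 1)
             for s in ("PARENT", "CHILD", "OTHER", "HALF")]
        )
        net = style_attributes(
            build_map(res, col, cutoff=0.5),
            min_edge_width=1.0, max_edge_width=8.0,
        )
        widths = {(e.a, e.b): e.width for e in net.edges}
        coefs = {(e.a, e.b): e.coefficient for e in net.edges}
        for pair, c in coefs.items():
            if c == 1.0:
                assert widths[pair] == 8.0
            if c == 0.5:
                assert widths[pair] == 1.0
        # monotone in the coefficient
        ordered = sorted(coefs, key=coefs.get)
        assert all(
            widths[a] <= widths[b] for a, b in zip(ordered, ordered[1:])
        )


class TestLayout:
    def _two_cliques(self):
        cores = [[f"a{i}" for i in range(10)], [f"b{i}" for i in range(10)]]
        sets = []
        for tag, core in zip("AB", cores):
            for j in range(5):
                sets.append(make_set(f"{tag}{j}", core + [f"{tag}{j}_priv"]))
        col = GeneSetCollection("c", sets)
        res = result_from(
            [EnrichmentRecord(gs.set_id, 1e-5, 0.01, 1) for gs in sets]
        )
        return build_map(res, col, cutoff=0.5)

    def test_single_node_at_origin(self):
        col = GeneSetCollection("c", [make_set("S", "abc")])
        res = result_from([EnrichmentRecord("S", 1e-5, 0.01, 1)])
        net = layout(build_map(res, col))
        assert (net.nodes["S"].x, net.nodes["S"].y) == (0.0, 0.0)

    def test_same_seed_identical_coordinates(self):
        net1 = layout(self._two_cliques(), seed=7)
        net2 = layout(self._two_cliques(), seed=7)
        for sid in net1.nodes:
            assert net1.nodes[sid].x == net2.nodes[sid].x
            assert net1.nodes[sid].y == net2.nodes[sid].y

    def test_cliques_are_spatially_separated(self):
        net = layout(self._two_cliques(), seed=42)
        pos = {sid: (n.x, n.y) for sid, n in net.nodes.items()}

        def dist(u, v):
            return math.dist(pos[u], pos[v])

        within, between = [], []
        for u, v in itertools.combinations(pos, 2):
            (within if u[0] == v[0] else between).append(dist(u, v))
        assert np.mean(within) < np.mean(between)

    def test_singletons_placed_apart_from_connected_part(self, small_collection,
                                                         significant_result):
        net = layout(build_map(significant_result, small_collection), seed=1)
        # S3 has no edge; it must still get coordinates
        assert net.nodes["S3"].x is not None
        xy = {(round(n.x, 6), round(n.y, 6)) for n in net.nodes.values()}
        assert len(xy) == 3  # no two nodes on the same spot


class TestExport:
    def test_graphml_is_valid_xml_with_expected_counts(
        self, tmp_path, small_collection, significant_result
    ):
        net = layout(style_attributes(
            build_map(significant_result, small_collection)))
        path = tmp_path / "map.graphml"
        export_graphml(net, path)
        root = ET.parse(path).getroot()
        ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
        assert len(root.findall(".//g:node", ns)) == 3
        assert len(root.findall(".//g:edge", ns)) == 1

    def test_round_trip_reproduces_network(
        self, tmp_path, small_collection, significant_result
    ):
        net = layout(style_attributes(
            build_map(significant_result, small_collection)))
        path = tmp_path / "map.graphml"
        export_graphml(net, path)
        assert import_graphml(path) == net

    def test_two_dataset_round_trip(self, tmp_path, small_collection):
        res1 = result_from([EnrichmentRecord("S1", 1e-5, 0.01, 1)], name="d1")
        res2 = result_from([EnrichmentRecord("S3", 1e-4, None, -1)], name="d2")
        net = layout(style_attributes(build_map([res1, res2], small_collection)))
        path = tmp_path / "map2.graphml"
        export_graphml(net, path)
        back = import_graphml(path)
        assert back == net
        assert back.nodes["S3"].slot2.q_value is None

    def test_edgeless_map_exports_valid_graphml(self, tmp_path, small_collection):
        res = result_from([EnrichmentRecord("S3", 1e-5, 0.01, 1)])
        net = layout(style_attributes(build_map(res, small_collection)))
        path = tmp_path / "single.graphml"
        export_graphml(net, path)
        root = ET.parse(path).getroot()
        ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
        assert len(root.findall(".//g:edge", ns)) == 0
        assert import_graphml(path) == net

    def test_tables_written(self, tmp_path, small_collection, significant_result):
        net = layout(style_attributes(
            build_map(significant_result, small_collection)))
        export_tables(net, tmp_path)
        assert (tmp_path / "node.tsv").exists()
        assert (tmp_path / "edge.tsv").exists()
        sif = (tmp_path / "map.sif").read_text().splitlines()
        assert "S1\toverlaps\tS2" in sif
        assert "S3" in sif  # singleton listed on its own line
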