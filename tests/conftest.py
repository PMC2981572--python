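"""Shared fixtures: tiny hand-built collections and generated files.

All file fixtures are written into tmp_path at test time; nothing is
stored in the repository.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from enrichmap import (
    EnrichmentRecord,
    EnrichmentResult,
    GeneSet,
    GeneSetCollection,
)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_set(set_id: str, genes, description: str = "") -> GeneSet:
    return GeneSet(set_id, frozenset(genes), description)


def random_collection(rng: np.random.Generator, n_sets: int, universe_size: int,
                      min_size: int = 1, max_size: int = 30) -> GeneSetCollection:
    genes = [f"g{i}" for i in range(universe_size)]
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(min_size, max_size + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets.append(make_set(f"S{i}", members))
    return GeneSetCollection("random", sets)


@pytest.fixture
def abcd_pair():
    """The worked 4-vs-4 pair: |A∩B|=2, |A∪B|=6, min size 4."""
    return make_set("A", "abcd"), make_set("B", "cdef")


@pytest.fixture
def parent_child():
    """Strict subset pair: 5-gene child inside a 20-gene parent."""
    genes = [f"g{i}" for i in range(20)]
    return make_set("PARENT", genes), make_set("CHILD", genes[:5])


@pytest.fixture
def small_collection():
    """Three sets; S1/S2 overlap strongly, S3 is disjoint."""
    return GeneSetCollection(
        "tiny",
        [
            make_set("S1", ["a", "b", "c", "d"], "first"),
            make_set("S2", ["b", "c", "d", "e"], "second"),
            make_set("S3", ["x", "y", "z"], "third"),
        ],
    )


def result_from(records, name="test", universe=None) -> EnrichmentResult:
    res = EnrichmentResult(dataset_name=name, universe=universe)
    for rec in records:
        res.add(rec)
    return res


@pytest.fixture
def significant_result(small_collection):
    """All three tiny sets significant at the default thresholds."""
    return result_from(
        [
            EnrichmentRecord("S1", p_value=1e-5, q_value=0.001, direction=1),
            EnrichmentRecord("S2", p_value=2e-4, q_value=0.01, direction=1),
            EnrichmentRecord("S3", p_value=5e-4, q_value=0.02, direction=-1),
        ]
    )


GSEA_COLUMNS = [
    "NAME", "GS<br> follows gene set", "GS DETAILS", "SIZE", "ES", "NES",
    "NOM p-val", "FDR q-val", "FWER p-val", "RANK AT MAX", "LEADING EDGE",
]


def write_gsea_report(path, rows):
    """rows: list of (name, size, es, nes, p, q); p/q may be '' (blank)."""
    lines = ["\t".join(GSEA_COLUMNS)]
    for name, size, es, nes, p, q in rows:
        lines.append(
            "\t".join(
                [name, name, "Details ...", str(size), str(es), str(nes),
                 str(p), str(q), "0.1", "100", "tags=50%"]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def gsea_report_pair(tmp_path):
    """10 sets: 6 in the positive report, 4 in the negative one."""
    pos = write_gsea_report(
        tmp_path / "gsea_pos.tsv",
        [
            ("S1", 20, 0.8, 2.1, 0.002, 0.04),
            ("S2", 30, 0.7, 1.9, "", 0.01),       # blank p => below resolution
            ("S3", 15, 0.6, 1.7, 0.0005, 0.03),
            ("S4", 40, 0.5, 1.5, 0.01, 0.2),
            ("S5", 25, 0.4, 1.2, 0.2, 0.6),
            ("S6", 12, 0.3, 1.1, 0.5, 0.9),
        ],
    )
    neg = write_gsea_report(
        tmp_path / "gsea_neg.tsv",
        [
            ("S7", 18, -0.8, -2.0, 0.0002, 0.01),
            ("S8", 22, -0.6, -1.6, 0.05, 0.3),
            ("S9", 35, -0.5, -1.4, 0.3, 0.7),
            ("S10", 28, -0.4, -1.1, 0.9, 1.0),
        ],
    )
    return pos, neg
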