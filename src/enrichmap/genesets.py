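"""Gene-set domain model, GMT input/output, and filtering.

A gene-set is a named collection of gene identifiers: a GO term's
annotated genes, a pathway's members, an experimentally derived
signature.  Gene-sets are the nodes of an enrichment map; everything
downstream (similarity coefficients, Fisher tests, node sizes) is
computed on the sets as represented here.

The file dialect is the Broad/GSEA GMT format: one set per line,
``name<TAB>description<TAB>gene1<TAB>gene2...``, UTF-8, no header.
Windows line endings and trailing tabs are tolerated, since GMT files
produced by different tools vary in these details.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "GmtParseError",
    "DuplicateSetIdError",
    "read_gmt",
    "write_gmt",
    "filter_by_size",
    "restrict_to_universe",
]


class GmtParseError(ValueError):
    """A GMT line could not be parsed (fewer than 3 tab-separated fields)."""


class DuplicateSetIdError(ValueError):
    """Two gene-sets share the same identifier within one collection."""


@dataclass(frozen=True)
class GeneSet:
    """A named, unordered set of unique gene identifiers.

    Parameters
    ----------
    set_id
        Unique, non-empty identifier (e.g. ``GO:0005657``).
    genes
        Gene identifiers; duplicates are collapsed, empty strings rejected.
    description
        Free-text description; may be empty.
    """

    set_id: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.set_id:
            raise ValueError("gene-set id must be a non-empty string")
        genes = frozenset(self.genes)
        if not genes:
            raise ValueError(f"gene-set {self.set_id!r} has no genes")
        if "" in genes:
            raise ValueError(f"gene-set {self.set_id!r} contains an empty gene id")
        object.__setattr__(self, "genes", genes)

    @property
    def size(self) -> int:
        """Number of distinct genes, |X|."""
        return len(self.genes)

    def restricted(self, universe: frozenset[str]) -> GeneSet | None:
        """Intersect with ``universe``; ``None`` if nothing remains."""
        kept = self.genes & universe
        if not kept:
            return None
        return GeneSet(self.set_id, kept, self.description)


class GeneSetCollection:
    """An ordered mapping of ``set_id`` to :class:`GeneSet`.

    Iteration order is the insertion order (for file-backed collections,
    the order of lines in the source file), which keeps all downstream
    computations deterministic.  Identifiers are case-sensitive.
    """

    def __init__(self, name: str = "", sets: Iterable[GeneSet] = ()) -> None:
        self.name = name
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            self.add(gs)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.set_id in self._sets:
            raise DuplicateSetIdError(
                f"duplicate gene-set id {gene_set.set_id!r} in collection {self.name!r}"
            )
        self._sets[gene_set.set_id] = gene_set

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._sets

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._sets[set_id]

    def __eq__(self, other: object) -> bool:
        # Name is presentation-only; two collections are equal when they
        # hold the same sets in the same order.
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return list(self._sets) == list(other._sets) and all(
            self._sets[k] == other._sets[k] for k in self._sets
        )

    @property
    def set_ids(self) -> list[str]:
        return list(self._sets)

    def get(self, set_id: str) -> GeneSet | None:
        return self._sets.get(set_id)

    def all_genes(self) -> frozenset[str]:
        """Union of genes over all member sets."""
        out: set[str] = set()
        for gs in self._sets.values():
            out |= gs.genes
        return frozenset(out)

    def __repr__(self) -> str:
        return f"GeneSetCollection(name={self.name!r}, n_sets={len(self)})"


def read_gmt(path: str | PathLike[str], uppercase: bool = False) -> GeneSetCollection:
    """Read a GMT file into a :class:`GeneSetCollection`.

    Each line must carry at least three tab-separated fields
    (id, description, one or more genes).  Duplicate genes within a
    line are collapsed; empty trailing fields are ignored; blank lines
    are skipped.  ``uppercase=True`` normalises gene symbols to upper
    case (the GSEA convention).

    Raises
    ------
    GmtParseError
        For a line with fewer than three fields (the message names the
        1-based line number).
    DuplicateSetIdError
        If two lines declare the same set id.
    """
    path = Path(path)
    collection = GeneSetCollection(name=path.stem)
    with path.open("r", encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields (id, description, genes...), got {len(fields)}"
                )
            set_id, description, *genes = fields
            genes = [g for g in genes if g]
            if uppercase:
                genes = [g.upper() for g in genes]
            collection.add(GeneSet(set_id, frozenset(genes), description))
    return collection


def write_gmt(collection: GeneSetCollection, path: str | PathLike[str]) -> None:
    """Write a collection as GMT, genes in sorted order per line.

    Sorting makes the output a pure function of the collection's
    contents, so repeated writes are byte-identical.
    """
    if len(collection) == 0:
        raise ValueError("refusing to write an empty gene-set collection")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for gs in collection:
            fh.write("\t".join([gs.set_id, gs.description, *sorted(gs.genes)]) + "\n")


def filter_by_size(
    collection: GeneSetCollection, min_size: int = 10, max_size: int = 500
) -> GeneSetCollection:
    """Keep only sets with ``min_size <= |X| <= max_size`` (inclusive).

    The defaults discard sets annotating fewer than 10 or more than 500
    genes — very large sets rarely convey specific biology while very
    small ones are prone to spurious enrichment — and sizes 10 and 500
    themselves are kept.
    """
    if not (1 <= min_size <= max_size):
        raise ValueError(
            f"invalid size bounds: need 1 <= min_size <= max_size, "
            f"got ({min_size}, {max_size})"
        )
    kept = [gs for gs in collection if min_size <= gs.size <= max_size]
    return GeneSetCollection(name=collection.name, sets=kept)


def restrict_to_universe(
    collection: GeneSetCollection, universe: Iterable[str]
) -> GeneSetCollection:
    """Intersect every set with ``universe``; drop sets that become empty.

    Aligns gene-set definitions with the genes actually measured in an
    experiment before similarity or over-representation statistics are
    computed, so reported set sizes reflect testable genes only.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    kept = []
    for gs in collection:
        restricted = gs.restricted(universe)
        if restricted is not None:
            kept.append(restricted)
    return GeneSetCollection(name=collection.name, sets=kept)
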