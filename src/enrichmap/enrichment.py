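"""Enrichment-result parsing, significance filtering, and a Fisher mode.

An enrichment map is built from per-gene-set significance records.  Two
table dialects are read: the GSEA report pair (one tab-separated table
per phenotype, columns ``NAME .. NOM p-val FDR q-val ..``) and a generic
tab-separated table (``id, pvalue`` required; ``fdr``, ``direction``,
``description`` optional), so any enrichment tool's output can be used.

For naturally discrete gene lists, :func:`fisher_enrichment` provides a
one-tailed over-representation test (Fisher's exact test / the
hypergeometric tail) of a query list against every set in a collection,
with Benjamini–Hochberg FDR across the tested sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from os import PathLike
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSetCollection, restrict_to_universe

__all__ = [
    "EnrichmentRecord",
    "EnrichmentResult",
    "TableParseError",
    "read_gsea_reports",
    "read_generic_table",
    "write_generic_table",
    "filter_significant",
    "fisher_enrichment",
]

GSEA_REQUIRED_COLUMNS = ("NAME", "SIZE", "ES", "NES", "NOM p-val", "FDR q-val")


class TableParseError(ValueError):
    """An enrichment table is missing columns or carries unparseable cells."""


@dataclass(frozen=True)
class EnrichmentRecord:
    """One gene-set's enrichment outcome in one dataset.

    ``direction`` is +1 / −1 for the two phenotypes of a two-class
    analysis (the red/blue hue of the map) and 0 for one-class analyses.
    ``score`` carries the NES when GSEA-sourced.
    """

    set_id: str
    p_value: float
    q_value: float | None = None
    direction: int = 0
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.set_id:
            raise ValueError("record set_id must be non-empty")
        if not 0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value):
            raise ValueError(
                f"p-value for {self.set_id!r} outside [0, 1]: {self.p_value}"
            )
        if self.q_value is not None and (
            not 0.0 <= self.q_value <= 1.0 or math.isnan(self.q_value)
        ):
            raise ValueError(
                f"q-value for {self.set_id!r} outside [0, 1]: {self.q_value}"
            )
        if self.direction not in (-1, 0, 1):
            raise ValueError(f"direction must be -1, 0 or +1, got {self.direction}")


@dataclass
class EnrichmentResult:
    """All enrichment records of one dataset, keyed by set id.

    ``universe`` optionally records the gene population scored in the
    experiment (used to restrict sets before overlap statistics).
    """

    dataset_name: str
    records: dict[str, EnrichmentRecord] = field(default_factory=dict)
    universe: frozenset[str] | None = None

    def add(self, record: EnrichmentRecord) -> None:
        if record.set_id in self.records:
            raise TableParseError(
                f"duplicate record for set {record.set_id!r} "
                f"in dataset {self.dataset_name!r}"
            )
        self.records[record.set_id] = record

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.records


def _read_gsea_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GSEA_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableParseError(
            f"{path}: missing required GSEA report column(s): {', '.join(missing)}"
        )
    df["NAME"] = df["NAME"].astype(str)
    return df


def read_gsea_reports(
    pos_path: str | PathLike[str],
    neg_path: str | PathLike[str],
    dataset_name: str,
) -> EnrichmentResult:
    """Merge a GSEA report pair into one :class:`EnrichmentResult`.

    Rows from the positive-phenotype report get ``direction=+1``, rows
    from the negative one ``direction=-1``.  Empty p-value or q-value
    cells are parsed as 0.0: GSEA prints an empty cell when the
    permutation p is below its resolution (p < 1/#permutations), so
    these rows must always pass a significance filter.  A set appearing
    in both reports is a format error.
    """
    result = EnrichmentResult(dataset_name=dataset_name)
    for path, direction in ((Path(pos_path), 1), (Path(neg_path), -1)):
        df = _read_gsea_table(path)
        for _, row in df.iterrows():
            p = row["NOM p-val"]
            q = row["FDR q-val"]
            nes = row["NES"]
            result.add(
                EnrichmentRecord(
                    set_id=str(row["NAME"]),
                    p_value=0.0 if pd.isna(p) else float(p),
                    q_value=0.0 if pd.isna(q) else float(q),
                    direction=direction,
                    score=None if pd.isna(nes) else float(nes),
                )
            )
    return result


_ID_ALIASES = ("id", "name", "set_id", "geneset", "gs")
_P_ALIASES = ("pvalue", "p_value", "pval", "p")
_Q_ALIASES = ("fdr", "qvalue", "q_value", "qval", "q", "padj")
_DIR_ALIASES = ("direction", "phenotype", "class", "sign")


def _find_column(columns: list[str], aliases: tuple[str, ...]) -> str | None:
    lowered = {c.lower().strip(): c for c in columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    return None


def read_generic_table(
    path: str | PathLike[str], dataset_name: str
) -> EnrichmentResult:
    """Read a generic tab-separated enrichment table.

    Required columns (matched case-insensitively, common aliases
    accepted): ``id`` and ``pvalue``.  Optional: ``fdr`` (absent or
    blank -> no q-value), ``direction`` (+1/-1 integers or two phenotype
    labels, the first-seen label mapping to +1), ``description``.
    Rows with missing or non-numeric p-values are rejected with the
    offending file line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    id_col = _find_column(cols, _ID_ALIASES)
    p_col = _find_column(cols, _P_ALIASES)
    if id_col is None or p_col is None:
        raise TableParseError(
            f"{path}: generic table requires 'id' and 'pvalue' columns; found {cols}"
        )
    q_col = _find_column(cols, _Q_ALIASES)
    dir_col = _find_column(cols, _DIR_ALIASES)

    result = EnrichmentResult(dataset_name=dataset_name)
    label_map: dict[str, int] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based, after the header line
        raw_p = row[p_col]
        if pd.isna(raw_p) or str(raw_p).strip() == "":
            raise TableParseError(f"{path}: line {line}: missing p-value")
        try:
            p = float(raw_p)
        except ValueError:
            raise TableParseError(
                f"{path}: line {line}: non-numeric p-value {raw_p!r}"
            ) from None
        q: float | None = None
        if q_col is not None and not pd.isna(row[q_col]) and str(row[q_col]).strip():
            try:
                q = float(row[q_col])
            except ValueError:
                raise TableParseError(
                    f"{path}: line {line}: non-numeric FDR {row[q_col]!r}"
                ) from None
        direction = 0
        if dir_col is not None and not pd.isna(row[dir_col]) and str(row[dir_col]).strip():
            raw_d = str(row[dir_col]).strip()
            try:
                direction = int(float(raw_d))
            except ValueError:
                if raw_d not in label_map:
                    if len(label_map) >= 2:
                        raise TableParseError(
                            f"{path}: line {line}: more than two phenotype "
                            f"labels in direction column"
                        ) from None
                    label_map[raw_d] = 1 if not label_map else -1
                direction = label_map[raw_d]
        try:
            result.add(
                EnrichmentRecord(
                    set_id=str(row[id_col]), p_value=p, q_value=q, direction=direction
                )
            )
        except ValueError as exc:
            raise TableParseError(f"{path}: line {line}: {exc}") from None
    return result


def write_generic_table(result: EnrichmentResult, path: str | PathLike[str]) -> None:
    """Serialise a result to the generic TSV dialect (id, pvalue, fdr, direction)."""
    rows = []
    for rec in result.records.values():
        rows.append(
            {
                "id": rec.set_id,
                "pvalue": repr(rec.p_value),
                "fdr": "" if rec.q_value is None else repr(rec.q_value),
                "direction": rec.direction,
            }
        )
    pd.DataFrame(rows, columns=["id", "pvalue", "fdr", "direction"]).to_csv(
        path, sep="\t", index=False
    )


def filter_significant(
    result: EnrichmentResult, p_max: float = 0.001, q_max: float = 0.05
) -> EnrichmentResult:
    """Keep records with ``p < p_max`` and (q missing or ``q < q_max``).

    Both inequalities are strict, so a record sitting exactly on a
    threshold is removed.  The defaults are the conservative
    nominal-p < 0.001, FDR < 5% pair.  Idempotent.
    """
    for name, value in (("p_max", p_max), ("q_max", q_max)):
        if not (0.0 < value <= 1.0):
            raise ValueError(f"{name} must be in (0, 1], got {value}")
    kept = {
        sid: rec
        for sid, rec in result.records.items()
        if rec.p_value < p_max and (rec.q_value is None or rec.q_value < q_max)
    }
    return EnrichmentResult(
        dataset_name=result.dataset_name, records=kept, universe=result.universe
    )


def fisher_enrichment(
    query_genes,
    collection: GeneSetCollection,
    universe,
    dataset_name: str = "fisher",
) -> EnrichmentResult:
    """One-tailed over-representation test of a gene list against a collection.

    For each gene-set with restricted size ``n``, query size ``m``,
    universe size ``N`` and overlap ``k``, the p-value is the upper
    hypergeometric tail

        p = sum_{i=k}^{min(n, m)} C(n, i) C(N-n, m-i) / C(N, m),

    i.e. the probability of observing an overlap at least as large
    under random draws of ``m`` genes from the universe.  Sets are
    restricted to the universe first; query genes outside the universe
    are dropped with a warning.  Benjamini–Hochberg q-values are
    computed across all tested sets; records carry ``direction=0``
    (one-class analysis).
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    query = frozenset(query_genes)
    if not query:
        raise ValueError("query gene list must be non-empty")
    dropped = query - universe
    if dropped:
        warnings.warn(
            f"{len(dropped)} query gene(s) outside the universe were dropped",
            stacklevel=2,
        )
        query &= universe
    if not query:
        raise ValueError("query gene list is empty after universe restriction")

    restricted = restrict_to_universe(collection, universe)
    N, m = len(universe), len(query)
    set_ids, p_values = [], []
    for gs in restricted:
        k = len(gs.genes & query)
        # survival function at k-1 gives P(overlap >= k)
        p = float(hypergeom.sf(k - 1, N, gs.size, m))
        p_values.append(min(max(p, 0.0), 1.0))
        set_ids.append(gs.set_id)

    result = EnrichmentResult(dataset_name=dataset_name, universe=universe)
    if not set_ids:
        return result
    q_values = multipletests(p_values, method="fdr_bh")[1]
    for sid, p, q in zip(set_ids, p_values, q_values):
        result.add(
            EnrichmentRecord(set_id=sid, p_value=p, q_value=float(q), direction=0)
        )
    return result
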