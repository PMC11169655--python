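"""Readers, writers and identifier mapping for leukocyte expression atlases.

The atlas is a genes x cell-types table of normalized transcripts per
million (nTPM), as published for sorted immune-cell populations.  Two
on-disk dialects are supported:

``long_tsv``
    One row per (gene, cell type) pair, the dialect of the public
    immune-cell download.  Header columns default to ``Gene``,
    ``Gene name``, ``Immune cell`` and ``nTPM`` and can be renamed
    through :class:`LongDialectConfig` because the download's header
    has varied across releases.

``wide_tsv``
    One row per gene, one column per cell type.

Ranked age-associated gene lists (rank, symbol, optional id, optional
association Z-score, direction of change) are read from a small TSV
format, and :func:`map_genes` matches list entries to atlas rows by
stable identifier first and symbol second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionAtlas",
    "RankedGene",
    "RankedGeneList",
    "MappingReport",
    "LongDialectConfig",
    "AtlasFormatError",
    "read_atlas",
    "write_atlas",
    "read_ranked_genes",
    "write_ranked_genes",
    "map_genes",
]

DECREASE = "decrease"
INCREASE = "increase"

_DIRECTION_CODES = {
    "-": DECREASE,
    "-1": DECREASE,
    "down": DECREASE,
    "decrease": DECREASE,
    "decreased": DECREASE,
    "+": INCREASE,
    "1": INCREASE,
    "+1": INCREASE,
    "up": INCREASE,
    "increase": INCREASE,
    "increased": INCREASE,
}


class AtlasFormatError(ValueError):
    """Raised when an atlas or ranked-list file violates its format."""


@dataclass(frozen=True)
class LongDialectConfig:
    """Column names of the long-format atlas TSV."""

    gene_id: str = "Gene"
    gene_symbol: str = "Gene name"
    cell_type: str = "Immune cell"
    value: str = "nTPM"


@dataclass
class ExpressionAtlas:
    """Genes x cell types matrix of normalized expression (nTPM).

    Parameters
    ----------
    gene_ids
        Stable identifier per gene (Ensembl-style accession).
    gene_symbols
        Display symbol per gene, aligned with ``gene_ids``.
    cell_types
        Ordered cell-type labels (18 in the reference use case).
    values
        Nonnegative ``(n_genes, n_cell_types)`` array of nTPM.
    """

    gene_ids: list[str]
    gene_symbols: list[str]
    cell_types: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if len(self.gene_ids) != n or len(self.gene_symbols) != n:
            raise ValueError("gene identifier count does not match value rows")
        if len(self.cell_types) != m:
            raise ValueError("cell-type count does not match value columns")
        if len(set(self.gene_ids)) != n:
            raise ValueError("gene_ids must be unique")
        if len(set(self.cell_types)) != m:
            raise ValueError("cell_types must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("atlas values must be finite")
        if np.any(self.values < 0):
            raise ValueError("atlas values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame indexed by gene id, one column per cell type."""
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_types)


@dataclass(frozen=True)
class RankedGene:
    rank: int
    gene_symbol: str
    gene_id: str | None
    score: float | None
    direction: str


@dataclass
class RankedGeneList:
    """Age-associated genes ordered by strength-of-association rank."""

    entries: list[RankedGene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e.rank)
        ranks = [e.rank for e in self.entries]
        if len(set(ranks)) != len(ranks):
            raise ValueError("ranks must be unique")
        if ranks and ranks != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be contiguous from 1")
        scores = [e.score for e in self.entries if e.score is not None]
        if len(scores) == len(self.entries) and len(scores) > 1:
            if any(b > a for a, b in zip(scores, scores[1:])):
                raise ValueError("scores must be non-increasing with rank")
        for e in self.entries:
            if e.direction not in (DECREASE, INCREASE):
                raise ValueError(f"unknown direction {e.direction!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, i):
        return self.entries[i]

    @property
    def n_decrease(self) -> int:
        return sum(e.direction == DECREASE for e in self.entries)


@dataclass
class MappingReport:
    """Outcome of matching a ranked list against an atlas."""

    n_input: int
    n_mapped: int
    unmapped: list[tuple[str, str]]  # (symbol-or-id, reason)
    match_route: dict[int, str]  # rank -> by_id | by_symbol | unmatched

    def __post_init__(self) -> None:
        if self.n_mapped + len(self.unmapped) != self.n_input:
            raise ValueError("mapping report counts are inconsistent")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rank": rank, "route": route}
            for rank, route in sorted(self.match_route.items())
        ]
        return pd.DataFrame(rows, columns=["rank", "route"])

    def summary(self) -> str:
        pct = 100.0 * self.n_mapped / self.n_input if self.n_input else 0.0
        return (
            f"mapped {self.n_mapped} of {self.n_input} listed genes "
            f"({pct:.1f}%); {len(self.unmapped)} unmapped"
        )


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_atlas(
    path: str | Path,
    dialect: Literal["long_tsv", "wide_tsv"] = "long_tsv",
    long_config: LongDialectConfig | None = None,
) -> ExpressionAtlas:
    """Read an expression atlas TSV in either dialect.

    Long-format files may omit (gene, cell type) pairs with zero
    expression; missing pairs are filled with 0 and reported through a
    single :class:`UserWarning` carrying the fill count.  Duplicate
    pairs are an error — no silent aggregation.
    """
    if dialect == "long_tsv":
        return _read_long(path, long_config or LongDialectConfig())
    if dialect == "wide_tsv":
        return _read_wide(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_value(raw: str, row_number: int) -> float:
    try:
        v = float(raw)
    except ValueError:
        raise AtlasFormatError(
            f"non-numeric nTPM value {raw!r} at data row {row_number}"
        ) from None
    if not np.isfinite(v) or v < 0:
        raise AtlasFormatError(f"negative or non-finite nTPM at data row {row_number}")
    return v


def _read_long(path: str | Path, cfg: LongDialectConfig) -> ExpressionAtlas:
    df = _read_tsv(path)
    required = [cfg.gene_id, cfg.gene_symbol, cfg.cell_type, cfg.value]
    for col in required:
        if col not in df.columns:
            raise AtlasFormatError(f"missing required column {col!r} in atlas header")

    values = [_parse_value(raw, i + 1) for i, raw in enumerate(df[cfg.value])]
    df = df.assign(_value=values)

    dup = df.duplicated(subset=[cfg.gene_id, cfg.cell_type], keep=False)
    if dup.any():
        g = df.loc[dup, cfg.gene_id].iloc[0]
        c = df.loc[dup, cfg.cell_type].iloc[0]
        raise AtlasFormatError(f"duplicate (gene, cell type) pair: ({g!r}, {c!r})")

    # canonical ordering: first appearance order of genes and cell types
    gene_ids = list(dict.fromkeys(sorted(df[cfg.gene_id])))
    cell_types = list(dict.fromkeys(sorted(df[cfg.cell_type])))
    symbol_of = dict(zip(df[cfg.gene_id], df[cfg.gene_symbol]))

    wide = df.pivot(index=cfg.gene_id, columns=cfg.cell_type, values="_value")
    wide = wide.reindex(index=gene_ids, columns=cell_types)
    n_missing = int(wide.isna().to_numpy().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} missing (gene, cell type) pairs filled with 0",
            UserWarning,
            stacklevel=2,
        )
        wide = wide.fillna(0.0)

    return ExpressionAtlas(
        gene_ids=gene_ids,
        gene_symbols=[symbol_of[g] for g in gene_ids],
        cell_types=cell_types,
        values=wide.to_numpy(dtype=float),
    )


def _read_wide(path: str | Path) -> ExpressionAtlas:
    df = _read_tsv(path)
    for col in ("Gene", "Gene name"):
        if col not in df.columns:
            raise AtlasFormatError(f"missing required column {col!r} in atlas header")
    cell_types = [c for c in df.columns if c not in ("Gene", "Gene name")]
    if not cell_types:
        raise AtlasFormatError("wide atlas has no cell-type columns")
    if df["Gene"].duplicated().any():
        g = df.loc[df["Gene"].duplicated(), "Gene"].iloc[0]
        raise AtlasFormatError(f"duplicate gene id {g!r}")
    values = np.empty((len(df), len(cell_types)))
    for j, ct in enumerate(cell_types):
        for i, raw in enumerate(df[ct]):
            values[i, j] = _parse_value(raw, i + 1)
    # canonical gene order for order-invariance across dialects
    order = np.argsort(df["Gene"].to_numpy())
    return ExpressionAtlas(
        gene_ids=list(df["Gene"].to_numpy()[order]),
        gene_symbols=list(df["Gene name"].to_numpy()[order]),
        cell_types=cell_types,
        values=values[order],
    )


def _format_value(v: float) -> str:
    return repr(float(v))


def write_atlas(
    atlas: ExpressionAtlas,
    path: str | Path,
    dialect: Literal["long_tsv", "wide_tsv"] = "long_tsv",
    long_config: LongDialectConfig | None = None,
) -> None:
    """Write an atlas TSV; values are written with full precision so
    that read/write round-trips are exact."""
    path = Path(path)
    cfg = long_config or LongDialectConfig()
    with path.open("w", encoding="utf-8") as fh:
        if dialect == "long_tsv":
            fh.write("\t".join([cfg.gene_id, cfg.gene_symbol, cfg.cell_type, cfg.value]) + "\n")
            for i, gid in enumerate(atlas.gene_ids):
                for j, ct in enumerate(atlas.cell_types):
                    fh.write(
                        f"{gid}\t{atlas.gene_symbols[i]}\t{ct}\t"
                        f"{_format_value(atlas.values[i, j])}\n"
                    )
        elif dialect == "wide_tsv":
            fh.write("\t".join(["Gene", "Gene name", *atlas.cell_types]) + "\n")
            for i, gid in enumerate(atlas.gene_ids):
                row = [gid, atlas.gene_symbols[i]] + [
                    _format_value(v) for v in atlas.values[i]
                ]
                fh.write("\t".join(row) + "\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_ranked_genes(path: str | Path) -> RankedGeneList:
    """Read a ranked age-associated gene list TSV.

    Expected header: ``rank``, ``symbol``, optional ``id``, optional
    ``score``, ``direction``.  Direction may be coded as a sign
    (``-``/``+``, ``-1``/``1``) or as words (down/up,
    decrease/increase).
    """
    df = _read_tsv(path)
    for col in ("rank", "symbol", "direction"):
        if col not in df.columns:
            raise AtlasFormatError(f"missing required column {col!r} in ranked-list header")
    entries = []
    for i, row in df.iterrows():
        try:
            rank = int(row["rank"])
        except ValueError:
            raise AtlasFormatError(f"non-integer rank {row['rank']!r} at data row {i + 1}") from None
        code = str(row["direction"]).strip().lower()
        if code not in _DIRECTION_CODES:
            raise AtlasFormatError(
                f"unknown direction code {row['direction']!r} at data row {i + 1}"
            )
        score = None
        if "score" in df.columns and str(row["score"]).strip() != "":
            score = float(row["score"])
        gid = None
        if "id" in df.columns and str(row["id"]).strip() != "":
            gid = str(row["id"])
        entries.append(
            RankedGene(
                rank=rank,
                gene_symbol=str(row["symbol"]),
                gene_id=gid,
                score=score,
                direction=_DIRECTION_CODES[code],
            )
        )
    ranks = [e.rank for e in entries]
    if len(set(ranks)) != len(ranks):
        dup_rank = next(r for r in ranks if ranks.count(r) > 1)
        raise AtlasFormatError(f"duplicate rank {dup_rank}")
    return RankedGeneList(entries=entries)


def write_ranked_genes(genes: RankedGeneList, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("rank\tsymbol\tid\tscore\tdirection\n")
        for e in genes:
            score = "" if e.score is None else repr(float(e.score))
            gid = e.gene_id or ""
            fh.write(f"{e.rank}\t{e.gene_symbol}\t{gid}\t{score}\t{e.direction}\n")


def map_genes(
    genes: RankedGeneList | Sequence[RankedGene],
    atlas: ExpressionAtlas,
) -> tuple[dict[int, int], MappingReport]:
    """Match ranked-list entries to atlas rows.

    Each entry is matched first by gene id (exact), else by symbol
    (case-insensitive exact).  A symbol shared by several atlas genes is
    ambiguous and the entry is reported unmatched with reason
    ``ambiguous_symbol``.  Several list entries may map to the same
    atlas gene.

    Returns
    -------
    mapping
        ``{rank: atlas row index}`` for mapped entries, and the
        :class:`MappingReport`.
    """
    id_index = {gid: i for i, gid in enumerate(atlas.gene_ids)}
    symbol_rows: dict[str, list[int]] = {}
    for i, sym in enumerate(atlas.gene_symbols):
        symbol_rows.setdefault(sym.lower(), []).append(i)

    mapping: dict[int, int] = {}
    unmapped: list[tuple[str, str]] = []
    route: dict[int, str] = {}
    entries = list(genes)
    for e in entries:
        if e.gene_id is not None and e.gene_id in id_index:
            mapping[e.rank] = id_index[e.gene_id]
            route[e.rank] = "by_id"
            continue
        rows = symbol_rows.get(e.gene_symbol.lower(), [])
        if len(rows) == 1:
            mapping[e.rank] = rows[0]
            route[e.rank] = "by_symbol"
        elif len(rows) > 1:
            unmapped.append((e.gene_symbol, "ambiguous_symbol"))
            route[e.rank] = "unmatched"
        else:
            unmapped.append((e.gene_id or e.gene_symbol, "not_found"))
            route[e.rank] = "unmatched"

    report = MappingReport(
        n_input=len(entries),
        n_mapped=len(mapping),
        unmapped=unmapped,
        match_route=route,
    )
    return mapping, report
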