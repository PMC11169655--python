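"""Per-gene attribution of expression to cell types.

For gene *i* and cell type *j* the attribution fraction is

    x[i, j] = nTPM[i, j] / sum_j nTPM[i, j]

the share of the gene's total atlas expression contributed by that cell
type.  Attribution is a property of the reference atlas alone (it
involves no bulk mixture or deconvolution) and is invariant to any
per-gene rescaling of the nTPM row.  Genes with zero total expression
have no defined attribution and are excluded, not errored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas_io import ExpressionAtlas

__all__ = [
    "AttributionMatrix",
    "CombinedAttribution",
    "compute_attribution",
    "combined_attribution",
    "background_medians",
]


@dataclass
class AttributionMatrix:
    """Row-stochastic genes x cell-types matrix of attribution fractions."""

    gene_ids: list[str]
    gene_symbols: list[str]
    cell_types: list[str]
    x: np.ndarray
    excluded_genes: list[str]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.size:
            if np.any(self.x < -1e-12) or np.any(self.x > 1 + 1e-12):
                raise ValueError("attribution fractions must lie in [0, 1]")
            sums = self.x.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise ValueError("attribution rows must sum to 1 within 1e-9")
        if set(self.excluded_genes) & set(self.gene_ids):
            raise ValueError("excluded genes overlap retained genes")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def column(self, cell_type: str) -> np.ndarray:
        try:
            j = self.cell_types.index(cell_type)
        except ValueError:
            raise KeyError(f"unknown cell type {cell_type!r}") from None
        return self.x[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.x, index=self.gene_ids, columns=self.cell_types)


@dataclass
class CombinedAttribution:
    """Per-gene attribution summed over a subset of cell types."""

    gene_ids: list[str]
    subset: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.gene_ids) != len(self.values):
            raise ValueError("gene count does not match value count")

    def value_of(self, gene_id: str) -> float:
        return float(self.values[self.gene_ids.index(gene_id)])


def compute_attribution(atlas: ExpressionAtlas) -> AttributionMatrix:
    """Normalize each gene's nTPM row to the attribution fractions.

    Genes whose nTPM sums to zero across all cell types are moved to
    ``excluded_genes``; all retained rows sum to exactly 1 up to
    floating point.
    """
    totals = atlas.values.sum(axis=1)
    retained = totals > 0
    x = atlas.values[retained] / totals[retained, None]
    return AttributionMatrix(
        gene_ids=[g for g, keep in zip(atlas.gene_ids, retained) if keep],
        gene_symbols=[s for s, keep in zip(atlas.gene_symbols, retained) if keep],
        cell_types=list(atlas.cell_types),
        x=x,
        excluded_genes=[g for g, keep in zip(atlas.gene_ids, retained) if not keep],
    )


def combined_attribution(
    attr: AttributionMatrix, subset: Sequence[str]
) -> CombinedAttribution:
    """Sum attribution over a nonempty subset of cell-type columns."""
    subset = list(subset)
    if not subset:
        raise ValueError("cell-type subset must be nonempty")
    cols = []
    for label in subset:
        if label not in attr.cell_types:
            raise KeyError(f"unknown cell type {label!r}")
        cols.append(attr.cell_types.index(label))
    return CombinedAttribution(
        gene_ids=list(attr.gene_ids),
        subset=subset,
        values=attr.x[:, cols].sum(axis=1),
    )


def background_medians(attr: AttributionMatrix) -> pd.Series:
    """Median attribution fraction per cell type over all retained genes.

    The medians of a row-stochastic matrix's columns need not sum to 1.
    Even-count medians use the midpoint convention (mean of the two
    central order statistics).
    """
    if attr.n_genes == 0:
        raise ValueError("attribution matrix has no retained genes")
    return pd.Series(np.median(attr.x, axis=0), index=attr.cell_types)
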