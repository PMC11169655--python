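"""Model/results surface tying the pipeline together.

:class:`CellTypeAttribution` is built from an expression atlas and a
ranked age-associated gene list; :meth:`CellTypeAttribution.fit`
evaluates one gene set and returns an :class:`AttributionResults`
carrying the per-cell-type enrichment table, the direction-of-change
binomial test, and accessors for cumulative median curves, with a
``summary()`` in the style of a statistical results table.

>>> from leukattr import CellTypeAttribution, SimulationConfig
>>> from leukattr.synthetic_data import generate_atlas, generate_ranked_list
>>> cfg = SimulationConfig()
>>> atlas, truth = generate_atlas(cfg, seed=7)
>>> genes = generate_ranked_list(cfg, truth, seed=7)
>>> res = CellTypeAttribution(atlas, genes).fit("frac:0.5")
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas_io import (
    ExpressionAtlas,
    MappingReport,
    RankedGene,
    RankedGeneList,
    map_genes,
    read_atlas,
    read_ranked_genes,
)
from .attribution import (
    AttributionMatrix,
    CombinedAttribution,
    background_medians,
    combined_attribution,
    compute_attribution,
)
from .enrichment import (
    EnrichmentConfig,
    EnrichmentTable,
    enrichment_table,
)
from .rank_direction import (
    CumulativeMedianCurve,
    DirectionTestResult,
    GeneSetSpec,
    cumulative_median_curve,
    direction_test_for,
    select_gene_set,
)
from .synthetic_data import NAIVE_T_LABELS

__all__ = ["CellTypeAttribution", "AttributionResults"]


def _fmt_p(p: float) -> str:
    return f"{p:.1e}"


class CellTypeAttribution:
    """Attribute a ranked bulk-expression gene list to cell types.

    Parameters
    ----------
    atlas
        Reference expression atlas (genes x cell types, nTPM).
    ranked_genes
        Age-associated genes ordered by strength of association.
    naive_labels
        The cell-type labels treated as the naive T-cell subset for
        combined-attribution curves; defaults to the two naive T
        columns when present in the atlas.
    """

    def __init__(
        self,
        atlas: ExpressionAtlas,
        ranked_genes: RankedGeneList,
        naive_labels: Sequence[str] | None = None,
    ) -> None:
        self.atlas = atlas
        self.ranked_genes = ranked_genes
        self.attribution: AttributionMatrix = compute_attribution(atlas)
        # map against retained (post-exclusion) genes, so indices are
        # rows of the attribution matrix
        self.mapping, self.mapping_report = map_genes(ranked_genes, self.attribution)
        if naive_labels is None:
            present = [c for c in NAIVE_T_LABELS if c in atlas.cell_types]
            naive_labels = present if len(present) == 2 else ()
        self.naive_labels = list(naive_labels)
        self.background = background_medians(self.attribution)

    @classmethod
    def from_files(
        cls,
        atlas_path: str | Path,
        genes_path: str | Path,
        dialect: str = "long_tsv",
        naive_labels: Sequence[str] | None = None,
    ) -> "CellTypeAttribution":
        atlas = read_atlas(atlas_path, dialect=dialect)
        genes = read_ranked_genes(genes_path)
        return cls(atlas, genes, naive_labels=naive_labels)

    def combined(self, subset: Sequence[str] | None = None) -> CombinedAttribution:
        subset = list(subset) if subset else self.naive_labels
        if not subset:
            raise ValueError("no cell-type subset given and no naive labels found")
        return combined_attribution(self.attribution, subset)

    def fit(
        self,
        gene_set: GeneSetSpec | str = "frac:0.5",
        config: EnrichmentConfig | None = None,
    ) -> "AttributionResults":
        """Evaluate one gene set: enrichment per cell type plus the
        direction-of-change binomial test."""
        spec = GeneSetSpec.parse(gene_set) if isinstance(gene_set, str) else gene_set
        config = config or EnrichmentConfig()
        selected = select_gene_set(self.ranked_genes, spec)
        mapped_idx = [self.mapping[e.rank] for e in selected if e.rank in self.mapping]
        table = enrichment_table(
            self.attribution, mapped_idx, config, gene_set_name=spec.label
        )
        direction = direction_test_for(selected)
        return AttributionResults(
            model=self,
            spec=spec,
            selected=selected,
            mapped_indices=mapped_idx,
            table=table,
            direction=direction,
        )


@dataclass
class AttributionResults:
    """Results of fitting one gene set; see ``summary()``."""

    model: CellTypeAttribution
    spec: GeneSetSpec
    selected: list[RankedGene]
    mapped_indices: list[int]
    table: EnrichmentTable
    direction: DirectionTestResult
    _curves: dict = field(default_factory=dict, repr=False)

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    @property
    def n_mapped(self) -> int:
        return len(self.mapped_indices)

    def curve(
        self,
        subset: Sequence[str] | None = None,
        k_min: int = 5,
        k_max: int | None = None,
    ) -> CumulativeMedianCurve:
        """Cumulative median combined-attribution curve over the
        mapped genes of this set, in rank order."""
        combined = self.model.combined(subset)
        mapped_ranks = [e.rank for e in self.selected if e.rank in self.model.mapping]
        bg = float(np.median(combined.values))
        return cumulative_median_curve(
            mapped_ranks,
            self.model.mapping,
            combined,
            k_min=k_min,
            k_max=k_max,
            background_median=bg,
        )

    def set_median_combined(self, subset: Sequence[str] | None = None) -> float:
        """Median combined attribution (fraction) of the mapped set."""
        combined = self.model.combined(subset)
        vals = combined.values[self.mapped_indices]
        return float(np.median(vals))

    def direction_sentence(self) -> str:
        d = self.direction
        if d.p_two_tailed > 0.999 and d.k_decrease * 2 == d.n:
            return (
                f"no directional bias: {d.k_decrease} of {d.n} decreased "
                f"(p = {_fmt_p(d.p_two_tailed)})"
            )
        pct = 100.0 * d.proportion_decrease
        return (
            f"{d.k_decrease} of {d.n} ({pct:.0f}%) had decreased expression "
            f"with age, p = {_fmt_p(d.p_two_tailed)}"
        )

    def summary(self) -> str:
        """Human-readable results table."""
        buf = io.StringIO()
        report = self.model.mapping_report
        buf.write(f"Gene set: {self.table.gene_set_name} "
                  f"({self.n_selected} genes, {self.n_mapped} mapped)\n")
        buf.write(f"Test variant: {self.table.config.test_variant}\n")
        buf.write(f"List mapping: {report.summary()}\n\n")
        buf.write(
            f"{'Cell type':<24}{'Background %':>13}{'Set %':>9}"
            f"{'p':>10}{'p_adj':>10}  {'sig':<4}{'direction'}\n"
        )
        for r in self.table.rows:
            buf.write(
                f"{r.cell_type:<24}{r.background_median_pct:>13.2f}"
                f"{r.set_median_pct:>9.2f}{_fmt_p(r.p_raw):>10}"
                f"{_fmt_p(r.p_adjusted):>10}  {r.stars:<4}{r.direction}\n"
            )
        buf.write("\nDirection of change: " + self.direction_sentence() + "\n")
        elevated = self.table.significant("elevated")
        depleted = self.table.significant("depleted")
        if elevated:
            buf.write("Elevated: " + ", ".join(r.cell_type for r in elevated) + "\n")
        if depleted:
            buf.write("Depleted: " + ", ".join(r.cell_type for r in depleted) + "\n")
        return buf.getvalue()

    def to_frame(self) -> pd.DataFrame:
        return self.table.to_frame()
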