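"""Synthetic leukocyte atlases and ranked ageing-gene lists.

The generator reproduces the statistical structure the analysis
assumes, so every pipeline stage can be exercised without any download:

* Background genes get a cell-type composition drawn from a symmetric
  Dirichlet over the 18 leukocyte subtypes, so no cell type is special.
* A chosen number of "planted" genes are naive-T specific: a fixed
  share of their composition (``specificity_weight``, default 0.85)
  sits on the two naive T-cell columns, split evenly, with the
  remainder spread by Dirichlet over the other subtypes.
* Per-gene total expression is log-normal; nTPM is total x composition.
  Specificity is modeled at the composition level only, which is
  sufficient because attribution is scale-invariant.
* The ranked list's top 20 ranks are enriched for planted genes and
  predominantly marked as decreasing with age; scores decrease
  strictly with rank and are laid out so the half-maximum cutoff
  selects exactly the top 20.

A single seed drives both the atlas and the list through independent
sub-streams, so regenerating the list never perturbs the atlas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .atlas_io import (
    DECREASE,
    INCREASE,
    ExpressionAtlas,
    RankedGene,
    RankedGeneList,
    write_atlas,
    write_ranked_genes,
)

__all__ = [
    "TABLE1_CELL_TYPES",
    "NAIVE_T_LABELS",
    "SimulationConfig",
    "GroundTruth",
    "generate_atlas",
    "generate_ranked_list",
    "simulate_to_dir",
]

# The 18 sorted immune-cell populations of the reference atlas, so
# synthetic outputs are drop-in for the real-data path.
TABLE1_CELL_TYPES: tuple[str, ...] = (
    "Naive CD8 T-cell",
    "Naive CD4 T-cell",
    "Memory CD4 T-cell",
    "NK-cell",
    "Memory CD8 T-cell",
    "T-reg",
    "GdT-cell",
    "MAIT T-cell",
    "Naive B-cell",
    "Memory B-cell",
    "Neutrophil",
    "Basophil",
    "Plasmacytoid DC",
    "Non-classical monocyte",
    "Myeloid DC",
    "Classical monocyte",
    "Eosinophil",
    "Intermediate monocyte",
)

NAIVE_T_LABELS: tuple[str, str] = ("Naive CD4 T-cell", "Naive CD8 T-cell")

_TOP_WINDOW = 20  # ranks treated as "highly ranked"
_TOP_SCORE = 30.0  # synthetic Z-score of the rank-1 gene


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; the defaults define the study conditions.

    ``concentration_background`` is the symmetric Dirichlet
    concentration for nonspecific compositions (1.0 = uniform over the
    simplex).  ``expression_scale`` gives (meanlog, sdlog) of the
    log-normal per-gene total nTPM.  ``p_top_planted`` is the chance a
    top-20 rank is filled from the planted pool; ``p_decrease_top`` and
    ``p_decrease_rest`` set the decrease-with-age probability inside
    and below the top 20.
    """

    n_genes: int = 2000
    cell_types: tuple[str, ...] = TABLE1_CELL_TYPES
    naive_labels: tuple[str, str] = NAIVE_T_LABELS
    n_planted: int = 40
    concentration_background: float = 1.0
    specificity_weight: float = 0.85
    expression_scale: tuple[float, float] = (3.0, 1.5)
    list_length: int = 200
    p_top_planted: float = 0.9
    p_decrease_top: float = 0.85
    p_decrease_rest: float = 0.58

    def __post_init__(self) -> None:
        for p in (self.p_top_planted, self.p_decrease_top, self.p_decrease_rest):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.specificity_weight <= 1.0:
            raise ValueError("specificity_weight must lie in [0, 1]")
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted cannot exceed n_genes")
        if self.list_length > self.n_genes:
            raise ValueError("list_length cannot exceed n_genes")
        if self.concentration_background <= 0:
            raise ValueError("concentration_background must be positive")
        missing = set(self.naive_labels) - set(self.cell_types)
        if missing:
            raise ValueError(f"naive labels {missing} not among cell types")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValueError("cell-type labels must be unique")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    planted_gene_ids: list[str]
    profiles: np.ndarray  # n_genes x n_cell_types true compositions
    gene_ids: list[str]
    cell_types: tuple[str, ...]
    rank_planted: dict[int, bool] = field(default_factory=dict)
    rank_direction: dict[int, str] = field(default_factory=dict)


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    atlas_ss, list_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(atlas_ss), np.random.default_rng(list_ss)


def generate_atlas(
    config: SimulationConfig, seed: int
) -> tuple[ExpressionAtlas, GroundTruth]:
    """Draw a synthetic atlas; deterministic given ``(config, seed)``."""
    rng, _ = _streams(seed)
    n, m = config.n_genes, len(config.cell_types)
    naive_cols = [config.cell_types.index(lbl) for lbl in config.naive_labels]
    other_cols = [j for j in range(m) if j not in naive_cols]

    profiles = rng.dirichlet(np.full(m, config.concentration_background), size=n)
    planted_idx = np.arange(config.n_planted)  # ids are shuffled below
    w = config.specificity_weight
    for i in planted_idx:
        rest = rng.dirichlet(
            np.full(len(other_cols), config.concentration_background)
        )
        profile = np.zeros(m)
        for c in naive_cols:
            profile[c] = w / len(naive_cols)
        profile[other_cols] = (1.0 - w) * rest
        profiles[i] = profile

    meanlog, sdlog = config.expression_scale
    totals = rng.lognormal(mean=meanlog, sigma=sdlog, size=n)
    values = totals[:, None] * profiles

    # shuffle rows so planted genes are not a prefix of the id space
    order = rng.permutation(n)
    profiles = profiles[order]
    values = values[order]
    planted_mask = np.isin(order, planted_idx)

    gene_ids = [f"SYNG{i:08d}" for i in range(n)]
    gene_symbols = [f"GENE{i:05d}" for i in range(n)]
    atlas = ExpressionAtlas(
        gene_ids=gene_ids,
        gene_symbols=gene_symbols,
        cell_types=list(config.cell_types),
        values=values,
    )
    truth = GroundTruth(
        planted_gene_ids=[g for g, p in zip(gene_ids, planted_mask) if p],
        profiles=profiles,
        gene_ids=gene_ids,
        cell_types=config.cell_types,
    )
    return atlas, truth


def _scores(list_length: int) -> np.ndarray:
    """Strictly decreasing synthetic Z-scores whose half-maximum cutoff
    lands exactly after rank 20 (when the list is that long)."""
    k = np.arange(1, list_length + 1, dtype=float)
    top = min(_TOP_WINDOW, list_length)
    scores = np.empty(list_length)
    if top > 1:
        scores[:top] = _TOP_SCORE * 0.5 ** ((k[:top] - 1) / (top - 1))
    else:
        scores[:top] = _TOP_SCORE
    if list_length > top:
        tail = k[top:] - top
        scores[top:] = (_TOP_SCORE / 2.0) * 0.98 ** (tail + 1)
    return scores


def generate_ranked_list(
    config: SimulationConfig, truth: GroundTruth, seed: int
) -> RankedGeneList:
    """Draw the ranked ageing-gene list matching a ``generate_atlas``
    call with the same config and seed."""
    _, rng = _streams(seed)
    planted_pool = list(truth.planted_gene_ids)
    planted_set = set(planted_pool)
    background_pool = [g for g in truth.gene_ids if g not in planted_set]
    rng.shuffle(planted_pool)
    rng.shuffle(background_pool)

    symbol_of = {
        g: f"GENE{int(g[4:]):05d}" for g in truth.gene_ids
    }
    scores = _scores(config.list_length)
    entries: list[RankedGene] = []
    top = min(_TOP_WINDOW, config.list_length)
    for rank in range(1, config.list_length + 1):
        in_top = rank <= top
        take_planted = in_top and planted_pool and rng.random() < config.p_top_planted
        if take_planted:
            gid = planted_pool.pop()
        else:
            if not background_pool:
                raise ValueError("not enough distinct genes for the ranked list")
            gid = background_pool.pop()
        p_dec = config.p_decrease_top if in_top else config.p_decrease_rest
        direction = DECREASE if rng.random() < p_dec else INCREASE
        truth.rank_planted[rank] = gid in planted_set
        truth.rank_direction[rank] = direction
        entries.append(
            RankedGene(
                rank=rank,
                gene_symbol=symbol_of[gid],
                gene_id=gid,
                score=float(scores[rank - 1]),
                direction=direction,
            )
        )
    return RankedGeneList(entries=entries)


def simulate_to_dir(
    config: SimulationConfig, seed: int, out_dir: str | Path
) -> dict[str, Path]:
    """Generate atlas + ranked list and write them (plus ground truth)
    as TSV files; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    atlas, truth = generate_atlas(config, seed)
    genes = generate_ranked_list(config, truth, seed)

    atlas_path = out_dir / "atlas.tsv"
    genes_path = out_dir / "ranked_genes.tsv"
    truth_path = out_dir / "ground_truth.tsv"
    write_atlas(atlas, atlas_path, dialect="long_tsv")
    write_ranked_genes(genes, genes_path)
    with truth_path.open("w", encoding="utf-8") as fh:
        fh.write("gene_id\tplanted\n")
        planted = set(truth.planted_gene_ids)
        for g in truth.gene_ids:
            fh.write(f"{g}\t{int(g in planted)}\n")
    return {"atlas": atlas_path, "genes": genes_path, "truth": truth_path}
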