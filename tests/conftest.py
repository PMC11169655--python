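import numpy as np
import pytest

from leukattr import (
    CellTypeAttribution,
    ExpressionAtlas,
    SimulationConfig,
    generate_atlas,
    generate_ranked_list,
)

CELLS4 = ["Naive CD8 T-cell", "Naive CD4 T-cell", "Neutrophil", "Basophil"]


@pytest.fixture
def tiny_atlas() -> ExpressionAtlas:
    """3 genes x 4 cell types with hand-checkable values."""
    values = np.array(
        [
            [2.0, 1.0, 1.0, 0.0],
            [0.0, 0.0, 5.0, 0.0],
            [3.0, 3.0, 3.0, 3.0],
        ]
    )
    return ExpressionAtlas(
        gene_ids=["G1", "G2", "G3"],
        gene_symbols=["ALPHA", "BETA", "GAMMA"],
        cell_types=list(CELLS4),
        values=values,
    )


@pytest.fixture
def tiny_atlas_long_tsv(tmp_path, tiny_atlas):
    path = tmp_path / "atlas.tsv"
    lines = ["Gene\tGene name\tImmune cell\tnTPM"]
    for i, gid in enumerate(tiny_atlas.gene_ids):
        for j, ct in enumerate(tiny_atlas.cell_types):
            lines.append(
                f"{gid}\t{tiny_atlas.gene_symbols[i]}\t{ct}\t{tiny_atlas.values[i, j]}"
            )
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def default_sim():
    """One default-config synthetic dataset shared across tests."""
    cfg = SimulationConfig()
    atlas, truth = generate_atlas(cfg, seed=11)
    genes = generate_ranked_list(cfg, truth, seed=11)
    return cfg, atlas, truth, genes


@pytest.fixture(scope="session")
def default_model(default_sim):
    _, atlas, _, genes = default_sim
    return CellTypeAttribution(atlas, genes)
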