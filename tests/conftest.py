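import numpy as np
import pandas as pd
import pytest

from mifspace import (
    CellTable,
    GatingConfig,
    IntensityModel,
    Rect,
    RegionSpec,
    SceneSpec,
    gate_cells,
    generate_scene,
)

#: reduced marker panel for fast scene generation in tests that do not gate
SMALL_MODEL = IntensityModel.default(markers=("CD3", "CD8", "CD68"))


@pytest.fixture(scope="session")
def default_gating() -> GatingConfig:
    return GatingConfig.from_intensity_model()


def uniform_scene_spec(
    density: float = 1000.0,
    mixture: dict | None = None,
    side: float = 1000.0,
    seed: int = 0,
    **kwargs,
) -> SceneSpec:
    """One uniform square region; the workhorse test scene."""
    mixture = mixture or {"CTL": 1.0}
    region = RegionSpec(
        geometry=Rect(0.0, 0.0, side, side),
        cell_density=density,
        phenotype_mixture=mixture,
        niche_id=1,
    )
    return SceneSpec(roi_width=side, roi_height=side, regions=(region,), seed=seed, **kwargs)


def random_cell_table(n: int, seed: int, side: float = 1000.0, labels=("CTL", "Th", "Mac")) -> CellTable:
    """Bare CellTable with uniform coordinates and CSR phenotype labels
    (no intensity columns), for geometry-only tests."""
    rng = np.random.default_rng(seed)
    data = pd.DataFrame({
        "cell_id": np.arange(n),
        "x": rng.uniform(0, side, n),
        "y": rng.uniform(0, side, n),
        "phenotype": rng.choice(list(labels), n),
    })
    return CellTable(data=data, markers=(), case_id=f"rand_{seed}")


@pytest.fixture(scope="session")
def gated_mixed_scene(default_gating) -> CellTable:
    """A 1 mm², ~2000-cell gated scene with a realistic mixture."""
    mixture = {"CTL": 0.15, "Th": 0.10, "B": 0.05, "Mac": 0.10,
               "Endothelial": 0.05, "Other": 0.55}
    spec = uniform_scene_spec(density=2000.0, mixture=mixture, seed=42)
    return gate_cells(generate_scene(spec), default_gating)
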