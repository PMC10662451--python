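import numpy as np
import pytest

from fluxgap import (
    ForestType,
    LandscapeConfig,
    example_factor_table,
    generate_landscape,
)


def make_config(seed: int, size: int = 64, **overrides) -> LandscapeConfig:
    defaults = dict(grid_height=size, grid_width=size, peat_fraction=0.1, seed=seed)
    defaults.update(overrides)
    return LandscapeConfig(**defaults)


@pytest.fixture(scope="session")
def default_factors():
    return example_factor_table()


@pytest.fixture(scope="session")
def stack64():
    """One 64x64 landscape shared by read-only tests."""
    return generate_landscape(make_config(seed=11))


def random_stack(seed: int, size: int = 16, biome_count: int = 2):
    """Small fully random stack exercising every transition category."""
    cfg = make_config(
        seed=seed,
        size=size,
        biome_count=biome_count,
        nonforest_gain_prob=0.3,
        annual_loss_prob={
            ForestType.primary_old_growth: 0.02,
            ForestType.old_secondary: 0.05,
            ForestType.young_secondary: 0.05,
            ForestType.plantation_forest: 0.10,
            ForestType.tree_crop: 0.08,
            ForestType.nonforest: 0.0,
        },
        patch_density=0.05,
    )
    return generate_landscape(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20230)
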