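import numpy as np
import pytest

from mitoprofiler import profiling
from mitoprofiler.synthetic import (
    ScreenConfig,
    TargetEffect,
    generate_feature_table,
)


@pytest.fixture(scope="session")
def small_config() -> ScreenConfig:
    """A scaled-down screen: 6 targets x 2 siRNAs x 3 replicates, ~120
    cells per condition."""
    return ScreenConfig(n_targets=6, mean_cells_per_sirna=120, seed=7)


@pytest.fixture(scope="session")
def small_screen(small_config):
    return generate_feature_table(small_config)


@pytest.fixture(scope="session")
def default_screen():
    """The full default screen design (47 targets, ~700 cells/siRNA)."""
    cfg = ScreenConfig(seed=42)
    table, truth = generate_feature_table(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def default_screen_scores(default_screen):
    """Held-out leave-one-replicate-out scores for every readout of the
    default screen."""
    _, table, _ = default_screen
    out = {}
    for readout in ("morphology", "53bp1", "gh2ax", "p53", "edu"):
        scores, _ = profiling.crossvalidate(table, "MOCK", readout)
        out[readout] = scores
    return out


@pytest.fixture(scope="session")
def null_screen():
    """A screen with all effects zero (10 targets, ~700 cells/siRNA)."""
    eff = {f"TGT{i:02d}": TargetEffect() for i in range(10)}
    cfg = ScreenConfig(n_targets=10, mean_cells_per_sirna=700, seed=0,
                       effect_table=eff)
    return generate_feature_table(cfg)
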