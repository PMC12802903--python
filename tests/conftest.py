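import numpy as np
import pytest

from mirderep.simulate import MirnaFamily, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast two-group configuration with one planted miRNA family."""
    return SimulationConfig(
        n_genes=300,
        n_samples_per_group=4,
        groups=("control", "hom"),
        group_effect_scale={"control": 0.0, "hom": 1.0},
        mirna_families=(
            MirnaFamily("mirX", (("mirX-5p", "UAGCUUAUCAGACUGAUGUUGA"),), 0.5),
        ),
        seed=7,
    )
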