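import numpy as np
import pytest

from crmkit.motifs import PWMModel
from crmkit.synthetic import FixtureConfig, generate, make_fixture

UNIFORM_BG = np.full(4, 0.25)


def sharp_pwm(consensus: str, p: float = 0.9, background=None) -> PWMModel:
    """PWM with probability p on the consensus base in every column."""
    from crmkit.motifs import _CODE

    w = len(consensus)
    m = np.full((4, w), (1 - p) / 3)
    for j, b in enumerate(consensus):
        m[_CODE[b], j] = p
    return PWMModel(m, background=UNIFORM_BG if background is None else background)


@pytest.fixture(scope="session")
def tiny_config():
    """Small single-chromosome fixture: 6 TFs in 3 cooperative pairs."""
    return FixtureConfig(
        seed=1,
        n_chroms=1,
        chrom_length=150_000,
        n_tfs=6,
        n_cell_types=2,
        n_crms=25,
        peaks_per_dataset=30,
        cooperation_pairs=((0, 1), (2, 3), (4, 5)),
    )


@pytest.fixture(scope="session")
def tiny_fixture(tiny_config):
    return generate(tiny_config)


@pytest.fixture(scope="session")
def tiny_fixture_paths(tiny_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("tiny_fixture")
    paths, truth = make_fixture(tiny_config, outdir)
    return paths, truth
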