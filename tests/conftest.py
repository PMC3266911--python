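import numpy as np
import pytest

from oncoamp.integrate import GeneModel
from oncoamp.simulate import AmpliconSpec, SimConfig


def make_config(**overrides) -> SimConfig:
    """Small single-amplicon cohort; noise-free unless overridden."""
    defaults = dict(
        n_tumours=4,
        chrom_layout=(("17", 200, 2_000_000), ("2", 200, 2_000_000)),
        ploidy_dist=((2, 1.0),),
        amplicons=(
            AmpliconSpec(chrom="17", center=1_000_000, width=400_000,
                         copy_number=6, penetrance=1.0),
        ),
        lrr_sd=0.0,
        baf_sd=0.0,
        expr_sd=0.0,
        dosage_coupling=1.0,
        dosage_slope=1.0,
        seed=0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture
def noise_free_config() -> SimConfig:
    return make_config()


@pytest.fixture
def amplicon_genes() -> list[GeneModel]:
    """One gene inside the default amplicon, one outside, one on the control chromosome."""
    return [
        GeneModel(name="IN_AMP", chrom="17", start=950_000, end=1_050_000),
        GeneModel(name="OUT_AMP", chrom="17", start=100_000, end=200_000),
        GeneModel(name="CTRL", chrom="2", start=500_000, end=600_000),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
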