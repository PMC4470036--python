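import numpy as np
import pandas as pd
import pytest

from allelic_cna.annotation import make_annotation
from allelic_cna.model import RunConfig


@pytest.fixture(scope="session")
def small_annotation() -> pd.DataFrame:
    """Two 45-Mb chromosomes at ~25 kb spacing (3,600 probes)."""
    return make_annotation(n_probes=3600, chrom_sizes_mb={"1": 45, "2": 45})


@pytest.fixture(scope="session")
def genome_annotation() -> pd.DataFrame:
    """Desk-scale 22-autosome manifest (~5,000 probes)."""
    return make_annotation(n_probes=5000, include_x=False)


@pytest.fixture()
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
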