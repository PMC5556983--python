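import numpy as np
import pandas as pd
import pytest

from fragtx.core import TIME_POINTS, DomainHit, LocusRecord
from fragtx.simulate import SynthConfig, generate_dataset


def make_record(
    locus_id,
    start=5000,
    end=6000,
    scaffold_length=1_000_000,
    scaffold_id="scaffold_0001",
    domains=(),
    **kw,
):
    """Small helper: a LocusRecord with sane defaults for unit tests."""
    return LocusRecord(
        locus_id=locus_id,
        scaffold_id=scaffold_id,
        start=start,
        end=end,
        scaffold_length=scaffold_length,
        domain_hits=tuple(DomainHit(d, t) for d, t in domains),
        **kw,
    )


def make_matrix(profiles: dict[str, list[float]]) -> pd.DataFrame:
    """Expression matrix from locus -> 12 FPKM values."""
    df = pd.DataFrame.from_dict(profiles, orient="index", columns=list(TIME_POINTS))
    df.index.name = "locus_id"
    return df.astype(float)


@pytest.fixture(scope="session")
def zero_noise_dataset():
    return generate_dataset(SynthConfig(noise_sd=0.0, seed=1))


@pytest.fixture(scope="session")
def noisy_dataset():
    return generate_dataset(SynthConfig(noise_sd=0.1, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
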