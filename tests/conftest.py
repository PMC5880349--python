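import numpy as np
import pytest

from retpoise.synthdata import SimParams, gen_genome, gen_proseq_tracks
from retpoise.tracks import StrandTracks


SMALL = dict(chrom_length=400_000, n_genes=20, n_tres=12)


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    return SimParams(seed=7, **SMALL)


@pytest.fixture(scope="session")
def small_genome(small_params):
    return gen_genome(small_params)


@pytest.fixture(scope="session")
def small_tracks(small_genome, small_params):
    return gen_proseq_tracks(small_genome, "A", small_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_tracks(length: int = 10_000, chrom: str = "chr1",
                total_mapped: int | None = None) -> StrandTracks:
    """Empty strand tracks to plant reads into by hand."""
    plus = {chrom: np.zeros(length, dtype=np.int64)}
    minus = {chrom: np.zeros(length, dtype=np.int64)}
    return StrandTracks(plus=plus, minus=minus,
                        total_mapped=total_mapped or 1_000_000)
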