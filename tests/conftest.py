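import numpy as np
import pytest

from mustat import Dataset, filter_monomorphic


def make_random_dataset(
    rng: np.random.Generator,
    sample_count: int,
    snp_count: int,
    region_length: int | None = None,
    pattern_reuse: float = 0.3,
) -> Dataset:
    """Random polymorphic dataset with deliberate pattern duplication so the
    pool and the LD counters see repeated columns."""
    region_length = region_length or max(snp_count * 5, 10)
    positions = np.sort(rng.integers(1, region_length + 1, size=snp_count))
    n_base = max(2, int(snp_count * pattern_reuse))
    base = rng.integers(0, 2, size=(n_base, sample_count), dtype=np.uint8)
    genotypes = base[rng.integers(0, n_base, size=snp_count)]
    ds = Dataset(genotypes, positions, region_length)
    filtered, _ = filter_monomorphic(ds)
    return filtered


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_917)


@pytest.fixture
def small_dataset(rng) -> Dataset:
    return make_random_dataset(rng, sample_count=12, snp_count=120)
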