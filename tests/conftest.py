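import numpy as np
import pytest

from eigenstream import fixtures


@pytest.fixture
def micro_prefix(tmp_path):
    """The hand-constructed 6x10 micro dataset written as a text triple."""
    prefix = str(tmp_path / "micro")
    fixtures.write_micro_dataset(prefix)
    return prefix


@pytest.fixture
def micro():
    return fixtures.micro_dataset()


def random_fixture(seed, n_ind=None, with_sex_chroms=True):
    """A small random dataset with mixed populations, sexes and
    missingness, exercising every statistic."""
    rng = np.random.default_rng(seed)
    n_ind = int(rng.integers(4, 20)) if n_ind is None else n_ind
    n_pop1 = int(rng.integers(1, n_ind))
    chrom_counts = {1: int(rng.integers(5, 40)), 2: int(rng.integers(5, 40))}
    if with_sex_chroms:
        chrom_counts[23] = int(rng.integers(2, 10))
        chrom_counts[24] = int(rng.integers(2, 10))
    spec = fixtures.FixtureSpec(
        n_ind=n_ind,
        snp_per_chrom=chrom_counts,
        populations={"P1": n_pop1, "P2": n_ind - n_pop1},
        sex_proportions=(0.5, 0.4, 0.1),
        missing_rate_range=(0.0, 0.4),
        seed=int(rng.integers(0, 2**31)),
    )
    return fixtures.generate(spec)
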