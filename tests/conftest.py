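from __future__ import annotations

import numpy as np
import pytest

from stmaburden import GenomicInterval, SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20130085)


@pytest.fixture
def small_spec():
    """Compact synthetic study used by fast unit tests."""
    return SyntheticSpec(
        n_genes=200,
        n_chromosomes=2,
        chrom_length=20_000_000,
        n_case_cnvs=20,
        n_control_cnvs=40,
        planted_enrichment=1.5,  # compact geometry cannot realise larger folds
        rng_seed=11,
    )


def random_intervals(rng, n, chrom_length=10_000, n_chroms=2, max_len=2_000):
    """Random small-coordinate intervals for merge/coverage oracle checks."""
    out = []
    for i in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, chrom_length - 1))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, min(start + length, chrom_length), f"iv{i}"))
    return out
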