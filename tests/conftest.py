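from __future__ import annotations

import pytest

from zcrtools.synthetic_data import SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def study():
    """Default synthetic study (three samples, planted truth), noise on."""
    return generate_study(SyntheticConfig(), seed=11)


@pytest.fixture(scope="session")
def small_config():
    """A reduced layout for tests that regenerate data repeatedly."""
    return SyntheticConfig(
        chromosomes=[("chr1", 400_000), ("chr2", 200_000)],
        clusters=[],
        n_scattered_genes=30,
        n_gaps_per_chrom=2,
        n_positive=5,
        n_purifying=5,
        snv_per_kb=2.0,
        indel_per_kb=0.5,
    )
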