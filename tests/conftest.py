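import pytest

from swinecon import HerdConfig, generate_herd


@pytest.fixture(scope="session")
def default_herd():
    """Study-sized cohort: 4 groups x 8 litters of 9-13 piglets."""
    return generate_herd(HerdConfig(), seed=42)


@pytest.fixture(scope="session")
def big_herd():
    """~50k pigs per regime, for moment-recovery checks."""
    return generate_herd(HerdConfig(litters_per_group=2300), seed=7)
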