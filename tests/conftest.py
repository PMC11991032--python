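import pytest

from sstkit import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def truth_bundle():
    """The standard 100-record zero-noise truth set (50 SST / 20 ST / 30 decoy)."""
    return generate_dataset(SimConfig(n_sst=50, n_st=20, n_decoy=30), seed=42)


@pytest.fixture(scope="session")
def flagged_bundle():
    """Canonical SSTs plus planted misannotated variants of every flag class."""
    return generate_dataset(
        SimConfig(n_sst=30, n_st=0, n_decoy=0, n_misannotated_per_flag=4), seed=7
    )
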