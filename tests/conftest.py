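import pytest

from allelix.io_formats import SNV
from allelix.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort reused across read-only tests."""
    return simulate_cohort(SimConfig(seed=42, n_snvs=8000))


@pytest.fixture
def snv():
    return SNV(chrom="chr1", pos=1000, ref_allele="A", alt_allele="G",
               strain_id="s1", snv_id="snv1")
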