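import pytest

from precevo.cna import ArmTable
from precevo.synthetic import SimConfig, simulate_cohort, write_cohort
from precevo.variants import Variant


@pytest.fixture(scope="session")
def toy_arms():
    return ArmTable.toy()


def make_variant(chrom="1", pos=100, ref="A", alt="T", **kw):
    defaults = dict(tumor_depth=400, tumor_alt=100, callers=frozenset({"M2"}))
    defaults.update(kw)
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, **defaults)


@pytest.fixture()
def variant_factory():
    return make_variant


@pytest.fixture(scope="session")
def noiseless_cohort():
    return simulate_cohort(SimConfig.noiseless(n_patients=3, seed=5))


@pytest.fixture(scope="session")
def noiseless_cohort_dir(noiseless_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort_noiseless")
    write_cohort(noiseless_cohort, out)
    return out
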