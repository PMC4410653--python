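import numpy as np
import pytest

from varsim_lite import fixtures as fx
from varsim_lite.diploid import build_diploid
from varsim_lite.readsim import ReadSimParams, simulate_reads
from varsim_lite.sampling import SamplingSpec, resolve_truth, sample_variants

SEED = 1


@pytest.fixture(scope="session")
def smoke():
    """Default 1 x 100 kb fixture: reference, tracts, database, donor pool."""
    return fx.smoke_fixture(seed=SEED)


@pytest.fixture(scope="session")
def truth_set(smoke):
    """50 SNV + 20 indel + 5 SV phased truth set sampled from the database."""
    spec = SamplingSpec(n_snv=50, n_indel=20, n_del=2, n_ins=1, n_dup=1,
                        n_inv=1, seed=SEED)
    sampled = sample_variants(smoke.db, spec, smoke.reference)
    return resolve_truth(sampled, smoke.pool, np.random.default_rng((SEED, 1)),
                         smoke.reference)


@pytest.fixture(scope="session")
def genome(smoke, truth_set):
    return build_diploid(smoke.reference, truth_set)


@pytest.fixture(scope="session")
def sim_low(genome, tmp_path_factory):
    """A small error-free read simulation shared across tests."""
    out = tmp_path_factory.mktemp("sim_low")
    params = ReadSimParams(coverage=4.0, read_len=100, frag_mean=400,
                           frag_sd=60, sub_error_rate=0.0, seed=SEED)
    res = simulate_reads(genome, params, out / "reads")
    return res


@pytest.fixture(scope="session")
def sim_full(genome, tmp_path_factory):
    """The 50x error-free simulation used by the end-to-end checks."""
    out = tmp_path_factory.mktemp("sim_full")
    params = ReadSimParams(coverage=50.0, read_len=100, frag_mean=400,
                           frag_sd=60, sub_error_rate=0.0, seed=SEED)
    return simulate_reads(genome, params, out / "reads")


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
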