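import numpy as np
import pytest

import nanovdj as nv


@pytest.fixture(scope="session")
def db():
    """Synthetic 8V/3D/1J mini-locus used across the suite."""
    return nv.build_fixture_db(8, seed=11)


@pytest.fixture(scope="session")
def error_model():
    return nv.ErrorModel(sub_rate=0.03, ins_rate=0.03, del_rate=0.04)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def simulate_to_fastq(db, specs, n_reads, error_model, seed, path):
    """Simulate a sample and write its FASTQ; returns (reads, truths)."""
    reads, truths = nv.simulate_sample(db, specs, n_reads, error_model, rng_seed=seed)
    nv.write_fastq(reads, path)
    return reads, truths
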