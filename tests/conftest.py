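import numpy as np
import pytest

from longotu.records import SeqRecord


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture
def fastq_records():
    return [
        SeqRecord(id="r1", seq="ACGTACGT", quals=[40] * 8, technology="ccs",
                  sample_id="s1", passes=12),
        SeqRecord(id="r2", seq="TTTTAAAA", quals=[2, 10, 20, 30, 40, 50, 60, 93],
                  technology="ccs"),
        SeqRecord(id="r3", seq="ACGTNACG", quals=[30] * 8, technology="ccs"),
    ]


@pytest.fixture(scope="session")
def small_db():
    from longotu.mocksim import synth_reference_db

    return synth_reference_db(8, 5, seed=11)
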