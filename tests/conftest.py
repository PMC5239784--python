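import pytest

from vdjlineage import (SequenceRecord, SimConfig, simulate_repertoire,
                        synthetic_germline_database)


@pytest.fixture(scope="session")
def db():
    return synthetic_germline_database()


@pytest.fixture(scope="session")
def small_sim(db):
    """8 clones, 2 rounds of hypermutation each: 24 truth-annotated reads."""
    cfg = SimConfig(n_germline=8, n_rounds=2, seed=0)
    seqs, truth = simulate_repertoire(db, cfg)
    return seqs, truth


@pytest.fixture(scope="session")
def small_records(small_sim):
    seqs, _ = small_sim
    return [SequenceRecord(id=s.id, sequence=s.sequence) for s in seqs]
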