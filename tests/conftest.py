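import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from locrec import fixtures
from locrec.evidence import EvidenceRecord
from locrec.vocab import COMPARTMENTS

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# Small pools keep random corpora collision-rich, so dedup, publication
# pooling and pairwise logic are actually exercised.
PROTEIN_POOL = [f"AT1G{i:05d}" for i in range(8)]
PUB_POOL = [f"PUB{c}" for c in "abcdef"]


def evidence_records(max_size: int = 60, methods=("FP", "MS")):
    """Strategy: a list of evidence records over small id pools."""
    record = st.builds(
        EvidenceRecord,
        protein_id=st.sampled_from(PROTEIN_POOL),
        compartment=st.sampled_from(COMPARTMENTS),
        method=st.sampled_from(list(methods)),
        publication_id=st.sampled_from(PUB_POOL),
    )
    return st.lists(record, max_size=max_size)


def rec(pid, comp, method="FP", pub="PUBa"):
    """Shorthand record constructor for example-based tests."""
    return EvidenceRecord(pid, comp, method, pub)


@pytest.fixture(scope="session")
def table1():
    return fixtures.load_table1()


@pytest.fixture(scope="session")
def table2():
    return fixtures.load_table2()


@pytest.fixture(scope="session")
def headline():
    return fixtures.load_headline_counts()
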