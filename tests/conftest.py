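import pytest
from hypothesis import HealthCheck, settings

from complexome.io import ComplexDataset, ComplexRecord, Member

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(name, complexes, paralog_sets=()):
    """Build a dataset from {complex_id: iterable of protein ids}."""
    records = [
        ComplexRecord(cid, [Member(p, "protein") for p in sorted(set(members))])
        for cid, members in complexes.items()
    ]
    return ComplexDataset(name, records, [frozenset(s) for s in paralog_sets])


@pytest.fixture
def abc_dataset():
    return make_dataset("abc", {"C1": ["A", "B", "C"], "C2": ["B", "C", "D"]})


@pytest.fixture
def disjoint_dataset():
    return make_dataset("disjoint", {"C1": ["A", "B"], "C2": ["C", "D"]})
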