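import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aptamotif.preprocess import SequenceRecord

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def fig1_records():
    """The three worked-example inserts; serials follow count/lex ordering."""
    return [
        SequenceRecord(0, "ACCAG", 1),
        SequenceRecord(1, "ACTAG", 1),
        SequenceRecord(2, "AGCAG", 1),
    ]


def random_records(rng: np.random.Generator, n: int, max_len: int = 30):
    """Random distinct-insert record sets with random counts."""
    inserts = set()
    while len(inserts) < n:
        length = int(rng.integers(5, max_len + 1))
        inserts.add("".join("ACGT"[b] for b in rng.integers(0, 4, size=length)))
    ordered = sorted(inserts)
    return [
        SequenceRecord(i, ins, int(rng.integers(1, 6)))
        for i, ins in enumerate(ordered)
    ]
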