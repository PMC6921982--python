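"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import pytest
from hypothesis import HealthCheck, settings

from umidedup.encoding import EncodedUMI, encode
from umidedup.index.core import UMIFreqTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

ALPHABET = "ACGTN"


def char_hamming(a: str, b: str) -> int:
    """Character-by-character Hamming oracle; N is an ordinary fifth letter."""
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def make_table(counts: dict[str, int]) -> UMIFreqTable:
    return UMIFreqTable({encode(s): f for s, f in counts.items()})


def brute_remove_near(
    freqs: dict[str, int], alive: set[str], u: str, k: int, F: float
) -> set[str]:
    """Set-scan oracle for remove_near; mutates `alive` like the contract."""
    S = {v for v in alive if char_hamming(u, v) <= k and freqs[v] <= F}
    if u in alive:
        S.add(u)
    alive -= S
    return S


def random_umis(rng: random.Random, n: int, m: int, with_n: bool = True) -> list[str]:
    alphabet = ALPHABET if with_n else "ACGT"
    return ["".join(rng.choice(alphabet) for _ in range(m)) for _ in range(n)]


def random_table(rng: random.Random, n: int, m: int, max_f: int = 40) -> UMIFreqTable:
    seqs = set(random_umis(rng, n, m))
    return make_table({s: rng.randint(1, max_f) for s in seqs})


def canonical(result) -> tuple:
    """Backend-comparable canonical form of a GroupingResult."""
    return tuple(
        (g.representative.seq, tuple(sorted(u.seq for u in g.members)), g.total_frequency)
        for g in result.groups
    )


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)


@pytest.fixture
def bridging_table() -> UMIFreqTable:
    """AAAT bridges AAAA and AATT: d(AAAA, AATT) = 2 but both are 1 from AAAT."""
    return make_table({"AAAA": 10, "AAAT": 5, "AATT": 3})
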