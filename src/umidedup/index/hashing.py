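"""Hash-table index backends: combinations, subsequences and n-grams.

All three reduce a near-neighbor query to exact hash lookups:

* combinations — enumerate every sequence within k substitutions of the
  query and probe each against the UMI hash table;
* subsequences — replace every choice of k positions with a placeholder;
  two UMIs share a masked key iff they differ only inside the masked
  positions, so bin membership alone proves d <= k (no verification);
* n-grams — split each UMI into k+1 contiguous, non-overlapping grams; by
  the pigeonhole principle two UMIs within k edits share at least one gram
  at the same location, so the union of the query's gram bins is a complete
  candidate set, verified by one Hamming evaluation each.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import NamedTuple

from ..encoding import EncodedUMI, encode
from ..errors import InvalidSequenceError
from .core import NearNeighborIndex, UMIFreqTable

#: Default alphabet for combination generation; matches the simulator's.
ALPHABET = "ACGTN"

#: Placeholder for masked positions in subsequence keys (internal only).
PLACEHOLDER = "*"


class NgramKey(NamedTuple):
    """One of the k+1 positional grams of a UMI."""

    slot: int            # which gram, 0..k
    span: tuple[int, int]  # half-open [start, end) within the UMI
    gram: str            # the substring itself


def ngram_spans(length: int, k: int) -> list[tuple[int, int]]:
    """Half-open spans of the k+1 grams covering a length-M UMI.

    The first k grams have length floor(M/(k+1)); the last takes the
    remainder and may be slightly longer.
    """
    if length < k + 1:
        raise InvalidSequenceError(
            f"cannot split length {length} into {k + 1} non-empty grams"
        )
    base = length // (k + 1)
    spans = [(i * base, (i + 1) * base) for i in range(k)]
    spans.append((k * base, length))
    return spans


def split_ngrams(u: EncodedUMI, k: int) -> list[NgramKey]:
    """Split a UMI into its k+1 positional n-gram keys."""
    return [
        NgramKey(slot, (a, b), u.seq[a:b])
        for slot, (a, b) in enumerate(ngram_spans(u.length, k))
    ]


def mask_subsequences(u: EncodedUMI, k: int) -> set[str]:
    """All C(M, k) placeholder masks of a UMI with exactly k masked positions."""
    if k > u.length:
        raise InvalidSequenceError(
            f"cannot mask {k} positions of a length-{u.length} UMI"
        )
    s = u.seq
    out = set()
    for positions in combinations(range(u.length), k):
        chars = list(s)
        for p in positions:
            chars[p] = PLACEHOLDER
        out.add("".join(chars))
    return out


def generate_within(
    u: EncodedUMI, k: int, alphabet: str = ALPHABET
) -> set[EncodedUMI]:
    """Every sequence within k substitutions of u over the given alphabet.

    Includes u itself; cardinality is sum_{j<=k} C(M, j) (|alphabet|-1)^j
    when u's own letters all belong to the alphabet.
    """
    s = u.seq
    out = {u}
    for j in range(1, k + 1):
        for positions in combinations(range(u.length), j):
            choices = [[c for c in alphabet if c != s[p]] for p in positions]
            for letters in product(*choices):
                chars = list(s)
                for p, c in zip(positions, letters):
                    chars[p] = c
                out.add(encode("".join(chars)))
    return out


class _BinnedIndex(NearNeighborIndex):
    """Shared bin storage with lazy compaction of mostly-dead bins."""

    def __init__(self, table: UMIFreqTable, k: int):
        super().__init__(table, k)
        self.bins: dict = {}
        for u in self.freqs:
            for key in self._keys_of(u):
                self.bins.setdefault(key, []).append(u)

    def _keys_of(self, u: EncodedUMI):
        raise NotImplementedError

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def bin_sizes(self) -> list[int]:
        return [len(b) for b in self.bins.values()]

    def _scan_bin(self, key, visited: set[EncodedUMI]):
        """Yield unseen alive members of a bin, compacting if >half are dead."""
        members = self.bins.get(key)
        if not members:
            return
        alive = self.alive
        n_dead = 0
        for v in members:
            if v in alive:
                if v not in visited:
                    visited.add(v)
                    yield v
            else:
                n_dead += 1
        if 2 * n_dead > len(members):
            self.bins[key] = [v for v in members if v in alive]


class CombinationIndex(NearNeighborIndex):
    """Generate-and-probe: enumerate all variants within k edits, hash-probe."""

    backend_name = "combo"

    def __init__(self, table: UMIFreqTable, k: int, alphabet: str = ALPHABET):
        super().__init__(table, k)
        self.alphabet = alphabet

    def _collect(self, u: EncodedUMI, F: float) -> set[EncodedUMI]:
        return {
            v
            for v in generate_within(u, self.k, self.alphabet)
            if v in self.alive and self.freqs[v] <= F
        }


class SubsequenceIndex(_BinnedIndex):
    """Placeholder-mask inverted index; bin sharing proves d <= k."""

    backend_name = "subseq"

    def _keys_of(self, u: EncodedUMI):
        return mask_subsequences(u, self.k)

    def _collect(self, u: EncodedUMI, F: float) -> set[EncodedUMI]:
        visited: set[EncodedUMI] = set()
        out = set()
        freqs = self.freqs
        for key in mask_subsequences(u, self.k):
            for v in self._scan_bin(key, visited):
                if freqs[v] <= F:
                    out.add(v)
        return out


class NgramIndex(_BinnedIndex):
    """Positional n-gram inverted index; candidates verified by distance."""

    backend_name = "ngram"

    def _keys_of(self, u: EncodedUMI):
        return split_ngrams(u, self.k)

    def _collect(self, u: EncodedUMI, F: float) -> set[EncodedUMI]:
        visited: set[EncodedUMI] = set()
        out = set()
        k = self.k
        freqs = self.freqs
        for key in split_ngrams(u, k):
            for v in self._scan_bin(key, visited):
                if self._dist(u, v) <= k and freqs[v] <= F:
                    out.add(v)
        return out
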