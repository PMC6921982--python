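"""UMI frequency bookkeeping and the remove_near/contains index contract.

Deduplication is framed as queries on a dynamic, implicitly represented
graph G = (V, E) whose vertices are the N unique UMIs and whose edges join
UMIs within Hamming distance k.  Every index backend implements two
operations:

``remove_near(u, k, F)``
    Return the set S of all still-alive UMIs v with d(u, v) <= k and
    f(v) <= F.  The queried UMI u is always included in S if it is alive,
    regardless of its own frequency, and every member of S is marked removed
    before the call returns.

``contains(u)``
    True iff u was in the table and has not been returned by any
    remove_near call.

The frequency ceiling F exists for the directional grouping algorithm; the
other algorithms pass F = infinity.
"""

from __future__ import annotations

import math
from collections import Counter
from collections.abc import Iterable, Iterator, Mapping

from ..encoding import EncodedUMI, encode, hamming
from ..errors import InvalidQueryError, LengthMismatchError, UMIDedupError


class UMIFreqTable:
    """Map from unique UMI to its read frequency f(v).

    All keys share one length M; all frequencies are >= 1.  ``len(table)``
    is N, the number of unique UMIs.
    """

    def __init__(self, counts: Mapping[EncodedUMI, int]):
        length = None
        for u, f in counts.items():
            if length is None:
                length = u.length
            elif u.length != length:
                raise LengthMismatchError(
                    f"mixed UMI lengths in table: {length} and {u.length}"
                )
            if f < 1:
                raise UMIDedupError(f"non-positive frequency {f} for {u.seq}")
        self._counts: dict[EncodedUMI, int] = dict(counts)
        self._length = length

    @property
    def length(self) -> int | None:
        """UMI length M (None for an empty table)."""
        return self._length

    @property
    def total_reads(self) -> int:
        """Sum of all frequencies (number of input reads)."""
        return sum(self._counts.values())

    def __len__(self) -> int:
        return len(self._counts)

    def __iter__(self) -> Iterator[EncodedUMI]:
        return iter(self._counts)

    def __contains__(self, u: EncodedUMI) -> bool:
        return u in self._counts

    def __getitem__(self, u: EncodedUMI) -> int:
        return self._counts[u]

    def items(self):
        return self._counts.items()

    def keys(self):
        return self._counts.keys()


def count_umis(umis: Iterable[str]) -> UMIFreqTable:
    """Count occurrences of each unique UMI string into a frequency table."""
    counts: Counter[EncodedUMI] = Counter(encode(s) for s in umis)
    return UMIFreqTable(counts)


class NearNeighborIndex:
    """Base class implementing the contract bookkeeping shared by backends.

    Subclasses implement :meth:`_collect`, returning the alive UMIs within
    k edits of the query whose frequency is <= F.  This wrapper owns the
    alive-set, enforces the contract (u always returned if alive; every
    returned UMI marked removed), and keeps two instrumentation counters:

    ``hamming_evals``
        Number of Hamming distance evaluations performed by this backend.
    ``naive_scan_equivalent``
        Number of evaluations a naive linear scan would have performed on
        the same query trace (one per alive UMI per query) — exact, because
        grouping output and hence the query trace is backend-invariant.
    """

    backend_name = "abstract"

    def __init__(self, table: UMIFreqTable, k: int):
        if k < 0:
            raise InvalidQueryError(f"edit threshold k must be >= 0, got {k}")
        self.table = table
        self.k = k
        self.freqs: dict[EncodedUMI, int] = dict(table.items())
        self.alive: set[EncodedUMI] = set(self.freqs)
        self.hamming_evals = 0
        self.naive_scan_equivalent = 0
        self.queries = 0

    # -- contract ---------------------------------------------------------

    def contains(self, u: EncodedUMI) -> bool:
        return u in self.alive

    def remove_near(
        self, u: EncodedUMI, k: int, F: float = math.inf
    ) -> set[EncodedUMI]:
        if k != self.k:
            raise InvalidQueryError(
                f"index was built with k={self.k}, queried with k={k}"
            )
        if u not in self.freqs:
            raise InvalidQueryError(f"UMI {u.seq} was never in the table")
        self.queries += 1
        self.naive_scan_equivalent += len(self.alive)
        S = self._collect(u, F)
        if u in self.alive:
            S.add(u)
        self.alive -= S
        self._after_remove(S)
        return S

    @property
    def is_fresh(self) -> bool:
        """True iff no remove_near query has been issued yet."""
        return self.queries == 0

    # -- backend hooks ----------------------------------------------------

    def _collect(self, u: EncodedUMI, F: float) -> set[EncodedUMI]:
        raise NotImplementedError

    def _after_remove(self, removed: set[EncodedUMI]) -> None:
        """Optional backend bookkeeping after a batch removal."""

    def _dist(self, a: EncodedUMI, b: EncodedUMI) -> int:
        self.hamming_evals += 1
        return hamming(a, b)


class NaiveIndex(NearNeighborIndex):
    """Reference backend: linear scan over all alive UMIs, O(NM) per query.

    This is the oracle every accelerated backend is checked against.
    """

    backend_name = "naive"

    def _collect(self, u: EncodedUMI, F: float) -> set[EncodedUMI]:
        k = self.k
        out = set()
        for v in self.alive:
            if self._dist(u, v) <= k and self.freqs[v] <= F:
                out.add(v)
        return out
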