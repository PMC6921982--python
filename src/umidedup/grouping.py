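"""The three network-based UMI grouping algorithms.

All three are written purely against the remove_near/contains contract, so
any index backend can stand behind them without changing their output:

* cluster — connected components of the UMI graph; transitive expansion
  can "bridge" UMIs more than k apart through intermediates;
* adjacency — visit UMIs in decreasing frequency; each seed claims exactly
  its still-alive direct neighbors, no recursion;
* directional — like adjacency but expands recursively, admitting a
  neighbor v of u only when f(v) <= eps * (f(u) + 1); with the default
  eps = 0.5 this is the classic UMI-tools edge rule 2 f(v) - 1 <= f(u).

Recursive expansions use an explicit stack so a single huge component
cannot overflow the interpreter call stack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .encoding import EncodedUMI
from .errors import InvalidQueryError, InvalidStateError
from .index.core import NearNeighborIndex, UMIFreqTable


@dataclass(frozen=True)
class UMIGroup:
    """One deduplicated group: its members and consensus representative."""

    representative: EncodedUMI
    members: frozenset[EncodedUMI]
    total_frequency: int


@dataclass(frozen=True)
class GroupingResult:
    """Partition of the unique UMIs produced by one grouping algorithm."""

    groups: tuple[UMIGroup, ...]
    algorithm: str
    k: int
    epsilon: float | None = None

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def member_sets(self) -> list[frozenset[EncodedUMI]]:
        return [g.members for g in self.groups]


def directional_threshold(freq: int, epsilon: float) -> float:
    """Frequency ceiling for neighbors of a UMI with the given frequency.

    The single place the eps * (f + 1) rule lives; equivalent to requiring
    2 f(v) - 1 <= f(u) at eps = 0.5.
    """
    return epsilon * (freq + 1)


def select_representative(
    members: Iterable[EncodedUMI], table: UMIFreqTable
) -> EncodedUMI:
    """Highest-frequency member; ties broken by lexicographically smallest."""
    best = None
    best_f = -1
    for u in members:
        f = table[u]
        if f > best_f or (f == best_f and u.seq < best.seq):
            best, best_f = u, f
    if best is None:
        raise InvalidQueryError("cannot pick a representative of an empty group")
    return best


def _make_group(members: set[EncodedUMI], table: UMIFreqTable) -> UMIGroup:
    return UMIGroup(
        representative=select_representative(members, table),
        members=frozenset(members),
        total_frequency=sum(table[u] for u in members),
    )


def _check_fresh(index: NearNeighborIndex, table: UMIFreqTable) -> None:
    if not index.is_fresh or len(index.alive) != len(table):
        raise InvalidStateError(
            "grouping requires a fresh index built on the same table"
        )


def _finalize(groups, algorithm, k, epsilon=None) -> GroupingResult:
    groups.sort(key=lambda g: g.representative.seq)
    return GroupingResult(tuple(groups), algorithm, k, epsilon)


def cluster(
    table: UMIFreqTable, index: NearNeighborIndex, k: int
) -> GroupingResult:
    """Connected components: transitive expansion with no frequency ceiling."""
    _check_fresh(index, table)
    groups: list[UMIGroup] = []
    for u in sorted(table.keys(), key=lambda x: x.seq):
        if not index.contains(u):
            continue
        members: set[EncodedUMI] = set()
        stack = [u]
        while stack:
            x = stack.pop()
            found = index.remove_near(x, k, math.inf)
            for v in found:
                members.add(v)
                if v != x:
                    stack.append(v)
        groups.append(_make_group(members, table))
    return _finalize(groups, "cluster", k)


def adjacency(
    table: UMIFreqTable, index: NearNeighborIndex, k: int
) -> GroupingResult:
    """Decreasing-frequency seeds each claim their direct alive neighbors."""
    _check_fresh(index, table)
    groups: list[UMIGroup] = []
    for u in sorted(table.keys(), key=lambda x: (-table[x], x.seq)):
        if not index.contains(u):
            continue
        members = index.remove_near(u, k, math.inf)
        groups.append(_make_group(members, table))
    return _finalize(groups, "adjacency", k)


def directional(
    table: UMIFreqTable,
    index: NearNeighborIndex,
    k: int,
    epsilon: float = 0.5,
) -> GroupingResult:
    """Frequency-gated recursive expansion (the default algorithm)."""
    if not 0.0 <= epsilon <= 1.0:
        raise InvalidQueryError(f"epsilon must be in [0, 1], got {epsilon}")
    _check_fresh(index, table)
    groups: list[UMIGroup] = []
    for u in sorted(table.keys(), key=lambda x: (-table[x], x.seq)):
        if not index.contains(u):
            continue
        members: set[EncodedUMI] = set()
        stack = [u]
        while stack:
            x = stack.pop()
            ceiling = directional_threshold(table[x], epsilon)
            found = index.remove_near(x, k, ceiling)
            for v in found:
                members.add(v)
                if v != x:
                    stack.append(v)
        groups.append(_make_group(members, table))
    return _finalize(groups, "directional", k, epsilon)


ALGORITHMS = {
    "cluster": cluster,
    "adjacency": adjacency,
    "directional": directional,
}


def run_grouping(
    algorithm: str,
    table: UMIFreqTable,
    index: NearNeighborIndex,
    k: int,
    epsilon: float = 0.5,
) -> GroupingResult:
    """Dispatch by algorithm name; epsilon applies to directional only."""
    if algorithm == "directional":
        return directional(table, index, k, epsilon)
    try:
        fn = ALGORITHMS[algorithm]
    except KeyError:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}"
        ) from None
    return fn(table, index, k)
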