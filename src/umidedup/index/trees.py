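"""Tree index backends: trie, BK-tree, Fenwick-over-BK-trees, n-gram BK-trees.

All four share two pruning devices maintained per subtree:

* an *all-removed* flag — true only if every UMI below has been removed, so
  the whole subtree can be skipped;
* a *minimum alive frequency* — a subtree whose minimum exceeds the query
  ceiling F cannot contribute and is skipped.

The flags are best-effort hints refreshed along the paths each query
visits; staleness is always in the safe direction (a stale flag can only
fail to prune, never prune a live result), and correctness rests solely on
the shared alive-set owned by the contract wrapper.
"""

from __future__ import annotations

import math
from bisect import bisect_right

from ..encoding import EncodedUMI
from ..errors import InvalidSequenceError
from .core import NearNeighborIndex, UMIFreqTable
from .hashing import split_ngrams

_INF = math.inf

LETTERS = "ACGTN"
_LETTER_IDX = {c: i for i, c in enumerate(LETTERS)}


# ---------------------------------------------------------------------------
# Trie
# ---------------------------------------------------------------------------

class TrieNode:
    """Node of the UMI trie; leaves at depth M carry the UMI itself."""

    __slots__ = ("children", "umi", "min_freq", "all_removed")

    def __init__(self):
        self.children: list[TrieNode | None] | None = None
        self.umi: EncodedUMI | None = None
        self.min_freq: float = _INF
        self.all_removed = False


class TrieIndex(NearNeighborIndex):
    """Trie over the UMIs; queries descend with an edits-remaining budget.

    Children are iterated in fixed alphabet order A, C, G, T, N; a branch
    is abandoned when the budget is exhausted, the subtree is fully
    removed, or its minimum alive frequency exceeds F.
    """

    backend_name = "trie"

    def __init__(self, table: UMIFreqTable, k: int):
        super().__init__(table, k)
        self.root = TrieNode()
        for u, f in table.items():
            node = self.root
            node.min_freq = min(node.min_freq, f)
            for ch in u.seq:
                if node.children is None:
                    node.children = [None] * 5
                i = _LETTER_IDX[ch]
                child = node.children[i]
                if child is None:
                    child = TrieNode()
                    node.children[i] = child
                node = child
                node.min_freq = min(node.min_freq, f)
            node.umi = u

    @property
    def node_count(self) -> int:
        """Number of trie nodes, root included."""
        count = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            count += 1
            if node.children:
                stack.extend(c for c in node.children if c is not None)
        return count

    def _collect(self, u: EncodedUMI, F: float) -> set[EncodedUMI]:
        out: set[EncodedUMI] = set()
        root = self.root
        if not root.all_removed and root.min_freq <= F:
            self._dfs(root, 0, self.k, u.seq, F, out)
        return out

    def _dfs(self, node, depth, budget, qseq, F, out):
        if node.umi is not None:  # leaf at depth M
            w = node.umi
            if w in self.alive and w not in out and self.freqs[w] <= F:
                out.add(w)
            alive = w in self.alive and w not in out
            node.all_removed = not alive
            node.min_freq = self.freqs[w] if alive else _INF
            return
        target = qseq[depth]
        for i, child in enumerate(node.children):
            if child is None:
                continue
            cost = 0 if LETTERS[i] == target else 1
            if (
                budget >= cost
                and not child.all_removed
                and child.min_freq <= F
            ):
                self._dfs(child, depth + 1, budget - cost, qseq, F, out)
        # Refresh pruning hints from (possibly stale, safe) child values.
        removed = True
        mf = _INF
        for child in node.children:
            if child is not None and not child.all_removed:
                removed = False
                if child.min_freq < mf:
                    mf = child.min_freq
        node.all_removed = removed
        node.min_freq = mf


# ---------------------------------------------------------------------------
# BK-tree
# ---------------------------------------------------------------------------

class BKNode:
    """BK-tree node; child at key i is at Hamming distance exactly i."""

    __slots__ = ("umi", "children", "min_freq", "all_removed")

    def __init__(self, umi: EncodedUMI, freq: int):
        self.umi = umi
        self.children: dict[int, BKNode] = {}
        self.min_freq: float = freq
        self.all_removed = False


def bk_insert(root: BKNode | None, u: EncodedUMI, freq: int, dist) -> BKNode:
    """Insert a UMI, walking down by computed distance until a free slot.

    Returns the (possibly new) root.  Inserting a UMI already in the tree
    is an error: table keys are unique.
    """
    node = BKNode(u, freq)
    if root is None:
        return node
    cur = root
    while True:
        if cur.min_freq > freq:
            cur.min_freq = freq
        d = dist(cur.umi, u)
        if d == 0:
            raise InvalidSequenceError(f"duplicate UMI {u.seq} in BK-tree")
        nxt = cur.children.get(d)
        if nxt is None:
            cur.children[d] = node
            return root
        cur = nxt


class BKTree:
    """A BK-tree bound to an owning index (for distances, freqs, alive-set).

    Queries prune children outside the triangle-inequality window
    [d(c, u) - k, d(c, u) + k], fully removed subtrees, and subtrees whose
    minimum alive frequency exceeds F.
    """

    __slots__ = ("index", "root")

    def __init__(self, index: NearNeighborIndex):
        self.index = index
        self.root: BKNode | None = None

    def insert(self, u: EncodedUMI) -> None:
        idx = self.index
        self.root = bk_insert(self.root, u, idx.freqs[u], idx._dist)

    def collect(self, u: EncodedUMI, F: float, out: set[EncodedUMI]) -> None:
        root = self.root
        if root is not None and not root.all_removed and root.min_freq <= F:
            self._dfs(root, u, F, out)

    def _dfs(self, node: BKNode, u: EncodedUMI, F: float, out) -> None:
        idx = self.index
        k = idx.k
        w = node.umi
        d = idx._dist(w, u)
        if (
            d <= k
            and w in idx.alive
            and w not in out
            and idx.freqs[w] <= F
        ):
            out.add(w)
        lo, hi = d - k, d + k
        for i, child in node.children.items():
            if (
                lo <= i <= hi
                and not child.all_removed
                and child.min_freq <= F
            ):
                self._dfs(child, u, F, out)
        alive = w in idx.alive and w not in out
        removed = not alive
        mf = idx.freqs[w] if alive else _INF
        for child in node.children.values():
            if not child.all_removed:
                removed = False
                if child.min_freq < mf:
                    mf = child.min_freq
        node.all_removed = removed
        node.min_freq = mf

    def depths(self) -> list[int]:
        """Depth of every node (root = 1); empty tree -> empty list."""
        if self.root is None:
            return []
        out = []
        stack = [(self.root, 1)]
        while stack:
            node, depth = stack.pop()
            out.append(depth)
            stack.extend((c, depth + 1) for c in node.children.values())
        return out


def _build_order(table: UMIFreqTable) -> list[EncodedUMI]:
    """Insertion order: increasing frequency, ties by sequence.

    Low-frequency UMIs end up near the root so frequency pruning can cut
    whole subtrees during directional queries.
    """
    return sorted(table.keys(), key=lambda u: (table[u], u.seq))


class BKTreeIndex(NearNeighborIndex):
    """A single BK-tree over all UMIs."""

    backend_name = "bktree"

    def __init__(self, table: UMIFreqTable, k: int):
        super().__init__(table, k)
        self.tree = BKTree(self)
        for u in _build_order(table):
            self.tree.insert(u)

    @property
    def root(self) -> BKNode | None:
        return self.tree.root

    def _collect(self, u: EncodedUMI, F: float) -> set[EncodedUMI]:
        out: set[EncodedUMI] = set()
        self.tree.collect(u, F, out)
        return out


# ---------------------------------------------------------------------------
# Fenwick BK-trees
# ---------------------------------------------------------------------------

def prefix_decompose(r: int) -> list[int]:
    """Binary-indexed-tree node ids whose intervals tile [1, r] disjointly.

    Node t covers the rank interval [t - lowbit(t) + 1, t].
    """
    ids = []
    t = r
    while t > 0:
        ids.append(t)
        t -= t & -t
    return ids


class FenwickBKIndex(NearNeighborIndex):
    """Frequency-prefix index: a Fenwick tree whose nodes hold BK-trees.

    Distinct frequency values are rank-compressed; each UMI is inserted
    into the O(log N) Fenwick nodes covering its rank, and a query with
    ceiling F traverses only the BK-trees of the prefix decomposition of
    rank(F), i.e. exactly the UMIs with f(v) <= F.
    """

    backend_name = "fenwickbk"

    def __init__(self, table: UMIFreqTable, k: int):
        super().__init__(table, k)
        self.freq_values = sorted({f for f in self.freqs.values()})
        n_ranks = len(self.freq_values)
        self.trees: list[BKTree | None] = [None] * (n_ranks + 1)
        for u in _build_order(table):
            t = bisect_right(self.freq_values, self.freqs[u])  # rank, 1-based
            while t <= n_ranks:
                if self.trees[t] is None:
                    self.trees[t] = BKTree(self)
                self.trees[t].insert(u)
                t += t & -t

    def rank_of(self, F: float) -> int:
        """Largest rank whose frequency value is <= F (0 if none)."""
        if F == _INF:
            return len(self.freq_values)
        return bisect_right(self.freq_values, F)

    def decompose(self, F: float) -> list[int]:
        """Fenwick node ids visited for ceiling F."""
        return prefix_decompose(self.rank_of(F))

    def node_interval(self, t: int) -> tuple[int, int]:
        """Closed rank interval [a, b] covered by Fenwick node t."""
        return (t - (t & -t) + 1, t)

    def _collect(self, u: EncodedUMI, F: float) -> set[EncodedUMI]:
        out: set[EncodedUMI] = set()
        for t in self.decompose(F):
            tree = self.trees[t]
            if tree is not None:
                tree.collect(u, F, out)
        return out


# ---------------------------------------------------------------------------
# n-grams BK-trees
# ---------------------------------------------------------------------------

class NgramBKIndex(NearNeighborIndex):
    """Hybrid backend: one BK-tree per positional n-gram bin.

    Keeps the n-gram filter's candidate narrowing while replacing each
    bin's linear scan with a triangle-pruned BK-tree traversal.
    """

    backend_name = "ngrambk"

    def __init__(self, table: UMIFreqTable, k: int):
        super().__init__(table, k)
        self.bins: dict = {}
        for u in _build_order(table):
            for key in split_ngrams(u, k):
                tree = self.bins.get(key)
                if tree is None:
                    tree = self.bins[key] = BKTree(self)
                tree.insert(u)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def _collect(self, u: EncodedUMI, F: float) -> set[EncodedUMI]:
        out: set[EncodedUMI] = set()
        for key in split_ngrams(u, self.k):
            tree = self.bins.get(key)
            if tree is not None:
                tree.collect(u, F, out)
        return out
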