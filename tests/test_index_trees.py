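"""Trie, BK-tree, Fenwick-BK and n-gram-BK backends."""

import math

import pytest

from umidedup.encoding import encode, hamming
from umidedup.errors import InvalidSequenceError
from umidedup.index.trees import (
    BKTreeIndex,
    FenwickBKIndex,
    NgramBKIndex,
    TrieIndex,
    bk_insert,
    prefix_decompose,
)

from conftest import brute_remove_near, make_table, random_table

INF = math.inf

FIVE_UMIS_TRIE = {"AAAA": 4, "ATAA": 3, "CTGA": 9, "AAAT": 2, "ATTA": 7}
FIVE_UMIS_BK = ["ATAA", "AAAA", "CCGG", "AAAT", "ATTA"]


# -- trie -------------------------------------------------------------------

def test_trie_traversal_finds_umis_within_budget():
    idx = TrieIndex(make_table(FIVE_UMIS_TRIE), 1)
    found = idx._collect(encode("AAAG"), INF)
    assert {u.seq for u in found} == {"AAAA", "AAAT"}


def test_trie_second_identical_query_is_empty():
    idx = TrieIndex(make_table(FIVE_UMIS_TRIE), 1)
    S = idx.remove_near(encode("AAAA"), 1, INF)
    assert {u.seq for u in S} == {"AAAA", "AAAT", "ATAA"}
    assert not idx.contains(encode("AAAA"))
    assert idx._collect(encode("AAAG"), INF) == set()


def test_trie_node_count_small():
    # root + 4+4+4 distinct path nodes: A-A-A-A, A-A-A-T shares 3,
    # A-T-A-A shares 1, A-T-T-A shares 2, C-T-G-A shares 0
    idx = TrieIndex(make_table(FIVE_UMIS_TRIE), 1)
    assert idx.node_count == 1 + 4 + 1 + 3 + 2 + 4


# -- BK-tree ----------------------------------------------------------------

def test_bk_insert_reproduces_hand_simulated_tree():
    """Insertion walks down by distance until a free child slot.

    With order ATAA, AAAA, CCGG, AAAT, ATTA: AAAA attaches to the root at
    d=1 and CCGG at d=4; AAAT is d(ATAA, AAAT)=2 from the root whose slot 2
    is free, so it attaches directly to the root; ATTA (d=1 from root,
    occupied) recurses to AAAA and attaches there at d=2.
    """
    root = None
    freqs = {s: 1 for s in FIVE_UMIS_BK}
    for s in FIVE_UMIS_BK:
        root = bk_insert(root, encode(s), freqs[s], hamming)
    assert root.umi.seq == "ATAA"
    assert {d: c.umi.seq for d, c in root.children.items()} == {
        1: "AAAA",
        2: "AAAT",
        4: "CCGG",
    }
    aaaa = root.children[1]
    assert {d: c.umi.seq for d, c in aaaa.children.items()} == {2: "ATTA"}


def test_bk_insert_duplicate_rejected():
    root = bk_insert(None, encode("AAAA"), 1, hamming)
    with pytest.raises(InvalidSequenceError):
        bk_insert(root, encode("AAAA"), 1, hamming)


def test_bk_single_insert_becomes_root():
    root = bk_insert(None, encode("ACGT"), 5, hamming)
    assert root.umi.seq == "ACGT" and root.children == {}


def test_bk_tree_contains_exactly_the_table_keys(rng):
    table = random_table(rng, 80, 6)
    idx = BKTreeIndex(table, 1)
    collected = []
    stack = [idx.root]
    while stack:
        node = stack.pop()
        collected.append(node.umi)
        stack.extend(node.children.values())
    assert sorted(u.seq for u in collected) == sorted(u.seq for u in table.keys())


def test_bk_child_indices_equal_parent_distance(rng):
    table = random_table(rng, 100, 7)
    idx = BKTreeIndex(table, 2)
    stack = [idx.root]
    while stack:
        node = stack.pop()
        for d, child in node.children.items():
            assert hamming(node.umi, child.umi) == d
            stack.append(child)


def test_bk_query_on_five_umi_tree():
    table = make_table({s: f for s, f in zip(FIVE_UMIS_BK, (3, 9, 5, 2, 7))})
    idx = BKTreeIndex(table, 1)
    found = idx._collect(encode("AAAG"), INF)
    assert {u.seq for u in found} == {"AAAA", "AAAT"}


def test_bk_query_f0_returns_only_the_queried_umi():
    table = make_table({"AAAA": 5, "AAAT": 2})
    idx = BKTreeIndex(table, 1)
    S = idx.remove_near(encode("AAAA"), 1, 0)
    assert {u.seq for u in S} == {"AAAA"}


def test_triangle_pruning_never_loses_results(rng):
    """bk_query equals a linear scan of the tree's UMIs, under removals."""
    for k in (1, 2):
        table = random_table(rng, 120, 6)
        idx = BKTreeIndex(table, k)
        freqs = {u.seq: f for u, f in table.items()}
        alive = set(freqs)
        for q in rng.sample(sorted(freqs), 60):
            F = rng.choice([INF, 2, 8, 30])
            got = {u.seq for u in idx.remove_near(encode(q), k, F)}
            want = brute_remove_near(freqs, alive, q, k, F)
            assert got == want


# -- subtree pruning hints --------------------------------------------------

def _audit_bk_flags(node, alive, freqs):
    subtree = []
    stack = [node]
    while stack:
        n = stack.pop()
        subtree.append(n.umi)
        stack.extend(n.children.values())
    alive_freqs = [freqs[u] for u in subtree if u in alive]
    if node.all_removed:
        assert not alive_freqs
    if alive_freqs:
        assert node.min_freq <= min(alive_freqs)


def test_bk_flags_are_safe_hints(rng):
    table = random_table(rng, 90, 6)
    idx = BKTreeIndex(table, 1)
    for q in rng.sample([u.seq for u in table.keys()], 40):
        idx.remove_near(encode(q), 1, rng.choice([INF, 5]))
    stack = [idx.root]
    while stack:
        node = stack.pop()
        _audit_bk_flags(node, idx.alive, idx.freqs)
        stack.extend(node.children.values())


# -- Fenwick BK -------------------------------------------------------------

def test_prefix_decomposition_worked_example():
    """Frequencies 1..7, ceiling 5: nodes covering [1..4] and [5..5]."""
    seqs = ["AAAA", "CAAA", "GAAA", "TAAA", "NAAA", "ACAA", "AGAA"]
    table = make_table({s: i + 1 for i, s in enumerate(seqs)})
    idx = FenwickBKIndex(table, 1)
    ids = idx.decompose(5)
    assert sorted(idx.node_interval(t) for t in ids) == [(1, 4), (5, 5)]


def test_prefix_decomposition_tiles_disjointly():
    for r in range(0, 65):
        ids = prefix_decompose(r)
        intervals = sorted((t - (t & -t) + 1, t) for t in ids)
        covered = []
        for a, b in intervals:
            covered.extend(range(a, b + 1))
        assert covered == list(range(1, r + 1))


def test_fenwick_full_ceiling_covers_all_ranks(rng):
    table = random_table(rng, 50, 5)
    idx = FenwickBKIndex(table, 1)
    ids = idx.decompose(INF)
    ranks = set()
    for t in ids:
        a, b = idx.node_interval(t)
        ranks.update(range(a, b + 1))
    assert ranks == set(range(1, len(idx.freq_values) + 1))


def test_fenwick_membership_follows_update_path(rng):
    from bisect import bisect_right

    table = random_table(rng, 40, 5)
    idx = FenwickBKIndex(table, 1)
    n_ranks = len(idx.freq_values)
    for u, f in table.items():
        expected_nodes = []
        t = bisect_right(idx.freq_values, f)
        while t <= n_ranks:
            expected_nodes.append(t)
            t += t & -t
        holding = [
            t
            for t, tree in enumerate(idx.trees)
            if tree is not None and _tree_holds(tree, u)
        ]
        assert sorted(holding) == sorted(expected_nodes)


def _tree_holds(tree, u):
    stack = [tree.root] if tree.root else []
    while stack:
        node = stack.pop()
        if node.umi == u:
            return True
        stack.extend(node.children.values())
    return False


def test_fenwick_degenerate_equal_frequencies_matches_naive(rng):
    table = make_table({s.seq: 7 for s in random_table(rng, 30, 5).keys()})
    idx = FenwickBKIndex(table, 1)
    assert sum(1 for t in idx.trees if t is not None) <= 2
    freqs = {u.seq: f for u, f in table.items()}
    alive = set(freqs)
    for q in sorted(freqs):
        got = {u.seq for u in idx.remove_near(encode(q), 1, INF)}
        assert got == brute_remove_near(freqs, alive, q, 1, INF)


# -- n-gram BK --------------------------------------------------------------

def test_every_umi_sits_in_k_plus_1_ngram_bins(rng):
    for k in (1, 2):
        table = random_table(rng, 60, 9)
        idx = NgramBKIndex(table, k)
        membership = {u: 0 for u in table.keys()}
        for tree in idx.bins.values():
            stack = [tree.root] if tree.root else []
            while stack:
                node = stack.pop()
                membership[node.umi] += 1
                stack.extend(node.children.values())
        assert all(count == k + 1 for count in membership.values())


@pytest.mark.parametrize("backend_cls", [TrieIndex, BKTreeIndex, FenwickBKIndex, NgramBKIndex])
def test_tree_backend_replay_matches_oracle(backend_cls, rng):
    for k in (1, 2):
        table = random_table(rng, 70, 7)
        idx = backend_cls(table, k)
        freqs = {u.seq: f for u, f in table.items()}
        alive = set(freqs)
        queries = rng.sample(sorted(freqs), len(freqs))
        for q in queries:
            F = rng.choice([INF, 1, 4, 12, 33])
            got = {u.seq for u in idx.remove_near(encode(q), k, F)}
            assert got == brute_remove_near(freqs, alive, q, k, F)
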