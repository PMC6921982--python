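"""Structural statistics of index backends (bin counts, depths, nodes)."""

from __future__ import annotations

from .index import build_index
from .index.core import UMIFreqTable
from .index.hashing import _BinnedIndex
from .index.trees import BKTreeIndex, FenwickBKIndex, NgramBKIndex, TrieIndex


def backend_stats(table: UMIFreqTable, k: int, backend: str) -> dict[str, float]:
    """Build the named backend and report its structural statistics.

    Always includes ``n_umis``; bin-based backends add bin counts/sizes,
    tree-based backends add node counts or depth statistics.
    """
    index = build_index(backend, table, k)
    out: dict[str, float] = {"n_umis": len(table)}
    if isinstance(index, _BinnedIndex):
        sizes = index.bin_sizes()
        out["n_bins"] = index.n_bins
        out["avg_bin_size"] = sum(sizes) / len(sizes) if sizes else 0.0
        out["max_bin_size"] = max(sizes, default=0)
    elif isinstance(index, TrieIndex):
        out["nodes"] = index.node_count
    elif isinstance(index, BKTreeIndex):
        depths = index.tree.depths()
        out["avg_depth"] = sum(depths) / len(depths) if depths else 0.0
        out["max_depth"] = max(depths, default=0)
    elif isinstance(index, NgramBKIndex):
        out["n_bins"] = index.n_bins
        sizes = [len(t.depths()) for t in index.bins.values()]
        out["avg_bin_size"] = sum(sizes) / len(sizes) if sizes else 0.0
        out["max_bin_size"] = max(sizes, default=0)
    elif isinstance(index, FenwickBKIndex):
        out["n_trees"] = sum(1 for t in index.trees if t is not None)
        out["n_ranks"] = len(index.freq_values)
    return out
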