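"""Near-neighbor index backends implementing the remove_near/contains contract."""

from .core import NaiveIndex, NearNeighborIndex, UMIFreqTable, count_umis
from .hashing import (
    CombinationIndex,
    NgramIndex,
    NgramKey,
    SubsequenceIndex,
    generate_within,
    mask_subsequences,
    ngram_spans,
    split_ngrams,
)
from .trees import (
    BKNode,
    BKTree,
    BKTreeIndex,
    FenwickBKIndex,
    NgramBKIndex,
    TrieIndex,
    bk_insert,
    prefix_decompose,
)

#: Registry of all 8 backends by CLI name.
BACKENDS: dict[str, type[NearNeighborIndex]] = {
    "naive": NaiveIndex,
    "combo": CombinationIndex,
    "subseq": SubsequenceIndex,
    "trie": TrieIndex,
    "ngram": NgramIndex,
    "bktree": BKTreeIndex,
    "fenwickbk": FenwickBKIndex,
    "ngrambk": NgramBKIndex,
}


def build_index(backend: str, table: UMIFreqTable, k: int, **kwargs) -> NearNeighborIndex:
    """Build the named backend over a frequency table with edit threshold k."""
    try:
        cls = BACKENDS[backend]
    except KeyError:
        raise ValueError(
            f"unknown backend {backend!r}; choose from {sorted(BACKENDS)}"
        ) from None
    return cls(table, k, **kwargs)


__all__ = [
    "BACKENDS",
    "BKNode",
    "BKTree",
    "BKTreeIndex",
    "CombinationIndex",
    "FenwickBKIndex",
    "NaiveIndex",
    "NearNeighborIndex",
    "NgramBKIndex",
    "NgramIndex",
    "NgramKey",
    "SubsequenceIndex",
    "TrieIndex",
    "UMIFreqTable",
    "bk_insert",
    "build_index",
    "count_umis",
    "generate_within",
    "mask_subsequences",
    "ngram_spans",
    "prefix_decompose",
    "split_ngrams",
]
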