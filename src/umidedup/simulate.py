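"""Synthetic (C, M, k) UMI dataset generator.

A dataset is built from C "center" UMIs drawn uniformly over the 5-letter
alphabet {A, C, G, T, N}^M (N is a legitimate fifth letter here, emulating
undetermined base calls).  Each center receives 20 "neighbor" UMIs obtained
by substituting e positions (e = k exactly when k = 1, otherwise uniform in
1..k) with a uniformly chosen different letter — amplification/sequencing
errors around a true molecule.  Centers get a high random frequency (19-100
reads) and neighbors a low one (1-10), so every center/non-center pair
(u, v) satisfies the directional edge rule 2 f(v) - 1 <= f(u) and the
ground-truth molecule count is recoverable.

Sequence draws always precede frequency draws (centers, then per-center
neighbors, then center frequencies, then neighbor frequencies) so a seed
fixes the dataset byte-for-byte.  Duplicate sequences keep the frequency of
their first generation; centers are generated first, so a neighbor
colliding with a center keeps the center's frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import EncodedUMI, encode
from .errors import ParseError, UMIDedupError
from .index.core import UMIFreqTable

#: Digit i of a generated code maps to this letter.
ALPHABET = "ACGTN"

CENTER_FREQ_RANGE = (19, 100)
NEIGHBOR_FREQ_RANGE = (1, 10)


@dataclass(frozen=True)
class SimParams:
    C: int
    M: int
    k: int
    neighbors_per_center: int
    seed: int


@dataclass(frozen=True)
class SimDataset:
    """Simulated dataset: distinct centers, the collapsed frequency table."""

    centers: tuple[EncodedUMI, ...]
    table: UMIFreqTable
    params: SimParams

    @property
    def n_unique(self) -> int:
        return len(self.table)


def _check_params(C: int, M: int, k: int, npc: int) -> None:
    if C < 0:
        raise UMIDedupError(f"C must be >= 0, got {C}")
    if M < 1:
        raise UMIDedupError(f"M must be >= 1, got {M}")
    if not 0 <= k < M:
        raise UMIDedupError(f"k must satisfy 0 <= k < M, got k={k}, M={M}")
    if npc < 0:
        raise UMIDedupError(f"neighbors_per_center must be >= 0, got {npc}")


def _simulate_codes(
    C: int, M: int, k: int, npc: int, rng: np.random.Generator
) -> np.ndarray:
    """Generate all sequences as a (C + C*npc, M) uint8 digit matrix.

    Rows 0..C-1 are the centers, in generation order; neighbor rows follow
    grouped per center.
    """
    centers = rng.integers(0, 5, size=(C, M), dtype=np.uint8)
    if C == 0 or npc == 0:
        return centers
    neighbors = np.repeat(centers, npc, axis=0)
    n = neighbors.shape[0]
    if k == 1:
        pos = rng.integers(0, M, size=n)
        offset = rng.integers(1, 5, size=n, dtype=np.uint8)
        rows = np.arange(n)
        neighbors[rows, pos] = (neighbors[rows, pos] + offset) % 5
    elif k > 1:
        for i in range(n):
            e = int(rng.integers(1, k + 1))
            pos = rng.choice(M, size=e, replace=False)
            offs = rng.integers(1, 5, size=e, dtype=np.uint8)
            neighbors[i, pos] = (neighbors[i, pos] + offs) % 5
    # k == 0: neighbors are exact copies of their centers.
    return np.concatenate([centers, neighbors], axis=0)


def _pack(codes: np.ndarray) -> np.ndarray:
    """Pack each base-5 digit row into one uint64 (requires M <= 27)."""
    M = codes.shape[1]
    if M > 27:
        raise UMIDedupError(f"packed comparison supports M <= 27, got {M}")
    pow5 = (5 ** np.arange(M, dtype=np.uint64))[::-1]
    return (codes.astype(np.uint64) * pow5).sum(axis=1, dtype=np.uint64)


def unique_umi_count(
    C: int,
    M: int,
    k: int = 1,
    neighbors_per_center: int = 20,
    *,
    seed: int,
) -> int:
    """Number of distinct sequences a (C, M, k) simulation produces.

    Identical sequence draws to :func:`simulate_dataset` for the same seed;
    kept fully vectorized so multi-million-UMI datasets count in seconds.
    """
    _check_params(C, M, k, neighbors_per_center)
    rng = np.random.default_rng(seed)
    codes = _simulate_codes(C, M, k, neighbors_per_center, rng)
    if codes.shape[0] == 0:
        return 0
    return int(np.unique(_pack(codes)).size)


def _codes_to_strings(codes: np.ndarray) -> list[str]:
    letters = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    as_bytes = letters[codes].tobytes()
    M = codes.shape[1]
    return [
        as_bytes[i : i + M].decode() for i in range(0, len(as_bytes), M)
    ]


def assign_frequencies(
    centers: list[str],
    neighbors: list[str],
    rng: np.random.Generator | int,
) -> UMIFreqTable:
    """Draw frequencies and collapse duplicates into a frequency table.

    Centers draw uniform integers in [19, 100], neighbors in [1, 10]; the
    low/high separation guarantees 2 f(v) - 1 <= f(u) for every
    center/non-center pair.  The first occurrence of a sequence (centers
    first) keeps its frequency draw.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lo_c, hi_c = CENTER_FREQ_RANGE
    lo_n, hi_n = NEIGHBOR_FREQ_RANGE
    center_freqs = rng.integers(lo_c, hi_c + 1, size=len(centers))
    neighbor_freqs = rng.integers(lo_n, hi_n + 1, size=len(neighbors))
    counts: dict[EncodedUMI, int] = {}
    for seq, f in zip(centers, center_freqs):
        counts.setdefault(encode(seq), int(f))
    for seq, f in zip(neighbors, neighbor_freqs):
        counts.setdefault(encode(seq), int(f))
    return UMIFreqTable(counts)


def simulate_dataset(
    C: int,
    M: int,
    k: int = 1,
    neighbors_per_center: int = 20,
    *,
    seed: int,
) -> SimDataset:
    """Generate a full (C, M, k) dataset with frequencies."""
    _check_params(C, M, k, neighbors_per_center)
    rng = np.random.default_rng(seed)
    codes = _simulate_codes(C, M, k, neighbors_per_center, rng)
    seqs = _codes_to_strings(codes)
    center_seqs, neighbor_seqs = seqs[:C], seqs[C:]
    table = assign_frequencies(center_seqs, neighbor_seqs, rng)
    centers: list[EncodedUMI] = []
    seen: set[EncodedUMI] = set()
    for s in center_seqs:
        e = encode(s)
        if e not in seen:
            seen.add(e)
            centers.append(e)
    return SimDataset(
        centers=tuple(centers),
        table=table,
        params=SimParams(C, M, k, neighbors_per_center, seed),
    )


# ---------------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------------

def write_dataset(ds: SimDataset | UMIFreqTable, path) -> None:
    """Write a dataset's frequency table as TSV (columns sequence, count)."""
    table = ds.table if isinstance(ds, SimDataset) else ds
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for u in sorted(table.keys(), key=lambda x: x.seq):
            fh.write(f"{u.seq}\t{table[u]}\n")


def read_dataset(path) -> UMIFreqTable:
    """Read a sequence/count TSV back into a frequency table."""
    counts: dict[EncodedUMI, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if header.strip() and header.strip().split("\t")[:2] != ["sequence", "count"]:
            raise ParseError(f"{path}: line 1: expected 'sequence\\tcount' header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            seq, count = parts
            try:
                counts[encode(seq)] = int(count)
            except (ValueError, UMIDedupError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return UMIFreqTable(counts)


# ---------------------------------------------------------------------------
# Read-level fixtures
# ---------------------------------------------------------------------------

def emit_fixture_reads(
    ds: SimDataset,
    path,
    mode: str = "fastq",
    positions: int = 1,
    *,
    seed: int = 0,
) -> int:
    """Expand a dataset into read records; returns the record count.

    FASTQ mode writes one record per UMI occurrence with the UMI as the
    whole read sequence.  SAM mode writes single-end records with the UMI
    appended to the read name after "_", spread over the requested number
    of alignment start coordinates (each unique UMI keeps all its copies at
    one coordinate).
    """
    table = ds.table
    rng = np.random.default_rng(seed)
    umis = sorted(table.keys(), key=lambda x: x.seq)
    if mode == "fastq":
        n = 0
        with open(path, "w") as fh:
            for u in umis:
                qual = "I" * u.length
                for copy in range(table[u]):
                    fh.write(f"@sim{n}_{u.seq} copy={copy}\n{u.seq}\n+\n{qual}\n")
                    n += 1
        return n
    if mode != "sam":
        raise UMIDedupError(f"unknown fixture mode {mode!r}")

    import pysam

    coords = [100 + 500 * i for i in range(max(positions, 1))]
    assignment = rng.integers(0, len(coords), size=len(umis))
    body = "A" * 50
    qual = "I" * 50
    records = []
    n = 0
    for u, coord_i in zip(umis, assignment):
        pos = coords[int(coord_i)]
        for _ in range(table[u]):
            records.append((pos, f"sim{n}_{u.seq}"))
            n += 1
    records.sort(key=lambda r: r[0])
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": "chr1", "LN": max(coords) + 1000}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for pos, name in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.query_sequence = body
            a.flag = 0
            a.reference_id = 0
            a.reference_start = pos - 1  # SAM text is 1-based
            a.mapping_quality = 60
            a.cigarstring = "50M"
            a.query_qualities = pysam.qualitystring_to_array(qual)
            out.write(a)
    return n
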