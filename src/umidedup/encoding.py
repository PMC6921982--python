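"""Bit-packed nucleotide encoding with constant-time Hamming distance.

Each base is stored as a 3-bit code chosen so the four codes are pairwise
equidistant in Hamming space (distance exactly 2 between any two distinct
codes — the vertices of a regular tetrahedron in {0,1}^3):

    A = 110    T = 011    C = 101    G = 000

Because every mismatching base pair contributes exactly two set bits to the
XOR of two encoded sequences, the nucleotide-level Hamming distance is
``popcount(a ^ b) / 2``, one machine-word XOR+popcount per 21 bases.

Undetermined ``N`` bases are treated as a fifth letter: they are recorded in
a separate per-position bit mask and hold the all-zero canonical pattern in
the coded bits, so a position where exactly one side is N counts as one
mismatch and a position where both are N counts as a match.
"""

from __future__ import annotations

from .errors import InvalidSequenceError, IntegrityError, LengthMismatchError

#: 3-bit pairwise-equidistant codes for the four determined nucleotides.
CODES = {"A": 0b110, "T": 0b011, "C": 0b101, "G": 0b000}

#: Canonical coded pattern stored at N positions (disambiguated by the mask).
N_PATTERN = 0b000

_DECODE = {code: base for base, code in CODES.items()}

#: Number of 3-bit positions that fit in one 64-bit machine word.
WORD_CAPACITY = 64 // 3  # 21


def word_capacity() -> int:
    """Return the number of nucleotides packed per 64-bit word (21)."""
    return WORD_CAPACITY


class EncodedUMI:
    """A bit-packed UMI sequence.

    Attributes
    ----------
    bits:
        Concatenated 3-bit codes, position 1 in the highest-order group
        (so ``encode("AAT").bits == 0b110110011``).
    nmask:
        One bit per position marking ``N`` bases; position 1 is the
        highest-order bit.
    length:
        Number of nucleotides M.
    seq:
        The uppercase source string (cached at construction; equality and
        hashing ignore it and use only ``(bits, nmask, length)``).
    """

    __slots__ = ("bits", "nmask", "nbits3", "length", "seq")

    def __init__(self, bits: int, nmask: int, length: int, seq: str):
        self.bits = bits
        self.nmask = nmask
        # 3-bit-expanded copy of nmask, used to blank N positions during XOR.
        self.nbits3 = _expand_mask(nmask, length)
        self.length = length
        self.seq = seq

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EncodedUMI):
            return NotImplemented
        return (
            self.bits == other.bits
            and self.nmask == other.nmask
            and self.length == other.length
        )

    def __hash__(self) -> int:
        return hash((self.bits, self.nmask, self.length))

    def __len__(self) -> int:
        return self.length

    def __str__(self) -> str:
        return self.seq

    def __repr__(self) -> str:
        return f"EncodedUMI({self.seq!r})"

    @property
    def words(self) -> tuple[int, ...]:
        """The coded bits split into 64-bit words, 21 positions per word."""
        n_words = -(-self.length // WORD_CAPACITY)
        padded = self.bits << (63 * n_words - 3 * self.length)
        mask = (1 << 63) - 1
        return tuple(
            (padded >> (63 * (n_words - 1 - w))) & mask for w in range(n_words)
        )


def _expand_mask(nmask: int, length: int) -> int:
    """Expand a per-position mask to 3 bits per position."""
    out = 0
    for i in range(length):
        if (nmask >> (length - 1 - i)) & 1:
            out |= 0b111 << (3 * (length - 1 - i))
    return out


def encode(seq: str) -> EncodedUMI:
    """Encode a nucleotide string over ``{A, C, G, T, N}`` (case-insensitive)."""
    if not seq:
        raise InvalidSequenceError("cannot encode an empty sequence")
    s = seq.upper()
    bits = 0
    nmask = 0
    for i, ch in enumerate(s):
        bits <<= 3
        nmask <<= 1
        if ch == "N":
            nmask |= 1
            bits |= N_PATTERN
        else:
            code = CODES.get(ch)
            if code is None:
                raise InvalidSequenceError(
                    f"invalid nucleotide {ch!r} at position {i + 1}"
                )
            bits |= code
    return EncodedUMI(bits, nmask, len(s), s)


def decode(e: EncodedUMI) -> str:
    """Recover the nucleotide string from the packed representation.

    Unlike ``e.seq`` (a cache), this re-derives every base from the bits and
    raises :class:`IntegrityError` on a corrupted 3-bit group.
    """
    out = []
    m = e.length
    for i in range(m):
        group = (e.bits >> (3 * (m - 1 - i))) & 0b111
        if (e.nmask >> (m - 1 - i)) & 1:
            if group != N_PATTERN:
                raise IntegrityError(
                    f"N position {i + 1} holds non-canonical pattern {group:03b}"
                )
            out.append("N")
        else:
            base = _DECODE.get(group)
            if base is None:
                raise IntegrityError(
                    f"corrupted 3-bit group {group:03b} at position {i + 1}"
                )
            out.append(base)
    return "".join(out)


def hamming(a: EncodedUMI, b: EncodedUMI) -> int:
    """Hamming distance between two equal-length UMIs, N as a fifth letter.

    Computed word-parallel: popcount of the coded XOR restricted to positions
    where neither side is N, halved, plus popcount of the XOR of the N masks.
    """
    if a.length != b.length:
        raise LengthMismatchError(
            f"length mismatch: {a.length} vs {b.length}"
        )
    nb = a.nbits3 | b.nbits3
    if nb:
        return (((a.bits ^ b.bits) & ~nb).bit_count() >> 1) + (
            a.nmask ^ b.nmask
        ).bit_count()
    return (a.bits ^ b.bits).bit_count() >> 1
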