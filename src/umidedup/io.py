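"""End-user drivers: FASTQ and SAM/BAM deduplication.

FASTQ mode treats the entire (fixed-length) read sequence as the UMI and
collapses the whole file with one grouping run.  SAM/BAM mode follows the
UMI-tools convention — the UMI is the read-name suffix after the last
``_`` — and deduplicates each alignment coordinate independently, keying
forward reads by their (soft-clip adjusted) alignment start and reverse
reads by their alignment end.  One consensus read is emitted per UMI
group: the input read carrying the group's representative UMI with the
best mapping quality, then mean base quality, then earliest file order.
No read is ever synthesized; every output record existed in the input.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import Any, Iterable, NamedTuple

import pysam
from Bio import SeqIO

from .errors import LengthMismatchError, UMIDedupError, UMIExtractionError
from .grouping import UMIGroup, run_grouping
from .index import build_index
from .index.core import count_umis

log = logging.getLogger("umidedup")

DEFAULT_K = 1
DEFAULT_ALGORITHM = "directional"
DEFAULT_BACKEND = "ngrambk"
DEFAULT_EPSILON = 0.5


class CoordinateKey(NamedTuple):
    """Alignment grouping key: reads sharing it are co-deduplicated."""

    reference: str
    strand: str  # "+" or "-"
    position: int  # 1-based; 5' start for forward reads, 3' end for reverse


@dataclass
class ReadRecord:
    """One input read reduced to the fields the consensus choice needs."""

    id: str
    umi: str
    key: CoordinateKey | None
    mapq: int
    mean_phred: float
    order: int
    payload: Any = None  # the underlying pysam/Biopython record


def extract_umi(read_name: str, separator: str = "_") -> str:
    """UMI embedded in a read name: the part after the last separator."""
    if separator not in read_name:
        raise UMIExtractionError(
            f"read name {read_name!r} lacks UMI separator {separator!r}"
        )
    return read_name.rsplit(separator, 1)[1]


def _soft_clips(cigartuples) -> tuple[int, int]:
    lead = cigartuples[0][1] if cigartuples and cigartuples[0][0] == 4 else 0
    tail = cigartuples[-1][1] if cigartuples and cigartuples[-1][0] == 4 else 0
    return lead, tail


def coordinate_key(
    read: pysam.AlignedSegment, clip_aware: bool = True
) -> CoordinateKey:
    """Deduplication key of a mapped record.

    Forward reads key on the 5' alignment start, reverse reads on the 3'
    alignment end; with ``clip_aware`` (the default) soft-clipped bases are
    counted back into the coordinate so clipped copies of one fragment
    still collide.
    """
    if read.is_unmapped:
        raise UMIDedupError(f"cannot key unmapped read {read.query_name}")
    lead, tail = _soft_clips(read.cigartuples or []) if clip_aware else (0, 0)
    if read.is_reverse:
        pos = read.reference_end + tail  # reference_end is 0-based exclusive
        strand = "-"
    else:
        pos = read.reference_start + 1 - lead
        strand = "+"
    return CoordinateKey(read.reference_name, strand, pos)


def choose_consensus_read(
    group: UMIGroup, reads: Iterable[ReadRecord]
) -> ReadRecord:
    """Best read carrying the group's representative UMI.

    Max by mapping quality, then mean Phred, then first occurrence in file
    order — fully deterministic.
    """
    rep = group.representative.seq
    candidates = [r for r in reads if r.umi == rep]
    if not candidates:
        raise UMIDedupError(f"no read carries representative UMI {rep}")
    return max(candidates, key=lambda r: (r.mapq, r.mean_phred, -r.order))


def _open_maybe_gzip(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _mean(values) -> float:
    values = list(values or [])
    return sum(values) / len(values) if values else 0.0


# ---------------------------------------------------------------------------
# FASTQ driver
# ---------------------------------------------------------------------------

def dedup_fastq(
    in_path,
    out_path,
    k: int = DEFAULT_K,
    algorithm: str = DEFAULT_ALGORITHM,
    backend: str = DEFAULT_BACKEND,
    epsilon: float = DEFAULT_EPSILON,
) -> dict:
    """Collapse a FASTQ file by full read sequence; returns summary stats."""
    with _open_maybe_gzip(in_path) as fh:
        seq_records = list(SeqIO.parse(fh, "fastq"))

    if not seq_records:
        with open(out_path, "w"):
            pass
        return {"reads_in": 0, "reads_out": 0, "groups": 0}

    length = len(seq_records[0].seq)
    records: list[ReadRecord] = []
    for order, rec in enumerate(seq_records):
        if len(rec.seq) != length:
            raise LengthMismatchError(
                f"variable read length at {rec.id}: {len(rec.seq)} != {length}"
            )
        records.append(
            ReadRecord(
                id=rec.id,
                umi=str(rec.seq).upper(),
                key=None,
                mapq=0,
                mean_phred=_mean(rec.letter_annotations.get("phred_quality")),
                order=order,
                payload=rec,
            )
        )

    table = count_umis(r.umi for r in records)
    index = build_index(backend, table, k)
    result = run_grouping(algorithm, table, index, k, epsilon)

    consensus = [choose_consensus_read(g, records) for g in result.groups]
    with open(out_path, "w") as out:
        SeqIO.write([r.payload for r in consensus], out, "fastq")
    return {
        "reads_in": len(records),
        "reads_out": len(consensus),
        "groups": result.n_groups,
    }


# ---------------------------------------------------------------------------
# SAM/BAM driver
# ---------------------------------------------------------------------------

def _out_mode(path) -> str:
    return "wb" if str(path).endswith(".bam") else "wh"


def dedup_bam(
    in_path,
    out_path,
    k: int = DEFAULT_K,
    algorithm: str = DEFAULT_ALGORITHM,
    backend: str = DEFAULT_BACKEND,
    epsilon: float = DEFAULT_EPSILON,
    umi_sep: str = "_",
    keep_unmapped: bool = False,
    keep_secondary: bool = False,
    clip_aware: bool = True,
    strict_umi: bool = False,
) -> dict:
    """Deduplicate a coordinate-sorted SAM/BAM per alignment coordinate."""
    infile = pysam.AlignmentFile(str(in_path), require_index=False)
    header = infile.header.to_dict()
    so = header.get("HD", {}).get("SO", "unknown")
    if so != "coordinate" and not infile.has_index():
        raise UMIDedupError(
            f"input must be coordinate-sorted or indexed (SO is {so!r})"
        )

    by_key: dict[CoordinateKey, list[ReadRecord]] = {}
    unmapped: list[pysam.AlignedSegment] = []
    reads_in = dropped_no_umi = n_unmapped = 0
    umi_length: int | None = None
    order = 0
    for read in infile:
        if read.is_secondary or read.is_supplementary:
            if not keep_secondary:
                continue
        reads_in += 1
        if read.is_unmapped:
            n_unmapped += 1
            if keep_unmapped:
                unmapped.append(read)
            continue
        try:
            umi = extract_umi(read.query_name, umi_sep).upper()
        except UMIExtractionError as exc:
            if strict_umi:
                raise
            dropped_no_umi += 1
            log.warning("%s; read dropped", exc)
            continue
        if umi_length is None:
            umi_length = len(umi)
        elif len(umi) != umi_length:
            raise LengthMismatchError(
                f"UMI length changed at read {read.query_name}: "
                f"{len(umi)} != {umi_length}"
            )
        rec = ReadRecord(
            id=read.query_name,
            umi=umi,
            key=coordinate_key(read, clip_aware),
            mapq=read.mapping_quality,
            mean_phred=_mean(read.query_qualities),
            order=order,
            payload=read,
        )
        by_key.setdefault(rec.key, []).append(rec)
        order += 1
    infile.close()

    header.setdefault("PG", []).append(
        {"ID": "umidedup", "PN": "umidedup", "VN": _version()}
    )
    consensus: list[ReadRecord] = []
    max_unique = 0
    for key in sorted(by_key):
        reads = by_key[key]
        log.debug("position %s: %d reads", key, len(reads))
        table = count_umis(r.umi for r in reads)
        max_unique = max(max_unique, len(table))
        index = build_index(backend, table, k)
        result = run_grouping(algorithm, table, index, k, epsilon)
        for group in result.groups:
            consensus.append(choose_consensus_read(group, reads))

    consensus.sort(
        key=lambda r: (
            r.payload.reference_id,
            r.payload.reference_start,
            r.order,
        )
    )
    with pysam.AlignmentFile(
        str(out_path), _out_mode(out_path), header=header
    ) as out:
        for rec in consensus:
            out.write(rec.payload)
        for read in unmapped:
            out.write(read)

    return {
        "reads_in": reads_in,
        "reads_out": len(consensus) + len(unmapped),
        "positions": len(by_key),
        "max_unique_umis": max_unique,
        "dropped_no_umi": dropped_no_umi,
        "unmapped": n_unmapped,
    }


def _version() -> str:
    from . import __version__

    return __version__
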