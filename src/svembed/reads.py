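"""Lightweight aligned-read and fragment containers shared by pileup and simulate.

Actual reads are converted from pysam ``AlignedSegment``s; simulated reads are
built directly by the analytic lifting step. Both end up in the same
``AlignedRead``/``Fragment`` form so image encoding treats them identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pysam

# CIGAR op codes (pysam convention)
CIGAR_M = 0
CIGAR_I = 1
CIGAR_D = 2
CIGAR_S = 4


@dataclass
class AlignedRead:
    name: str
    seq: str
    quals: np.ndarray  # phred scores, uint8, len == len(seq)
    ref_start: int  # 0-based leftmost aligned position (excludes leading clip)
    cigar: list  # list[(op, length)] over M/I/D/S
    mapq: int = 60
    is_reverse: bool = False
    is_proper: bool = True
    has_mate: bool = True
    mate_unmapped: bool = False
    hap_tag: int = 0  # 0 = untagged, 1/2 = phased haplotype
    anchored_only: bool = False  # fully soft-clipped read anchored at an INS site

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(l for op, l in self.cigar if op in (CIGAR_M, CIGAR_D))

    @property
    def n_mismatch_capable_bases(self) -> int:
        return sum(l for op, l in self.cigar if op == CIGAR_M)


@dataclass
class Fragment:
    """A sequenced fragment: one read or a read pair rendered on one image row."""

    reads: list  # list[AlignedRead], sorted by ref_start
    insert_size: int = 0  # 0 when unknown/unpaired
    name: str = ""
    realign_support: float = 0.5  # filled by realign_fragment; 0.5 = uninformative

    def __post_init__(self) -> None:
        self.reads.sort(key=lambda r: r.ref_start)
        if not self.name and self.reads:
            self.name = self.reads[0].name

    @property
    def ref_start(self) -> int:
        return min(r.ref_start for r in self.reads)

    @property
    def ref_end(self) -> int:
        return max(r.ref_end for r in self.reads)


def read_from_pysam(aln: pysam.AlignedSegment) -> Optional[AlignedRead]:
    """Convert a pysam alignment; returns None for unusable records."""
    if aln.is_unmapped or aln.is_secondary or aln.is_supplementary or aln.is_duplicate:
        return None
    if aln.query_sequence is None or aln.cigartuples is None:
        return None
    cigar = []
    for op, length in aln.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            op = CIGAR_M
        elif op == 3:  # N treated as a deletion-like reference skip
            op = CIGAR_D
        elif op == 5:  # hard clip: no bases present
            continue
        elif op not in (CIGAR_I, CIGAR_D, CIGAR_S):
            return None
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + length)
        else:
            cigar.append((op, length))
    quals = aln.query_qualities
    if quals is None:
        quals = np.full(len(aln.query_sequence), 30, dtype=np.uint8)
    else:
        quals = np.asarray(quals, dtype=np.uint8)
    hap = 0
    try:
        hap = int(aln.get_tag("HP"))
    except KeyError:
        pass
    return AlignedRead(
        name=aln.query_name,
        seq=aln.query_sequence.upper(),
        quals=quals,
        ref_start=aln.reference_start,
        cigar=cigar,
        mapq=aln.mapping_quality,
        is_reverse=aln.is_reverse,
        is_proper=aln.is_proper_pair,
        has_mate=aln.is_paired,
        mate_unmapped=aln.is_paired and aln.mate_is_unmapped,
        hap_tag=hap,
    )


def fragments_from_alignments(
    alignment_file: pysam.AlignmentFile, contig: str, start: int, end: int
) -> list:
    """Group primary alignments overlapping [start, end) into fragments by name."""
    by_name: dict = {}
    tlen: dict = {}
    for aln in alignment_file.fetch(contig, max(start, 0), end):
        read = read_from_pysam(aln)
        if read is None:
            continue
        by_name.setdefault(read.name, []).append(read)
        if aln.template_length:
            tlen[read.name] = abs(aln.template_length)
    fragments = []
    for name, reads in by_name.items():
        fragments.append(
            Fragment(reads=reads, insert_size=tlen.get(name, 0), name=name)
        )
    fragments.sort(key=lambda f: (f.ref_start, name_hash(f.name)))
    return fragments


def name_hash(name: str) -> int:
    """Stable tie-break hash for deterministic row ordering across runs."""
    return zlib.crc32(name.encode())
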