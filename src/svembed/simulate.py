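"""Sequencing-profile estimation and genotype-conditioned read simulation.

Replicates are generated per genotype hypothesis by drawing paired-end
fragments from the two implied haplotypes at half the target coverage each,
then *lifting* each read into reference coordinates analytically through the
haplotype's known breakpoint map — no external simulator or aligner is run.
Reads crossing a deletion junction become gapped (D) alignments; reads
overhanging into inserted sequence become soft-clipped at the insertion
anchor; reads entirely inside novel inserted sequence are emitted as fully
soft-clipped anchors at the insertion point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pysam

from svembed.reads import CIGAR_D, CIGAR_I, CIGAR_M, CIGAR_S, AlignedRead, Fragment
from svembed.variants import (
    GenotypeHypothesis,
    HaplotypeSeq,
    MapBlock,
    SVRecord,
    construct_haplotype,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: mapping quality assigned to confidently placed reads
MAPQ_UNIQUE = 60
#: mapping quality for reads fully contained in an annotated repeat interval
MAPQ_REPEAT = 20


@dataclass
class SeqStats:
    """Sequencing profile matched between actual data and simulations."""

    mean_coverage: float
    read_length: int
    insert_mean: float
    insert_sd: float
    base_error_rate: float

    def __post_init__(self) -> None:
        if min(self.mean_coverage, self.read_length, self.insert_mean, self.insert_sd) <= 0:
            raise ValueError("all sequencing statistics must be strictly positive")
        if self.base_error_rate < 0:
            raise ValueError("base_error_rate must be non-negative")
        if self.insert_mean <= self.read_length:
            raise ValueError("insert_mean must exceed read_length")

    @property
    def base_quality(self) -> int:
        err = max(self.base_error_rate, 1e-4)
        return int(np.clip(round(-10 * math.log10(err)), 2, 40))

    def insert_cap(self) -> int:
        return int(self.insert_mean + 5 * self.insert_sd)

    def to_dict(self) -> dict:
        return {
            "mean_coverage": self.mean_coverage,
            "read_length": self.read_length,
            "insert_mean": self.insert_mean,
            "insert_sd": self.insert_sd,
            "base_error_rate": self.base_error_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SeqStats":
        return cls(
            mean_coverage=float(d["mean_coverage"]),
            read_length=int(d["read_length"]),
            insert_mean=float(d["insert_mean"]),
            insert_sd=float(d["insert_sd"]),
            base_error_rate=float(d["base_error_rate"]),
        )


@dataclass
class SimReplicate:
    """One simulated sequencing replicate under a genotype hypothesis."""

    genotype: GenotypeHypothesis
    replicate_index: int
    seed: int
    fragments: list  # list[Fragment] in reference coordinates


def estimate_stats(
    alignments: str,
    sample_regions: Sequence[tuple],
    seed: int = 0,
    min_pairs: int = 1000,
) -> SeqStats:
    """Estimate the sequencing profile from sampled regions of the actual data.

    Coverage is the mean aligned-base depth over the sampled regions; insert
    mean/sd come from proper pairs (one pass of >10 SD outlier rejection);
    the base error rate is the mismatch (NM) rate of high-mapq reads.
    """
    inserts = []
    aligned_bases = 0
    region_bases = 0
    mismatches = 0
    nm_bases = 0
    read_lengths = []
    with pysam.AlignmentFile(alignments) as bam:
        for contig, start, end in sample_regions:
            region_bases += end - start
            for aln in bam.fetch(contig, start, end):
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                overlap = min(aln.reference_end, end) - max(aln.reference_start, start)
                if overlap > 0:
                    aligned_bases += overlap
                read_lengths.append(aln.query_length)
                if aln.is_proper_pair and aln.template_length > 0:
                    inserts.append(aln.template_length)
                if aln.mapping_quality >= 40:
                    try:
                        nm = aln.get_tag("NM")
                    except KeyError:
                        nm = None
                    if nm is not None:
                        mismatches += int(nm)
                        nm_bases += aln.query_alignment_length
    if len(inserts) < min_pairs:
        raise ValueError(
            f"only {len(inserts)} proper pairs in sampled regions "
            f"(need {min_pairs}); supply explicit sequencing statistics via config"
        )
    inserts = np.asarray(inserts, dtype=float)
    mean, sd = inserts.mean(), inserts.std()
    keep = np.abs(inserts - mean) <= 10 * sd
    inserts = inserts[keep]
    coverage = aligned_bases / max(region_bases, 1)
    error = mismatches / nm_bases if nm_bases else 0.0
    return SeqStats(
        mean_coverage=coverage,
        read_length=int(np.median(read_lengths)),
        insert_mean=float(inserts.mean()),
        insert_sd=float(max(inserts.std(), 1.0)),
        base_error_rate=float(error),
    )


def _apply_errors(seq: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Introduce i.i.d. substitution errors into a uint8 base array."""
    if error_rate <= 0:
        return seq
    hits = np.nonzero(rng.random(seq.size) < error_rate)[0]
    if hits.size:
        seq = seq.copy()
        # shift within the 4-letter alphabet so the base always changes
        current = np.searchsorted(_BASES, seq[hits])
        current[current >= 4] = 0  # N bases: substitute arbitrarily
        seq[hits] = _BASES[(current + rng.integers(1, 4, size=hits.size)) % 4]
    return seq


def _span_in_repeat(ref_start: int, ref_end: int, repeat_intervals) -> bool:
    if not repeat_intervals:
        return False
    for iv in repeat_intervals:
        if ref_start >= iv[0] and ref_end <= iv[1]:
            return True
    return False


def lift_alignment(
    hap_start: int,
    seq: str,
    quals: np.ndarray,
    blocks: Sequence[MapBlock],
    name: str,
    mapq_intervals=None,
    **read_kwargs,
) -> AlignedRead:
    """Project a read placed on a haplotype into reference coordinates.

    Reads inside a single mapped block become ungapped M alignments; crossing
    a deletion gap between blocks introduces a D op; overlap with a novel
    (insertion) block becomes a soft clip at the anchor; a read fully inside
    novel sequence is a fully soft-clipped anchor at the insertion point.
    Mapping quality is ``MAPQ_UNIQUE`` unless the aligned span lies entirely
    within one of ``mapq_intervals`` (annotated repeats), then ``MAPQ_REPEAT``.
    """
    hap_end = hap_start + len(seq)
    cigar = []
    ref_start = None
    last_ref_end = None

    def push(op: int, length: int) -> None:
        if length <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + length)
        else:
            cigar.append((op, length))

    for block in blocks:
        lo = max(hap_start, block.hap_start)
        hi = min(hap_end, block.hap_end)
        if lo >= hi:
            continue
        if block.ref_start is None:
            push(CIGAR_S, hi - lo)
            continue
        block_ref_lo = block.ref_start + (lo - block.hap_start)
        if ref_start is None:
            ref_start = block_ref_lo
        elif last_ref_end is not None and block_ref_lo > last_ref_end:
            push(CIGAR_D, block_ref_lo - last_ref_end)
        push(CIGAR_M, hi - lo)
        last_ref_end = block_ref_lo + (hi - lo)

    # a read spanning an entire insertion carries the novel bases as an
    # insertion op, not a clip: convert interior S ops (flanked by M) to I
    m_positions = [i for i, (op, _) in enumerate(cigar) if op == CIGAR_M]
    if m_positions:
        for i in range(m_positions[0] + 1, m_positions[-1]):
            if cigar[i][0] == CIGAR_S:
                cigar[i] = (CIGAR_I, cigar[i][1])

    anchored_only = False
    if ref_start is None:
        # fully inside novel sequence: anchor at the insertion site
        anchor = None
        for block in blocks:
            if block.ref_start is None and block.hap_start <= hap_start < block.hap_end:
                anchor = next(
                    (b.ref_end for b in blocks if b.ref_start is not None and b.hap_end <= block.hap_start),
                    None,
                )
                break
        ref_start = anchor if anchor is not None else blocks[0].ref_start or 0
        cigar = [(CIGAR_S, len(seq))]
        anchored_only = True

    ref_end = ref_start + sum(l for op, l in cigar if op in (CIGAR_M, CIGAR_D))
    mapq = MAPQ_REPEAT if _span_in_repeat(ref_start, ref_end, mapq_intervals) else MAPQ_UNIQUE
    return AlignedRead(
        name=name,
        seq=seq,
        quals=quals,
        ref_start=ref_start,
        cigar=cigar,
        mapq=mapq,
        anchored_only=anchored_only,
        **read_kwargs,
    )


def sample_fragments(
    haplotype: HaplotypeSeq,
    n_fragments: int,
    stats: SeqStats,
    rng: np.random.Generator,
    name_prefix: str = "sim",
    hap_tag: int = 0,
    repeat_intervals=None,
) -> list:
    """Draw paired-end fragments from a haplotype and lift them to the reference.

    Inserts follow a truncated Normal(insert_mean, insert_sd) on
    [2*read_length, insert_mean + 5*insert_sd]; substitution errors are
    i.i.d. at the profile's base error rate with base qualities to match.
    """
    L = len(haplotype.sequence)
    rl = stats.read_length
    lo_ins, hi_ins = 2 * rl, stats.insert_cap()
    if L < hi_ins:
        raise ValueError(
            f"haplotype window ({L} bp) shorter than the insert distribution support ({hi_ins} bp)"
        )
    hap_arr = np.frombuffer(haplotype.sequence.upper().encode(), dtype=np.uint8)
    base_q = stats.base_quality
    fragments = []
    inserts = np.clip(
        rng.normal(stats.insert_mean, stats.insert_sd, size=n_fragments), lo_ins, hi_ins
    ).astype(int)
    starts = (rng.random(n_fragments) * (L - inserts)).astype(int)
    for i in range(n_fragments):
        isize, start = int(inserts[i]), int(starts[i])
        name = f"{name_prefix}_{i}"
        reads = []
        for mate, (s, is_rev) in enumerate(
            (((start, False)), ((start + isize - rl, True)))
        ):
            seq_arr = _apply_errors(hap_arr[s : s + rl], stats.base_error_rate, rng)
            quals = np.full(rl, base_q, dtype=np.uint8)
            reads.append(
                lift_alignment(
                    s,
                    seq_arr.tobytes().decode(),
                    quals,
                    haplotype.blocks,
                    name=name,
                    mapq_intervals=repeat_intervals,
                    is_reverse=is_rev,
                    is_proper=True,
                    has_mate=True,
                    hap_tag=hap_tag,
                )
            )
        ref_span = max(r.ref_end for r in reads) - min(r.ref_start for r in reads)
        lifted_insert = ref_span if not any(r.anchored_only for r in reads) else 0
        fragments.append(Fragment(reads=reads, insert_size=lifted_insert, name=name))
    return fragments


def expected_fragments(haplotype_len: int, stats: SeqStats, diploid_share: float = 0.5) -> int:
    """Fragment count giving ``diploid_share * mean_coverage`` interior depth."""
    effective = max(haplotype_len - stats.insert_mean, 1.0)
    return int(round(diploid_share * stats.mean_coverage * effective / (2 * stats.read_length)))


def simulate_replicate(
    sv: SVRecord,
    hypothesis: GenotypeHypothesis,
    stats: SeqStats,
    reference,
    flank_bp: int = 1000,
    seed: int = 0,
    replicate_index: int = 0,
    repeat_intervals=None,
) -> SimReplicate:
    """Simulate one sequencing replicate under a genotype hypothesis.

    Each of the two haplotypes implied by the hypothesis contributes an
    expected ``mean_coverage / 2`` depth. The haplotype window is widened
    beyond ``flank_bp`` if needed so that breakpoint-spanning pairs exist and
    interior coverage over the image window is uniform.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, replicate_index]))
    needed = stats.insert_cap() + stats.read_length
    flank = max(flank_bp, needed + flank_bp // 2)
    fragments = []
    for hap_no, allele_index in enumerate(hypothesis.alleles):
        haplotype = construct_haplotype(sv, allele_index, reference, flank)
        n = expected_fragments(len(haplotype.sequence), stats, 0.5)
        n = int(rng.poisson(n))
        rel_repeats = None
        if repeat_intervals:
            rel_repeats = [
                (iv.start, iv.end) if hasattr(iv, "start") else (iv[0], iv[1])
                for iv in repeat_intervals
            ]
        fragments.extend(
            sample_fragments(
                haplotype,
                n,
                stats,
                rng,
                name_prefix=f"sim{replicate_index}_h{hap_no}",
                repeat_intervals=rel_repeats,
            )
        )
    return SimReplicate(
        genotype=hypothesis,
        replicate_index=replicate_index,
        seed=seed,
        fragments=fragments,
    )


def _count_mismatches(read: AlignedRead, reference_seq: str) -> int:
    """Mismatches of the read's M segments against the contig sequence."""
    nm = 0
    pos, qpos = read.ref_start, 0
    for op, length in read.cigar:
        if op == CIGAR_M:
            ref = reference_seq[pos : pos + length].upper()
            qry = read.seq[qpos : qpos + length]
            nm += sum(1 for a, b in zip(ref, qry) if a != b)
            pos += length
            qpos += length
        elif op == CIGAR_D:
            pos += length
        else:  # I or S consume query only
            qpos += length
    return nm


def write_sam(
    fragments: Sequence[Fragment],
    contig: str,
    contig_length: int,
    path: str,
    sort_and_index: bool = False,
    reference_seq: Optional[str] = None,
) -> str:
    """Write fragments as SAM/BAM for inspection or downstream use.

    With ``sort_and_index`` the output is coordinate-sorted BAM with a .bai
    index (path should end in .bam). When ``reference_seq`` (the full contig
    sequence) is given, NM tags are computed from the M-segment mismatches.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": contig, "LN": contig_length}],
        }
    )
    mode = "wb" if path.endswith(".bam") else "w"
    tmp = path + ".unsorted.bam" if sort_and_index else path
    with pysam.AlignmentFile(tmp, mode if not sort_and_index else "wb", header=header) as out:
        for frag in fragments:
            paired = len(frag.reads) == 2
            for i, read in enumerate(frag.reads):
                a = pysam.AlignedSegment(header)
                a.query_name = read.name
                a.query_sequence = read.seq
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in read.quals)
                )
                a.reference_id = 0
                a.reference_start = read.ref_start
                a.cigartuples = read.cigar
                a.mapping_quality = read.mapq
                flag = 0
                if paired:
                    flag |= 0x1 | 0x2 if read.is_proper else 0x1
                    flag |= 0x40 if i == 0 else 0x80
                    mate = frag.reads[1 - i]
                    a.next_reference_id = 0
                    a.next_reference_start = mate.ref_start
                    if mate.is_reverse:
                        flag |= 0x20
                    sign = 1 if read.ref_start <= mate.ref_start else -1
                    a.template_length = sign * frag.insert_size
                if read.is_reverse:
                    flag |= 0x10
                a.flag = flag
                if read.hap_tag:
                    a.set_tag("HP", read.hap_tag)
                if reference_seq is not None:
                    a.set_tag("NM", _count_mismatches(read, reference_seq))
                out.write(a)
    if sort_and_index:
        pysam.sort("-o", path, tmp)
        pysam.index(path)
        import os

        os.remove(tmp)
    return path
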