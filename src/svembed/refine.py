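"""Breakpoint refining for deletion SVs in repetitive regions.

Reported SV breakpoints are frequently offset from the true breakpoints
inside tandem repeats. The refiner proposes alternate deletion descriptions at
candidate start positions across the overlapping repeat intervals, discards
proposals without read k-mer support at their novel junction, genotypes the
survivors, smooths the per-genotype distances along the coordinate axis with
an exponentially weighted moving average, and selects the proposal at the
nonreference distance minimum. Distant (wrong) proposals are expected to be
confidently homozygous reference, so a proposal only wins if its closest
simulated genotype is nonreference.

Refining never changes the deletion length, only its position. Proposals whose
alternate haplotypes are identical strings (repeat-unit ambiguity) are
indistinguishable by any read evidence and are collapsed to the leftmost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from svembed.genotype import (
    GenotypeCall,
    GenotypeConfig,
    _call_from_distances,
    genotype_sv,
)
from svembed.pileup import gather_fragments
from svembed.simulate import SeqStats
from svembed.variants import (
    GenotypeHypothesis,
    SVRecord,
    fetch_reference,
    reference_length,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RepeatInterval:
    """A repetitive reference interval (e.g. a tandem repeat from a BED track)."""

    contig: str
    start: int  # 0-based half-open
    end: int
    unit_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("repeat interval must have length >= 1")


@dataclass
class Proposal:
    """An alternate deletion description considered during refining."""

    origin_sv_id: str
    record: SVRecord
    offset: int  # signed shift of the start relative to the original record
    distances: Dict[GenotypeHypothesis, float] = field(default_factory=dict)
    smoothed_distances: Dict[GenotypeHypothesis, float] = field(default_factory=dict)
    call: Optional[GenotypeCall] = None
    is_original: bool = False


@dataclass
class RefineConfig:
    alpha: float = 0.3  # EWMA smoothing weight on the current proposal
    k: int = 31  # junction k-mer size
    min_support: int = 2  # junction k-mers required in the actual reads
    stride: int = 1  # candidate start spacing within repeat intervals


def load_repeats_bed(path: str) -> List[RepeatInterval]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split()
            unit = int(fields[3]) if len(fields) > 3 and fields[3].isdigit() else None
            intervals.append(
                RepeatInterval(fields[0], int(fields[1]), int(fields[2]), unit)
            )
    return intervals


def _deletion_record(sv: SVRecord, start: int, reference, dlen: int, suffix: str) -> SVRecord:
    ref_allele = fetch_reference(reference, sv.contig, start, start + dlen + 1)
    return SVRecord(
        id=f"{sv.id}_{suffix}",
        contig=sv.contig,
        start=start,
        ref_allele=ref_allele,
        alt_alleles=[ref_allele[0]],
        info={"ORIGINAL_POS": sv.start + 1},
    )


def propose_alternates(
    sv: SVRecord,
    repeat_intervals: Sequence[RepeatInterval],
    reference,
    stride: int = 1,
) -> List[Proposal]:
    """One same-length deletion proposal per candidate start, plus the original.

    Candidate starts sweep the union of repeat intervals overlapping the SV
    (every ``stride``-th position); each proposal's REF allele is re-read from
    the reference. Only deletions are supported.
    """
    if sv.n_alts != 1 or sv.sv_type(0) != "DEL":
        raise ValueError(
            f"SV refining is implemented for bi-allelic DEL records only (got {sv.id})"
        )
    dlen = -sv.svlen(0)
    contig_len = reference_length(reference, sv.contig)
    overlapping = [
        iv
        for iv in repeat_intervals
        if iv.contig == sv.contig and iv.start < sv.end and iv.end > sv.start
    ]
    starts = set()
    for iv in overlapping:
        for p in range(iv.start, iv.end, stride):
            if p + dlen + 1 <= contig_len:
                starts.add(p)
    starts.discard(sv.start)
    proposals = [
        Proposal(origin_sv_id=sv.id, record=sv, offset=0, is_original=True)
    ]
    for p in sorted(starts):
        proposals.append(
            Proposal(
                origin_sv_id=sv.id,
                record=_deletion_record(sv, p, reference, dlen, f"p{p}"),
                offset=p - sv.start,
            )
        )
    proposals.sort(key=lambda pr: pr.record.start)
    return proposals


def dedup_proposals(
    proposals: Sequence[Proposal], reference, pad: int = 200
) -> List[Proposal]:
    """Collapse proposals with identical alternate haplotypes, keeping the leftmost.

    Within a tandem repeat, shifted deletions of the same length often produce
    byte-identical alternate haplotypes; no read evidence can distinguish
    them. The original description is always kept.
    """
    if not proposals:
        return []
    lo = min(p.record.start for p in proposals) - pad
    hi = max(p.record.end for p in proposals) + pad
    contig = proposals[0].record.contig
    window = fetch_reference(reference, contig, max(lo, 0), hi)
    w0 = max(lo, 0)
    seen: Dict[str, Proposal] = {}
    out = []
    for p in sorted(proposals, key=lambda pr: (pr.record.start, not pr.is_original)):
        rec = p.record
        alt_hap = (
            window[: rec.start + 1 - w0]
            + rec.alt_alleles[0][1:]
            + window[rec.end - w0 :]
        )
        if alt_hap not in seen:
            seen[alt_hap] = p
            out.append(p)
        elif p.is_original and not seen[alt_hap].is_original:
            # keep the original alongside its leftmost equivalent
            out.append(p)
    out.sort(key=lambda pr: pr.record.start)
    return out


def _junction_kmers(record: SVRecord, reference, k: int) -> set:
    """k-mers spanning the proposal's novel junction, minus local reference k-mers."""
    dlen = -record.svlen(0)
    anchor = record.start + 1  # first deleted base
    left = fetch_reference(reference, record.contig, max(anchor - (k - 1), 0), anchor)
    right = fetch_reference(
        reference,
        record.contig,
        anchor + dlen,
        min(anchor + dlen + (k - 1), reference_length(reference, record.contig)),
    )
    junction = left + right
    kmers = {junction[i : i + k] for i in range(len(junction) - k + 1)}
    # drop k-mers already present in the unmodified local reference
    span = 2 * (k + dlen)
    local = fetch_reference(
        reference,
        record.contig,
        max(record.start - span, 0),
        record.end + span,
    )
    local_kmers = {local[i : i + k] for i in range(len(local) - k + 1)}
    return kmers - local_kmers


def kmer_filter(
    proposals: Sequence[Proposal],
    actual_alignments,
    reference,
    k: int = 31,
    min_support: int = 2,
    window_flank: int = 1000,
) -> List[Proposal]:
    """Keep proposals whose novel junction k-mers appear >= min_support times in reads.

    The original description is always retained. ``min_support=0`` disables
    the filter.
    """
    if min_support <= 0:
        return list(proposals)
    lo = min(p.record.start for p in proposals) - window_flank
    hi = max(p.record.end for p in proposals) + window_flank
    contig = proposals[0].record.contig
    from svembed.pileup import Window

    fragments = gather_fragments(
        actual_alignments, Window(contig, max(lo, 0), hi), max_rows=10**9
    )
    read_kmers: Dict[str, int] = {}
    for frag in fragments:
        for read in frag.reads:
            seq = read.seq
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                read_kmers[kmer] = read_kmers.get(kmer, 0) + 1
    retained = []
    for p in proposals:
        if p.is_original:
            retained.append(p)
            continue
        junction = _junction_kmers(p.record, reference, k)
        if not junction:
            # fully ambiguous junction (all its k-mers also occur in the
            # local reference): absence of novel k-mers cannot rule it out
            retained.append(p)
            continue
        support = sum(read_kmers.get(km, 0) for km in junction)
        if support >= min_support:
            retained.append(p)
    return retained


def smooth_distances(
    proposals: Sequence[Proposal], alpha: float = 0.3, stride: int = 1
) -> List[Proposal]:
    """EWMA along the start coordinate, independently per genotype.

    s_0 = d_0; s_i = alpha * d_i + (1 - alpha) * s_{i-1} for consecutive
    proposals (``stride`` bp apart). When filtering leaves gaps in the
    position series, the carry-over weight decays with the gap —
    (1 - alpha)**(gap/stride) — so distant survivors do not smear each
    other's minima. Proposals must be sorted by start and carry raw
    distances.
    """
    prev: Optional[Dict[GenotypeHypothesis, float]] = None
    prev_start: Optional[int] = None
    for p in proposals:
        if prev is None:
            p.smoothed_distances = dict(p.distances)
        else:
            gap = max(1.0, (p.record.start - prev_start) / max(stride, 1))
            carry = (1.0 - alpha) ** gap
            p.smoothed_distances = {
                h: (1.0 - carry) * d + carry * prev[h]
                for h, d in p.distances.items()
            }
        prev = p.smoothed_distances
        prev_start = p.record.start
    return list(proposals)


def select_refined(proposals: Sequence[Proposal]) -> tuple:
    """Pick the proposal at the global nonreference smoothed-distance minimum.

    A proposal qualifies if its smallest smoothed distance belongs to a
    nonreference genotype; among qualifiers the smallest smoothed nonreference
    distance wins, ties toward the smaller |offset|. With no qualifier the
    original description and its own call are returned.
    """
    qualifiers = []
    original = next(p for p in proposals if p.is_original)
    for p in proposals:
        if not p.smoothed_distances:
            continue
        best = min(
            p.smoothed_distances,
            key=lambda h: (p.smoothed_distances[h], h.n_alt_alleles, h.alleles),
        )
        if not best.is_reference:
            qualifiers.append((p.smoothed_distances[best], abs(p.offset), p, best))
    if not qualifiers:
        return original.record, original.call
    _, _, chosen, genotype = min(qualifiers, key=lambda t: (t[0], t[1]))
    call = _call_from_distances(
        chosen.record.id,
        chosen.smoothed_distances,
        temperature=1.0,
        n_replicates=chosen.call.n_replicates if chosen.call else 0,
        seed=chosen.call.seed if chosen.call else 0,
    )
    return chosen.record, call


def refine_sv(
    sv: SVRecord,
    repeat_intervals: Sequence[RepeatInterval],
    actual_alignments,
    models,
    stats: SeqStats,
    reference,
    genotype_config: GenotypeConfig = GenotypeConfig(),
    refine_config: RefineConfig = RefineConfig(),
) -> tuple:
    """Full refining workflow for one DEL: propose, filter, genotype, select.

    Returns ``(chosen SVRecord, GenotypeCall, proposals)``.
    """
    proposals = propose_alternates(
        sv, repeat_intervals, reference, stride=refine_config.stride
    )
    proposals = dedup_proposals(proposals, reference)
    proposals = kmer_filter(
        proposals,
        actual_alignments,
        reference,
        k=refine_config.k,
        min_support=refine_config.min_support,
    )
    for p in proposals:
        p.call = genotype_sv(
            p.record, actual_alignments, models, stats, reference, genotype_config,
            repeat_intervals=repeat_intervals,
        )
        p.distances = dict(p.call.hypothesis_distances)
    smooth_distances(proposals, alpha=refine_config.alpha, stride=refine_config.stride)
    record, call = select_refined(proposals)
    return record, call, proposals
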