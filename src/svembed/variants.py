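"""Sequence-resolved structural variants: parsing, filtering, alleles, VCF I/O.

All coordinates are 0-based half-open internally; conversion to/from the
1-based VCF convention happens only at the VCF boundary (pysam already
exposes 0-based ``record.start``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pysam

logger = logging.getLogger(__name__)

#: default size filters: SVs are >= 50 bp; events above 15 Mbp are excluded
DEFAULT_SIZE_MIN = 50
DEFAULT_SIZE_MAX = 15_000_000

_DNA = set("ACGTNacgtn")


def _is_symbolic(allele: str) -> bool:
    return any(ch in allele for ch in "<>[].*") or not set(allele) <= _DNA


def fetch_reference(reference, contig: str, start: int, end: int) -> str:
    """Fetch reference sequence; accepts pysam/pyfaidx handles or a plain mapping."""
    start = max(start, 0)
    if hasattr(reference, "fetch"):  # pysam.FastaFile
        return reference.fetch(contig, start, end).upper()
    seq = reference[contig]
    if hasattr(seq, "seq"):  # pyfaidx record slice
        return seq[start:end].seq.upper()
    return seq[start:end].upper()


def reference_length(reference, contig: str) -> int:
    if hasattr(reference, "get_reference_length"):
        return reference.get_reference_length(contig)
    return len(reference[contig])


def reference_contigs(reference) -> list:
    if hasattr(reference, "references"):
        return list(reference.references)
    return list(reference.keys())


@dataclass
class SVRecord:
    """One sequence-resolved DEL/INS variant.

    ``start`` is the 0-based half-open start of the REF allele (the position of
    the shared VCF anchor base). ``svlen`` is signed per alternate allele:
    negative for deletions, positive for insertions.
    """

    id: str
    contig: str
    start: int
    ref_allele: str
    alt_alleles: list
    truth_genotype: Optional[tuple] = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.alt_alleles:
            raise ValueError(f"SV {self.id}: at least one alternate allele required")
        self.ref_allele = self.ref_allele.upper()
        self.alt_alleles = [a.upper() for a in self.alt_alleles]
        for alt in self.alt_alleles:
            if not alt or alt[0] != self.ref_allele[0]:
                raise ValueError(
                    f"SV {self.id}: REF and ALT must share a leading anchor base"
                )

    @property
    def end(self) -> int:
        """0-based half-open end of the REF allele on the reference."""
        return self.start + len(self.ref_allele)

    def svlen(self, alt_index: int = 0) -> int:
        return len(self.alt_alleles[alt_index]) - len(self.ref_allele)

    def sv_type(self, alt_index: int = 0) -> str:
        return "DEL" if self.svlen(alt_index) < 0 else "INS"

    @property
    def n_alts(self) -> int:
        return len(self.alt_alleles)

    def allele(self, index: int) -> str:
        """Allele sequence by index; 0 is the reference allele."""
        return self.ref_allele if index == 0 else self.alt_alleles[index - 1]


@dataclass(frozen=True)
class MapBlock:
    """One colinear block of a haplotype-to-reference coordinate map.

    ``ref_start`` is ``None`` for novel (inserted) sequence that maps to no
    reference position.
    """

    hap_start: int
    hap_end: int
    ref_start: Optional[int]

    @property
    def ref_end(self) -> Optional[int]:
        if self.ref_start is None:
            return None
        return self.ref_start + (self.hap_end - self.hap_start)

    def hap_to_ref(self, hap_pos: int) -> Optional[int]:
        if not (self.hap_start <= hap_pos < self.hap_end):
            raise ValueError("position outside block")
        if self.ref_start is None:
            return None
        return self.ref_start + (hap_pos - self.hap_start)


@dataclass
class HaplotypeSeq:
    """A window haplotype plus a piecewise-linear map back to the reference."""

    sequence: str
    blocks: list  # list[MapBlock], non-overlapping, increasing in both systems
    contig: str
    window_start: int  # reference coordinate of the window's left end
    window_end: int
    achieved_left_flank: int
    achieved_right_flank: int

    def __post_init__(self) -> None:
        prev_hap = prev_ref = -1
        for b in self.blocks:
            if b.hap_start < prev_hap:
                raise ValueError("map blocks must be increasing in haplotype coords")
            prev_hap = b.hap_end
            if b.ref_start is not None:
                if b.ref_start < prev_ref:
                    raise ValueError("map blocks must be increasing in reference coords")
                prev_ref = b.ref_end

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenotypeHypothesis:
    """An unordered diploid genotype over allele indices (0 = reference)."""

    alleles: tuple

    def __post_init__(self) -> None:
        a, b = self.alleles
        if a > b:
            object.__setattr__(self, "alleles", (b, a))

    @property
    def label(self) -> str:
        return f"{self.alleles[0]}/{self.alleles[1]}"

    @property
    def is_reference(self) -> bool:
        return self.alleles == (0, 0)

    @property
    def n_alt_alleles(self) -> int:
        return sum(1 for a in self.alleles if a != 0)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def enumerate_hypotheses(sv: SVRecord) -> list:
    """All canonical unordered genotypes over the record's alleles.

    Emitted in VCF genotype-likelihood order (0/0, 0/1, 1/1, 0/2, 1/2, 2/2,
    ...), so a ``Number=G`` FORMAT field lines up index-for-index. For A
    alternate alleles the count is (A+1)(A+2)/2.
    """
    n = sv.n_alts
    return [
        GenotypeHypothesis((j, k)) for k in range(n + 1) for j in range(k + 1)
    ]


def load_svs(
    vcf_path: str,
    reference,
    size_min: int = DEFAULT_SIZE_MIN,
    size_max: int = DEFAULT_SIZE_MAX,
    skip_counts: Optional[dict] = None,
) -> list:
    """Load sequence-resolved DEL/INS records passing type and size filters.

    Records with symbolic alternate alleles (``<DEL>``, breakends, ...),
    non-DEL/INS alleles, or |svlen| outside ``[size_min, size_max]`` are
    skipped and counted in ``skip_counts`` when a dict is supplied.
    Raises ``ValueError`` for contigs absent from the reference.
    """
    counts = skip_counts if skip_counts is not None else {}
    counts.setdefault("symbolic", 0)
    counts.setdefault("type", 0)
    counts.setdefault("size", 0)
    known = set(reference_contigs(reference))

    records = []
    with pysam.VariantFile(vcf_path) as vcf:
        for i, rec in enumerate(vcf):
            try:
                if rec.contig not in known:
                    raise ValueError(
                        f"contig {rec.contig!r} not present in the reference"
                    )
                alts = rec.alts or ()
                if not alts or any(_is_symbolic(a) for a in alts):
                    counts["symbolic"] += 1
                    continue
                kept = []
                for alt in alts:
                    svlen = len(alt) - len(rec.ref)
                    if svlen == 0:
                        counts["type"] += 1
                        kept = None
                        break
                    if not (size_min <= abs(svlen) <= size_max):
                        counts["size"] += 1
                        kept = None
                        break
                    kept.append(alt)
                if not kept:
                    continue
                truth = None
                if rec.samples:
                    gt = rec.samples[0].get("GT")
                    if gt is not None and None not in gt and len(gt) == 2:
                        truth = tuple(sorted(gt))
                records.append(
                    SVRecord(
                        id=rec.id or f"sv_{rec.contig}_{rec.start}",
                        contig=rec.contig,
                        start=rec.start,
                        ref_allele=rec.ref,
                        alt_alleles=list(kept),
                        truth_genotype=truth,
                        info=dict(rec.info),
                    )
                )
            except ValueError:
                raise
            except Exception as exc:  # malformed record
                raise ValueError(f"malformed VCF record #{i + 1} in {vcf_path}: {exc}")
    records.sort(key=lambda r: (r.contig, r.start))
    n_skipped = sum(counts.values())
    if n_skipped:
        logger.info("load_svs: %d records loaded, %d skipped %s", len(records), n_skipped, counts)
    return records


def construct_haplotype(
    sv: SVRecord, allele_index: int, reference, flank_bp: int = 1000
) -> HaplotypeSeq:
    """Build ``left flank + allele + right flank`` with its reference map.

    The map has 2 blocks for the reference allele (split at the variant
    anchor), 2 blocks for a DEL (the deleted bases fall in the gap between
    them) and 3 for an INS (the middle, novel block maps to no reference
    position). Windows running past a contig end are clamped; the achieved
    flanks are recorded on the result.
    """
    contig_len = reference_length(reference, sv.contig)
    win_start = max(0, sv.start - flank_bp)
    win_end = min(contig_len, sv.end + flank_bp)
    left = fetch_reference(reference, sv.contig, win_start, sv.start)
    right = fetch_reference(reference, sv.contig, sv.end, win_end)
    allele = sv.allele(allele_index)
    sequence = left + allele + right

    lflank = len(left)
    rstart = lflank + len(allele)  # hap coord where the right flank begins
    if allele_index == 0:
        blocks = [
            MapBlock(0, lflank + 1, win_start),
            MapBlock(lflank + 1, len(sequence), sv.start + 1),
        ]
        if lflank + 1 >= len(sequence):  # degenerate tiny window
            blocks = [MapBlock(0, len(sequence), win_start)]
    else:
        svlen = sv.svlen(allele_index - 1)
        if svlen < 0:  # DEL: alt maps onto the head of the REF span
            blocks = [
                MapBlock(0, rstart, win_start),
                MapBlock(rstart, len(sequence), sv.end),
            ]
        else:  # INS: shared ref-length head, novel middle, right flank
            shared = lflank + len(sv.ref_allele)
            blocks = [
                MapBlock(0, shared, win_start),
                MapBlock(shared, shared + svlen, None),
                MapBlock(shared + svlen, len(sequence), sv.end),
            ]
    return HaplotypeSeq(
        sequence=sequence,
        blocks=blocks,
        contig=sv.contig,
        window_start=win_start,
        window_end=win_end,
        achieved_left_flank=sv.start - win_start,
        achieved_right_flank=win_end - sv.end,
    )


def write_genotyped_vcf(
    records: Sequence[SVRecord],
    calls: Mapping[str, "GenotypeCallLike"],
    out_path: str,
    reference=None,
    sample: str = "SAMPLE",
) -> None:
    """Write input sites back out with predicted genotypes.

    FORMAT carries GT, the per-hypothesis mean embedding distances (``DS``,
    ``Number=G`` in VCF genotype order), the probability of the called
    genotype (``GP``) and a pass/fail flag (``FT``). Records without a call
    get ``GT=./.`` and ``FT=FAIL``.
    """
    header = pysam.VariantHeader()
    contigs = {}
    for r in records:
        contigs.setdefault(r.contig, 0)
    for contig in contigs:
        if reference is not None:
            header.contigs.add(contig, length=reference_length(reference, contig))
        else:
            header.contigs.add(contig)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", "A", "Integer", "Signed SV length per alternate allele")
    header.info.add("ORIGINAL_POS", 1, "Integer", "1-based original POS before refining")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add(
        "DS", "G", "Float", "Mean actual-simulated embedding distance per genotype"
    )
    header.formats.add(
        "GP", "G", "Float", "Genotype probabilities (softmax of distances)"
    )
    header.formats.add("FT", 1, "String", "Per-call filter: PASS or failure reason")
    header.add_sample(sample)

    with pysam.VariantFile(out_path, "w", header=header) as out:
        for r in sorted(records, key=lambda x: (x.contig, x.start)):
            rec = out.new_record(
                contig=r.contig,
                start=r.start,
                alleles=tuple([r.ref_allele] + list(r.alt_alleles)),
                id=r.id,
            )
            rec.info["SVTYPE"] = r.sv_type(0)
            rec.info["SVLEN"] = tuple(r.svlen(i) for i in range(r.n_alts))
            if "ORIGINAL_POS" in r.info:
                rec.info["ORIGINAL_POS"] = int(r.info["ORIGINAL_POS"])
            call = calls.get(r.id)
            fmt = rec.samples[sample]
            if call is None:
                fmt["GT"] = (None, None)
                fmt["FT"] = "FAIL"
            else:
                fmt["GT"] = tuple(call.called.alleles)
                fmt.phased = False
                order = enumerate_hypotheses(r)
                fmt["DS"] = tuple(
                    float(call.hypothesis_distances[h]) for h in order
                )
                fmt["GP"] = tuple(float(call.probabilities[h]) for h in order)
                fmt["FT"] = call.flag or "PASS"
            out.write(rec)
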