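"""Self-contained synthetic studies: toy reference, planted SVs, reads.

Generates everything the genotyper consumes — a reference contig with planted
tandem repeats, diploid samples with known DEL/INS genotypes, and "actual"
paired-end reads over the whole contig — so training and evaluation run
without any external data. The same fragment sampler and analytic lifting
used for genotype-conditioned simulation produce the actual reads, applied to
each sample's full-length haplotypes.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from svembed.refine import RepeatInterval
from svembed.reads import Fragment
from svembed.simulate import SeqStats, expected_fragments, sample_fragments, write_sam
from svembed.variants import HaplotypeSeq, MapBlock, SVRecord

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class RepeatSpec:
    """A tandem repeat to plant: ``copies`` copies of a random unit.

    ``divergence`` mutates each copy independently at the given per-base
    rate, emulating the unit degeneracy of real tandem repeats (0 = perfect
    copies, fully ambiguous breakpoints).
    """

    unit_length: int
    copies: int
    count: int = 1  # how many such repeats to place
    divergence: float = 0.0


@dataclass
class SyntheticStudy:
    """A toy reference, its repeat annotation, SV truth set and samples."""

    contig: str
    reference: Dict[str, str]
    repeats: List[RepeatInterval]
    svs: List[SVRecord]
    genotypes: Dict[str, Dict[str, Tuple[int, int]]]  # sample -> sv_id -> GT
    samples: List[str]
    manifest: dict = field(default_factory=dict)
    bam_paths: Dict[str, str] = field(default_factory=dict)

    @property
    def sv_by_id(self) -> Dict[str, SVRecord]:
        return {sv.id: sv for sv in self.svs}

    def sample_haplotypes(self, sample: str) -> List[Tuple[str, List[MapBlock]]]:
        """The sample's two haplotype sequences with genome-wide reference maps."""
        gts = self.genotypes[sample]
        haplotypes = []
        for hap_no in range(2):
            chosen = [(sv, gts[sv.id][hap_no]) for sv in self.svs]
            haplotypes.append(apply_alleles(self.reference[self.contig], chosen))
        return haplotypes


def generate_reference(
    length: int,
    gc: float = 0.41,
    repeat_spec: Optional[Sequence[RepeatSpec]] = None,
    seed: int = 0,
    contig: str = "chr1",
    margin: int = 2000,
) -> Tuple[Dict[str, str], List[RepeatInterval]]:
    """An i.i.d. background sequence with planted tandem repeats.

    Repeats are placed uniformly at random, non-overlapping and at least
    ``margin`` bp apart; deterministic per seed. Raises if the requested
    repeats cannot be placed.
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(_ALPHABET, size=length, p=p)
    repeats: List[RepeatInterval] = []
    if repeat_spec:
        occupied: List[Tuple[int, int]] = []
        for spec in repeat_spec:
            for _ in range(spec.count):
                span = spec.unit_length * spec.copies
                if length - span - margin <= margin:
                    raise ValueError(
                        f"cannot place repeat of span {span} bp in {length} bp reference"
                    )
                placed = False
                for _attempt in range(1000):
                    start = int(rng.integers(margin, length - span - margin))
                    if all(
                        start + span + margin <= a or start >= b + margin
                        for a, b in occupied
                    ):
                        placed = True
                        break
                if not placed:
                    raise ValueError(
                        f"cannot place repeat of span {span} bp in {length} bp reference"
                    )
                unit = rng.choice(_ALPHABET, size=spec.unit_length)
                array = np.tile(unit, spec.copies)
                if spec.divergence > 0:
                    hits = np.nonzero(rng.random(span) < spec.divergence)[0]
                    array[hits] = _ALPHABET[rng.integers(0, 4, size=hits.size)]
                seq[start : start + span] = array
                occupied.append((start, start + span))
                repeats.append(
                    RepeatInterval(contig, start, start + span, spec.unit_length)
                )
    repeats.sort(key=lambda r: r.start)
    return {contig: seq.tobytes().decode()}, repeats


def plant_svs(
    reference: Dict[str, str],
    n: int,
    size_range: Tuple[int, int] = (50, 500),
    del_fraction: float = 0.5,
    genotype_mix: Tuple[float, float, float] = (0.34, 0.33, 0.33),
    samples: Sequence[str] = ("S1",),
    seed: int = 0,
    spacing: int = 3000,
    repeats: Sequence[RepeatInterval] = (),
) -> Tuple[List[SVRecord], Dict[str, Dict[str, Tuple[int, int]]]]:
    """Plant ``n`` non-overlapping DEL/INS SVs with per-sample genotypes.

    Sizes are uniform in ``size_range`` (>= 50 bp); per-sample genotypes are
    drawn from ``genotype_mix`` = (p(0/0), p(0/1), p(1/1)), so call sets
    enriched for homozygous reference are directly expressible. SV positions
    avoid planted repeat intervals (those are reserved for refine studies).
    Raises when ``n`` SVs cannot be spaced ``spacing`` bp apart.
    """
    contig = next(iter(reference))
    refseq = reference[contig]
    length = len(refseq)
    lo, hi = size_range
    if lo < 50:
        raise ValueError("SV sizes below 50 bp are not structural variants")
    rng = np.random.default_rng(seed)
    edge = spacing
    usable = length - 2 * edge - n * spacing
    if usable < 0:
        raise ValueError(
            f"cannot place {n} SVs with {spacing} bp spacing in {length} bp reference"
        )
    # stratified-uniform placement keeps spacing guarantees deterministic
    gaps = rng.random(n)
    if n:
        gaps = (gaps / gaps.sum() * usable).astype(int)
    forbidden = [(iv.start - spacing, iv.end + spacing) for iv in repeats]

    svs: List[SVRecord] = []
    genotypes: Dict[str, Dict[str, Tuple[int, int]]] = {s: {} for s in samples}
    gt_choices = [(0, 0), (0, 1), (1, 1)]
    pos = edge
    for i in range(n):
        pos += int(gaps[i])
        size = int(rng.integers(lo, hi + 1))
        while any(a < pos + size + 1 and pos < b for a, b in forbidden):
            pos += spacing  # hop past reserved repeat neighborhoods
        if pos + size + 1 + edge > length:
            raise ValueError("ran out of reference sequence while planting SVs")
        is_del = rng.random() < del_fraction
        if is_del:
            ref_allele = refseq[pos : pos + size + 1]
            rec = SVRecord(
                id=f"sv{i:04d}_DEL",
                contig=contig,
                start=pos,
                ref_allele=ref_allele,
                alt_alleles=[ref_allele[0]],
            )
        else:
            anchor = refseq[pos]
            insert = rng.choice(_ALPHABET, size=size).tobytes().decode()
            rec = SVRecord(
                id=f"sv{i:04d}_INS",
                contig=contig,
                start=pos,
                ref_allele=anchor,
                alt_alleles=[anchor + insert],
            )
        svs.append(rec)
        for s in samples:
            gt = gt_choices[int(rng.choice(3, p=genotype_mix))]
            genotypes[s][rec.id] = gt
        pos += spacing
    return svs, genotypes


def plant_offset_repeat_dels(
    reference: Dict[str, str],
    repeats: Sequence[RepeatInterval],
    units_deleted: int = 2,
    offset_range: Tuple[int, int] = (10, 150),
    genotype_mix: Tuple[float, float, float] = (0.0, 0.5, 0.5),
    samples: Sequence[str] = ("S1",),
    seed: int = 0,
) -> Tuple[List[SVRecord], List[SVRecord], Dict[str, Dict[str, Tuple[int, int]]]]:
    """Plant whole-unit deletions inside tandem repeats, then mis-report them.

    For each repeat interval a deletion of ``units_deleted`` repeat units is
    planted at a unit boundary (the *true* record). A second, *reported*
    record of the same length but with a start offset by a value drawn from
    ``offset_range`` (sign random, clamped into the repeat) emulates an
    imprecise SV description. Returns (true_records, reported_records,
    genotypes-for-true-records).
    """
    contig = next(iter(reference))
    refseq = reference[contig]
    rng = np.random.default_rng(seed)
    true_recs: List[SVRecord] = []
    reported: List[SVRecord] = []
    genotypes: Dict[str, Dict[str, Tuple[int, int]]] = {s: {} for s in samples}
    gt_choices = [(0, 0), (0, 1), (1, 1)]
    for j, iv in enumerate(repeats):
        unit = iv.unit_length
        if unit is None:
            raise ValueError("repeat intervals need a unit length for offset planting")
        copies = (iv.end - iv.start) // unit
        if copies <= units_deleted + 1:
            raise ValueError("repeat too short to delete the requested units")
        dlen = units_deleted * unit
        # plant at a unit boundary away from the repeat edges
        unit_at = int(rng.integers(1, copies - units_deleted))
        true_start = iv.start + unit_at * unit - 1  # anchor base precedes the unit
        ref_allele = refseq[true_start : true_start + dlen + 1]
        rec = SVRecord(
            id=f"rdel{j:03d}",
            contig=contig,
            start=true_start,
            ref_allele=ref_allele,
            alt_alleles=[ref_allele[0]],
        )
        true_recs.append(rec)
        offset = int(rng.integers(*offset_range)) * int(rng.choice([-1, 1]))
        rep_start = int(np.clip(true_start + offset, iv.start, iv.end - dlen - 1))
        rep_allele = refseq[rep_start : rep_start + dlen + 1]
        reported.append(
            SVRecord(
                id=f"rdel{j:03d}",
                contig=contig,
                start=rep_start,
                ref_allele=rep_allele,
                alt_alleles=[rep_allele[0]],
            )
        )
        for s in samples:
            gt = gt_choices[int(rng.choice(3, p=genotype_mix))]
            genotypes[s][rec.id] = gt
    return true_recs, reported, genotypes


def apply_alleles(
    refseq: str, svs_with_allele: Sequence[Tuple[SVRecord, int]]
) -> Tuple[str, List[MapBlock]]:
    """Apply chosen alleles to a reference sequence, tracking the coordinate map.

    ``svs_with_allele`` pairs each (position-sorted, non-overlapping) SV with
    the allele index carried by this haplotype (0 = reference). Returns the
    haplotype sequence and its genome-wide block map.
    """
    parts: List[str] = []
    blocks: List[MapBlock] = []
    cursor = 0
    hap_pos = 0
    for sv, allele_idx in sorted(svs_with_allele, key=lambda t: t[0].start):
        if allele_idx == 0:
            continue
        if sv.start < cursor:
            raise ValueError(f"overlapping SVs at {sv.id}")
        seg = refseq[cursor : sv.start]
        if seg:
            blocks.append(MapBlock(hap_pos, hap_pos + len(seg), cursor))
            parts.append(seg)
            hap_pos += len(seg)
        allele = sv.allele(allele_idx)
        svlen = sv.svlen(allele_idx - 1)
        parts.append(allele)
        if svlen < 0:  # DEL: allele maps colinearly onto the head of the REF span
            blocks.append(MapBlock(hap_pos, hap_pos + len(allele), sv.start))
        else:  # INS: shared head then novel middle
            shared = len(sv.ref_allele)
            blocks.append(MapBlock(hap_pos, hap_pos + shared, sv.start))
            blocks.append(MapBlock(hap_pos + shared, hap_pos + len(allele), None))
        hap_pos += len(allele)
        cursor = sv.end
    tail = refseq[cursor:]
    if tail:
        blocks.append(MapBlock(hap_pos, hap_pos + len(tail), cursor))
        parts.append(tail)
    return "".join(parts), blocks


def generate_actual_reads(
    study: SyntheticStudy,
    sample: str,
    stats: SeqStats,
    seed: int,
    out_dir: str,
    phased: bool = False,
) -> str:
    """Whole-contig paired-end reads for one sample, as sorted+indexed BAM.

    Each haplotype contributes half the target coverage; reads are lifted to
    reference coordinates through the sample's genome-wide haplotype map.
    ``phased`` adds HP tags recording the source haplotype.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(sample.encode())]))
    contig = study.contig
    refseq = study.reference[contig]
    fragments: List[Fragment] = []
    rep_tuples = [(iv.start, iv.end) for iv in study.repeats]
    for hap_no, (seq, blocks) in enumerate(study.sample_haplotypes(sample)):
        hap = HaplotypeSeq(
            sequence=seq,
            blocks=blocks,
            contig=contig,
            window_start=0,
            window_end=len(refseq),
            achieved_left_flank=0,
            achieved_right_flank=0,
        )
        n = int(rng.poisson(expected_fragments(len(seq), stats, 0.5)))
        fragments.extend(
            sample_fragments(
                hap,
                n,
                stats,
                rng,
                name_prefix=f"{sample}_h{hap_no}",
                hap_tag=(hap_no + 1) if phased else 0,
                repeat_intervals=rep_tuples,
            )
        )
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, f"{sample}.bam")
    write_sam(
        fragments,
        contig,
        len(refseq),
        path,
        sort_and_index=True,
        reference_seq=refseq,
    )
    study.bam_paths[sample] = path
    return path


def split_train_eval(study: SyntheticStudy, held_out_samples: Sequence[str]):
    """Split samples for training/evaluation, dropping private held-out SVs.

    SVs whose only nonreference genotypes occur in held-out samples are
    removed from the training SV list (they carry no labeled nonreference
    signal for the training samples).
    """
    held = set(held_out_samples)
    unknown = held - set(study.samples)
    if unknown:
        raise ValueError(f"unknown samples: {sorted(unknown)}")
    train_samples = [s for s in study.samples if s not in held]
    train_svs = []
    for sv in study.svs:
        nonref_in_train = any(
            study.genotypes[s][sv.id] != (0, 0) for s in train_samples
        )
        nonref_anywhere = any(
            study.genotypes[s][sv.id] != (0, 0) for s in study.samples
        )
        if nonref_anywhere and not nonref_in_train:
            continue  # private to held-out samples
        train_svs.append(sv)
    return train_samples, train_svs, sorted(held)


def make_trio(
    study: SyntheticStudy,
    father: str,
    mother: str,
    child: str,
    seed: int = 0,
) -> None:
    """Rewrite the child's genotypes by faithful Mendelian transmission.

    One allele is drawn uniformly from each parent's genotype at every SV, so
    the resulting trio contains no Mendelian errors by construction.
    """
    for s in (father, mother, child):
        if s not in study.samples:
            raise ValueError(f"unknown sample {s!r}")
    rng = np.random.default_rng(seed)
    for sv in study.svs:
        pa = study.genotypes[father][sv.id]
        ma = study.genotypes[mother][sv.id]
        gt = tuple(sorted((pa[int(rng.integers(2))], ma[int(rng.integers(2))])))
        study.genotypes[child][sv.id] = gt


def write_truth_vcf(study: SyntheticStudy, path: str) -> str:
    """Write the truth set with per-sample genotypes."""
    header = pysam.VariantHeader()
    header.contigs.add(study.contig, length=len(study.reference[study.contig]))
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", "A", "Integer", "Signed SV length per alternate allele")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in study.samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for sv in sorted(study.svs, key=lambda r: r.start):
            rec = out.new_record(
                contig=sv.contig,
                start=sv.start,
                alleles=tuple([sv.ref_allele] + sv.alt_alleles),
                id=sv.id,
            )
            rec.info["SVTYPE"] = sv.sv_type(0)
            rec.info["SVLEN"] = tuple(sv.svlen(i) for i in range(sv.n_alts))
            for s in study.samples:
                rec.samples[s]["GT"] = study.genotypes[s][sv.id]
                rec.samples[s].phased = False
            out.write(rec)
    return path


def write_reference_fasta(study: SyntheticStudy, path: str) -> str:
    with open(path, "w") as fh:
        for contig, seq in study.reference.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    pysam.faidx(path)
    return path


def write_repeats_bed(study: SyntheticStudy, path: str) -> str:
    with open(path, "w") as fh:
        for iv in study.repeats:
            unit = iv.unit_length if iv.unit_length is not None else "."
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{unit}\n")
    return path


def generate_study(
    length: int = 1_000_000,
    n_svs: int = 100,
    samples: Sequence[str] = ("S1", "S2", "S3"),
    size_range: Tuple[int, int] = (50, 500),
    del_fraction: float = 0.5,
    genotype_mix: Tuple[float, float, float] = (0.34, 0.33, 0.33),
    repeat_spec: Optional[Sequence[RepeatSpec]] = None,
    seed: int = 0,
    spacing: int = 3000,
    contig: str = "chr1",
) -> SyntheticStudy:
    """Convenience wrapper: reference + repeats + SV truth set in one call."""
    reference, repeats = generate_reference(
        length, repeat_spec=repeat_spec, seed=seed, contig=contig
    )
    svs, genotypes = plant_svs(
        reference,
        n_svs,
        size_range=size_range,
        del_fraction=del_fraction,
        genotype_mix=genotype_mix,
        samples=samples,
        seed=seed + 1,
        spacing=spacing,
        repeats=repeats,
    )
    manifest = {
        "length": length,
        "n_svs": n_svs,
        "samples": list(samples),
        "size_range": list(size_range),
        "del_fraction": del_fraction,
        "genotype_mix": list(genotype_mix),
        "seed": seed,
        "spacing": spacing,
        "contig": contig,
    }
    return SyntheticStudy(
        contig=contig,
        reference=reference,
        repeats=repeats,
        svs=svs,
        genotypes=genotypes,
        samples=list(samples),
        manifest=manifest,
    )


def save_manifest(study: SyntheticStudy, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {**study.manifest, "bam_paths": study.bam_paths},
            fh,
            indent=2,
        )
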