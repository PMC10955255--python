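"""Shared fixtures: tiny references, VCF writers, read builders."""

import numpy as np
import pysam
import pytest

from svembed.reads import CIGAR_M, AlignedRead, Fragment
from svembed.simulate import SeqStats
from svembed.variants import SVRecord


@pytest.fixture(scope="session")
def stats() -> SeqStats:
    return SeqStats(
        mean_coverage=28,
        read_length=70,
        insert_mean=250,
        insert_sd=40,
        base_error_rate=0.002,
    )


@pytest.fixture(scope="session")
def tiny_reference() -> dict:
    """A 30 kb deterministic reference contig (dict form, no files needed)."""
    rng = np.random.default_rng(1234)
    seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=30_000)
    return {"chr1": seq.tobytes().decode()}


@pytest.fixture
def del_sv(tiny_reference) -> SVRecord:
    """A 200 bp deletion at position 15000."""
    ref = tiny_reference["chr1"]
    return SVRecord(
        id="del200",
        contig="chr1",
        start=15_000,
        ref_allele=ref[15_000 : 15_201],
        alt_alleles=[ref[15_000]],
    )


@pytest.fixture
def ins_sv(tiny_reference) -> SVRecord:
    """A 120 bp insertion at position 10000."""
    ref = tiny_reference["chr1"]
    rng = np.random.default_rng(77)
    insert = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=120).tobytes().decode()
    return SVRecord(
        id="ins120",
        contig="chr1",
        start=10_000,
        ref_allele=ref[10_000],
        alt_alleles=[ref[10_000] + insert],
    )


def make_read(
    ref: str,
    start: int,
    length: int = 70,
    name: str = "r",
    qual: int = 30,
    **kwargs,
) -> AlignedRead:
    """A perfectly matching ungapped read sampled from a reference string."""
    return AlignedRead(
        name=name,
        seq=ref[start : start + length],
        quals=np.full(length, qual, dtype=np.uint8),
        ref_start=start,
        cigar=[(CIGAR_M, length)],
        **kwargs,
    )


def make_fragment(ref: str, start: int, insert: int = 250, length: int = 70, name: str = "f", **kw) -> Fragment:
    r1 = make_read(ref, start, length, name=name, is_reverse=False, **kw)
    r2 = make_read(ref, start + insert - length, length, name=name, is_reverse=True, **kw)
    return Fragment(reads=[r1, r2], insert_size=insert, name=name)


def write_vcf(path, records, reference, sample_gts=None, sample="S1", extra_lines=()):
    """Write a minimal plain-text VCF for test inputs.

    ``records`` may contain SVRecord objects or raw (contig, pos0, id, ref,
    alts) tuples (for symbolic-allele cases).
    """
    contigs = {}
    for rec in records:
        contig = rec.contig if isinstance(rec, SVRecord) else rec[0]
        contigs[contig] = len(reference[contig])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, ln in contigs.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for line in extra_lines:
            fh.write(line + "\n")
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if sample_gts is not None:
            cols += f"\tFORMAT\t{sample}"
        fh.write(cols + "\n")
        for i, rec in enumerate(records):
            if isinstance(rec, SVRecord):
                contig, pos0, rid = rec.contig, rec.start, rec.id
                ref_a, alts = rec.ref_allele, ",".join(rec.alt_alleles)
            else:
                contig, pos0, rid, ref_a, alts = rec
            row = f"{contig}\t{pos0 + 1}\t{rid}\t{ref_a}\t{alts}\t.\tPASS\t."
            if sample_gts is not None:
                gt = sample_gts[i]
                row += f"\tGT\t{gt[0]}/{gt[1]}" if gt is not None else "\tGT\t./."
            fh.write(row + "\n")
    return str(path)


class DictReference(dict):
    """Plain mapping reference; exercises the non-pysam fetch path."""
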