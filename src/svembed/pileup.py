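"""Render read pileups over an SV window as fixed-size multi-channel images.

Each fragment (read pair) occupies one image row across its full reference
span; the unsequenced inter-mate gap stays black. Nine feature channels are
encoded per sequenced base; a pixel whose channel 0 is exactly zero means "no
sequenced base here" and all its other channels are zero too. The
variable-width pileup (one column per reference base) is compressed to the
fixed network width by area-weighted averaging, which conserves coverage mass.

Channel map (values in [0, 1]; nonzero floors distinguish "low/absent feature"
from "no base"):

0. base presence/match: 1.0 match, 0.6 mismatch, 0.3 soft-clipped
1. base quality / 60 (capped at 60)
2. mapping quality / 60 (capped at 60)
3. strand: forward 1.0, reverse 0.5
4. insert-size percentile under the reference-allele insert distribution
5. pair status: proper 1.0, discordant 0.5, unpaired/mate-unmapped 0.25
6. allele realignment support s = sigmoid(alt_score - ref_score)
7. clipped / split-adjacent indicator: 1.0 at such bases, else 0.5
8. phasing tag: untagged 0.33, haplotype 1 0.66, haplotype 2 1.0
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Union

import edlib
import numpy as np
import pysam
from scipy.stats import norm

from svembed.reads import (
    CIGAR_D,
    CIGAR_I,
    CIGAR_M,
    CIGAR_S,
    AlignedRead,
    Fragment,
    fragments_from_alignments,
    name_hash,
)
from svembed.simulate import SeqStats
from svembed.variants import HaplotypeSeq, SVRecord, fetch_reference, reference_length

N_CHANNELS = 9

CH_BASE = 0
CH_BASEQ = 1
CH_MAPQ = 2
CH_STRAND = 3
CH_INSERT = 4
CH_PAIR = 5
CH_REALIGN = 6
CH_CLIP = 7
CH_HAPLOTYPE = 8

VAL_MATCH = 1.0
VAL_MISMATCH = 0.6
VAL_SOFTCLIP = 0.3


class Window(NamedTuple):
    contig: str
    start: int  # 0-based half-open
    end: int


@dataclass
class ImageConfig:
    """Pileup image geometry and rendering options."""

    height: int = 100
    width: int = 300
    channels: int = N_CHANNELS
    render_flank: Optional[int] = None  # default: insert_mean + 2*insert_sd
    realign_flank: Optional[int] = None  # default: 2*read_length (junction-local)

    def __post_init__(self) -> None:
        if self.channels != N_CHANNELS:
            raise ValueError(f"channel count is fixed at {N_CHANNELS}")
        if self.height < 1 or self.width < 1:
            raise ValueError("image height and width must be positive")

    def flank_for(self, stats: SeqStats) -> int:
        if self.render_flank is not None:
            return self.render_flank
        return int(stats.insert_mean + 2 * stats.insert_sd)

    def realign_flank_for(self, stats: SeqStats) -> int:
        """Flank of the haplotypes used as realignment targets (channel 6).

        Defaults to the render flank plus one read length, so any read in
        the image can align fully to either target; reads in shared flank
        sequence score equally on both and stay at the uninformative 0.5.
        """
        if self.realign_flank is not None:
            return self.realign_flank
        return self.flank_for(stats) + stats.read_length


@dataclass
class ImageTensor:
    """H x W x C pileup image with its genomic window and provenance."""

    data: np.ndarray
    region: Window
    provenance: str = "actual"  # or "simulated:<genotype>:<replicate>"

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[2] != N_CHANNELS:
            raise ValueError(f"image must be H x W x {N_CHANNELS}")


def gather_fragments(
    alignments: Union[str, pysam.AlignmentFile, Sequence[Fragment]],
    region: Window,
    max_rows: int,
    seed: int = 0,
) -> list:
    """Fragments overlapping ``region``, position-sorted, randomly downsampled.

    When more than ``max_rows`` fragments overlap the window, a uniform random
    subset of exactly ``max_rows`` is retained (reproducible for a given
    seed), mirroring how deep pileups are thinned to the image height.
    """
    if isinstance(alignments, (str, pysam.AlignmentFile)):
        handle = (
            alignments
            if isinstance(alignments, pysam.AlignmentFile)
            else pysam.AlignmentFile(alignments)
        )
        try:
            fragments = fragments_from_alignments(
                handle, region.contig, region.start, region.end
            )
        except ValueError as exc:
            raise ValueError(
                f"alignment file must be coordinate-sorted and indexed: {exc}"
            )
        finally:
            if not isinstance(alignments, pysam.AlignmentFile):
                handle.close()
    else:
        fragments = [
            f
            for f in alignments
            if f.ref_start < region.end and f.ref_end > region.start
        ]
        fragments = sorted(fragments, key=lambda f: (f.ref_start, name_hash(f.name)))
    if len(fragments) > max_rows:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(fragments), size=max_rows, replace=False)
        fragments = [fragments[i] for i in sorted(keep)]
    return fragments


def _glocal_score(seq: str, haplotype: str) -> float:
    """Negative best infix edit distance of the read against the haplotype."""
    if not seq:
        return 0.0
    res = edlib.align(seq, haplotype, mode="HW", task="distance")
    return -float(res["editDistance"])


def realign_fragment(
    fragment: Fragment,
    ref_haplotype: HaplotypeSeq,
    alt_haplotypes: Union[HaplotypeSeq, Sequence[HaplotypeSeq]],
) -> tuple:
    """Score the fragment's reads against the reference and alternate haplotypes.

    The per-haplotype score is the summed best glocal (whole-read vs haplotype
    infix) alignment score over the fragment's reads. Returns
    ``(ref_score, [alt_score, ...])``; the normalized support value is
    ``support_value(ref_score, alt_scores)``.
    """
    if isinstance(alt_haplotypes, HaplotypeSeq):
        alt_haplotypes = [alt_haplotypes]
    ref_score = sum(_glocal_score(r.seq, ref_haplotype.sequence) for r in fragment.reads)
    alt_scores = [
        sum(_glocal_score(r.seq, alt.sequence) for r in fragment.reads)
        for alt in alt_haplotypes
    ]
    return ref_score, alt_scores


def support_value(ref_score: float, alt_scores: Sequence[float]) -> float:
    """Map realignment scores to [0, 1]; 0.5 = uninformative read."""
    best_alt = max(alt_scores)
    return float(1.0 / (1.0 + np.exp(-(best_alt - ref_score))))


def _insert_percentile(insert_size: int, stats: SeqStats) -> float:
    if insert_size <= 0:
        return 0.5
    return float(norm.cdf(insert_size, loc=stats.insert_mean, scale=stats.insert_sd))


def encode_base_features(
    fragment: Fragment,
    window: Window,
    stats: SeqStats,
    ref_seq: str,
) -> np.ndarray:
    """Per-base feature vectors for one fragment across the window.

    Returns a ``(window length, 9)`` float32 array; columns not covered by a
    sequenced base of this fragment are all-zero. ``ref_seq`` must be the
    reference sequence of exactly this window (used for mismatch marking).
    """
    width = window.end - window.start
    arr = np.zeros((width, N_CHANNELS), dtype=np.float32)
    ref_arr = np.frombuffer(ref_seq.upper().encode(), dtype=np.uint8)
    if len(ref_arr) != width:
        raise ValueError("ref_seq length must equal the window length")
    ins_pct = _insert_percentile(fragment.insert_size, stats)

    for read in fragment.reads:
        qseq = np.frombuffer(read.seq.encode(), dtype=np.uint8)
        quals = np.minimum(read.quals.astype(np.float32), 60.0) / 60.0
        covered = np.zeros(width, dtype=bool)
        junctions = []  # columns adjacent to indel junctions
        pos = read.ref_start
        qpos = 0
        n_ops = len(read.cigar)
        for k, (op, length) in enumerate(read.cigar):
            if op == CIGAR_M:
                c0, c1 = pos - window.start, pos - window.start + length
                lo, hi = max(c0, 0), min(c1, width)
                if lo < hi:
                    qs = qpos + (lo - c0)
                    qe = qs + (hi - lo)
                    match = qseq[qs:qe] == ref_arr[lo:hi]
                    arr[lo:hi, CH_BASE] = np.where(match, VAL_MATCH, VAL_MISMATCH)
                    arr[lo:hi, CH_BASEQ] = quals[qs:qe]
                    arr[lo:hi, CH_CLIP] = 0.5
                    covered[lo:hi] = True
                pos += length
                qpos += length
            elif op == CIGAR_I:
                for col in (pos - window.start - 1, pos - window.start):
                    if 0 <= col < width and covered[col]:
                        arr[col, CH_CLIP] = 1.0
                junctions.append(pos)
                qpos += length
            elif op == CIGAR_D:
                for col in (pos - window.start - 1, pos + length - window.start):
                    if 0 <= col < width:
                        junctions.append(col + window.start)
                pos += length
            elif op == CIGAR_S:
                # paint clipped bases extrapolated from the anchor
                if k == 0 and not read.anchored_only:
                    c0 = read.ref_start - length - window.start
                else:
                    c0 = pos - window.start
                c1 = c0 + length
                lo, hi = max(c0, 0), min(c1, width)
                if lo < hi:
                    qs = qpos + (lo - c0)
                    qe = qs + (hi - lo)
                    arr[lo:hi, CH_BASE] = VAL_SOFTCLIP
                    arr[lo:hi, CH_BASEQ] = quals[qs:qe]
                    arr[lo:hi, CH_CLIP] = 1.0
                    covered[lo:hi] = True
                qpos += length
        # split-adjacent bases flank deletion/insertion junctions
        for ref_pos in junctions:
            col = ref_pos - window.start
            if 0 <= col < width and covered[col]:
                arr[col, CH_CLIP] = 1.0
        if not covered.any():
            continue
        arr[covered, CH_MAPQ] = min(read.mapq, 60) / 60.0
        arr[covered, CH_STRAND] = 0.5 if read.is_reverse else 1.0
        if not read.has_mate or read.mate_unmapped:
            pair = 0.25
        elif read.is_proper:
            pair = 1.0
        else:
            pair = 0.5
        arr[covered, CH_PAIR] = pair
        arr[covered, CH_HAPLOTYPE] = (0.33, 0.66, 1.0)[read.hap_tag]
        arr[covered, CH_INSERT] = ins_pct
        arr[covered, CH_REALIGN] = fragment.realign_support
    return arr


def render_image(
    fragments: Sequence[Fragment],
    window: Window,
    config: ImageConfig,
    stats: SeqStats,
    ref_seq: str,
    provenance: str = "actual",
) -> ImageTensor:
    """Stack encoded fragment rows top-down and compress to the fixed width.

    ``fragments`` should come from :func:`gather_fragments` (position-sorted,
    at most ``config.height`` rows after downsampling); surplus rows are
    dropped from the bottom. Absent bases are all-zero pixels.
    """
    width = window.end - window.start
    if width <= 0:
        raise ValueError("window length must be positive")
    variable = np.zeros((config.height, width, N_CHANNELS), dtype=np.float32)
    for i, fragment in enumerate(fragments[: config.height]):
        variable[i] = encode_base_features(fragment, window, stats, ref_seq)
    data = compress_width(variable, config.width)
    return ImageTensor(data=data, region=window, provenance=provenance)


def compress_width(variable_image: np.ndarray, target_w: int) -> np.ndarray:
    """Area-weighted average pooling along the width axis onto ``target_w`` bins.

    Narrow images (width <= target) are left-anchored and zero-padded rather
    than stretched. For widths divisible by ``target_w`` this is an exact
    block mean, so per-channel means are conserved.
    """
    h, w, c = variable_image.shape
    if w == target_w:
        return variable_image.copy()
    if w < target_w:
        out = np.zeros((h, target_w, c), dtype=variable_image.dtype)
        out[:, :w] = variable_image
        return out
    prefix = np.zeros((h, w + 1, c), dtype=np.float64)
    np.cumsum(variable_image, axis=1, out=prefix[:, 1:])
    edges = np.linspace(0.0, float(w), target_w + 1)
    idx = np.minimum(edges.astype(int), w)
    frac = edges - idx
    contrib = variable_image[:, np.minimum(idx, w - 1), :] * frac[None, :, None]
    integrals = prefix[:, idx, :] + contrib
    out = (integrals[:, 1:] - integrals[:, :-1]) / (w / target_w)
    return out.astype(variable_image.dtype)


def sv_window(sv: SVRecord, flank: int, reference=None) -> Window:
    """The image window: union of the record's allele spans plus flanks."""
    start = max(0, sv.start - flank)
    end = sv.end + flank
    if reference is not None:
        end = min(end, reference_length(reference, sv.contig))
    return Window(sv.contig, start, end)


def render_sv_image(
    sv: SVRecord,
    fragments: Sequence[Fragment],
    reference,
    stats: SeqStats,
    config: ImageConfig,
    ref_haplotype: HaplotypeSeq,
    alt_haplotypes: Sequence[HaplotypeSeq],
    provenance: str = "actual",
) -> ImageTensor:
    """Realign fragments against the candidate haplotypes and render the image."""
    window = sv_window(sv, config.flank_for(stats), reference)
    ref_seq = fetch_reference(reference, window.contig, window.start, window.end)
    for fragment in fragments:
        ref_score, alt_scores = realign_fragment(fragment, ref_haplotype, alt_haplotypes)
        fragment.realign_support = support_value(ref_score, alt_scores)
    return render_image(fragments, window, config, stats, ref_seq, provenance)


def export_composite_png(image: ImageTensor, path: str) -> None:
    """Write a grid of the per-channel images for manual review."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 3, figsize=(12, 8))
    names = [
        "base/match",
        "base quality",
        "mapping quality",
        "strand",
        "insert percentile",
        "pair status",
        "realign support",
        "clip/split",
        "haplotype",
    ]
    for ch, ax in enumerate(axes.flat):
        ax.imshow(image.data[:, :, ch], cmap="gray", vmin=0, vmax=1, aspect="auto")
        ax.set_title(names[ch], fontsize=8)
        ax.axis("off")
    fig.suptitle(f"{image.region.contig}:{image.region.start}-{image.region.end} ({image.provenance})")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
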