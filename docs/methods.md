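# Methods

## The genotyping model

svembed genotypes previously reported, sequence-resolved deletion (DEL) and
insertion (INS) structural variants (SVs, >= 50 bp) in short-read sequencing
data. Rather than classifying the observed evidence directly, it treats
genotyping as an *image similarity* problem:

1. The reads overlapping the SV window are rendered as a multi-channel pileup
   image (the **actual** image).
2. For each candidate diploid genotype (0/0, 0/1, 1/1 for a bi-allelic
   record; all unordered allele pairs for multi-allelic records), reads are
   *simulated* from the haplotypes that genotype implies, using a sequencing
   profile matched to the actual data, and rendered the same way
   (**simulated** images).
3. A shared-weight convolutional encoder maps both images into a
   d-dimensional embedding space. The genotype whose simulated images embed
   closest to the actual image (mean Euclidean distance over replicates, and
   over ensemble members when several models are supplied) is called.
   Genotype probabilities are the softmax of the negated per-genotype
   distances, `p(g) = exp(-d_g / tau) / sum_h exp(-d_h / tau)`.

The encoder is trained with contrastive loss over actual/simulated pairs,

    L(Y, D) = Y * D^2 + (1 - Y) * max(m - D, 0)^2,

with `Y = 1` iff the simulated genotype equals the truth genotype and `D`
the embedding distance: matched pairs are pulled together, mismatched pairs
pushed beyond the margin `m`. Because the network only judges *similarity*,
it generalizes to SVs never seen in training; the per-SV signal comes from
the simulations performed at genotyping time.

### Assumptions

- Input SVs are sequence-resolved (full REF/ALT strings; symbolic alleles
  are rejected) so that candidate haplotypes can be constructed and
  simulated. Each VCF record is treated independently — no compound
  heterozygotes or multi-SV haplotypes.
- Diploid samples; genotypes are reported unphased.
- The sequencing profile (coverage, read length, insert-size mean/sd, base
  error rate) is stationary enough that a genome-wide estimate applies at
  each SV locus.

## Pileup images

Images are `H x W x 9` tensors in `[0, 1]` (defaults H=100, W=300). Each
*fragment* (read pair) occupies one row across its whole reference span; the
unsequenced gap between mates stays black. A pixel with channel 0 equal to 0
means "no sequenced base here", and all its other channels are 0 — black is
reserved for absence. All feature floors are therefore nonzero (e.g. 0.25,
0.3, 0.33, 0.5) so "feature at its lowest level" stays distinguishable from
"no base". The nine channels:

| ch | feature | encoding |
|----|---------|----------|
| 0 | base presence/match | match 1.0, mismatch 0.6, soft-clip 0.3 |
| 1 | base quality | q/60, capped at 60 |
| 2 | mapping quality | mapq/60, capped at 60 |
| 3 | strand | forward 1.0, reverse 0.5 |
| 4 | insert size | Normal-CDF percentile under the reference-allele insert distribution |
| 5 | pair status | proper 1.0, discordant 0.5, unpaired/mate-unmapped 0.25 |
| 6 | allele realignment support | `s = sigmoid(alt_score - ref_score)`; 0.5 = uninformative |
| 7 | clip/split indicator | clipped or junction-adjacent 1.0, else 0.5 |
| 8 | phasing tag | untagged 0.33, haplotype 1 0.66, haplotype 2 1.0 |

Realignment scores (channel 6) are negative glocal edit distances — the
whole read aligned to the best-matching infix of the candidate reference and
alternate haplotypes (computed with edlib) — summed over the fragment's
reads. For multi-allelic records the best alternate score is used.

The window spans the SV plus a flank (default `insert_mean + 2*insert_sd`,
so discordant-pair evidence is visible). One column per reference base gives
a variable-width image; it is compressed to the fixed width by area-weighted
average pooling, which conserves per-channel coverage mass exactly (block
means when the width divides evenly). Narrow windows are left-anchored and
zero-padded, never stretched. When more fragments overlap the window than
the image height, a uniform random subset of exactly H fragments is kept
(seeded, reproducible); H defaults to 100 so that typical 30-40x data is not
downsampled. Rows are sorted by leftmost position with a stable name-hash
tie-break, so rendering is deterministic.

## Simulation and analytic lifting

Genotype-conditioned replicates are drawn directly from the candidate
haplotype sequences: each haplotype contributes an expected
`mean_coverage/2`; insert sizes follow a truncated Normal
(`[2*read_length, insert_mean + 5*insert_sd]`); substitution errors are
i.i.d. at the profile's base error rate, with constant base qualities set to
match. Instead of realigning simulated reads, alignments are *lifted*
analytically through the haplotype's known breakpoint map: reads inside one
colinear block become ungapped matches, reads crossing a deletion junction
become split (D-gapped) alignments, reads overhanging inserted sequence are
soft-clipped at the anchor, reads spanning a whole insertion carry it as an
insertion op, and reads entirely inside novel sequence become fully
soft-clipped anchors at the insertion point. Mapping quality is 60 except
for reads fully contained in an annotated repeat interval, which get 20 —
a deliberately coarse stand-in for aligner ambiguity in repeats, applied
identically to simulated and synthetic "actual" reads so the two remain
comparable. No GC bias, PCR duplicates or sequencer-specific error profiles
are modeled; the paired design tolerates simulator simplicity because both
sides of each comparison share it.

The sequencing profile is estimated from sampled regions of the actual BAM
(mean aligned-base depth; insert moments from proper pairs after one pass of
10-SD outlier rejection; error rate from the NM mismatch rate of high-mapq
reads), or supplied explicitly.

## Network and training

The encoder is a small convolutional network implemented directly on numpy
arrays (forward and backward passes, Adam optimizer): two 3x3
conv/ReLU/2x2-average-pool stages (12 and 24 filters), collapse over image
height, adaptive area-average pooling of the width axis to 16 columns, a
linear projection to d dimensions, and L2 normalization. Embedding dimension
defaults to 512; the benchmark studies use d=32, where the synthetic task
saturates. Distances are Euclidean. Training pairs share one actual image
per SV across all hypotheses; labels follow the truth genotype. Default
margin m=1.0, learning rate 1e-3, batch 32. Training is stochastic;
the reproducibility contract is that a seeded run reproduces the recorded
loss curve, not bit-identical weights. Checkpoints embed the image geometry
and refuse to load under a mismatched runtime geometry. Ensembles average
the distances predicted independently by each member.

Tie-breaks: equal per-genotype distances resolve toward fewer alternate
alleles (0/0 < 0/1 < 1/1) — conservative calls. Windows with no reads yield
a flagged (`NO_READS`) homozygous-reference call with uniform probabilities
rather than a missing genotype.

## Breakpoint refining (DEL only)

Reported breakpoints inside tandem repeats are frequently offset from the
true ones. For a deletion overlapping annotated repeat intervals, the
refiner: (1) proposes a same-length deletion at every stride-th start across
the union of overlapping intervals (REF re-read from the reference);
(2) collapses proposals whose alternate haplotypes are byte-identical —
indistinguishable by any read evidence — keeping the leftmost; (3) discards
proposals none of whose *novel junction k-mers* (k=31 k-mers spanning the
proposed breakpoint and absent from the local reference) occur at least
`min_support=2` times in the reads; proposals with no novel junction k-mers
at all are retained, since absence of evidence cannot rule them out, and the
original description is always kept; (4) genotypes every surviving proposal;
(5) smooths each genotype's distance series along the start coordinate with
an exponentially weighted moving average (`alpha = 0.3` per stride; the
carry-over decays as `(1-alpha)**(gap/stride)` across gaps left by
filtering, so sparse survivors do not smear each other); and (6) selects,
among proposals whose smallest smoothed distance belongs to a nonreference
genotype, the one with the globally smallest smoothed nonreference distance
(ties to the smaller |offset|). If no proposal qualifies, the original
description and its own call stand. Refining never changes the deletion
length, only its position.

## Synthetic studies

The synthetic module generates everything the genotyper consumes: an i.i.d.
background reference with planted tandem repeats (optionally with per-copy
divergence — real tandem repeats are degenerate, and divergence is what
makes breakpoint placements distinguishable at all), non-overlapping DEL/INS
SVs with per-sample genotypes drawn from a configurable mix (including
homozygous-reference-enriched call sets), per-sample diploid haplotypes with
genome-wide coordinate maps, and whole-contig "actual" reads produced by the
same fragment sampler and lifting machinery. Faithful trio transmission is
available for Mendelian-error studies.

What passing the closed-loop tests shows — and what it does not: the actual
reads are generated by the same simulator family the genotyper uses, so the
benchmark isolates the *method* (images, metric learning, decision rule)
from simulator-vs-reality mismatch. Real data adds alignment artifacts,
coverage bias, indel errors and repeat structure the toy reference lacks;
performance there depends on the profile match and is not established by
these tests.

## Benchmark study conditions

Defined once in `svembed.studies` and used by both the test suite and
`scripts/acceptance.py`: 28x coverage, 2x70 bp pairs, insert 250 +/- 40 bp,
base error rate 2e-3; image geometry 100 x 64 x 9 with a 300 bp render flank
(full height so a 28x pileup is not row-downsampled; reduced width and d=32
keep a single-CPU run in minutes); a 2-model ensemble trained 10 epochs on
150 SVs x 3 genotypes x 2 replicates from one sample; 200 SVs held out in a
second sample (SV- and sample-disjoint). Genotyping uses 3 simulated
replicates per hypothesis; refining uses 4 (per-proposal distances must
separate neighboring breakpoints, which is noise-limited). The refining
study plants 90 bp whole-unit deletions in twenty 30 bp x 24-copy repeats
with 3% unit divergence and reports them 10-150 bp off. Refiner recovery is
scored ambiguity-aware: a selected start counts if it lies within one repeat
unit of the truth or describes a byte-identical alternate haplotype.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere internally; conversion
  happens only at the VCF boundary.
- Insert-size percentiles use the Normal CDF of the estimated insert
  distribution; unpaired fragments sit at the uninformative 0.5.
- Width compression uses exact prefix-sum integration, so fractional bin
  edges conserve mass to float precision.
- `max(norm, 1e-8)` guards L2 normalization; distance gradients use
  `max(D, 1e-8)`.
- SV windows running past contig ends are clamped, and the achieved flank is
  recorded.
- Simulated fragment counts are Poisson around the coverage target;
  realized depth is tested to 4 binomial SDs.

## Known limitations

- DEL and INS only; no inversions, duplications, translocations, or
  compound events. Refining is DEL-only.
- Refiner position resolution inside repeats is limited by the learned
  metric at the benchmark image width: nearby breakpoint placements whose
  haplotypes differ at only a handful of divergence bases can be misranked,
  so recovery varies by a few SVs in twenty across study draws even when the
  called genotype is correct. Near-truth proposals always survive
  deduplication and k-mer filtering; the residual errors are ranking errors.
- The simulator has no GC/coverage bias, no indel sequencing errors, and a
  single coarse mapq rule; profile mismatch on real data degrades both
  actual and simulated sides asymmetrically.
- Site-identity evaluation only: calls and truth must describe the same
  sites; no fuzzy interval matching of discovery call sets.
- The numpy encoder trains comfortably at benchmark scale but is not suited
  to training at full 100 x 300 geometry on genome-scale SV sets.
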