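"""Canonical synthetic benchmark studies and their drivers.

These functions define the package's reference evaluation conditions — the
study sizes, sequencing profile, image geometry and training settings used to
measure closed-loop genotype recovery, breakpoint-refining recovery and trio
Mendelian consistency on synthetic data. Tests and reproduction scripts both
call into this module so the conditions are defined exactly once.

Conditions (see docs/methods.md for rationale):

* sequencing profile: 28x coverage, 2x70 bp pairs, insert 250 +/- 40 bp,
  base error rate 2e-3;
* image geometry 100 x 64 x 9 with a 300 bp render flank (reduced width,
  full height so ~28x pileups are not row-downsampled);
* embedding dimension 32; 2-model ensemble trained with contrastive loss
  (margin 1.0) for 10 epochs on 2 simulated replicates per genotype;
* closed loop: 360 planted SVs, 150 for training (one sample), 200 held out
  (a different sample), DEL:INS 1:1, genotypes ~uniform over 0/0, 0/1, 1/1;
* refining: 20 tandem repeats (30 bp unit x 24 copies, 3% unit divergence),
  planted 90 bp whole-unit deletions reported with 10-150 bp start offsets.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from svembed import synthetic as syn
from svembed.evaluate import ConcordanceReport, concordance, mendelian_errors
from svembed.genotype import GenotypeConfig, genotype_sv
from svembed.model import EmbeddingModel, LossConfig, ModelConfig, TrainConfig, train
from svembed.pileup import ImageConfig
from svembed.pipeline import build_training_pairs, sv_images
from svembed.refine import RefineConfig, refine_sv
from svembed.simulate import SeqStats


def default_stats() -> SeqStats:
    return SeqStats(
        mean_coverage=28,
        read_length=70,
        insert_mean=250,
        insert_sd=40,
        base_error_rate=0.002,
    )


def default_image_config() -> ImageConfig:
    return ImageConfig(height=100, width=64, render_flank=300)


def make_closed_loop_study(
    seed: int,
    out_dir: str,
    n_svs: int = 360,
    length: int = 1_150_000,
    stats: Optional[SeqStats] = None,
) -> syn.SyntheticStudy:
    """Two-sample study (TRAIN/EVAL) with reads generated for both."""
    stats = stats or default_stats()
    study = syn.generate_study(
        length=length,
        n_svs=n_svs,
        samples=("TRAIN", "EVAL"),
        seed=seed,
        spacing=3000,
    )
    for s in study.samples:
        syn.generate_actual_reads(study, s, stats, seed=seed + 1, out_dir=out_dir)
    return study


def train_ensemble(
    study: syn.SyntheticStudy,
    train_svs,
    stats: SeqStats,
    image_config: ImageConfig,
    seed: int,
    n_models: int = 2,
    epochs: int = 10,
    replicates: int = 2,
    embedding_dim: int = 32,
    sample: str = "TRAIN",
) -> Tuple[List[EmbeddingModel], list]:
    """Train an ensemble of encoders on one sample's labeled SVs.

    Ensemble members share the training pairs but start from different
    parameter initializations (per-member seeds), and their distances are
    averaged at genotyping time.
    """
    with pysam.AlignmentFile(study.bam_paths[sample]) as handle:
        pairs = build_training_pairs(
            train_svs,
            {sample: handle},
            study.genotypes,
            study.reference,
            stats,
            image_config,
            replicates=replicates,
            seed=seed,
        )
    models = [
        train(
            pairs,
            LossConfig(margin=1.0),
            TrainConfig(epochs=epochs, seed=seed + member),
            ModelConfig(
                height=image_config.height,
                width=image_config.width,
                embedding_dim=embedding_dim,
            ),
        )
        for member in range(n_models)
    ]
    return models, pairs


def run_closed_loop(
    study: syn.SyntheticStudy,
    eval_svs,
    models: Sequence[EmbeddingModel],
    stats: SeqStats,
    image_config: ImageConfig,
    seed: int,
    replicates: int = 3,
    sample: str = "EVAL",
) -> Tuple[Dict[str, object], Dict[str, tuple], ConcordanceReport]:
    """Genotype held-out SVs against the held-out sample; score vs truth."""
    config = GenotypeConfig(replicates=replicates, seed=seed, image=image_config)
    calls: Dict[str, object] = {}
    with pysam.AlignmentFile(study.bam_paths[sample]) as handle:
        for sv in eval_svs:
            calls[sv.id] = genotype_sv(
                sv, handle, models, stats, study.reference, config
            )
    truth = {sv.id: study.genotypes[sample][sv.id] for sv in eval_svs}
    return calls, truth, concordance(calls, truth)


def heldout_pair_separation(
    study: syn.SyntheticStudy,
    eval_svs,
    models: Sequence[EmbeddingModel],
    stats: SeqStats,
    image_config: ImageConfig,
    seed: int,
    sample: str = "EVAL",
    replicates: int = 1,
) -> Tuple[float, float]:
    """Mean embedding distance of matched (Y=1) vs mismatched (Y=0) pairs.

    A trained encoder must place the actual image closer to simulations of
    the true genotype than to simulations of the other genotypes.
    """
    from svembed.model import pair_distance

    d_match, d_mismatch = [], []
    with pysam.AlignmentFile(study.bam_paths[sample]) as handle:
        for sv in eval_svs:
            truth = study.genotypes[sample][sv.id]
            rendered = sv_images(
                sv, handle, stats, study.reference, image_config,
                replicates=replicates, seed=seed,
            )
            if rendered is None:
                continue
            actual_image, sims = rendered
            e_actual = [m.embed(actual_image) for m in models]
            for hyp, images in sims.items():
                for img in images:
                    d = float(
                        np.mean(
                            [
                                pair_distance(e_actual[i], m.embed(img))
                                for i, m in enumerate(models)
                            ]
                        )
                    )
                    (d_match if tuple(hyp.alleles) == tuple(truth) else d_mismatch).append(d)
    return float(np.mean(d_match)), float(np.mean(d_mismatch))


def make_refine_study(
    seed: int,
    out_dir: str,
    n_repeats: int = 20,
    unit_length: int = 30,
    copies: int = 24,
    divergence: float = 0.03,
    units_deleted: int = 3,
    offset_range: Tuple[int, int] = (10, 150),
    length: int = 250_000,
    stats: Optional[SeqStats] = None,
):
    """Tandem-repeat study with planted, deliberately mis-reported deletions.

    Returns ``(study, reported_records)`` where the study's SV list holds the
    *true* descriptions and ``reported_records`` the offset ones handed to
    the refiner.
    """
    stats = stats or default_stats()
    reference, repeats = syn.generate_reference(
        length,
        repeat_spec=[
            syn.RepeatSpec(unit_length, copies, count=n_repeats, divergence=divergence)
        ],
        seed=seed,
    )
    true_recs, reported, genotypes = syn.plant_offset_repeat_dels(
        reference,
        repeats,
        units_deleted=units_deleted,
        offset_range=offset_range,
        genotype_mix=(0.0, 0.5, 0.5),
        samples=("S",),
        seed=seed + 1,
    )
    study = syn.SyntheticStudy(
        contig="chr1",
        reference=reference,
        repeats=repeats,
        svs=true_recs,
        genotypes=genotypes,
        samples=["S"],
    )
    syn.generate_actual_reads(study, "S", stats, seed=seed + 2, out_dir=out_dir)
    return study, reported


def alt_haplotype_identical(reference: Dict[str, str], a, b, pad: int = 400) -> bool:
    """Whether two same-length deletions produce byte-identical alt haplotypes.

    Such descriptions are indistinguishable by any read evidence
    (repeat-unit ambiguity), so recovery scoring treats them as equal.
    """
    seq = reference[a.contig]
    lo = min(a.start, b.start) - pad
    hi = max(a.end, b.end) + pad
    apply = lambda r: seq[lo : r.start + 1] + seq[r.end : hi]
    return apply(a) == apply(b)


def run_refine_benchmark(
    study: syn.SyntheticStudy,
    reported,
    models: Sequence[EmbeddingModel],
    stats: SeqStats,
    image_config: ImageConfig,
    seed: int,
    replicates: int = 4,
) -> Tuple[float, List[dict]]:
    """Refine each mis-reported deletion; score ambiguity-aware recovery.

    An SV counts as recovered when the selected start is within one repeat
    unit of the true start (or describes a byte-identical alternate
    haplotype) *and* the reported genotype matches the truth.
    """
    gcfg = GenotypeConfig(replicates=replicates, seed=seed, image=image_config)
    rcfg = RefineConfig()
    unit = study.repeats[0].unit_length or 0
    details = []
    with pysam.AlignmentFile(study.bam_paths["S"]) as handle:
        for true_rec, rep_rec in zip(study.svs, reported):
            truth_gt = study.genotypes["S"][true_rec.id]
            record, call, proposals = refine_sv(
                rep_rec, study.repeats, handle, models, stats, study.reference,
                gcfg, rcfg,
            )
            offset = abs(record.start - true_rec.start)
            equivalent = alt_haplotype_identical(study.reference, record, true_rec)
            recovered = (offset <= unit or equivalent) and (
                tuple(call.called.alleles) == tuple(truth_gt)
            )
            details.append(
                {
                    "sv_id": true_rec.id,
                    "true_start": true_rec.start,
                    "reported_start": rep_rec.start,
                    "selected_start": record.start,
                    "offset_after_refine": offset,
                    "equivalent_haplotype": equivalent,
                    "called": call.called.label,
                    "truth": f"{truth_gt[0]}/{truth_gt[1]}",
                    "recovered": recovered,
                    "n_proposals": len(proposals),
                }
            )
    rate = float(np.mean([d["recovered"] for d in details]))
    return rate, details


def make_trio_study(
    seed: int,
    out_dir: str,
    n_svs: int = 60,
    length: int = 260_000,
    stats: Optional[SeqStats] = None,
) -> syn.SyntheticStudy:
    """Father/mother/child study with faithful Mendelian transmission."""
    stats = stats or default_stats()
    study = syn.generate_study(
        length=length,
        n_svs=n_svs,
        samples=("FA", "MO", "CH"),
        seed=seed,
        spacing=3000,
    )
    syn.make_trio(study, "FA", "MO", "CH", seed=seed + 1)
    for s in study.samples:
        syn.generate_actual_reads(study, s, stats, seed=seed + 2, out_dir=out_dir)
    return study


def run_trio_benchmark(
    study: syn.SyntheticStudy,
    models: Sequence[EmbeddingModel],
    stats: SeqStats,
    image_config: ImageConfig,
    seed: int,
    replicates: int = 3,
):
    """Genotype all trio members and measure the Mendelian error rate."""
    config = GenotypeConfig(replicates=replicates, seed=seed, image=image_config)
    calls = {}
    for sample in study.samples:
        with pysam.AlignmentFile(study.bam_paths[sample]) as handle:
            calls[sample] = {
                sv.id: genotype_sv(sv, handle, models, stats, study.reference, config)
                for sv in study.svs
            }
    return mendelian_errors(calls["CH"], calls["FA"], calls["MO"]), calls
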