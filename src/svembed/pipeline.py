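"""High-level orchestration shared by the CLI, tests and batch scripts.

These helpers glue the modules together along the standard dataflow:
actual image + genotype-conditioned simulated images -> training pairs ->
trained encoder -> genotype calls.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Sequence, Tuple

import pysam

from svembed.genotype import GenotypeConfig, _sv_seed, genotype_sv
from svembed.model import (
    EmbeddingModel,
    LossConfig,
    ModelConfig,
    TrainConfig,
    TrainingPair,
    make_training_pairs,
    train,
)
from svembed.pileup import ImageConfig, gather_fragments, render_sv_image, sv_window
from svembed.simulate import SeqStats, simulate_replicate
from svembed.variants import (
    SVRecord,
    construct_haplotype,
    enumerate_hypotheses,
    load_svs,
)

logger = logging.getLogger(__name__)


def sv_images(
    sv: SVRecord,
    actual_alignments,
    stats: SeqStats,
    reference,
    image_config: ImageConfig,
    replicates: int = 2,
    seed: int = 0,
    flank_bp: int = 1000,
):
    """Render the actual image and per-hypothesis simulated replicate images.

    Returns ``(actual_image, {hypothesis: [images]})``, or ``None`` when the
    window holds no actual reads.
    """
    sv_seed = _sv_seed(seed, sv.id)
    window = sv_window(sv, image_config.flank_for(stats), reference)
    actual = gather_fragments(
        actual_alignments, window, max_rows=image_config.height, seed=sv_seed
    )
    if not actual:
        return None
    realign_flank = image_config.realign_flank_for(stats)
    ref_hap = construct_haplotype(sv, 0, reference, realign_flank)
    alt_haps = [
        construct_haplotype(sv, i + 1, reference, realign_flank)
        for i in range(sv.n_alts)
    ]
    actual_image = render_sv_image(
        sv, actual, reference, stats, image_config, ref_hap, alt_haps, "actual"
    )
    sims: Dict = {}
    for hyp in enumerate_hypotheses(sv):
        images = []
        for r in range(replicates):
            rep = simulate_replicate(
                sv, hyp, stats, reference, flank_bp=flank_bp, seed=sv_seed,
                replicate_index=r + 1000 * (hyp.alleles[0] * 7 + hyp.alleles[1]),
            )
            fragments = gather_fragments(
                rep.fragments, window, max_rows=image_config.height, seed=sv_seed + r
            )
            images.append(
                render_sv_image(
                    sv, fragments, reference, stats, image_config, ref_hap, alt_haps,
                    f"simulated:{hyp.label}:{r}",
                )
            )
        sims[hyp] = images
    return actual_image, sims


def build_training_pairs(
    svs: Sequence[SVRecord],
    alignments_by_sample: Dict[str, object],
    truth_by_sample: Dict[str, Dict[str, Tuple[int, int]]],
    reference,
    stats: SeqStats,
    image_config: ImageConfig,
    replicates: int = 2,
    seed: int = 0,
) -> List[TrainingPair]:
    """Labeled actual/simulated pairs over SVs x samples."""
    pairs: List[TrainingPair] = []
    for sample, alignments in alignments_by_sample.items():
        truths = truth_by_sample[sample]
        for sv in svs:
            truth = truths.get(sv.id)
            if truth is None:
                continue
            rendered = sv_images(
                sv, alignments, stats, reference, image_config,
                replicates=replicates, seed=seed,
            )
            if rendered is None:
                logger.debug("no reads for %s in %s; skipped for training", sv.id, sample)
                continue
            actual_image, sims = rendered
            pairs.extend(make_training_pairs(sv, actual_image, sims, truth=truth))
    return pairs


def build_training_pairs_from_vcf(
    vcf_path: str,
    bam_by_sample: Dict[str, str],
    reference,
    stats: SeqStats,
    image_config: ImageConfig,
    replicates: int = 2,
    seed: int = 0,
) -> List[TrainingPair]:
    """Training pairs from a truth VCF carrying per-sample genotypes."""
    truth_by_sample: Dict[str, Dict[str, Tuple[int, int]]] = {}
    with pysam.VariantFile(vcf_path) as vcf:
        vcf_samples = list(vcf.header.samples)
        for rec in vcf:
            for s in vcf_samples:
                if s not in bam_by_sample:
                    continue
                gt = rec.samples[s].get("GT")
                if gt is not None and None not in gt:
                    truth_by_sample.setdefault(s, {})[rec.id] = tuple(sorted(gt))
    svs = load_svs(vcf_path, reference)
    handles = {s: pysam.AlignmentFile(p) for s, p in bam_by_sample.items()}
    try:
        return build_training_pairs(
            svs, handles, truth_by_sample, reference, stats, image_config,
            replicates=replicates, seed=seed,
        )
    finally:
        for h in handles.values():
            h.close()


def train_study_model(
    study,
    stats: SeqStats,
    image_config: ImageConfig,
    held_out_samples: Sequence[str],
    replicates: int = 2,
    epochs: int = 10,
    embedding_dim: int = 32,
    margin: float = 1.0,
    seed: int = 0,
) -> Tuple[EmbeddingModel, List[TrainingPair]]:
    """Train an encoder on a synthetic study's training split."""
    from svembed.synthetic import split_train_eval

    train_samples, train_svs, _ = split_train_eval(study, held_out_samples)
    handles = {s: pysam.AlignmentFile(study.bam_paths[s]) for s in train_samples}
    try:
        pairs = build_training_pairs(
            train_svs, handles, study.genotypes, study.reference, stats,
            image_config, replicates=replicates, seed=seed,
        )
    finally:
        for h in handles.values():
            h.close()
    model = train(
        pairs,
        loss_config=LossConfig(margin=margin),
        train_config=TrainConfig(epochs=epochs, seed=seed),
        model_config=ModelConfig(
            height=image_config.height,
            width=image_config.width,
            embedding_dim=embedding_dim,
        ),
    )
    return model, pairs


def genotype_sample(
    svs: Sequence[SVRecord],
    alignments,
    models: Sequence[EmbeddingModel],
    stats: SeqStats,
    reference,
    config: GenotypeConfig,
) -> Dict[str, object]:
    """Genotype a list of SVs against one sample's alignments."""
    calls = {}
    for sv in svs:
        calls[sv.id] = genotype_sv(sv, alignments, models, stats, reference, config)
    return calls
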