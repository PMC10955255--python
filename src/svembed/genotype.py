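"""Genotype calling from actual-vs-simulated image embedding distances.

For each SV the actual pileup image is rendered once; for every candidate
genotype a configurable number of simulated replicates is rendered and
embedded, the per-pair distances are averaged over replicates and ensemble
members, and the genotype with the smallest mean distance is called. Genotype
probabilities are the softmax of the negated distances.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np

from svembed.model import EmbeddingModel, pair_distance
from svembed.pileup import ImageConfig, gather_fragments, render_sv_image, sv_window
from svembed.simulate import SeqStats, simulate_replicate
from svembed.variants import (
    GenotypeHypothesis,
    SVRecord,
    construct_haplotype,
    enumerate_hypotheses,
    load_svs,
    write_genotyped_vcf,
)

logger = logging.getLogger(__name__)


@dataclass
class GenotypeConfig:
    replicates: int = 3
    flank_bp: int = 1000
    temperature: float = 1.0
    seed: int = 0
    image: ImageConfig = field(default_factory=ImageConfig)


@dataclass
class GenotypeCall:
    """Distances, probabilities and the selected genotype for one SV."""

    sv_id: str
    hypothesis_distances: Dict[GenotypeHypothesis, float]
    called: GenotypeHypothesis
    probabilities: Dict[GenotypeHypothesis, float]
    n_replicates: int
    seed: int
    flag: Optional[str] = None  # None/"PASS", or e.g. "NO_READS"


def genotype_probabilities(
    hypothesis_distances: Mapping[GenotypeHypothesis, float],
    temperature: float = 1.0,
) -> Dict[GenotypeHypothesis, float]:
    """Softmax over negated distances: p(g) = exp(-d_g/tau) / sum_h exp(-d_h/tau)."""
    if len(hypothesis_distances) < 2:
        raise ValueError("need at least two hypotheses")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    hyps = list(hypothesis_distances)
    d = np.array([hypothesis_distances[h] for h in hyps], dtype=float)
    logits = -d / temperature
    logits -= logits.max()
    p = np.exp(logits)
    p /= p.sum()
    return dict(zip(hyps, p.tolist()))


def _call_from_distances(
    sv_id: str,
    distances: Dict[GenotypeHypothesis, float],
    temperature: float,
    n_replicates: int,
    seed: int,
    flag: Optional[str] = None,
) -> GenotypeCall:
    # ties break toward fewer alternate alleles (0/0 < 0/1 < 1/1), then label
    called = min(
        distances, key=lambda h: (distances[h], h.n_alt_alleles, h.alleles)
    )
    probs = genotype_probabilities(distances, temperature)
    return GenotypeCall(
        sv_id=sv_id,
        hypothesis_distances=distances,
        called=called,
        probabilities=probs,
        n_replicates=n_replicates,
        seed=seed,
        flag=flag,
    )


def _sv_seed(base_seed: int, sv_id: str) -> int:
    return int(
        np.random.SeedSequence([base_seed, zlib.crc32(sv_id.encode())]).generate_state(1)[0]
        % (2**31)
    )


def genotype_sv(
    sv: SVRecord,
    actual_alignments,
    models: Sequence[EmbeddingModel],
    stats: SeqStats,
    reference,
    config: GenotypeConfig = GenotypeConfig(),
    repeat_intervals=None,
) -> GenotypeCall:
    """Call one SV from the closest actual-simulated image pair.

    ``actual_alignments`` may be a BAM/SAM path, an open pysam handle, or a
    list of in-memory fragments. A window without any actual reads yields a
    flagged homozygous-reference call with uniform probabilities.
    """
    if not models:
        raise ValueError("at least one embedding model is required")
    sv_seed = _sv_seed(config.seed, sv.id)
    window = sv_window(sv, config.image.flank_for(stats), reference)
    actual = gather_fragments(
        actual_alignments, window, max_rows=config.image.height, seed=sv_seed
    )
    hypotheses = enumerate_hypotheses(sv)
    if not actual:
        distances = {h: 1.0 for h in hypotheses}
        return _call_from_distances(
            sv.id, distances, config.temperature, 0, sv_seed, flag="NO_READS"
        )

    realign_flank = config.image.realign_flank_for(stats)
    ref_hap = construct_haplotype(sv, 0, reference, realign_flank)
    alt_haps = [
        construct_haplotype(sv, i + 1, reference, realign_flank)
        for i in range(sv.n_alts)
    ]
    actual_image = render_sv_image(
        sv, actual, reference, stats, config.image, ref_hap, alt_haps, "actual"
    )
    actual_embeddings = [mod.embed(actual_image) for mod in models]

    distances: Dict[GenotypeHypothesis, float] = {}
    for hyp in hypotheses:
        per_replicate = []
        for r in range(config.replicates):
            rep = simulate_replicate(
                sv,
                hyp,
                stats,
                reference,
                flank_bp=config.flank_bp,
                seed=sv_seed,
                replicate_index=r + 1000 * (hyp.alleles[0] * 7 + hyp.alleles[1]),
                repeat_intervals=repeat_intervals,
            )
            sim = gather_fragments(
                rep.fragments, window, max_rows=config.image.height, seed=sv_seed + r
            )
            sim_image = render_sv_image(
                sv, sim, reference, stats, config.image, ref_hap, alt_haps,
                f"simulated:{hyp.label}:{r}",
            )
            per_model = [
                pair_distance(actual_embeddings[i], mod.embed(sim_image))
                for i, mod in enumerate(models)
            ]
            per_replicate.append(float(np.mean(per_model)))
        distances[hyp] = float(np.mean(per_replicate))
    return _call_from_distances(
        sv.id, distances, config.temperature, config.replicates, sv_seed
    )


def genotype_vcf(
    vcf_in: str,
    alignments,
    models: Sequence[EmbeddingModel],
    stats: SeqStats,
    reference,
    config: GenotypeConfig,
    vcf_out: str,
    sample: str = "SAMPLE",
) -> dict:
    """Genotype every loadable SV in a VCF; returns a run report."""
    t0 = time.time()
    skip_counts: dict = {}
    records = load_svs(vcf_in, reference, skip_counts=skip_counts)
    calls: Dict[str, GenotypeCall] = {}
    failed = 0
    for sv in records:
        t_sv = time.time()
        try:
            calls[sv.id] = genotype_sv(
                sv, alignments, models, stats, reference, config
            )
        except Exception as exc:  # per-record failure: flag and continue
            logger.warning("genotyping failed for %s: %s", sv.id, exc)
            failed += 1
        logger.debug("genotyped %s in %.2fs", sv.id, time.time() - t_sv)
    write_genotyped_vcf(records, calls, vcf_out, reference=reference, sample=sample)
    return {
        "n_processed": len(records),
        "n_skipped": sum(skip_counts.values()),
        "n_failed": failed,
        "wall_time_s": time.time() - t0,
        "out": vcf_out,
    }
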