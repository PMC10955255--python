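"""Genotype-concordance, event-level and Mendelian-error evaluation.

Sites are matched by identity (contig, start, alleles share the same SV id);
evaluation assumes calls and truth describe the same sites. Exact concordance
is the fraction of identical unordered genotypes; nonreference concordance
treats heterozygous and homozygous alternate as equivalent ("presence versus
absence" of the variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Mapping, Optional, Tuple

import pandas as pd


def _gt(value) -> Tuple[int, int]:
    """Normalize a call, hypothesis, or raw tuple to a sorted allele pair."""
    if hasattr(value, "called"):  # GenotypeCall
        value = value.called
    if hasattr(value, "alleles"):  # GenotypeHypothesis
        value = value.alleles
    a, b = value
    return (a, b) if a <= b else (b, a)


def _nonref(gt: Tuple[int, int]) -> bool:
    return gt != (0, 0)


@dataclass
class ConcordanceReport:
    n_svs: int
    exact_concordance: float
    nonref_concordance: float
    event_precision: Optional[float]
    event_recall: Optional[float]
    strata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> str:
        lines = [
            f"SVs evaluated:            {self.n_svs}",
            f"Exact concordance:        {self.exact_concordance:.4f}",
            f"Nonreference concordance: {self.nonref_concordance:.4f}",
            f"Event precision:          {self.event_precision if self.event_precision is not None else 'NA'}",
            f"Event recall:             {self.event_recall if self.event_recall is not None else 'NA'}",
        ]
        return "\n".join(lines)


def concordance(
    calls: Mapping[str, object],
    truth: Mapping[str, object],
    svlen: Optional[Mapping[str, int]] = None,
    repeat_overlap: Optional[Mapping[str, bool]] = None,
) -> ConcordanceReport:
    """Exact and nonreference genotype concordance over shared sites.

    ``calls`` and ``truth`` map SV id -> genotype (tuple, hypothesis or call
    object). A site mismatch between the two keyings is an error. Optional
    per-SV annotations produce a stratified breakdown by size bin and repeat
    overlap.
    """
    missing = sorted(set(truth) ^ set(calls))
    if missing:
        raise ValueError(f"call/truth site mismatch for ids: {missing[:10]}")
    if not truth:
        raise ValueError("empty truth set")
    rows = []
    for sv_id in truth:
        c, t = _gt(calls[sv_id]), _gt(truth[sv_id])
        rows.append(
            {
                "sv_id": sv_id,
                "exact": c == t,
                # het and hom-alt count as equivalent: presence vs absence
                "nonref": _nonref(c) == _nonref(t),
                "called_nonref": _nonref(c),
                "truth_nonref": _nonref(t),
            }
        )
    df = pd.DataFrame(rows)
    precision, recall = event_metrics(calls, truth)
    strata = pd.DataFrame()
    if svlen is not None:
        bins = [50, 100, 300, 1000, 15_000_000]
        labels = ["50-99", "100-299", "300-999", ">=1000"]
        df["size_bin"] = pd.cut(
            df["sv_id"].map(lambda i: abs(svlen[i])), bins=bins, labels=labels, right=False
        )
        group_keys = ["size_bin"]
        if repeat_overlap is not None:
            df["in_repeat"] = df["sv_id"].map(repeat_overlap)
            group_keys.append("in_repeat")
        strata = (
            df.groupby(group_keys, observed=True)[["exact", "nonref"]]
            .agg(["mean", "count"])
        )
    return ConcordanceReport(
        n_svs=len(df),
        exact_concordance=float(df["exact"].mean()),
        nonref_concordance=float(df["nonref"].mean()),
        event_precision=precision,
        event_recall=recall,
        strata=strata,
    )


def event_metrics(
    calls: Mapping[str, object], truth: Mapping[str, object]
) -> Tuple[Optional[float], Optional[float]]:
    """Event-level precision/recall with 'nonreference' as the positive class.

    Precision is None (undefined) when nothing is called nonreference.
    """
    tp = fp = fn = 0
    for sv_id in truth:
        c, t = _nonref(_gt(calls[sv_id])), _nonref(_gt(truth[sv_id]))
        if c and t:
            tp += 1
        elif c and not t:
            fp += 1
        elif t and not c:
            fn += 1
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    return precision, recall


def is_mendelian_error(
    child: Tuple[int, int], parent1: Tuple[int, int], parent2: Tuple[int, int]
) -> bool:
    """True iff no transmittable allele pair from the parents yields the child."""
    child = tuple(sorted(child))
    for a in parent1:
        for b in parent2:
            if tuple(sorted((a, b))) == child:
                return False
    return True


@dataclass
class MendelianReport:
    n_sites: int
    n_excluded: int
    n_errors: int
    ranked_errors: List[dict]  # sorted by confidence, descending

    @property
    def mer(self) -> float:
        return self.n_errors / self.n_sites if self.n_sites else 0.0


def mendelian_errors(
    child_calls: Mapping[str, object],
    parent1_calls: Mapping[str, object],
    parent2_calls: Mapping[str, object],
) -> MendelianReport:
    """Mendelian-error rate for a trio plus a confidence-ranked error list.

    A site is an error iff the child genotype is impossible under allele
    transmission from the parents. Each error's confidence is the minimum,
    across the trio, of the called genotype's probability; sites with a
    missing member genotype are excluded and counted.
    """
    shared = set(child_calls) & set(parent1_calls) & set(parent2_calls)
    excluded = len(set(child_calls) | set(parent1_calls) | set(parent2_calls)) - len(shared)
    errors = []
    evaluated = 0
    for sv_id in sorted(shared):
        members = [child_calls[sv_id], parent1_calls[sv_id], parent2_calls[sv_id]]
        gts = []
        skip = False
        for mbr in members:
            try:
                gts.append(_gt(mbr))
            except (TypeError, ValueError):
                skip = True
        if skip:
            excluded += 1
            continue
        evaluated += 1
        if is_mendelian_error(*gts):
            confidence = None
            probs = []
            for mbr in members:
                if hasattr(mbr, "probabilities"):
                    probs.append(mbr.probabilities[mbr.called])
            if probs:
                confidence = min(probs)
            errors.append(
                {"sv_id": sv_id, "child": gts[0], "parent1": gts[1], "parent2": gts[2],
                 "confidence": confidence}
            )
    errors.sort(key=lambda e: -(e["confidence"] if e["confidence"] is not None else 0.0))
    return MendelianReport(
        n_sites=evaluated,
        n_excluded=excluded,
        n_errors=len(errors),
        ranked_errors=errors,
    )
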