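"""Family-based candidate-gene discovery.

Four sequential filters over the variants of one family:

(i)   sharing — carried (het or hom) by every affected, genotyped member;
(ii)  novelty — no record (MAF = 0) in every named control source;
(iii) consequence — synonymous, missense, nonsense, frameshift indel, or
      intronic change within +/-2 of an exon-intron boundary;
(iv)  in-silico prediction — missense needs >= 2 of the four pathogenicity
      scores (CADD, REVEL, M-CAP, ClinPred) at or above threshold;
      truncating variants (nonsense / frameshift) need CADD at or above its
      threshold; synonymous (and near-boundary intronic, by the same
      splicing logic) need > 1 splice predictor calling an impact.

Every input variant is accounted for in a :class:`FilterTrace` with the
stage that removed it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .types import (
    AnnotatedVariant,
    CallSet,
    Consequence,
    Pedigree,
    PredictorScores,
    SpliceEffect,
    VariantKey,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_THRESHOLDS", "FilterTrace", "VariantTrace",
    "shared_variants", "absent_from_controls", "consequence_filter",
    "predictor_vote", "splice_vote", "prioritize_family",
]

#: published per-predictor pathogenicity thresholds (inclusive)
DEFAULT_THRESHOLDS: Mapping[str, float] = {
    "cadd": 20.0,
    "revel": 0.5,
    "mcap": 0.025,
    "clinpred": 0.5,
}

STAGE_NOT_SHARED = "not_shared"
STAGE_IN_CONTROLS = "in_controls"
STAGE_CONSEQUENCE = "consequence"
STAGE_PREDICTION = "prediction"

#: consequence classes admitted by stage (iii)
_ADMITTED = {
    Consequence.SYNONYMOUS,
    Consequence.MISSENSE,
    Consequence.NONSENSE,
    Consequence.FRAMESHIFT_INDEL,
    Consequence.INTRONIC_BOUNDARY,
}

_MAX_INTRON_OFFSET = 2


@dataclass(frozen=True)
class VariantTrace:
    variant: VariantKey
    outcome: str  # "retained" | "removed"
    removal_stage: Optional[str]  # exactly one stage for removed variants
    pathogenic_votes: Optional[int] = None
    available_scores: Optional[int] = None
    splice_impact_calls: Optional[int] = None
    rule: Optional[str] = None  # step-(iv) rule applied, e.g. "missense"


@dataclass
class FilterTrace:
    family_id: str
    records: list = field(default_factory=list)

    def append(self, rec: VariantTrace) -> None:
        self.records.append(rec)

    def retained(self) -> list[VariantKey]:
        return [r.variant for r in self.records if r.outcome == "retained"]

    def removed_at(self, stage: str) -> list[VariantKey]:
        return [r.variant for r in self.records if r.removal_stage == stage]

    def stage_of(self, variant: VariantKey) -> Optional[str]:
        for r in self.records:
            if r.variant == variant:
                return r.removal_stage
        raise KeyError(f"{variant} not in trace")

    def to_rows(self) -> list[dict]:
        return [{
            "gene": r.variant.gene_symbol,
            "transcript": r.variant.transcript_id,
            "hgvs_c": r.variant.hgvs_c,
            "outcome": r.outcome,
            "removal_stage": r.removal_stage,
            "pathogenic_votes": r.pathogenic_votes,
            "available_scores": r.available_scores,
            "splice_impact_calls": r.splice_impact_calls,
            "rule": r.rule,
        } for r in self.records]


# --------------------------------------------------------------------------
# individual stages
# --------------------------------------------------------------------------

def shared_variants(
    callset: CallSet,
    pedigree: Pedigree,
    family_id: str,
    include_probable: bool = False,
) -> list[VariantKey]:
    """Variants carried by every affected, genotyped member of the family.

    ``probable_affected`` individuals join the mandatory-sharing set only
    when ``include_probable`` is set.  Raises ValueError when no affected
    member is genotyped; a single genotyped affected member degenerates to
    that member's carried set (logged).
    """
    affected = [i.individual_id
                for i in pedigree.affected(family_id, include_probable)
                if callset.has_sample(i.individual_id)]
    if not affected:
        raise ValueError(
            f"family {family_id!r} has no affected genotyped members")
    if len(affected) == 1:
        logger.warning(
            "shared_variants: family %s has a single affected genotyped "
            "member; sharing filter is degenerate", family_id)
    shared = []
    for v in callset.variants:
        if all(callset.is_carrier(s, v) for s in affected):
            shared.append(v)
    return shared


def absent_from_controls(
    variants: Sequence[VariantKey],
    annotations: Mapping[VariantKey, AnnotatedVariant],
    control_sources: Sequence[str],
    epsilon: float = 0.0,
) -> list[VariantKey]:
    """Variants with MAF = 0 (strictly, or <= ``epsilon``) or no record in
    every named control source."""
    if not control_sources:
        raise ValueError("control source list must not be empty")
    out = []
    for v in variants:
        mafs = (annotations[v].maf(src) for src in control_sources)
        if all(m is None or m <= epsilon for m in mafs):
            out.append(v)
    return out


def consequence_filter(
    variants: Sequence[VariantKey],
    annotations: Mapping[VariantKey, AnnotatedVariant],
) -> list[VariantKey]:
    """Retain the admitted consequence classes; intronic changes qualify
    only within +/-2 of the exon-intron boundary."""
    out = []
    for v in variants:
        cons = annotations[v].consequence
        if cons.kind not in _ADMITTED:
            continue
        if (cons.kind is Consequence.INTRONIC_BOUNDARY
                and abs(cons.intron_offset) > _MAX_INTRON_OFFSET):
            continue
        out.append(v)
    return out


def predictor_vote(
    scores: PredictorScores,
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
) -> tuple[int, int]:
    """(number of available scores at/above threshold, number available)."""
    votes = 0
    available = 0
    for name in ("cadd", "revel", "mcap", "clinpred"):
        value = getattr(scores, name)
        if value is None:
            continue
        available += 1
        if value >= thresholds[name]:
            votes += 1
    return votes, available


def splice_vote(scores: PredictorScores) -> int:
    """Number of distinct splice predictors calling an impact effect."""
    return sum(1 for eff in scores.splice_calls.values()
               if eff is not SpliceEffect.NO_IMPACT)


# --------------------------------------------------------------------------
# composed filter
# --------------------------------------------------------------------------

def _passes_prediction(ann: AnnotatedVariant,
                       thresholds: Mapping[str, float]) -> tuple[bool, str]:
    kind = ann.consequence.kind
    if kind is Consequence.MISSENSE:
        votes, _ = predictor_vote(ann.scores, thresholds)
        return votes >= 2, "missense"
    if kind in (Consequence.NONSENSE, Consequence.FRAMESHIFT_INDEL):
        cadd = ann.scores.cadd
        return cadd is not None and cadd >= thresholds["cadd"], "truncating"
    if kind is Consequence.SYNONYMOUS:
        return splice_vote(ann.scores) > 1, "synonymous"
    if kind is Consequence.INTRONIC_BOUNDARY:
        # near-boundary intronic changes can only act through splicing, so
        # they use the synonymous rule
        return splice_vote(ann.scores) > 1, "intronic-as-synonymous"
    return False, "other"  # pragma: no cover - excluded at stage (iii)


def prioritize_family(
    callset: CallSet,
    annotations: Sequence[AnnotatedVariant],
    pedigree: Pedigree,
    family_id: str,
    control_sources: Sequence[str] = ("gnomad_all", "popgen_ikmb"),
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    include_probable: bool = False,
    control_epsilon: float = 0.0,
) -> tuple[list[VariantKey], FilterTrace]:
    """Run stages (i)-(iv) for one family.

    Returns the candidate list and a :class:`FilterTrace` that attributes
    each input variant either to retention or to exactly one removal stage
    (the first failed stage, in pipeline order).
    """
    by_key = {a.key: a for a in annotations}
    for v in callset.variants:
        if v not in by_key:
            raise ValueError(f"variant {v} in CallSet has no annotation")

    shared = set(shared_variants(callset, pedigree, family_id,
                                 include_probable))
    novel = set(absent_from_controls(
        sorted(shared), by_key, control_sources, control_epsilon))
    good_consequence = set(consequence_filter(sorted(novel), by_key))

    trace = FilterTrace(family_id=family_id)
    candidates: list[VariantKey] = []
    for v in callset.variants:
        ann = by_key[v]
        votes, avail = predictor_vote(ann.scores, thresholds)
        n_splice = splice_vote(ann.scores)
        if v not in shared:
            trace.append(VariantTrace(v, "removed", STAGE_NOT_SHARED,
                                      votes, avail, n_splice))
            continue
        if v not in novel:
            trace.append(VariantTrace(v, "removed", STAGE_IN_CONTROLS,
                                      votes, avail, n_splice))
            continue
        if v not in good_consequence:
            trace.append(VariantTrace(v, "removed", STAGE_CONSEQUENCE,
                                      votes, avail, n_splice))
            continue
        ok, rule = _passes_prediction(ann, thresholds)
        if not ok:
            trace.append(VariantTrace(v, "removed", STAGE_PREDICTION,
                                      votes, avail, n_splice, rule))
            continue
        trace.append(VariantTrace(v, "retained", None,
                                  votes, avail, n_splice, rule))
        candidates.append(v)
    return candidates, trace
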