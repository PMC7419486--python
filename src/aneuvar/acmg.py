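"""ACMG/AMP evidence assignment and 5-tier classification.

Two separable layers:

* :func:`assign_criteria` derives evidence codes from annotations under a
  :class:`CriteriaConfig` (frequency-based PM2, computational PP3/BP4,
  hotspot PM1, gene-policy BP1/PP2, segregation-driven BS4).  Only the
  codes this study design uses have assignment rules; all 28 codes parse
  and combine correctly.
* :func:`combine_criteria` implements the published combining rules that
  map a set of evidence codes to pathogenic / likely pathogenic / VUS /
  likely benign / benign, with any pathogenic-with-benign conflict
  resolving to VUS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import yaml

from .family import DEFAULT_THRESHOLDS, predictor_vote, splice_vote
from .types import (
    AcmgClass,
    AcmgCriterion,
    AnnotatedVariant,
    Consequence,
    CriterionTier,
)

__all__ = [
    "CriteriaConfig", "study_default_config", "assign_criteria",
    "combine_criteria", "parse_criteria_string", "classify_table",
]

BP1_MISSENSE = "BP1_missense"
PP2_MISSENSE = "PP2_missense"


@dataclass
class CriteriaConfig:
    """Tunable rule set for evidence assignment.

    ``pm2_maf_threshold`` is the control frequency at or below which a
    variant counts as absent/very rare (PM2); it must be well below 1%.
    ``gene_policies`` maps gene symbols to ``BP1_missense`` (truncating
    disease mechanism) or ``PP2_missense`` (missense-constrained gene) —
    one gene cannot carry both.  ``domain_hotspots`` maps genes to domain
    tags conferring PM1 when a variant is tagged with one of them.
    """

    pm2_maf_threshold: float = 1.05e-4
    pm2_source: str = "gnomad_all"
    gene_policies: dict = field(default_factory=dict)
    domain_hotspots: dict = field(default_factory=dict)
    bs4_from_segregation: bool = True
    predictor_thresholds: dict = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    def __post_init__(self) -> None:
        if not (0.0 < self.pm2_maf_threshold < 0.01):
            raise ValueError("pm2_maf_threshold must lie in (0, 0.01)")
        for gene, policy in self.gene_policies.items():
            if policy not in (BP1_MISSENSE, PP2_MISSENSE):
                raise ValueError(f"unknown gene policy {policy!r} for {gene}")
        self.domain_hotspots = {g: set(tags)
                                for g, tags in self.domain_hotspots.items()}

    # -- round-trip serialization -----------------------------------------
    def to_dict(self) -> dict:
        return {
            "pm2_maf_threshold": self.pm2_maf_threshold,
            "pm2_source": self.pm2_source,
            "gene_policies": dict(self.gene_policies),
            "domain_hotspots": {g: sorted(t)
                                for g, t in self.domain_hotspots.items()},
            "bs4_from_segregation": self.bs4_from_segregation,
            "predictor_thresholds": dict(self.predictor_thresholds),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CriteriaConfig":
        return cls(**dict(data))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "CriteriaConfig":
        return cls.from_dict(yaml.safe_load(text))


def study_default_config() -> CriteriaConfig:
    """Rule set reproducing this study's published evidence assignments:
    BP1 for pericentrin (truncating mechanism), PP2 for RNF213
    (missense-constrained), and the documented domain hotspots."""
    return CriteriaConfig(
        gene_policies={"PCNT": BP1_MISSENSE, "RNF213": PP2_MISSENSE},
        domain_hotspots={
            "EDIL3": {"EGF-like"},
            "NEK4": {"tyrosine-down-motif"},
            "ADAMTS15": {"critical-domain"},
            "ANGPTL6": {"critical-domain"},
            "TMEM132B": {"critical-domain"},
        },
    )


# --------------------------------------------------------------------------
# evidence assignment
# --------------------------------------------------------------------------

def assign_criteria(
    variant: AnnotatedVariant,
    config: Optional[CriteriaConfig] = None,
    segregation: Optional[str] = None,  # "supported"/"refuted"/"uninformative"
) -> frozenset[AcmgCriterion]:
    """Derive evidence codes for one variant; missing evidence simply
    yields no criterion, never an error."""
    config = config or CriteriaConfig()
    out: set[AcmgCriterion] = set()

    # PM2 — absent or very rare in the designated control source
    maf = variant.maf(config.pm2_source)
    if maf is None or maf <= config.pm2_maf_threshold:
        out.add(AcmgCriterion("PM2"))

    # PP3 / BP4 — computational evidence (strict majority of available
    # scores; splice predictions can establish PP3 and veto BP4)
    votes, available = predictor_vote(variant.scores,
                                      config.predictor_thresholds)
    n_splice = splice_vote(variant.scores)
    if available and votes * 2 > available or n_splice > 1:
        out.add(AcmgCriterion("PP3"))
    benign_votes = available - votes
    if available and benign_votes * 2 > available and n_splice <= 1:
        out.add(AcmgCriterion("BP4"))

    # PM1 — mutational hotspot / critical domain
    hotspots = config.domain_hotspots.get(variant.key.gene_symbol, set())
    if variant.domain_tags & hotspots:
        out.add(AcmgCriterion("PM1"))

    # BP1 / PP2 — gene-level missense policy
    if variant.consequence.kind is Consequence.MISSENSE:
        policy = config.gene_policies.get(variant.key.gene_symbol)
        if policy == BP1_MISSENSE:
            out.add(AcmgCriterion("BP1"))
        elif policy == PP2_MISSENSE:
            out.add(AcmgCriterion("PP2"))

    # BS4 — lack of familial segregation, supplied by the segregation stage
    if config.bs4_from_segregation and segregation == "refuted":
        out.add(AcmgCriterion("BS4"))

    return frozenset(out)


# --------------------------------------------------------------------------
# combining rules
# --------------------------------------------------------------------------

def _pathogenic_class(pvs: int, ps: int, pm: int, pp: int) -> Optional[AcmgClass]:
    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2))
        or pvs >= 2
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2)
                         or (pm == 1 and pp >= 4)))
    )
    if pathogenic:
        return AcmgClass.PATHOGENIC
    likely = (
        (pvs == 1 and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    if likely:
        return AcmgClass.LIKELY_PATHOGENIC
    return None


def _benign_class(ba: int, bs: int, bp: int) -> Optional[AcmgClass]:
    if ba >= 1 or bs >= 2:
        return AcmgClass.BENIGN
    if (bs == 1 and bp >= 1) or bp >= 2:
        return AcmgClass.LIKELY_BENIGN
    return None


def combine_criteria(criteria: Iterable[AcmgCriterion]) -> AcmgClass:
    """Combine evidence codes into the 5-tier classification.

    Conflicting evidence — pathogenic-side and benign-side codes that each
    on their own would reach a non-VUS class — and any mixture that meets
    no combining rule resolve to VUS.
    """
    crits = set(criteria)
    tiers = [c.tier for c in crits]
    pvs = tiers.count(CriterionTier.PATHOGENIC_VERY_STRONG)
    ps = tiers.count(CriterionTier.PATHOGENIC_STRONG)
    pm = tiers.count(CriterionTier.PATHOGENIC_MODERATE)
    pp = tiers.count(CriterionTier.PATHOGENIC_SUPPORTING)
    ba = tiers.count(CriterionTier.BENIGN_STANDALONE)
    bs = tiers.count(CriterionTier.BENIGN_STRONG)
    bp = tiers.count(CriterionTier.BENIGN_SUPPORTING)

    path_class = _pathogenic_class(pvs, ps, pm, pp)
    benign_class = _benign_class(ba, bs, bp)
    any_pathogenic = (pvs + ps + pm + pp) > 0
    any_benign = (ba + bs + bp) > 0

    if path_class is not None and not any_benign:
        return path_class
    if benign_class is not None and not any_pathogenic:
        return benign_class
    return AcmgClass.VUS


def parse_criteria_string(text: str) -> frozenset[AcmgCriterion]:
    """Parse a published criteria string like ``"PM1+PP3"``; raises
    ValueError on unknown codes."""
    codes = [tok.strip() for tok in text.split("+") if tok.strip()]
    return frozenset(AcmgCriterion(code) for code in codes)


def classify_table(
    criteria_strings: Mapping[str, str] | Iterable[tuple[str, str]],
) -> tuple[dict[str, AcmgClass], dict[AcmgClass, int]]:
    """Classify variants from their printed criteria strings.

    Accepts ``{variant label: "PM1+PP3", ...}``; returns per-variant
    classes and a tally per class (all five classes present, possibly 0).
    """
    items = (criteria_strings.items()
             if isinstance(criteria_strings, Mapping) else criteria_strings)
    classes: dict[str, AcmgClass] = {}
    tally: dict[AcmgClass, int] = {c: 0 for c in AcmgClass}
    for label, text in items:
        cls = combine_criteria(parse_criteria_string(text))
        classes[label] = cls
        tally[cls] += 1
    return classes, tally
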