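"""Categorical cosegregation assessment of a variant within a family.

Under a dominant model with incomplete penetrance, an affected genotyped
relative who lacks the variant refutes cosegregation; an additional
affected carrier relative supports it; unaffected carriers are counted but
never refute.  The proband is excluded from the counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .types import Affection, CallSet, Pedigree, VariantKey

__all__ = ["SegregationResult", "assess_cosegregation"]

SUPPORTED = "supported"
REFUTED = "refuted"
UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class SegregationResult:
    verdict: str  # supported | refuted | uninformative
    affected_carriers: int
    affected_noncarriers: int
    unaffected_carriers: int
    unaffected_noncarriers: int

    @property
    def n_informative_relatives(self) -> int:
        return (self.affected_carriers + self.affected_noncarriers
                + self.unaffected_carriers + self.unaffected_noncarriers)


def assess_cosegregation(
    variant: VariantKey,
    callset: CallSet,
    pedigree: Pedigree,
    proband_id: str,
    probable_counts_as_affected: bool = False,
) -> SegregationResult:
    """Assess whether ``variant`` tracks with disease in the proband's
    family.

    Verdict: ``refuted`` if any genotyped affected relative lacks the
    variant; ``supported`` if at least one additional affected relative
    carries it and none lacks it; else ``uninformative``.  Relatives with
    probable affection count as affected only when
    ``probable_counts_as_affected`` is set; hom and het carriage are
    equivalent.  Raises ValueError when the proband is absent from the
    pedigree or does not carry the variant.
    """
    if proband_id not in pedigree:
        raise ValueError(f"proband {proband_id!r} absent from pedigree")
    if not (callset.has_sample(proband_id)
            and callset.is_carrier(proband_id, variant)):
        raise ValueError(f"proband {proband_id!r} does not carry {variant}")

    family_id = pedigree[proband_id].family_id
    affected_set = {Affection.AFFECTED}
    if probable_counts_as_affected:
        affected_set.add(Affection.PROBABLE_AFFECTED)

    aff_carr = aff_non = unaff_carr = unaff_non = 0
    for ind in sorted(pedigree.members(family_id),
                      key=lambda i: i.individual_id):
        if ind.individual_id == proband_id:
            continue
        if not callset.has_sample(ind.individual_id):
            continue
        carrier = callset.is_carrier(ind.individual_id, variant)
        if ind.affection in affected_set:
            aff_carr += carrier
            aff_non += not carrier
        elif ind.affection is Affection.UNAFFECTED:
            unaff_carr += carrier
            unaff_non += not carrier
        # unknown affection: genotype alone is uninformative

    if aff_non >= 1:
        verdict = REFUTED
    elif aff_carr >= 1:
        verdict = SUPPORTED
    else:
        verdict = UNINFORMATIVE
    return SegregationResult(verdict, aff_carr, aff_non,
                             unaff_carr, unaff_non)
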