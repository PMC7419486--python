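"""Reported-risk-gene screen: MAF-tier filtering, recurrence and
concomitance over a gene panel.

The screen retains variants that (a) lie in a panel gene, (b) have a
screening MAF at or below the cutoff in the chosen frequency source
(variants absent from the source count as MAF = 0 and are retained, with a
warning), and (c) are carried by at least one cohort sample.  Per-gene
tallies, recurrent variants (>= 2 carriers) and per-sample concomitant
variant sets are computed from the retained set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .types import AnnotatedVariant, CallSet, VariantKey, categorize_maf

logger = logging.getLogger(__name__)

__all__ = ["GeneTally", "ScreenResult", "screen_risk_genes",
           "find_recurrent", "find_concomitant", "categorize_maf"]

DEFAULT_FREQ_SOURCE = "gnomad_all"
DEFAULT_MAF_CUTOFF = 0.05


@dataclass(frozen=True)
class GeneTally:
    gene: str
    n_variants: int
    n_carriers: int  # distinct samples carrying >=1 retained variant of gene


@dataclass
class ScreenResult:
    """Outcome of one risk-gene screen run."""

    panel: tuple
    maf_cutoff: float
    freq_source: str
    retained: list  # list[VariantKey], input order
    carriers: dict  # VariantKey -> list[str]
    screening_maf: dict  # VariantKey -> float (0.0 when unknown)
    phase: dict = field(default_factory=dict)  # sample -> {cis,trans,unknown}

    # -- derived views -----------------------------------------------------
    def distinct_carriers(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.retained:
            for s in self.carriers[v]:
                seen.setdefault(s, None)
        return sorted(seen)

    def gene_tallies(self) -> list[GeneTally]:
        genes: dict[str, list[VariantKey]] = {}
        for v in self.retained:
            genes.setdefault(v.gene_symbol, []).append(v)
        tallies = []
        for gene in sorted(genes):
            vs = genes[gene]
            samples = {s for v in vs for s in self.carriers[v]}
            tallies.append(GeneTally(gene, len(vs), len(samples)))
        return tallies

    def genes_with_variants(self) -> list[str]:
        return [t.gene for t in self.gene_tallies()]

    def to_rows(self) -> list[dict]:
        rows = []
        for v in self.retained:
            rows.append({
                "gene": v.gene_symbol,
                "transcript": v.transcript_id,
                "hgvs_c": v.hgvs_c,
                "hgvs_p": v.hgvs_p,
                "maf": self.screening_maf[v],
                "maf_category": categorize_maf(self.screening_maf[v]).value,
                "n_carriers": len(self.carriers[v]),
                "carriers": ";".join(self.carriers[v]),
            })
        return rows


def screen_risk_genes(
    callset: CallSet,
    annotations: Sequence[AnnotatedVariant],
    panel: Sequence[str],
    maf_cutoff: float = DEFAULT_MAF_CUTOFF,
    freq_source: str = DEFAULT_FREQ_SOURCE,
) -> ScreenResult:
    """Screen a cohort for qualifying variants in reported risk genes.

    Raises ValueError for an empty panel, a cutoff outside (0, 1], or a
    CallSet variant without an annotation.
    """
    if not panel:
        raise ValueError("gene panel must not be empty")
    if not (0.0 < maf_cutoff <= 1.0):
        raise ValueError(f"MAF cutoff must lie in (0, 1], got {maf_cutoff}")
    by_key: dict[VariantKey, AnnotatedVariant] = {a.key: a for a in annotations}
    panel_set = set(panel)

    retained: list[VariantKey] = []
    carriers: dict[VariantKey, list[str]] = {}
    screening_maf: dict[VariantKey, float] = {}
    n_unknown_maf = 0
    for key in callset.variants:
        ann = by_key.get(key)
        if ann is None:
            raise ValueError(f"variant {key} in CallSet has no annotation")
        if key.gene_symbol not in panel_set:
            continue
        maf = ann.maf(freq_source)
        if maf is None:
            n_unknown_maf += 1
            maf = 0.0  # database-absent variants are retained
        if maf > maf_cutoff:
            continue
        carrying = callset.carriers_of(key)
        if not carrying:
            continue
        retained.append(key)
        carriers[key] = carrying
        screening_maf[key] = maf
    if n_unknown_maf:
        logger.warning(
            "screen_risk_genes: %d panel variants lack a %s record; "
            "treated as MAF = 0 and retained where carried",
            n_unknown_maf, freq_source,
        )
    return ScreenResult(
        panel=tuple(panel),
        maf_cutoff=maf_cutoff,
        freq_source=freq_source,
        retained=retained,
        carriers=carriers,
        screening_maf=screening_maf,
    )


def find_recurrent(result: ScreenResult,
                   min_carriers: int = 2) -> list[tuple[VariantKey, int]]:
    """Retained variants carried by >= ``min_carriers`` samples, sorted by
    carrier count (descending), then variant key."""
    if min_carriers < 2:
        raise ValueError("min_carriers must be >= 2")
    hits = [(v, len(result.carriers[v])) for v in result.retained
            if len(result.carriers[v]) >= min_carriers]
    hits.sort(key=lambda item: (-item[1], item[0]))
    return hits


def find_concomitant(
    result: ScreenResult,
    phase: Optional[Mapping[str, str]] = None,
) -> dict[str, dict]:
    """Samples carrying >= 2 retained variants.

    Returns sample -> {"variants": [VariantKey, ...], "phase": str}; phase
    ("cis"/"trans") is copied from the optional input annotation and never
    inferred, defaulting to "unknown".
    """
    per_sample: dict[str, list[VariantKey]] = {}
    for v in result.retained:
        for s in result.carriers[v]:
            per_sample.setdefault(s, []).append(v)
    phase = dict(phase or {})
    out: dict[str, dict] = {}
    for sample in sorted(per_sample):
        variants = sorted(per_sample[sample])
        if len(variants) >= 2:
            out[sample] = {
                "variants": variants,
                "phase": phase.get(sample, "unknown"),
            }
    return out
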