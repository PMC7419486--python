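"""Synthetic cohorts and packaged study fixtures.

Two kinds of inputs make every downstream stage testable without any
download:

* :func:`generate_cohort` builds a case/control cohort with exactly
  specified carrier configurations, rule-violating decoy variants and a
  log-uniform background frequency spectrum, deterministically from a
  seed.
* :func:`build_table2_fixture` / :func:`build_family_fixture` reconstruct
  the two published variant tables (the risk-gene screen table and the
  three-affected-siblings candidate table) from packaged TSV resources.
  Panel/candidate rows are transcriptions of the published tables; decoy
  rows (``role = decoy``) are synthetic and each violates exactly one
  filtering rule.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .io import read_annotations
from .types import (
    Affection,
    AnnotatedVariant,
    CallSet,
    ConsequenceClass,
    Consequence,
    Individual,
    Pedigree,
    PopulationFrequency,
    PredictorScores,
    VariantKey,
    Zygosity,
)

__all__ = [
    "DecoyRule", "CarrierSpec", "SyntheticCohortConfig", "generate_cohort",
    "build_table2_fixture", "build_family_fixture",
    "RISK_GENE_PANEL", "FAMILY_ID", "FAMILY_SIBS",
]

#: the eight reported risk genes screened in the study
RISK_GENE_PANEL = ("ADAMTS15", "ANGPTL6", "ARHGEF17", "LOXL2",
                   "PCNT", "RNF213", "THSD1", "TMEM132B")

FAMILY_ID = "FAM_A"
FAMILY_SIBS = ("IA7", "IA8", "IA15")
CONTROL_SOURCES = ("gnomad_all", "popgen_ikmb")


class DecoyRule(enum.Enum):
    MAF_ABOVE_CUTOFF = "maf_above_cutoff"
    OFF_PANEL_GENE = "off_panel_gene"
    PRESENT_IN_CONTROLS = "present_in_controls"
    INSUFFICIENT_PREDICTOR_VOTES = "insufficient_predictor_votes"
    WRONG_CONSEQUENCE = "wrong_consequence"
    NOT_SHARED_BY_FAMILY = "not_shared_by_family"


@dataclass(frozen=True)
class CarrierSpec:
    """One planted variant: exactly ``n_carriers`` carriers in the target
    group, at the given zygosity."""

    gene: str
    hgvs_c: str
    target_group: str  # "cases" | "controls"
    n_carriers: int
    zygosity: Zygosity = Zygosity.HET
    maf: float = 0.0  # control-database frequency of the planted variant
    consequence: Consequence = Consequence.MISSENSE
    scores: Optional[PredictorScores] = None

    def __post_init__(self) -> None:
        if self.target_group not in ("cases", "controls"):
            raise ValueError(f"unknown target group {self.target_group!r}")
        if self.n_carriers < 0:
            raise ValueError("carrier count must be nonnegative")


@dataclass
class SyntheticCohortConfig:
    seed: int
    n_cases: int
    n_controls: int
    panel_genes: Sequence[str] = RISK_GENE_PANEL
    carrier_specs: Sequence[CarrierSpec] = ()
    decoy_specs: Sequence[tuple] = ()  # (DecoyRule, count)
    n_background_variants: int = 20
    background_maf_range: tuple = (1e-5, 0.5)  # log-uniform spectrum

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        if self.n_controls < 0:
            raise ValueError("n_controls must be nonnegative")
        for spec in self.carrier_specs:
            group = self.n_cases if spec.target_group == "cases" \
                else self.n_controls
            if spec.n_carriers > group:
                raise ValueError(
                    f"carrier count {spec.n_carriers} exceeds "
                    f"{spec.target_group} group size {group}")


_PATHOGENIC_SCORES = PredictorScores(cadd=28.0, revel=0.8, mcap=0.3,
                                     clinpred=0.95)
_BENIGN_SCORES = PredictorScores(cadd=5.0, revel=0.1, mcap=0.005,
                                 clinpred=0.05)


def _annotation_for(key: VariantKey, maf: float,
                    consequence: Consequence = Consequence.MISSENSE,
                    scores: PredictorScores = _PATHOGENIC_SCORES,
                    intron_offset: Optional[int] = None) -> AnnotatedVariant:
    freqs = {}
    for source in CONTROL_SOURCES:
        freqs[source] = PopulationFrequency(source=source, maf=maf)
    return AnnotatedVariant(
        key=key,
        consequence=ConsequenceClass(consequence, intron_offset),
        frequencies=freqs,
        scores=scores,
    )


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[CallSet, list[AnnotatedVariant], Pedigree]:
    """Generate a deterministic case/control cohort.

    Realized carrier counts equal ``carrier_specs`` exactly (carriers are
    placed by seeded sampling without replacement within the target
    group); decoys violate exactly their named rule; filler variants draw
    their control MAF from a log-uniform spectrum and their cohort
    genotypes from the corresponding binomial.
    """
    rng = np.random.default_rng(config.seed)
    cases = [f"CASE{i + 1:04d}" for i in range(config.n_cases)]
    controls = [f"CTRL{i + 1:04d}" for i in range(config.n_controls)]
    samples = cases + controls

    variants: list[VariantKey] = []
    annotations: list[AnnotatedVariant] = []
    columns: list[np.ndarray] = []

    def add_variant(key: VariantKey, ann: AnnotatedVariant,
                    column: np.ndarray) -> None:
        variants.append(key)
        annotations.append(ann)
        columns.append(column)

    # planted carrier configurations
    for spec in config.carrier_specs:
        key = VariantKey(spec.gene, f"NM_SYN_{spec.gene}", spec.hgvs_c)
        column = np.zeros(len(samples), dtype=np.int8)
        group_idx = (np.arange(len(cases)) if spec.target_group == "cases"
                     else len(cases) + np.arange(len(controls)))
        chosen = rng.choice(group_idx, size=spec.n_carriers, replace=False)
        column[chosen] = int(spec.zygosity)
        ann = _annotation_for(key, spec.maf, spec.consequence,
                              spec.scores or _PATHOGENIC_SCORES)
        add_variant(key, ann, column)

    # decoys, each violating exactly one rule
    panel = list(config.panel_genes)
    decoy_i = 0
    for rule, count in config.decoy_specs:
        rule = DecoyRule(rule)
        for _ in range(count):
            decoy_i += 1
            gene = panel[decoy_i % len(panel)]
            column = np.zeros(len(samples), dtype=np.int8)
            carrier = int(rng.integers(0, config.n_cases))
            column[carrier] = 1
            if rule is DecoyRule.MAF_ABOVE_CUTOFF:
                ann = _annotation_for(
                    VariantKey(gene, f"NM_SYN_{gene}", f"c.{decoy_i}00A>G"),
                    maf=float(rng.uniform(0.06, 0.4)))
            elif rule is DecoyRule.OFF_PANEL_GENE:
                off_gene = f"OFFPANEL{decoy_i}"
                ann = _annotation_for(
                    VariantKey(off_gene, f"NM_SYN_{off_gene}",
                               f"c.{decoy_i}00A>G"),
                    maf=0.0)
            elif rule is DecoyRule.PRESENT_IN_CONTROLS:
                ann = _annotation_for(
                    VariantKey(gene, f"NM_SYN_{gene}", f"c.{decoy_i}00A>G"),
                    maf=float(rng.uniform(1e-5, 1e-4)))
            elif rule is DecoyRule.INSUFFICIENT_PREDICTOR_VOTES:
                ann = _annotation_for(
                    VariantKey(gene, f"NM_SYN_{gene}", f"c.{decoy_i}00A>G"),
                    maf=0.0, scores=_BENIGN_SCORES)
            elif rule is DecoyRule.WRONG_CONSEQUENCE:
                ann = _annotation_for(
                    VariantKey(gene, f"NM_SYN_{gene}", f"c.*{decoy_i}0G>A"),
                    maf=0.0, consequence=Consequence.OTHER)
            else:  # NOT_SHARED_BY_FAMILY: carried by a single individual
                ann = _annotation_for(
                    VariantKey(gene, f"NM_SYN_{gene}", f"c.{decoy_i}00A>G"),
                    maf=0.0)
            add_variant(ann.key, ann, column)

    # background filler spectrum
    lo, hi = config.background_maf_range
    for b in range(config.n_background_variants):
        maf = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        gene = f"BGGENE{b + 1}"
        key = VariantKey(gene, f"NM_SYN_{gene}", "c.1A>G")
        # HWE-ish genotypes from the background frequency
        dosage = rng.binomial(2, maf, size=len(samples)).astype(np.int8)
        ann = _annotation_for(key, maf, scores=_BENIGN_SCORES)
        add_variant(key, ann, dosage)

    matrix = (np.stack(columns, axis=1) if columns
              else np.zeros((len(samples), 0), dtype=np.int8))
    callset = CallSet(samples, variants, matrix)
    pedigree = Pedigree([
        Individual(s, s, None, None, "unknown",
                   Affection.AFFECTED if s in set(cases)
                   else Affection.UNAFFECTED)
        for s in samples
    ])
    return callset, annotations, pedigree


# --------------------------------------------------------------------------
# packaged fixtures
# --------------------------------------------------------------------------

def _load_fixture(name: str):
    text = (resources.files("aneuvar.data") / name).read_text()
    annotations = read_annotations(text)
    lines = [l for l in text.splitlines() if l.strip()]
    header = lines[0].split("\t")
    idx = {c: i for i, c in enumerate(header)}
    carriers: dict[VariantKey, list[str]] = {}
    roles: dict[VariantKey, str] = {}
    rules: dict[VariantKey, Optional[str]] = {}
    for ann, line in zip(annotations, lines[1:]):
        cells = line.split("\t")
        carr = cells[idx["carriers"]]
        carriers[ann.key] = [] if carr == "n.a." else carr.split(";")
        roles[ann.key] = cells[idx["role"]]
        rule = cells[idx["decoy_rule"]]
        rules[ann.key] = None if rule == "n.a." else rule
    return annotations, carriers, roles, rules


def _callset_from_carriers(samples: Sequence[str],
                           variants: Sequence[VariantKey],
                           carriers: dict) -> CallSet:
    matrix = np.zeros((len(samples), len(variants)), dtype=np.int8)
    sample_idx = {s: i for i, s in enumerate(samples)}
    for j, v in enumerate(variants):
        for s in carriers[v]:
            matrix[sample_idx[s], j] = int(Zygosity.HET)
    return CallSet(samples, variants, matrix)


#: full exome-sequenced cohort of the screen fixture (38 samples: the 18
#: published carriers, decoy carriers, the three family siblings, fillers)
TABLE2_SAMPLES = tuple(sorted(
    {"IA17", "IA24", "IA49", "IA54", "IA57", "IA59", "IA61", "IA63",
     "IA64", "IA72", "IA75", "IA76", "IA78", "IA79", "IA83", "IA84",
     "IA85", "IA90",
     "IA02", "IA05", "IA08", "IA11", "IA14", "IA20",
     "IA7", "IA8", "IA15",
     "IA01", "IA03", "IA04", "IA06", "IA09", "IA10", "IA12", "IA13",
     "IA16", "IA18", "IA19"}
))


def build_table2_fixture() -> tuple[CallSet, list[AnnotatedVariant]]:
    """The risk-gene screen fixture: every published variant row with its
    carrier assignments (all heterozygous), plus >= 15 synthetic decoys
    each violating exactly one screen rule."""
    annotations, carriers, _roles, _rules = _load_fixture(
        "table2_variants.tsv")
    callset = _callset_from_carriers(
        list(TABLE2_SAMPLES), [a.key for a in annotations], carriers)
    return callset, annotations


def table2_fixture_metadata() -> tuple[dict, dict]:
    """(role, decoy_rule) per variant key of the screen fixture."""
    _annotations, _carriers, roles, rules = _load_fixture(
        "table2_variants.tsv")
    return roles, rules


def build_family_fixture() -> tuple[
        CallSet, list[AnnotatedVariant], Pedigree, dict]:
    """The three-affected-siblings fixture: five published candidate
    variants shared by all sibs and absent from every control source, plus
    synthetic decoys removed by each filter stage.

    Returns (callset, annotations, pedigree, control frequency table);
    the control table maps variant -> {source: MAF, absent = 0.0}.
    """
    annotations, carriers, _roles, _rules = _load_fixture(
        "table3_variants.tsv")
    samples = list(FAMILY_SIBS)
    callset = _callset_from_carriers(
        samples, [a.key for a in annotations], carriers)
    father, mother = "FA_F", "FA_M"
    pedigree = Pedigree([
        Individual(father, FAMILY_ID, None, None, "male", Affection.UNKNOWN),
        Individual(mother, FAMILY_ID, None, None, "female",
                   Affection.UNKNOWN),
        *[Individual(s, FAMILY_ID, father, mother, "unknown",
                     Affection.AFFECTED) for s in FAMILY_SIBS],
    ])
    control_table = {
        str(a.key): {src: (a.maf(src) or 0.0) for src in CONTROL_SOURCES}
        for a in annotations
    }
    return callset, annotations, pedigree, control_table


def family_fixture_metadata() -> tuple[dict, dict]:
    """(role, decoy_rule) per variant key of the family fixture."""
    _annotations, _carriers, roles, rules = _load_fixture(
        "table3_variants.tsv")
    return roles, rules
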