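"""Core domain types shared by every pipeline stage.

The unit of analysis is an annotated sequence variant identified by its
HGVS description on a named RefSeq transcript (the convention used when a
study publishes variant tables rather than genomic coordinates).  Genotypes
live in a :class:`CallSet` (samples x variants zygosity matrix), family
structure in a :class:`Pedigree`, and per-variant evidence in an
:class:`AnnotatedVariant`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GenomicPosition",
    "VariantKey",
    "Consequence",
    "ConsequenceClass",
    "PopulationFrequency",
    "SplicePredictor",
    "SpliceEffect",
    "PredictorScores",
    "GeneConstraint",
    "AnnotatedVariant",
    "Zygosity",
    "CallSet",
    "Affection",
    "Individual",
    "Pedigree",
    "MafCategory",
    "categorize_maf",
    "AcmgCriterion",
    "CriterionTier",
    "AcmgClass",
    "AssociationResult",
]


# --------------------------------------------------------------------------
# variant identity
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicPosition:
    """Optional 1-based, fully-closed forward-strand coordinate pass-through."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"genomic position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a variant: (gene symbol, transcript, HGVS c.) is the
    primary key within one dataset; genomic coordinates are optional."""

    gene_symbol: str
    transcript_id: str
    hgvs_c: str
    hgvs_p: Optional[str] = field(default=None, compare=False)
    rsid: Optional[str] = field(default=None, compare=False)
    genomic: Optional[GenomicPosition] = field(default=None, compare=False)

    def __str__(self) -> str:  # e.g. "PCNT:NM_006031:c.4354G>A"
        return f"{self.gene_symbol}:{self.transcript_id}:{self.hgvs_c}"


class Consequence(enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INTRONIC_BOUNDARY = "intronic_boundary"
    OTHER = "other"


@dataclass(frozen=True)
class ConsequenceClass:
    """Predicted molecular consequence.

    ``intronic_boundary`` carries a nonzero offset relative to the nearest
    exon-intron junction (negative = upstream of the acceptor, positive =
    downstream of the donor); filters decide how far from the junction is
    still interesting, the type itself only forbids offset 0.
    """

    kind: Consequence
    intron_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind is Consequence.INTRONIC_BOUNDARY:
            if self.intron_offset is None or self.intron_offset == 0:
                raise ValueError("intronic_boundary requires a nonzero offset")
        elif self.intron_offset is not None:
            raise ValueError(f"{self.kind.value} carries no intron offset")


# --------------------------------------------------------------------------
# population frequency
# --------------------------------------------------------------------------

#: relative tolerance for MAF vs count consistency; published tables round
#: frequencies to ~4 significant figures.
_MAF_CONSISTENCY_RTOL = 1e-3


@dataclass(frozen=True)
class PopulationFrequency:
    """Allele frequency of a variant in one reference source.

    Counts follow the gnomAD convention: ``allele_count`` is the total
    number of alternate alleles observed (AC), ``hom_count`` the number of
    homozygous individuals (nhomalt) and ``total_alleles`` the number of
    analyzed alleles (AN), so ``maf = allele_count / total_alleles``.
    """

    source: str
    maf: float
    allele_count: Optional[int] = None
    hom_count: Optional[int] = None
    total_alleles: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"MAF must lie in [0, 1], got {self.maf}")
        ac, hom, an = self.allele_count, self.hom_count, self.total_alleles
        for name, v in (("allele_count", ac), ("hom_count", hom)):
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if an is not None and an <= 0:
            raise ValueError(f"total_alleles must be positive, got {an}")
        if ac is not None and hom is not None and 2 * hom > ac:
            raise ValueError(
                f"hom_count {hom} implies more alleles than allele_count {ac}"
            )
        if ac is not None and an is not None:
            if ac > an:
                raise ValueError(f"allele_count {ac} exceeds total_alleles {an}")
            implied = ac / an
            if not math.isclose(self.maf, implied, rel_tol=_MAF_CONSISTENCY_RTOL,
                                abs_tol=1e-6):
                raise ValueError(
                    f"MAF {self.maf} inconsistent with counts "
                    f"{ac}/{an} = {implied:.6g} for source {self.source}"
                )


# --------------------------------------------------------------------------
# in-silico predictions
# --------------------------------------------------------------------------

class SplicePredictor(enum.Enum):
    HSF = "HSF"
    NETGENE2 = "NG2"
    MAXENTSCAN = "MES"
    BDGP = "BDGP"


class SpliceEffect(enum.Enum):
    DONOR_LOSS = "donor_loss"
    DONOR_GAIN = "donor_gain"
    ACCEPTOR_GAIN = "acceptor_gain"
    ACCEPTOR_LOSS = "acceptor_loss"
    ESS_GAIN = "ess_gain"
    NO_IMPACT = "no_impact"


@dataclass(frozen=True)
class PredictorScores:
    """Precomputed pathogenicity scores; a missing score is ``None``, never 0.

    ``splice_calls`` maps each splice predictor to at most one call, so the
    "one call per predictor / no_impact excludes impact" invariant holds by
    construction.
    """

    cadd: Optional[float] = None
    revel: Optional[float] = None
    mcap: Optional[float] = None
    clinpred: Optional[float] = None
    splice_calls: Mapping[SplicePredictor, SpliceEffect] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.cadd is not None and self.cadd < 0:
            raise ValueError("CADD score must be nonnegative")
        for name, v in (("REVEL", self.revel), ("M-CAP", self.mcap),
                        ("ClinPred", self.clinpred)):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} score must lie in [0, 1], got {v}")
        object.__setattr__(self, "splice_calls", dict(self.splice_calls))

    def as_tuple(self) -> tuple:
        return (self.cadd, self.revel, self.mcap, self.clinpred)


@dataclass(frozen=True)
class GeneConstraint:
    """gnomAD constraint metrics consumed as annotations."""

    mis_z: float
    pli: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pli <= 1.0):
            raise ValueError(f"pLI must lie in [0, 1], got {self.pli}")


@dataclass(frozen=True)
class AnnotatedVariant:
    key: VariantKey
    consequence: ConsequenceClass
    frequencies: Mapping[str, PopulationFrequency] = field(default_factory=dict)
    scores: PredictorScores = field(default_factory=PredictorScores)
    constraint: Optional[GeneConstraint] = None
    domain_tags: frozenset = field(default_factory=frozenset)
    criteria_string: Optional[str] = None  # e.g. "PM1+PP3", as published

    def __post_init__(self) -> None:
        freqs = dict(self.frequencies)
        for source, freq in freqs.items():
            if freq.source != source:
                raise ValueError(
                    f"frequency keyed {source!r} labelled {freq.source!r}"
                )
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "domain_tags", frozenset(self.domain_tags))

    def maf(self, source: str) -> Optional[float]:
        """MAF in ``source``, or None when the source has no record."""
        freq = self.frequencies.get(source)
        return None if freq is None else freq.maf


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

class Zygosity(enum.IntEnum):
    REF = 0
    HET = 1
    HOM = 2


class CallSet:
    """Samples x variants zygosity matrix.

    Missing genotypes were recorded as REF on read; ``missing_count`` keeps
    the tally so downstream carrier denominators stay honest.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        variants: Sequence[VariantKey],
        zygosity: np.ndarray,
        missing_count: int = 0,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.variants = list(variants)
        zyg = np.asarray(zygosity, dtype=np.int8)
        if zyg.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"zygosity shape {zyg.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if zyg.size and (zyg.min() < 0 or zyg.max() > 2):
            raise ValueError("zygosity codes must be 0 (ref), 1 (het) or 2 (hom)")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("duplicate variant keys")
        self.zygosity = zyg
        self.missing_count = missing_count
        self._variant_index = {v: i for i, v in enumerate(self.variants)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    # -- lookups ----------------------------------------------------------
    def zygosity_of(self, sample_id: str, variant: VariantKey) -> Zygosity:
        return Zygosity(
            self.zygosity[self._sample_index[sample_id],
                          self._variant_index[variant]]
        )

    def is_carrier(self, sample_id: str, variant: VariantKey) -> bool:
        return self.zygosity_of(sample_id, variant) != Zygosity.REF

    def carriers_of(self, variant: VariantKey) -> list[str]:
        col = self.zygosity[:, self._variant_index[variant]]
        return [s for s, z in zip(self.sample_ids, col) if z > 0]

    def variants_of(self, sample_id: str) -> list[VariantKey]:
        row = self.zygosity[self._sample_index[sample_id], :]
        return [v for v, z in zip(self.variants, row) if z > 0]

    def has_sample(self, sample_id: str) -> bool:
        return sample_id in self._sample_index

    def dosage_matrix(self) -> np.ndarray:
        """Alternate-allele dosage (0/1/2) as float, samples x variants."""
        return self.zygosity.astype(float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CallSet):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.variants == other.variants
            and np.array_equal(self.zygosity, other.zygosity)
        )

    def __repr__(self) -> str:
        return (f"CallSet({len(self.sample_ids)} samples x "
                f"{len(self.variants)} variants)")


# --------------------------------------------------------------------------
# pedigree
# --------------------------------------------------------------------------

class Affection(enum.Enum):
    AFFECTED = "affected"
    PROBABLE_AFFECTED = "probable_affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str  # "male" / "female" / "unknown"
    affection: Affection


class Pedigree:
    """Family structure with affection status.

    Parent references must resolve within the same family (or be absent)
    and the parent graph must be acyclic.
    """

    def __init__(self, individuals: Iterable[Individual]) -> None:
        self.individuals = list(individuals)
        self._by_id: dict[str, Individual] = {}
        for ind in self.individuals:
            if ind.individual_id in self._by_id:
                raise ValueError(f"duplicate individual id {ind.individual_id!r}")
            self._by_id[ind.individual_id] = ind
        for ind in self.individuals:
            for pid in (ind.father_id, ind.mother_id):
                if pid is None:
                    continue
                parent = self._by_id.get(pid)
                if parent is None:
                    raise ValueError(
                        f"parent {pid!r} of {ind.individual_id!r} not in pedigree"
                    )
                if parent.family_id != ind.family_id:
                    raise ValueError(
                        f"parent {pid!r} of {ind.individual_id!r} "
                        "belongs to a different family"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise ValueError(f"cyclic ancestry involving {iid!r}")
            state[iid] = 0
            ind = self._by_id[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    visit(pid, stack + [iid])
            state[iid] = 1

        for ind in self.individuals:
            visit(ind.individual_id, [])

    def __getitem__(self, individual_id: str) -> Individual:
        return self._by_id[individual_id]

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def __len__(self) -> int:
        return len(self.individuals)

    def family_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.family_id, None)
        return list(seen)

    def members(self, family_id: str) -> list[Individual]:
        return [i for i in self.individuals if i.family_id == family_id]

    def affected(self, family_id: str,
                 include_probable: bool = False) -> list[Individual]:
        wanted = {Affection.AFFECTED}
        if include_probable:
            wanted.add(Affection.PROBABLE_AFFECTED)
        return [i for i in self.members(family_id) if i.affection in wanted]


# --------------------------------------------------------------------------
# MAF tiers
# --------------------------------------------------------------------------

class MafCategory(enum.Enum):
    """Frequency tiers partitioning [0, 1]; boundaries belong to the lower
    tier: unknown = {0}, very_rare = (0, 0.001], rare = (0.001, 0.01],
    low_frequency = (0.01, 0.05], common = (0.05, 1]."""

    UNKNOWN = "unknown"
    VERY_RARE = "very_rare"
    RARE = "rare"
    LOW_FREQUENCY = "low_frequency"
    COMMON = "common"


def categorize_maf(maf: float) -> MafCategory:
    """Assign a MAF to its frequency tier.

    Raises ValueError for values outside [0, 1].
    """
    if not (0.0 <= maf <= 1.0):
        raise ValueError(f"MAF must lie in [0, 1], got {maf}")
    if maf == 0.0:
        return MafCategory.UNKNOWN
    if maf <= 0.001:
        return MafCategory.VERY_RARE
    if maf <= 0.01:
        return MafCategory.RARE
    if maf <= 0.05:
        return MafCategory.LOW_FREQUENCY
    return MafCategory.COMMON


# --------------------------------------------------------------------------
# ACMG/AMP evidence codes
# --------------------------------------------------------------------------

class CriterionTier(enum.Enum):
    PATHOGENIC_VERY_STRONG = "pathogenic_very_strong"
    PATHOGENIC_STRONG = "pathogenic_strong"
    PATHOGENIC_MODERATE = "pathogenic_moderate"
    PATHOGENIC_SUPPORTING = "pathogenic_supporting"
    BENIGN_STANDALONE = "benign_standalone"
    BENIGN_STRONG = "benign_strong"
    BENIGN_SUPPORTING = "benign_supporting"


_VALID_CRITERIA = (
    {"PVS1"}
    | {f"PS{i}" for i in range(1, 5)}
    | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
    | {"BA1"}
    | {f"BS{i}" for i in range(1, 5)}
    | {f"BP{i}" for i in range(1, 8)}
)

_TIER_BY_PREFIX = {
    "PVS": CriterionTier.PATHOGENIC_VERY_STRONG,
    "PS": CriterionTier.PATHOGENIC_STRONG,
    "PM": CriterionTier.PATHOGENIC_MODERATE,
    "PP": CriterionTier.PATHOGENIC_SUPPORTING,
    "BA": CriterionTier.BENIGN_STANDALONE,
    "BS": CriterionTier.BENIGN_STRONG,
    "BP": CriterionTier.BENIGN_SUPPORTING,
}


@dataclass(frozen=True, order=True)
class AcmgCriterion:
    """One ACMG/AMP evidence code; its strength tier is a pure function of
    the code prefix (PVS / PS / PM / PP / BA / BS / BP)."""

    code: str

    def __post_init__(self) -> None:
        if self.code not in _VALID_CRITERIA:
            raise ValueError(f"unknown ACMG criterion code {self.code!r}")

    @property
    def tier(self) -> CriterionTier:
        for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
            if self.code.startswith(prefix):
                return _TIER_BY_PREFIX[prefix]
        raise AssertionError("unreachable")  # pragma: no cover

    @property
    def is_pathogenic(self) -> bool:
        return self.code.startswith("P")

    @property
    def is_benign(self) -> bool:
        return self.code.startswith("B")

    def __str__(self) -> str:
        return self.code


class AcmgClass(enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


# --------------------------------------------------------------------------
# association results
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationResult:
    """Outcome of one association test.

    Permutation p-values use the add-one estimator, so they are strictly
    positive by construction.
    """

    test_name: str
    statistic: float
    p_value: float
    contingency: Optional[tuple] = None  # ((a, b), (c, d))
    odds_ratio: Optional[float] = None
    odds_ratio_haldane: Optional[float] = None
    p_value_moment: Optional[float] = None
    n_permutations: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value must lie in (0, 1], got {self.p_value}")
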