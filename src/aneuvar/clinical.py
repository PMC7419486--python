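"""PHASES rupture-risk scoring and cohort-table summarization.

PHASES is an additive point score over six aneurysm/patient components —
Population, Hypertension, Age, Size of aneurysm, Earlier SAH from another
aneurysm, Site — estimating 5-year rupture risk of an unruptured
intracranial aneurysm.  The point table ships as a package data file
(``data/phases_points.json``); size bins are half-open, closed on the
left: <7.0 / 7.0-9.9 / 10.0-19.9 / >=20.0 mm.  For patients with multiple
aneurysms, the documented score is the per-aneurysm maximum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "PhasesInput", "phases_score", "patient_phases", "phases_point_table",
    "FieldSummary", "CohortSummary", "summarize_cohort",
    "POPULATIONS", "SITES",
]

POPULATIONS = ("north_american_european", "japanese", "finnish")
SITES = ("ICA", "MCA", "ACA_Pcom_posterior")


@dataclass(frozen=True)
class PhasesInput:
    """One aneurysm in one patient."""

    population: str
    hypertension: bool
    age_years: float
    aneurysm_size_mm: float
    earlier_sah_other_aneurysm: bool
    site: str

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        if self.age_years < 0:
            raise ValueError("age must be nonnegative")
        if self.aneurysm_size_mm <= 0:
            raise ValueError("aneurysm size must be positive")


def phases_point_table() -> dict:
    """The shipped PHASES point table."""
    text = (resources.files("aneuvar.data") / "phases_points.json").read_text()
    return json.loads(text)


_TABLE = None


def _table() -> dict:
    global _TABLE
    if _TABLE is None:
        _TABLE = phases_point_table()
    return _TABLE


def phases_score(inp: PhasesInput) -> int:
    """Sum of the six component points for one aneurysm."""
    t = _table()
    score = t["population"][inp.population]
    score += t["hypertension"]["yes" if inp.hypertension else "no"]
    age = t["age"]
    score += (age["at_or_above"] if inp.age_years >= age["threshold_years"]
              else age["below"])
    for bin_ in t["size_mm_bins"]:
        lo = bin_["min"]
        hi = bin_["max"] if bin_["max"] is not None else math.inf
        if lo <= inp.aneurysm_size_mm < hi:
            score += bin_["points"]
            break
    score += t["earlier_sah_other_aneurysm"][
        "yes" if inp.earlier_sah_other_aneurysm else "no"]
    score += t["site"][inp.site]
    return int(score)


def patient_phases(aneurysms: Sequence[PhasesInput]) -> int:
    """Documented per-patient score: maximum over the patient's aneurysms."""
    if not aneurysms:
        raise ValueError("at least one aneurysm required")
    return max(phases_score(a) for a in aneurysms)


# --------------------------------------------------------------------------
# cohort summarization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldSummary:
    field: str
    kind: str  # "numeric" | "categorical"
    n: int  # non-missing
    n_missing: int
    mean: Optional[float] = None
    sd: Optional[float] = None
    min: Optional[float] = None
    max: Optional[float] = None
    counts: Optional[dict] = None  # category -> (count, percent)

    @property
    def empty(self) -> bool:
        return self.n == 0


@dataclass
class CohortSummary:
    fields: dict  # field name -> FieldSummary

    def __getitem__(self, field: str) -> FieldSummary:
        return self.fields[field]

    def to_rows(self) -> list[dict]:
        rows = []
        for name in sorted(self.fields):
            s = self.fields[name]
            if s.kind == "numeric":
                rows.append({
                    "field": name, "kind": s.kind, "n": s.n,
                    "n_missing": s.n_missing,
                    "summary": ("" if s.empty else
                                f"{s.mean:.1f} ± {s.sd:.1f} "
                                f"({s.min:g}–{s.max:g})"),
                })
            else:
                for cat in sorted(s.counts or {}):
                    count, pct = s.counts[cat]
                    rows.append({
                        "field": name, "kind": s.kind, "n": s.n,
                        "n_missing": s.n_missing,
                        "summary": f"{cat} {count} ({pct:.1f})",
                    })
        return rows


def summarize_cohort(
    records: Sequence[Mapping],
    schema: Mapping[str, str],
    missing_token: str = "n.a.",
) -> CohortSummary:
    """Summarize tabular clinical records.

    ``schema`` maps field name -> "numeric" | "categorical".  Numeric
    fields get mean, sample SD and range over non-missing values;
    categorical fields get counts and percentages over the non-missing
    denominator (reported to 1 decimal).  Missing values are tallied
    separately; an all-missing field is flagged empty rather than dividing
    by zero.  Raises KeyError for a schema field absent from the records.
    """
    fields: dict[str, FieldSummary] = {}
    for name, kind in schema.items():
        if kind not in ("numeric", "categorical"):
            raise ValueError(f"unknown field kind {kind!r} for {name!r}")
        values = []
        n_missing = 0
        for rec in records:
            if name not in rec:
                raise KeyError(f"field {name!r} absent from record")
            v = rec[name]
            if v is None or (isinstance(v, str) and v.strip() in
                             ("", missing_token)):
                n_missing += 1
                continue
            if isinstance(v, float) and math.isnan(v):
                n_missing += 1
                continue
            values.append(v)
        if kind == "numeric":
            nums = np.array([float(v) for v in values])
            if nums.size == 0:
                fields[name] = FieldSummary(name, kind, 0, n_missing)
            else:
                sd = float(nums.std(ddof=1)) if nums.size > 1 else 0.0
                fields[name] = FieldSummary(
                    name, kind, int(nums.size), n_missing,
                    mean=float(nums.mean()), sd=sd,
                    min=float(nums.min()), max=float(nums.max()),
                )
        else:
            n = len(values)
            counts: dict[str, tuple[int, float]] = {}
            for v in values:
                key = str(v)
                counts[key] = (counts.get(key, (0, 0.0))[0] + 1, 0.0)
            if n:
                counts = {k: (c, 100.0 * c / n) for k, (c, _) in counts.items()}
            fields[name] = FieldSummary(name, kind, n, n_missing,
                                        counts=counts)
    return CohortSummary(fields)
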