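"""Carrier-based association tests for a candidate gene.

* Fisher's exact test on a 2x2 carrier table (two-sided,
  minimum-likelihood convention: sum the hypergeometric probabilities of
  all tables with fixed margins whose point probability does not exceed
  the observed one).
* Cumulative carrier frequency (qualifying-variant carriers / individuals).
* Collapsing burden test and a SKAT-style variance-component test, both
  with phenotype-label permutation p-values (add-one estimator) against an
  intercept-only null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import AssociationResult

__all__ = [
    "CarrierTable", "SkatInput", "fisher_exact",
    "cumulative_carrier_frequency", "burden_test", "skat_test",
    "beta_maf_weights",
]

DEFAULT_PERMUTATIONS = 99_999


@dataclass(frozen=True)
class CarrierTable:
    """2x2 table: rows (cases, comparison group) x columns
    (carriers, non-carriers)."""

    case_carriers: int
    case_noncarriers: int
    comparison_carriers: int
    comparison_noncarriers: int

    def __post_init__(self) -> None:
        cells = (self.case_carriers, self.case_noncarriers,
                 self.comparison_carriers, self.comparison_noncarriers)
        if any(c < 0 for c in cells):
            raise ValueError("table cells must be nonnegative")
        if self.case_carriers + self.case_noncarriers == 0:
            raise ValueError("case row sum must be positive")
        if self.comparison_carriers + self.comparison_noncarriers == 0:
            raise ValueError("comparison row sum must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.case_carriers, self.case_noncarriers],
                         [self.comparison_carriers,
                          self.comparison_noncarriers]])


def fisher_exact(table: CarrierTable) -> AssociationResult:
    """Two-sided Fisher's exact test on a carrier table.

    The statistic is the sample odds ratio (ad/bc, infinite on a zero
    denominator cell); a Haldane-corrected odds ratio (0.5 added to every
    cell) is reported alongside for degenerate tables.
    """
    arr = table.as_array()
    a, b = arr[0]
    c, d = arr[1]
    p = float(stats.fisher_exact(arr, alternative="two-sided").pvalue)
    odds = float(a * d) / (b * c) if b * c else float("inf")
    haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return AssociationResult(
        test_name="fisher_exact",
        statistic=odds,
        p_value=min(p, 1.0),
        contingency=((int(a), int(b)), (int(c), int(d))),
        odds_ratio=odds,
        odds_ratio_haldane=float(haldane),
    )


def cumulative_carrier_frequency(carriers: int, individuals: int) -> float:
    """Fraction of individuals carrying at least one qualifying variant."""
    if individuals <= 0:
        raise ValueError("individuals must be positive")
    if not (0 <= carriers <= individuals):
        raise ValueError("carriers must lie in [0, individuals]")
    return carriers / individuals


# --------------------------------------------------------------------------
# permutation score tests
# --------------------------------------------------------------------------

@dataclass
class SkatInput:
    """Inputs shared by the burden and SKAT-style tests.

    ``genotypes`` is a samples x variants dosage matrix (0/1/2);
    ``phenotype`` is binary per sample; ``weights`` default to flat 1.0.
    """

    phenotype: np.ndarray
    genotypes: np.ndarray
    weights: Optional[np.ndarray] = None
    n_permutations: int = DEFAULT_PERMUTATIONS
    seed: int = 0

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-dimensional")
        n, m = self.genotypes.shape
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype length must match genotype rows")
        if m < 1:
            raise ValueError("at least one variant required")
        if self.weights is None:
            self.weights = np.ones(m)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (m,):
                raise ValueError("weights length must equal variant count")
            if np.any(self.weights < 0):
                raise ValueError("weights must be nonnegative")
        classes = np.unique(self.phenotype)
        if classes.size < 2:
            raise ValueError("both phenotype classes must be present")


def beta_maf_weights(mafs: Sequence[float], a: float = 1.0,
                     b: float = 25.0) -> np.ndarray:
    """Beta(1, 25) density weights upweighting the rarest variants."""
    mafs = np.asarray(mafs, dtype=float)
    return stats.beta.pdf(np.clip(mafs, 1e-12, 1 - 1e-12), a, b)


def _burden_stat(residual_rows: np.ndarray, burden: np.ndarray) -> np.ndarray:
    # squared score of the weighted dosage sum against phenotype residuals
    return (residual_rows @ burden) ** 2


def _skat_stat(residual_rows: np.ndarray, gw: np.ndarray) -> np.ndarray:
    # Q = r' G W^2 G' r computed as ||(G W)' r||^2 per residual row
    return np.square(residual_rows @ gw).sum(axis=-1)


def _permutation_test(
    input_: SkatInput, kind: str
) -> AssociationResult:
    y = input_.phenotype
    r = y - y.mean()  # intercept-only null residuals
    gw = input_.genotypes * input_.weights  # G W (columns scaled)
    if kind == "burden":
        burden = gw.sum(axis=1)
        observed = float(_burden_stat(r[None, :], burden)[0])
    else:
        observed = float(_skat_stat(r[None, :], gw)[0])

    rng = np.random.default_rng(input_.seed)
    nperm = int(input_.n_permutations)
    if nperm < 1:
        raise ValueError("n_permutations must be >= 1")
    # permute phenotype labels in blocks to bound peak memory
    block = max(1, min(nperm, 20_000))
    exceed = 0
    perm_values = []
    done = 0
    while done < nperm:
        k = min(block, nperm - done)
        perm = rng.permuted(np.tile(r, (k, 1)), axis=1)
        if kind == "burden":
            vals = _burden_stat(perm, burden)
        else:
            vals = _skat_stat(perm, gw)
        exceed += int(np.sum(vals >= observed))
        perm_values.append(vals)
        done += k
    p_perm = (1 + exceed) / (1 + nperm)

    p_moment = None
    if kind == "skat" and nperm > 1:
        vals = np.concatenate(perm_values)
        mu = float(vals.mean())
        var = float(vals.var(ddof=1))
        if mu > 0 and var > 0:
            # Satterthwaite-style scaled chi-square matching (mean, variance)
            scale = var / (2 * mu)
            dof = 2 * mu * mu / var
            p_moment = float(stats.chi2.sf(observed / scale, dof))

    return AssociationResult(
        test_name=kind,
        statistic=observed,
        p_value=p_perm,
        p_value_moment=p_moment,
        n_permutations=nperm,
        seed=input_.seed,
    )


def burden_test(input_: SkatInput) -> AssociationResult:
    """Collapsing burden test: squared score of the weighted per-sample
    dosage sum, permutation p-value (add-one estimator)."""
    return _permutation_test(input_, "burden")


def skat_test(input_: SkatInput) -> AssociationResult:
    """Variance-component score test Q = r' G W^2 G' r with permutation
    p-value; a moment-matched (scaled chi-square) p-value is reported
    alongside."""
    return _permutation_test(input_, "skat")
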