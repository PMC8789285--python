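"""Estimators from count data: inbreeding coefficients, mating efficiency,
and expected zygote frequencies in mixed-isolate crosses.

Two routes to the inbreeding coefficient F are implemented, mirroring the
microscopy and genetic assays used on fission yeast:

* from fluorescence-scored zygote/ascus genotype counts,
  F = 1 - observed_het_freq / (2 p (1-p));
* from the recombinant fraction among progeny of a cross segregating n
  unlinked markers: a heterozygous (outcrossed) diploid yields the 2^n
  multi-locus genotypes in equal frequency, of which 2 are parental, so the
  true outcross fraction is recombinant_fraction / ((2^n - 2) / 2^n) and
  F = 1 - outcross_fraction / (2 p (1-p)).

Mating efficiency is scored from a census of vegetative cells (V), zygotes
(Z), asci (A) and free spores (S) as (2Z + 2A + S/2) / (wV + 2Z + 2A + S/2)
with vegetative weight w = 2 by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core_model import GenotypeFrequencies

__all__ = [
    "ZygoteCounts",
    "CellCensus",
    "ProgenyTable",
    "MixedCrossParams",
    "inbreeding_from_zygotes",
    "mating_efficiency",
    "outcross_fraction_from_recombinants",
    "inbreeding_from_genetic",
    "expected_mixed_cross",
    "bootstrap_ci",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ZygoteCounts:
    """Mated-unit (zygote/ascus) genotype counts by fluorescence class."""

    n_hom1: int
    n_het: int
    n_hom2: int
    p_initial: float

    def __post_init__(self) -> None:
        for name in ("n_hom1", "n_het", "n_hom2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.p_initial <= 1.0:
            raise ValueError("p_initial must be in [0, 1]")

    @property
    def total(self) -> int:
        return self.n_hom1 + self.n_het + self.n_hom2

    def as_array(self) -> np.ndarray:
        return np.array([self.n_hom1, self.n_het, self.n_hom2])


@dataclass(frozen=True)
class CellCensus:
    """Counts of vegetative cells, zygotes, asci, and free spores."""

    V: int
    Z: int
    A: int
    S: int

    def __post_init__(self) -> None:
        for name in ("V", "Z", "A", "S"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.V + self.Z + self.A + self.S == 0:
            raise ValueError("census is empty")


@dataclass(frozen=True)
class ProgenyTable:
    """Per-progeny marker genotypes over 2-3 unlinked loci.

    ``genotypes`` is an (n_progeny, n_markers) array of 1/2 parental-origin
    codes; the parental genotypes are all-1 and all-2 rows.
    """

    genotypes: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.ndim != 2 or g.shape[1] not in (2, 3):
            raise ValueError("genotypes must be (n_progeny, 2 or 3)")
        if g.size and not np.isin(g, (1, 2)).all():
            raise ValueError("marker states must be 1 or 2")
        object.__setattr__(self, "genotypes", g)

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_progeny(self) -> int:
        return self.genotypes.shape[0]

    def recombinant_fraction(self) -> float:
        """Fraction of progeny with a non-parental multi-locus genotype."""
        if self.n_progeny == 0:
            raise ValueError("empty progeny table")
        g = self.genotypes
        parental = np.all(g == 1, axis=1) | np.all(g == 2, axis=1)
        return float(1.0 - parental.mean())


@dataclass(frozen=True)
class MixedCrossParams:
    """Parameters of a cross between two isolates with their own mating traits.

    F_I1/F_I2 are each strain's isogenic-cross inbreeding coefficients and
    me1/me2 their mating efficiencies as fractions (me = 1 - u).
    """

    p: float
    F_I1: float
    F_I2: float
    me1: float
    me2: float

    def __post_init__(self) -> None:
        for name in ("p", "F_I1", "F_I2", "me1", "me2"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {x!r}")


def inbreeding_from_zygotes(counts: ZygoteCounts) -> float:
    """F = 1 - observed heterozygote frequency / 2p(1-p).

    p is the pre-mating frequency of parent 1.  Returns 1 when no
    heterozygotes were observed; can be negative (excess heterozygosity).
    """
    if counts.total == 0:
        raise ValueError("no mated units observed; F undefined")
    p = counts.p_initial
    if p in (0.0, 1.0):
        raise ValueError("p_initial of 0 or 1 gives zero expected heterozygotes")
    observed_het = counts.n_het / counts.total
    expected_het = 2.0 * p * (1.0 - p)
    return 1.0 - observed_het / expected_het


def mating_efficiency(census: CellCensus, vegetative_weight: float = 2.0) -> float:
    """Percentage of cells that entered mating.

    Default weighting follows the printed formula
    (2Z + 2A + S/2) / (2V + 2Z + 2A + S/2) * 100; the vegetative weight is
    exposed because a strict per-cell accounting would use 1.
    """
    mated = 2.0 * census.Z + 2.0 * census.A + census.S / 2.0
    denom = vegetative_weight * census.V + mated
    if denom == 0:
        raise ValueError("census denominator is zero")
    return 100.0 * mated / denom


def outcross_fraction_from_recombinants(recombinant_fraction: float, n_markers: int) -> float:
    """Correct the observed recombinant fraction for undetected parentals.

    Among the 2^n equally frequent progeny genotypes of an outcrossed
    heterozygote, 2 look parental, so outcrossing is observed with
    probability (2^n - 2)/2^n (6/8 for three markers, 2/4 for two).  Results
    above 1 (sampling overshoot) are capped at 1 with a warning.
    """
    if not 0.0 <= recombinant_fraction <= 1.0:
        raise ValueError("recombinant_fraction must be in [0, 1]")
    if n_markers < 2:
        raise ValueError("need at least 2 unlinked markers to observe recombinants")
    detectable = (2**n_markers - 2) / 2**n_markers
    out = recombinant_fraction / detectable
    if out > 1.0:
        warnings.warn(
            f"corrected outcross fraction {out:.4g} > 1; capping at 1", stacklevel=2
        )
        out = 1.0
    return out


def inbreeding_from_genetic(recombinant_fraction: float, n_markers: int, p: float) -> float:
    """F from recombinant progeny: 1 - corrected outcross fraction / 2p(1-p)."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    outcross = outcross_fraction_from_recombinants(recombinant_fraction, n_markers)
    return 1.0 - outcross / (2.0 * p * (1.0 - p))


def expected_mixed_cross(params: MixedCrossParams) -> GenotypeFrequencies:
    """Expected zygote genotype frequencies in a mixed-isolate cross.

    Additive model: each strain contributes its isogenic inbreeding
    coefficient and mating efficiency, and does not change its behaviour in
    response to the partner.  With u_i = 1 - me_i,

        hom1 = [p^2 + p(1-p) F_I1] (1 - u_1)
        het  = 2p(1-p) [1 - (F_I1+F_I2)/2] [1 - (u_1+u_2)/2]
        hom2 = 1 - hom1 - het.
    """
    p = params.p
    q = 1.0 - p
    u1 = 1.0 - params.me1
    u2 = 1.0 - params.me2
    hom1 = (p * p + p * q * params.F_I1) * (1.0 - u1)
    het = 2.0 * p * q * (1.0 - (params.F_I1 + params.F_I2) / 2.0) * (1.0 - (u1 + u2) / 2.0)
    hom2 = 1.0 - hom1 - het
    if hom2 < -1e-12:
        raise ValueError(
            f"inconsistent parameters: remainder homozygote frequency {hom2:.4g} < 0"
        )
    return GenotypeFrequencies(hom1, het, max(hom2, 0.0))


def bootstrap_ci(
    estimator: Callable[[ZygoteCounts], float],
    counts: ZygoteCounts,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI for a ZygoteCounts-based estimator.

    Resamples the count table multinomially; degenerate resamples (where the
    estimator is undefined) are skipped and logged.  Returns
    (point_estimate, lower, upper).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    point = estimator(counts)
    rng = np.random.default_rng(seed)
    n = counts.total
    probs = counts.as_array() / n
    draws = rng.multinomial(n, probs, size=n_boot)
    stats = []
    skipped = 0
    for row in draws:
        try:
            stats.append(
                estimator(ZygoteCounts(int(row[0]), int(row[1]), int(row[2]), counts.p_initial))
            )
        except (ValueError, ZeroDivisionError):
            skipped += 1
    if skipped:
        logger.warning("bootstrap_ci: skipped %d degenerate resamples", skipped)
    if not stats:
        raise ValueError("all bootstrap resamples were degenerate")
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return point, float(lo), float(hi)
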