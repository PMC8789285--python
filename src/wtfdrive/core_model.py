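"""Deterministic one-locus, two-allele meiotic-drive model with inbreeding.

A *wtf*-type meiotic driver destroys the spores of a heterozygote that do
not inherit it, so a surviving spore of a heterozygote carries the driver
with probability ``k`` (the transmission bias; 0.5 is Mendelian, 1 is
complete drive).  Spore killing itself reduces the reproductive output of
heterozygous diploids, which is captured by the heterozygote fitness
``w12 = 1/(2k)`` when no additional linked costs act.

Mating need not be random: an inbreeding coefficient ``F`` scales the
heterozygote deficit relative to Hardy-Weinberg.  With genotype frequencies

    f11 = p^2 + F p (1-p)
    f12 = 2 p (1-p) (1-F)
    f22 = (1-p)^2 + F p (1-p)

and diploid fitnesses (w11, w12, w22), the driver allele frequency after one
sexual generation is

    p' = [f11 * w11 + k * f12 * w12] / Wbar,
    Wbar = f11 * w11 + f12 * w12 + f22 * w22.

Everything in this module is deterministic (infinite-population limit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FREQ_TOL",
    "DriveParams",
    "GenotypeFrequencies",
    "Trajectory",
    "genotype_frequencies",
    "mean_fitness",
    "next_frequency",
    "delta_p",
    "iterate",
    "heterozygote_drive_fitness",
    "fitness_from_costs",
]

#: absolute tolerance for frequency-sum and fixed-point checks
FREQ_TOL = 1e-12


class InfeasibleFrequencyWarning(UserWarning):
    """Raised when a negative-F genotype frequency had to be clamped to 0."""


def _check_prob(x: float, name: str) -> float:
    x = float(x)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {x!r}")
    return x


@dataclass(frozen=True)
class DriveParams:
    """Parameters of the drive-with-inbreeding recursion.

    k : transmission bias of the driver from a heterozygote, in [0.5, 1].
    w11, w12, w22 : relative diploid fitnesses (driver hom, het, non-driver
        hom), each in [0, 1], at least one positive.
    F : inbreeding coefficient in [-1, 1] (1 = exclusive same-clone mating,
        0 = random mating, negative = excess heterozygosity).
    strict : if True, infeasible negative genotype frequencies raise instead
        of being clamped and renormalised.
    """

    k: float = 0.98
    w11: float = 1.0
    w12: float = 1.0
    w22: float = 1.0
    F: float = 0.0
    strict: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not 0.5 <= self.k <= 1.0:
            raise ValueError(f"k must be in [0.5, 1], got {self.k!r}")
        for name in ("w11", "w12", "w22"):
            w = getattr(self, name)
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {w!r}")
        if self.w11 == self.w12 == self.w22 == 0.0:
            raise ValueError("at least one fitness must be positive")
        if not -1.0 <= self.F <= 1.0:
            raise ValueError(f"F must be in [-1, 1], got {self.F!r}")

    def with_F(self, F: float) -> "DriveParams":
        return replace(self, F=F)


@dataclass(frozen=True)
class GenotypeFrequencies:
    """Diploid genotype frequencies (driver hom, het, non-driver hom)."""

    f11: float
    f12: float
    f22: float

    def __iter__(self):
        yield self.f11
        yield self.f12
        yield self.f22

    def as_array(self) -> np.ndarray:
        return np.array([self.f11, self.f12, self.f22])


def genotype_frequencies(p: float, F: float, *, strict: bool = False) -> GenotypeFrequencies:
    """Genotype frequencies at allele frequency ``p`` and inbreeding ``F``.

    For F < 0 the raw homozygote terms can go negative outside the feasible
    excess-heterozygosity range (only F >= -min(p, 1-p)/max(p, 1-p) keeps all
    three non-negative).  The default clamps negatives to zero, renormalises
    to sum 1, and emits :class:`InfeasibleFrequencyWarning`; ``strict=True``
    raises instead.
    """
    p = _check_prob(p, "p")
    F = float(F)
    if not -1.0 <= F <= 1.0:
        raise ValueError(f"F must be in [-1, 1], got {F!r}")
    q = 1.0 - p
    f11 = p * p + F * p * q
    f12 = 2.0 * p * q * (1.0 - F)
    f22 = q * q + F * p * q
    if f11 < 0.0 or f22 < 0.0:
        if strict:
            raise ValueError(
                f"infeasible (p={p}, F={F}): genotype frequencies "
                f"({f11:.6g}, {f12:.6g}, {f22:.6g}) include a negative value"
            )
        warnings.warn(
            f"clamping negative genotype frequency at (p={p}, F={F})",
            InfeasibleFrequencyWarning,
            stacklevel=2,
        )
        f11, f12, f22 = max(f11, 0.0), max(f12, 0.0), max(f22, 0.0)
        total = f11 + f12 + f22
        f11, f12, f22 = f11 / total, f12 / total, f22 / total
    return GenotypeFrequencies(f11, f12, f22)


def mean_fitness(p: float, params: DriveParams) -> float:
    """Population mean fitness Wbar at allele frequency ``p``.

    Equals the genotype-frequency-weighted fitness sum, which for feasible
    (p, F) coincides with the expanded form
    p^2 w11 + 2p(1-p) w12 + (1-p)^2 w22 + F p(1-p)(w11 + w22 - 2 w12).
    """
    f = genotype_frequencies(p, params.F, strict=params.strict)
    wbar = f.f11 * params.w11 + f.f12 * params.w12 + f.f22 * params.w22
    if wbar <= 0.0:
        raise ValueError(f"mean fitness is non-positive ({wbar}) at p={p}; degenerate fitnesses")
    return wbar


def next_frequency(p: float, params: DriveParams) -> float:
    """Driver allele frequency after one sexual generation."""
    p = _check_prob(p, "p")
    if p == 0.0 or p == 1.0:  # absorbing boundaries, no meiosis needed
        return p
    f = genotype_frequencies(p, params.F, strict=params.strict)
    wbar = f.f11 * params.w11 + f.f12 * params.w12 + f.f22 * params.w22
    if wbar <= 0.0:
        raise ValueError(f"mean fitness is non-positive ({wbar}) at p={p}; degenerate fitnesses")
    p_next = (f.f11 * params.w11 + params.k * f.f12 * params.w12) / wbar
    return min(max(p_next, 0.0), 1.0)


def delta_p(p: float, params: DriveParams) -> float:
    """One-generation change in driver frequency, next_frequency(p) - p."""
    return next_frequency(p, params) - p


def heterozygote_drive_fitness(k: float) -> float:
    """Heterozygote fitness 1/(2k) when reduced only by drive-killed spores.

    A heterozygote with transmission bias k loses the fraction 1 - 1/(2k) of
    its spores (k=0.98 gives 0.5102..., the 0.51 used for *wtf4*; k=1 gives
    0.5; k=0.5 gives 1, no killing).
    """
    k = float(k)
    if not 0.5 <= k <= 1.0:
        raise ValueError(f"k must be in [0.5, 1], got {k!r}")
    return 1.0 / (2.0 * k)


def fitness_from_costs(
    c: float,
    h: float,
    k: float = 0.5,
    driver_linked_to_costly_marker: bool = True,
) -> tuple[float, float, float]:
    """Diploid fitnesses (w11, w12, w22) from a linked marker cost.

    The costly marker reduces its homozygote's fitness to ``1 - c`` and
    contributes a factor ``1 - c*h`` to the heterozygote (``h`` is the
    dominance of the cost); the cost-free homozygote has fitness 1.  When the
    diploid is heterozygous for a driver with bias ``k``, the heterozygote
    fitness is additionally multiplied by 1/(2k) for drive-killed spores
    (k=0.5 means no drive and no reduction).

    Allele 1 is the focal allele of the recursion.  With the default flag the
    costly marker rides on allele 1 (w11 = 1-c, w22 = 1); with the flag False
    the cost is on allele 2 (w11 = 1, w22 = 1-c).

    With the fitted GFP cost c=0.234, h=0.083 this reproduces the assigned
    values: GFP homozygote 0.766, GFP/mCherry heterozygote 0.98 (no drive) or
    ~0.5 when the pair is also heterozygous for the driver.
    """
    c = _check_prob(c, "c")
    h = _check_prob(h, "h")
    w12 = (1.0 - c * h) * heterozygote_drive_fitness(k)
    if driver_linked_to_costly_marker:
        return (1.0 - c, w12, 1.0)
    return (1.0, w12, 1.0 - c)


@dataclass(frozen=True)
class Trajectory:
    """An allele-frequency trajectory over sexual generations."""

    generations: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.generations, dtype=int)
        f = np.asarray(self.frequencies, dtype=float)
        if g.shape != f.shape or g.ndim != 1:
            raise ValueError("generations and frequencies must be 1-D and equal length")
        if g.size and np.any(np.diff(g) <= 0):
            raise ValueError("generation index must be strictly increasing")
        if np.any((f < 0.0) | (f > 1.0)):
            raise ValueError("frequencies must be in [0, 1]")
        object.__setattr__(self, "generations", g)
        object.__setattr__(self, "frequencies", f)

    def __len__(self) -> int:
        return self.generations.size

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"generation": self.generations, "p": self.frequencies}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "Trajectory":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df["generation"].to_numpy(), df["p"].to_numpy())


def iterate(p0: float, params: DriveParams, G: int) -> Trajectory:
    """Iterate the recursion for ``G`` generations starting from ``p0``.

    Returns a trajectory of length G+1 with frequencies[0] = p0.
    """
    G = int(G)
    if G < 0:
        raise ValueError(f"G must be >= 0, got {G}")
    p = _check_prob(p0, "p0")
    freqs = np.empty(G + 1)
    freqs[0] = p
    for g in range(G):
        p = next_frequency(p, params)
        freqs[g + 1] = p
    return Trajectory(np.arange(G + 1), freqs)
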