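"""Invasion analysis for a driver linked to a deleterious allele.

A driver haplotype carrying a linked cost (homozygous cost ``c``, dominance
``h``) spreads from frequency ``p`` only if the population mates randomly
enough.  Under complete drive (k=1), with fitnesses w11 = 1-c,
w12 = 0.5*(1 - c*h), w22 = 1, the driver increases in frequency iff

    F < F_critical(p, c, h) = [c*h*(p-1) - c*p + p] / [c*(h-1)*(p-1) + p].

This module evaluates that threshold, the boolean invasion condition, and
(numerically) the minimum initial frequency needed to invade at a given F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import DriveParams, delta_p, heterozygote_drive_fitness

__all__ = ["InvasionQuery", "critical_F", "can_invade", "min_invasion_frequency", "critical_F_grid"]

_DENOM_TOL = 1e-12


@dataclass(frozen=True)
class InvasionQuery:
    """An (initial frequency, linked cost, dominance, inbreeding) query."""

    p: float
    c: float
    h: float
    F: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must be in (0, 1), got {self.p!r}")
        for name in ("c", "h", "F"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {x!r}")


def critical_F(p: float, c: float, h: float) -> float:
    """Critical inbreeding coefficient below which the driver spreads.

    Assumes complete drive (k=1) and w11 = 1-c.  For c=0 the expression
    reduces to p/p = 1: a cost-free driver spreads for every F < 1.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p!r}")
    for name, x in (("c", c), ("h", h)):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {x!r}")
    if c == 0.0:
        return 1.0
    num = c * h * (p - 1.0) - c * p + p
    den = c * (h - 1.0) * (p - 1.0) + p
    if abs(den) < _DENOM_TOL:
        raise ZeroDivisionError(f"degenerate invasion query: denominator ~0 at (p={p}, c={c}, h={h})")
    return num / den


def can_invade(q: InvasionQuery) -> bool:
    """True iff the driver increases in frequency at q.p, i.e. q.F < F_critical."""
    return q.F < critical_F(q.p, q.c, q.h)


def _linked_cost_params(c: float, h: float, F: float, k: float) -> DriveParams:
    w12 = heterozygote_drive_fitness(k) * (1.0 - c * h)
    return DriveParams(k=k, w11=1.0 - c, w12=w12, w22=1.0, F=F)


def min_invasion_frequency(
    c: float,
    h: float,
    F: float,
    k: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    grid: int = 512,
) -> float | None:
    """Smallest initial frequency at which the driver haplotype invades.

    Invasion is the strict sign of the one-generation change delta_p under
    fitnesses w11 = 1-c, w12 = (1/(2k))*(1 - c*h), w22 = 1.  The threshold is
    located by a coarse sign scan followed by bisection to precision ``tol``.
    Returns 0.0 if every positive frequency invades and None if no p in (0, 1)
    does.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not 0.5 < k <= 1.0:
        raise ValueError(f"k must be in (0.5, 1], got {k!r}")
    params = _linked_cost_params(c, h, F, k)

    lo = tol / 10.0
    if delta_p(lo, params) > 0.0:
        return 0.0
    ps = np.linspace(lo, 1.0 - lo, grid)
    signs = np.array([delta_p(p, params) > 0.0 for p in ps])
    idx = np.flatnonzero(signs)
    if idx.size == 0:
        return None
    a, b = ps[idx[0] - 1], ps[idx[0]]  # delta_p(a) <= 0 < delta_p(b)
    for _ in range(max_iter):
        if b - a <= tol:
            return b
        mid = 0.5 * (a + b)
        if delta_p(mid, params) > 0.0:
            b = mid
        else:
            a = mid
    raise RuntimeError(f"bisection did not converge to tol={tol} in {max_iter} iterations")


def critical_F_grid(ps, cs, hs):
    """Tabulate F_critical over a grid, for plotting invasion surfaces.

    Returns a pandas DataFrame with columns p, c, h, F_critical.
    """
    import pandas as pd

    rows = [
        (p, c, h, critical_F(p, c, h))
        for p in np.atleast_1d(ps)
        for c in np.atleast_1d(cs)
        for h in np.atleast_1d(hs)
    ]
    return pd.DataFrame(rows, columns=["p", "c", "h", "F_critical"])
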