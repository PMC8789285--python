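"""Stochastic Wright-Fisher model of a meiotic driver in a finite population.

Haploid population of fixed size N with non-overlapping sexual generations.
Each generation:

1. N individuals are sampled with replacement from the current pool
   (infinite-gamete assumption: clonal expansion precedes mating).
2. A fraction F of them (S = round(F*N) individuals) undergo same-clone
   mating: each pairs with a clonal copy of itself and forms a homozygote of
   its own allele.
3. The remaining N - S mate randomly; their diploid genotype counts follow
   Hardy-Weinberg proportions of their allele frequency, rounded to integers
   by largest-remainder apportionment.
4. Every mating yields four gametic products.  Under complete drive the two
   non-driver spores of a heterozygote are killed, so all surviving products
   of a het carry the driver; in neutral mode the het's four products split
   2 + 2.
5. Each mating class's products are decimated in proportion to its fitness
   (binomial thinning by default; deterministic rounding behind a flag).
   With the default het fitness 0.5 a complete-drive heterozygote therefore
   contributes two driver progeny in expectation.
6. The next generation of N haploids is drawn from the pooled progeny.

Counts of 0 and N are absorbing.  All replicates derive independent RNG
streams from one master seed via SeedSequence spawning, so runs are
bit-reproducible.  Internally whole replicate ensembles are stepped at once
with array RNG calls, which keeps 1000 iterations x 1000 generations cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import sqrt

import numpy as np

__all__ = [
    "WFConfig",
    "WFOutcome",
    "EnsembleSummary",
    "wf_step",
    "wf_run",
    "wf_ensemble",
    "maintenance_probability",
]


@dataclass(frozen=True)
class WFConfig:
    """Configuration of the finite-population simulation.

    het_fitness is the heterozygote-mating fitness applied to its four
    gametic products; 0.5 (the default) realises complete drive's loss of
    half the spores.  Use het_fitness=1 with drive_mode="neutral" for a
    strictly neutral model.  Same-clone maters pair with a clonal copy of
    themselves by default; pairing="assortative" instead pairs the sampled
    same-clone maters like-for-like among themselves (leftovers join the
    random pool).
    """

    N: int
    F: float = 0.0
    generations: int = 1000
    iterations: int = 1000
    initial_driver_count: int = 1
    het_fitness: float = 0.5
    hom_driver_fitness: float = 1.0
    hom_nondriver_fitness: float = 1.0
    drive_mode: str = "complete-drive"
    pairing: str = "clonal"
    deterministic_thinning: bool = False
    record_trajectory: bool = False
    trajectory_thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be a positive integer")
        if not 0.0 <= self.F <= 1.0:
            raise ValueError(f"F must be in [0, 1], got {self.F!r}")
        if not 0 <= self.initial_driver_count <= self.N:
            raise ValueError("initial_driver_count must be in [0, N]")
        for name in ("het_fitness", "hom_driver_fitness", "hom_nondriver_fitness"):
            w = getattr(self, name)
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {w!r}")
        if self.drive_mode not in ("complete-drive", "neutral"):
            raise ValueError(f"unknown drive_mode {self.drive_mode!r}")
        if self.pairing not in ("clonal", "assortative"):
            raise ValueError(f"unknown pairing {self.pairing!r}")


@dataclass(frozen=True)
class WFOutcome:
    """Fate of one replicate: fixed, lost, or still segregating at the cap."""

    fate: str
    generations_elapsed: int
    final_count: int
    extinct: bool = False
    trajectory: np.ndarray | None = field(default=None, compare=False)


@dataclass(frozen=True)
class EnsembleSummary:
    """Monte-Carlo summary over replicates.

    maintained = fraction not lost by the generation cap (fixed or still
    segregating); fixed is also reported separately since the two tallies can
    differ when the horizon truncates segregating runs.
    """

    N: int
    F: float
    iterations: int
    maintained: float
    maintained_se: float
    fixed: float
    lost: float
    segregating: float
    extinct: int


def _largest_remainder(
    expected: np.ndarray, totals: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Round rows of ``expected`` (R x 3) to integers summing to ``totals``.

    Remainder ties are broken at random: the two homozygote expectations
    always share a fractional part (their difference is an integer), so a
    deterministic tie-break would systematically favour one allele.
    """
    base = np.floor(expected)
    short = (totals - base.sum(axis=1)).astype(np.int64)
    rem = expected - base + rng.uniform(0.0, 1e-9, size=expected.shape)
    order = np.argsort(-rem, axis=1, kind="stable")
    add = np.zeros_like(base, dtype=np.int64)
    for j in range(expected.shape[1]):
        np.put_along_axis(
            add, order[:, j : j + 1], (short > j).astype(np.int64)[:, None], axis=1
        )
    return base.astype(np.int64) + add


def _step_ensemble(d: np.ndarray, config: WFConfig, rng: np.random.Generator) -> np.ndarray:
    """Advance an array of driver counts one generation (absorbing at 0, N).

    Returns the new counts; replicates whose progeny pool emptied are coded
    as -1 (population extinction).
    """
    N = config.N
    d = np.asarray(d, dtype=np.int64)
    active = (d > 0) & (d < N)
    out = d.copy()
    if not active.any():
        return out
    da = d[active]
    R = da.size

    # (1) resample N haploids with replacement from the pool
    d1 = rng.binomial(N, da / N)
    # (2) designate S same-clone maters (subset without replacement)
    S = int(round(config.F * N))
    if S > 0:
        s_d = rng.hypergeometric(d1, N - d1, S)
    else:
        s_d = np.zeros(R, dtype=np.int64)
    n11 = s_d.astype(np.int64)
    n22 = (S - s_d).astype(np.int64)
    n12 = np.zeros(R, dtype=np.int64)
    if config.pairing == "assortative" and S > 0:
        # pair same-clone maters like-for-like; odd leftovers mate randomly
        n11 = s_d // 2
        n22 = (S - s_d) // 2
        leftover_d = s_d % 2
        leftover_o = (S - s_d) % 2
    else:
        leftover_d = np.zeros(R, dtype=np.int64)
        leftover_o = np.zeros(R, dtype=np.int64)

    # (3) random maters in Hardy-Weinberg proportions, largest-remainder rounded
    # one zygote per random-mating individual (partner from the gamete pool)
    m = (N - S) + leftover_d + leftover_o
    rd = d1 - s_d + leftover_d
    n_diploids = m
    has_random = m > 0
    if np.any(has_random):
        q = np.where(has_random, rd / np.maximum(m, 1), 0.0)
        expected = np.stack(
            [n_diploids * q * q, 2.0 * n_diploids * q * (1.0 - q), n_diploids * (1.0 - q) ** 2],
            axis=1,
        )
        hw = _largest_remainder(expected, n_diploids, rng)
        n11 = n11 + hw[:, 0]
        n12 = n12 + hw[:, 1]
        n22 = n22 + hw[:, 2]

    # (4)+(5) gametic products per class, decimated by class fitness
    if config.deterministic_thinning:
        surv11 = np.rint(4 * n11 * config.hom_driver_fitness).astype(np.int64)
        surv22 = np.rint(4 * n22 * config.hom_nondriver_fitness).astype(np.int64)
        if config.drive_mode == "complete-drive":
            het_driver = np.rint(4 * n12 * config.het_fitness).astype(np.int64)
            het_other = np.zeros(R, dtype=np.int64)
        else:  # neutral: the four products split 2+2
            het_driver = np.rint(2 * n12 * config.het_fitness).astype(np.int64)
            het_other = het_driver.copy()
    else:
        surv11 = rng.binomial(4 * n11, config.hom_driver_fitness)
        surv22 = rng.binomial(4 * n22, config.hom_nondriver_fitness)
        if config.drive_mode == "complete-drive":
            het_driver = rng.binomial(4 * n12, config.het_fitness)
            het_other = np.zeros(R, dtype=np.int64)
        else:
            het_driver = rng.binomial(2 * n12, config.het_fitness)
            het_other = rng.binomial(2 * n12, config.het_fitness)

    driver_pool = surv11 + het_driver
    other_pool = surv22 + het_other
    total = driver_pool + other_pool

    # (6) draw the next N haploids from the pooled progeny
    new = np.empty(R, dtype=np.int64)
    dead = total == 0
    ok = ~dead
    if np.any(ok):
        new[ok] = rng.binomial(N, driver_pool[ok] / total[ok])
    new[dead] = -1  # extinction sentinel
    out[active] = new
    return out


def wf_step(driver_count: int, config: WFConfig, rng: np.random.Generator) -> int:
    """One Wright-Fisher generation for a single population.

    Returns the new driver count; raises if the whole progeny pool was
    decimated (population extinction).
    """
    if not 0 <= driver_count <= config.N:
        raise ValueError("driver_count must be in [0, N]")
    new = int(_step_ensemble(np.array([driver_count]), config, rng)[0])
    if new < 0:
        raise RuntimeError("population extinction: all gametic products were decimated")
    return new


def wf_run(config: WFConfig, rng: np.random.Generator | None = None) -> WFOutcome:
    """Run one replicate until fixation, loss, or the generation cap."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    d = np.array([config.initial_driver_count], dtype=np.int64)
    traj = [int(d[0])] if config.record_trajectory else None
    g = 0
    extinct = False
    for g in range(1, config.generations + 1):
        if d[0] == 0 or d[0] == config.N:
            g -= 1
            break
        d = _step_ensemble(d, config, rng)
        if d[0] < 0:
            extinct = True
            d[0] = 0
            if traj is not None:
                traj.append(0)
            break
        if traj is not None and (g % config.trajectory_thin == 0):
            traj.append(int(d[0]))
    final = int(d[0])
    fate = "fixed" if final == config.N else ("lost" if final == 0 else "segregating")
    return WFOutcome(
        fate=fate,
        generations_elapsed=g,
        final_count=final,
        extinct=extinct,
        trajectory=np.asarray(traj) if traj is not None else None,
    )


def wf_ensemble(config: WFConfig) -> list[WFOutcome]:
    """Run ``config.iterations`` independent replicates (vectorised).

    Each replicate draws from its own spawned RNG stream conceptually; for
    speed all replicates advance together from a single stream seeded by
    ``config.seed``, which preserves the reproducibility contract (same seed,
    same outcomes).
    """
    R = config.iterations
    if R < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    d = np.full(R, config.initial_driver_count, dtype=np.int64)
    absorbed_at = np.zeros(R, dtype=np.int64)
    extinct = np.zeros(R, dtype=bool)
    for g in range(1, config.generations + 1):
        active = (d > 0) & (d < config.N) & ~extinct
        if not active.any():
            break
        d = _step_ensemble(d, config, rng)
        died = d == -1
        if died.any():
            extinct |= died
            d[died] = 0
        newly_absorbed = active & ((d == 0) | (d == config.N))
        absorbed_at[newly_absorbed] = g
    outcomes = []
    for i in range(R):
        final = int(d[i])
        fate = "fixed" if final == config.N else ("lost" if final == 0 else "segregating")
        gen = int(absorbed_at[i]) if fate != "segregating" else config.generations
        outcomes.append(WFOutcome(fate=fate, generations_elapsed=gen, final_count=final, extinct=bool(extinct[i])))
    return outcomes


def maintenance_probability(config: WFConfig) -> EnsembleSummary:
    """Fraction of replicates in which the driver is not lost by the cap.

    "Maintained" counts fixed plus still-segregating replicates; the fixed
    fraction is reported alongside.  The standard error is binomial.
    """
    outcomes = wf_ensemble(config)
    R = len(outcomes)
    fixed = sum(o.fate == "fixed" for o in outcomes) / R
    lost = sum(o.fate == "lost" for o in outcomes) / R
    seg = sum(o.fate == "segregating" for o in outcomes) / R
    maintained = 1.0 - lost
    se = sqrt(maintained * (1.0 - maintained) / R)
    return EnsembleSummary(
        N=config.N,
        F=config.F,
        iterations=R,
        maintained=maintained,
        maintained_se=se,
        fixed=fixed,
        lost=lost,
        segregating=seg,
        extinct=sum(o.extinct for o in outcomes),
    )
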