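"""Synthetic observables with the statistical structure the estimators assume.

These generators stand in for the wet-lab inputs of the analysis: multinomial
zygote genotype counts at a true (p, F), progeny marker-genotype tables under
2-3 unlinked loci, multi-generation fluorophore-frequency trajectories under
drive/inbreeding/linked costs with binomial measurement noise and optional
per-generation marker loss, and cell censuses for mating-efficiency
calibration.  Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging

import numpy as np

from .core_model import DriveParams, fitness_from_costs, genotype_frequencies, next_frequency
from .cost_fit import ObservedTrajectory
from .estimators import CellCensus, ProgenyTable, ZygoteCounts

__all__ = [
    "gen_zygote_counts",
    "gen_progeny_table",
    "gen_evolution_trajectories",
    "gen_census",
]

logger = logging.getLogger(__name__)


def gen_zygote_counts(p: float, F: float, n_zygotes: int, seed: int = 0) -> ZygoteCounts:
    """Multinomial zygote genotype counts at true allele frequency p and inbreeding F."""
    if n_zygotes < 0:
        raise ValueError("n_zygotes must be >= 0")
    f = genotype_frequencies(p, F, strict=True)
    rng = np.random.default_rng(seed)
    n11, n12, n22 = rng.multinomial(n_zygotes, f.as_array())
    return ZygoteCounts(int(n11), int(n12), int(n22), p_initial=p)


def gen_progeny_table(
    p: float, F: float, n_markers: int, n_progeny: int, seed: int = 0
) -> ProgenyTable:
    """Progeny marker genotypes from matings at true (p, F).

    Each progeny's parental mating is drawn from the genotype frequencies;
    homozygous matings emit the parental multi-locus genotype, heterozygous
    (outcrossed) matings emit one of the 2^n unlinked-marker combinations
    uniformly.
    """
    if n_markers not in (2, 3):
        raise ValueError("n_markers must be 2 or 3")
    if n_progeny < 0:
        raise ValueError("n_progeny must be >= 0")
    f = genotype_frequencies(p, F, strict=True)
    rng = np.random.default_rng(seed)
    mating = rng.choice(3, size=n_progeny, p=f.as_array())  # 0=hom1, 1=het, 2=hom2
    genotypes = np.empty((n_progeny, n_markers), dtype=np.int8)
    genotypes[mating == 0] = 1
    genotypes[mating == 2] = 2
    n_het = int((mating == 1).sum())
    genotypes[mating == 1] = rng.integers(1, 3, size=(n_het, n_markers))
    return ProgenyTable(genotypes)


def gen_evolution_trajectories(
    p0: float,
    c: float,
    h: float,
    k: float,
    F: float,
    driver_linked_to_costly_marker: bool = True,
    G: int = 6,
    replicates: int = 3,
    effective_n: int = 10_000,
    marker_loss_rates: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
) -> list[ObservedTrajectory]:
    """Simulated experimental-evolution trajectories of the focal marker.

    The underlying allele frequency follows the deterministic recursion with
    fitnesses from the linked cost (and drive when k > 0.5).  Marker loss is
    an optional per-generation per-lineage excision probability for each
    fluorophore (focal marker first); the observed frequency is renormalised
    among still-fluorescent cells.  Binomial measurement noise with
    ``effective_n`` trials is added per observation.  If more than 95% of
    cells have lost fluorescence the trajectory is truncated with a warning.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if effective_n < 1:
        raise ValueError("effective_n must be >= 1")
    loss1, loss2 = marker_loss_rates
    for name, r in (("marker 1", loss1), ("marker 2", loss2)):
        if not 0.0 <= r < 1.0:
            raise ValueError(f"loss rate for {name} must be in [0, 1)")
    w11, w12, w22 = fitness_from_costs(c, h, k, driver_linked_to_costly_marker)
    params = DriveParams(k=k, w11=w11, w12=w12, w22=w22, F=F)
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(replicates):
        p = float(p0)
        retain1 = retain2 = 1.0
        gens, freqs = [], []
        for g in range(G + 1):
            if g > 0:
                p = next_frequency(p, params)
                retain1 *= 1.0 - loss1
                retain2 *= 1.0 - loss2
            fluorescent = p * retain1 + (1.0 - p) * retain2
            if fluorescent < 0.05:
                logger.warning(
                    "replicate %d: >95%% of cells non-fluorescent at generation %d; truncating",
                    rep, g,
                )
                break
            visible = p * retain1 / fluorescent
            obs = rng.binomial(effective_n, visible) / effective_n
            gens.append(g)
            freqs.append(obs)
        out.append(
            ObservedTrajectory(
                replicate=f"rep{rep + 1}",
                generations=np.array(gens),
                observed_freq=np.array(freqs),
                effective_n=np.full(len(gens), effective_n, dtype=float),
            )
        )
    return out


def gen_census(
    me_true: float,
    n_cells: int,
    ascus_mix: tuple[float, float, float] = (0.3, 0.5, 0.2),
    seed: int = 0,
) -> CellCensus:
    """A cell census whose default-weight mating efficiency recovers me_true.

    ``ascus_mix`` splits the mated weight among zygotes, asci and free
    spores.  The construction works on the weight scale of the efficiency
    formula (zygotes and asci count 2, spores 1/2, vegetative cells 2): the
    mated weight is a binomial draw of n_cells trials at me_true, vegetative
    cells are half the unmated weight, zygote/ascus counts are half their
    weight share and the spore count is twice its share, so the printed
    estimator is unbiased for me_true by design.
    """
    if not 0.0 <= me_true <= 1.0:
        raise ValueError("me_true must be in [0, 1]")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    fz, fa, fs = ascus_mix
    if not np.isclose(fz + fa + fs, 1.0):
        raise ValueError("ascus_mix fractions must sum to 1")
    rng = np.random.default_rng(seed)
    mated_weight = rng.binomial(n_cells, me_true)
    V = int(round((n_cells - mated_weight) / 2.0))
    nz, na, ns = rng.multinomial(mated_weight, [fz, fa, fs])
    Z = int(round(nz / 2.0))
    A = int(round(na / 2.0))
    S = int(round(2.0 * ns))
    if V + Z + A + S == 0:
        V = 1  # degenerate tiny draw; keep the census valid
    return CellCensus(V=V, Z=Z, A=A, S=S)
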