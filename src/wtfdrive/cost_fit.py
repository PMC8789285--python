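"""Maximum-likelihood estimation of a linked fitness cost from
experimental-evolution allele-frequency trajectories.

In control crosses without drive (k = 0.5), a fluorophore marker linked to a
deleterious variant declines across sexual generations.  The forward model
is the deterministic recursion with fitnesses w_hom_costly = 1 - c,
w_het = 1 - c*h, w_hom_other = 1 (dominance h of the homozygous cost c).
Observed frequencies are treated as binomial draws with a per-observation
effective count (cytometry event scale), and (c, h) are fitted by bounded
L-BFGS-B over [0, 1]^2 from a seeded Latin-hypercube of starting points,
using only the first `window` generations (default 6, before extensive
marker loss corrupts the later observations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.stats import qmc

from .core_model import DriveParams, Trajectory, fitness_from_costs, iterate

__all__ = ["ObservedTrajectory", "CostFitResult", "predict_trajectory",
           "negative_log_likelihood", "fit_costs"]

_FREQ_FLOOR = 1e-9


@dataclass(frozen=True)
class ObservedTrajectory:
    """One replicate's focal-marker frequencies among fluorescent cells.

    Generation 0 is the measured starting frequency; effective_n gives the
    per-observation count scale of the sampling likelihood.
    """

    replicate: str
    generations: np.ndarray
    observed_freq: np.ndarray
    effective_n: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.generations, dtype=int)
        f = np.asarray(self.observed_freq, dtype=float)
        n = np.asarray(self.effective_n, dtype=float)
        if not (g.shape == f.shape == n.shape) or g.ndim != 1 or g.size == 0:
            raise ValueError("generations, observed_freq, effective_n must be equal-length 1-D")
        if g[0] != 0:
            raise ValueError("trajectory must start at generation 0 (initial frequency)")
        if np.any(np.diff(g) <= 0):
            raise ValueError("generations must be strictly increasing")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("frequencies must be in [0, 1]")
        if np.any(n <= 0):
            raise ValueError("effective_n must be positive")
        object.__setattr__(self, "generations", g)
        object.__setattr__(self, "observed_freq", f)
        object.__setattr__(self, "effective_n", n)

    @property
    def p0(self) -> float:
        return float(self.observed_freq[0])


@dataclass(frozen=True)
class CostFitResult:
    """Fitted homozygous cost and dominance with optimisation diagnostics."""

    c_hat: float
    h_hat: float
    loglik: float
    converged: bool
    n_generations_used: int
    n_starts: int = 0
    message: str = ""
    starts: np.ndarray | None = field(default=None, compare=False)


def predict_trajectory(
    p0: float, c: float, h: float, F: float, k: float = 0.5, G: int = 6
) -> Trajectory:
    """Deterministic predicted frequencies of the costly-marker allele.

    The focal allele carries the cost (and the driver, when k > 0.5); with
    k = 0.5 this is the no-drive control model used for cost fitting.
    """
    w11, w12, w22 = fitness_from_costs(c, h, k, driver_linked_to_costly_marker=True)
    params = DriveParams(k=k, w11=w11, w12=w12, w22=w22, F=F)
    return iterate(p0, params, G)


def negative_log_likelihood(
    c: float,
    h: float,
    data: list[ObservedTrajectory],
    F: float,
    k: float = 0.5,
    window: int = 6,
    obs_model: str = "binomial",
) -> float:
    """Summed NLL of the observations under the deterministic forward model.

    Each replicate is forward-predicted from its own generation-0 frequency;
    generations 1..window contribute.  Binomial model (default): the
    observation at generation g is round(freq * effective_n) successes in
    effective_n trials at the predicted frequency (floored away from 0/1).
    Gaussian alternative: residuals with variance p(1-p)/effective_n.
    """
    if not data:
        raise ValueError("no trajectories supplied")
    if window < 1:
        raise ValueError("window must be >= 1")
    if obs_model not in ("binomial", "gaussian"):
        raise ValueError(f"unknown obs_model {obs_model!r}")
    nll = 0.0
    n_used = 0
    for traj in data:
        pred = predict_trajectory(traj.p0, c, h, F, k, G=int(traj.generations.max()))
        use = (traj.generations >= 1) & (traj.generations <= window)
        if not use.any():
            continue
        p_hat = np.clip(pred.frequencies[traj.generations[use]], _FREQ_FLOOR, 1 - _FREQ_FLOOR)
        n = traj.effective_n[use]
        obs = traj.observed_freq[use]
        if obs_model == "binomial":
            successes = np.rint(obs * n)
            nll -= stats.binom.logpmf(successes, np.rint(n), p_hat).sum()
        else:
            var = np.maximum(p_hat * (1 - p_hat), _FREQ_FLOOR) / n
            nll -= stats.norm.logpdf(obs, loc=p_hat, scale=np.sqrt(var)).sum()
        n_used += int(use.sum())
    if n_used == 0:
        raise ValueError(f"no observations fall in generations 1..{window}")
    return float(nll)


def fit_costs(
    data: list[ObservedTrajectory],
    F: float,
    k: float = 0.5,
    window: int = 6,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 1.0), (0.0, 1.0)),
    starts: int = 8,
    seed: int = 0,
    obs_model: str = "binomial",
) -> CostFitResult:
    """ML fit of (c, h) by multi-start bounded L-BFGS-B.

    Starting points come from a seeded Latin hypercube over the bounds; the
    best converged optimum wins, ties broken toward smaller c.  If no start
    converges the result carries converged=False and diagnostics instead of
    raising.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if starts < 1:
        raise ValueError("need at least one start")

    def objective(x: np.ndarray) -> float:
        try:
            return negative_log_likelihood(x[0], x[1], data, F, k, window, obs_model)
        except ValueError:
            return np.inf

    sampler = qmc.LatinHypercube(d=2, seed=seed)
    lo = np.array([bounds[0][0], bounds[1][0]])
    hi = np.array([bounds[0][1], bounds[1][1]])
    x0s = qmc.scale(sampler.random(starts), lo, hi)

    best = None
    messages = []
    for x0 in x0s:
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        messages.append(str(res.message))
        if not res.success or not np.isfinite(res.fun):
            continue
        if (
            best is None
            or res.fun < best.fun - 1e-9
            or (abs(res.fun - best.fun) <= 1e-9 and res.x[0] < best.x[0])
        ):
            best = res
    if best is None:
        return CostFitResult(
            c_hat=np.nan, h_hat=np.nan, loglik=-np.inf, converged=False,
            n_generations_used=window, n_starts=starts,
            message="; ".join(sorted(set(messages))), starts=x0s,
        )
    return CostFitResult(
        c_hat=float(best.x[0]), h_hat=float(best.x[1]), loglik=float(-best.fun),
        converged=True, n_generations_used=window, n_starts=starts,
        message=str(best.message), starts=x0s,
    )
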