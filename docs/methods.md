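# Methods

## Deterministic drive model

The core model is a one-locus, two-allele selection recursion for a
haploid-dominant life cycle with one mating round per sexual generation.
Inbreeding enters as Wright's *F*, scaling the heterozygote deficit
relative to Hardy–Weinberg: f11 = p² + Fp(1−p), f12 = 2p(1−p)(1−F),
f22 = (1−p)² + Fp(1−p). Selection acts on diploids (w11, w12, w22 ∈ [0,1]);
drive acts at meiosis, biasing transmission from heterozygotes so that a
surviving spore carries the driver with probability k ∈ [0.5, 1]:

    p′ = (f11·w11 + k·f12·w12) / (f11·w11 + f12·w12 + f22·w22).

Assumptions: infinite population (no drift), equal haploid fitness of all
genotypes, no mutation, no multi-locus interactions, one driver per
population. 0 and 1 are absorbing; with k = 0.5 and equal fitnesses the
recursion is the identity for every feasible F.

Key parameter defaults and their provenance:

| parameter | default | meaning |
|---|---|---|
| k | 0.98 | measured transmission bias of the *Sk wtf4* driver |
| w12 (drive only) | 1/(2k) ≈ 0.51 | heterozygote keeps half its spores, corrected for the 2% that escape |
| c | 0.234 | fitted homozygous cost of the GFP-linked variant |
| h | 0.083 | fitted dominance of that cost (heterozygous cost c·h ≈ 1.9%) |

`fitness_from_costs` composes these: the costly-marker homozygote gets
1−c, the heterozygote gets (1−ch)·1/(2k), the other homozygote 1. With
(c, h, k) = (0.234, 0.083, 0.98) this reproduces the assigned genotype
fitnesses 0.766, ≈0.98 (no drive) and ≈0.5 (drive plus cost). Rounding is
presentation-only; all computation keeps full precision.

### Negative F

F < 0 (heterozygote excess) makes a raw homozygote frequency negative
whenever F < −min(p, 1−p)/max(p, 1−p). The convention for plotting full
F = −1 curves across all p is not determined by the algebra, so the
package makes a documented choice: clamp negative genotype frequencies to
zero, renormalise to sum 1, and emit `InfeasibleFrequencyWarning`; a
`strict` flag raises instead. Frequency sums and fixed points are checked
to 1e−12 absolute.

## Invasion analysis

A driver linked to a deleterious allele spreads from frequency p iff the
one-generation change Δp is strictly positive. Under complete drive
(k = 1) with w11 = 1−c, w12 = ½(1−ch), w22 = 1 this is equivalent to
F < F_crit(p, c, h) = [ch(p−1) − cp + p]/[c(h−1)(p−1) + p]; for c = 0 the
threshold is exactly 1. `min_invasion_frequency` inverts this numerically
for any k ∈ (0.5, 1]: a coarse 512-point sign scan of Δp followed by
bisection to tol = 1e−6 (cap 200 iterations). It returns 0 when every
positive frequency invades and None when none does (e.g. F ≥ 1−c, or a
lethal haplotype). Invasion here is a single-generation criterion, not
long-run fixation; the two coincide for this monotone system except at
the threshold itself.

## Wright–Fisher simulation

Finite haploid population of constant size N, non-overlapping
generations. Per generation: (1) N individuals are drawn with replacement
from the current pool (clonal expansion before mating supplies effectively
infinite gametes); (2) S = round(F·N) of them mate with a clonal copy of
themselves, each yielding a homozygote of its own allele; (3) the rest
form one zygote each with genotype counts at Hardy–Weinberg proportions
of their allele frequency, rounded by largest-remainder apportionment;
(4) every zygote makes four gametic products — under complete drive all
surviving products of a heterozygote carry the driver, in neutral mode
they split 2+2; (5) each mating class's products are thinned binomially
by its fitness (deterministic rounding behind a flag); with the default
heterozygote fitness 0.5 a complete-drive heterozygote therefore yields
two driver progeny in expectation, the classic 4/2 progeny rule realised
stochastically; (6) the next N haploids are drawn from the pooled
products. Counts 0 and N are absorbing; an emptied pool is recorded as a
population-extinction event.

Two numerical details matter:

- **Rounding tie-break.** The two homozygote Hardy–Weinberg expectations
  m·q² and m·(1−q)² always share a fractional part (their difference is an
  integer), so any deterministic tie-break systematically favours one
  allele — enough to shift the neutral fixation probability from 1/N.
  Ties are broken by a seeded 1e−9 jitter on the remainders.
- **Analytic check.** With complete drive the expected one-generation map
  is p′ = p/(1 − p(1−p)(1−F)), identical to the deterministic recursion at
  k = 1, w12 = 0.5; the simulator's mean change is tested against it at
  N = 100,000.

Replicate ensembles are stepped as arrays from a single `SeedSequence`-
seeded generator, so a 1000-replicate × 1000-generation run takes well
under a second and identical seeds give bit-identical outcomes.
"Maintenance" is reported as the fraction of replicates not lost at the
generation cap, with the fixed-only tally alongside (the two can differ
when the horizon truncates segregating runs). Verifying that maintenance
decreases with F at N = 1000 requires more replicates than the
1000-iteration reporting protocol: the true gaps are ≈ 0.008 while the
Monte-Carlo SE at 1000 iterations is ≈ 0.005, so the monotonicity check
uses 10,000 iterations.

An alternative same-clone pairing (`pairing="assortative"`: sampled
same-clone maters pair like-for-like among themselves, odd leftovers
joining the random pool) is available; the clonal-copy default reflects
the biology of sibling mating after mitosis.

## Estimators

- **Zygote assay**: F = 1 − (observed heterozygote frequency)/(2p(1−p)),
  with p the pre-mating frequency of parent 1 taken from the census, not
  re-estimated from the zygote table. Zygotes and asci each count as one
  diploid observation.
- **Genetic assay**: an outcrossed heterozygote's progeny fall into 2ⁿ
  equally frequent multi-locus genotypes of which 2 look parental, so the
  observed recombinant fraction underestimates outcrossing by the factor
  (2ⁿ−2)/2ⁿ — 6/8 for three unlinked markers, 2/4 for two. Corrections
  above 1 (sampling overshoot) are capped at 1 with a warning.
- **Mating efficiency**: 100·(2Z + 2A + S/2)/(2V + 2Z + 2A + S/2). The
  vegetative weight 2 follows the printed formula but is exposed as a
  parameter since a per-cell accounting would use 1.
- **Mixed crosses**: additive model in which each strain contributes its
  isogenic-cross inbreeding coefficient and mating efficiency and does not
  adjust to its partner; the second homozygote class is the remainder, so
  the three frequencies sum to 1 exactly.
- **Uncertainty**: percentile bootstrap by multinomial resampling of the
  count table; degenerate resamples are skipped and counted.

## Linked-cost likelihood

Control experimental evolution without drive (k = 0.5) identifies the
cost of a marker from its decline across sexual generations. The forward
model is the deterministic recursion started from each replicate's
measured generation-0 frequency; the observation model is binomial —
round(freq·n) successes in n trials at the predicted frequency (floored
at 1e−9), with n the per-observation effective count (default 10,000,
the scale of cytometry event counts). A Gaussian-residual alternative
with variance p(1−p)/n sits behind a flag. Only generations 1..window
enter the likelihood; the window defaults to 6 because later generations
are corrupted by progressive fluorescent-marker loss. (c, h) are fitted
by L-BFGS-B inside [0,1]² from a seeded Latin-hypercube multi-start
(default 8), best optimum winning, ties broken toward smaller c.

**Identifiability of dominance.** Without drive a heterozygote transmits
both alleles equally, so the recursion's sensitivity to w12 is
f12·(0.5 − p′)/W̄ — it vanishes at p ≈ 0.5. Replicates started only at
50:50 therefore carry almost no information about h (its sampling sd
exceeds 0.15 at effective_n = 10⁴), while c remains well identified. The
package's parameter-recovery experiments place replicates at starting
frequencies 0.2/0.5/0.8; the contrast in genotype composition brings the
sd of ĥ to ≈ 0.05 with no detectable bias. Recovery is summarised as the
median over seeded repetitions of the experiment. Even so, h is the
weakly determined parameter: tolerances of ±0.03 on c and ±0.08 on h
reflect the estimator's intrinsic sampling error at these sample sizes,
not optimisation error.

## Synthetic data

The generators emulate the statistical structure of the assays, not their
physics: multinomial zygote counts from the genotype frequencies;
progeny tables drawn mating-first (homozygous matings emit parental
genotypes, heterozygous matings emit one of the 2ⁿ unlinked-marker
combinations uniformly — free recombination, no interference or linkage
maps); evolution trajectories as the deterministic recursion plus
binomial measurement noise at the frequency level (individual cytometry
events, gating error, and day effects are not simulated); censuses
constructed on the weight scale of the mating-efficiency formula so the
printed-default estimator is unbiased for the generating efficiency.
Marker loss is an optional per-generation per-lineage excision
probability, independent of genotype, defaulting to 0 (no quantitative
loss rate is established; any non-zero value is illustrative). Observed
frequencies are renormalised among still-fluorescent cells and a
trajectory is truncated with a warning once more than 95% of cells are
non-fluorescent. Because generator and fit share the same forward model,
passing recovery tests demonstrate estimator correctness and calibration
under the stated noise model — not robustness to model misspecification
in real populations.

## Problem sizes and determinism

Default test and acceptance runs use: 99-point frequency grids; a
50×10×10 (p, c, h) invasion grid; 20,000 neutral Wright–Fisher replicates
at N = 20; 1000 replicates × 1000 generations for maintenance
probabilities (10,000 for the F-monotonicity check); 100,000 synthetic
zygotes/progeny for estimator calibration; and 5 repetitions × 3
replicates × 6 generations for cost recovery. Every stochastic component
draws from `numpy.random.Generator` streams derived from one master seed
via `SeedSequence`, so all results are bit-reproducible under a fixed
seed.

## Known limitations

- Single locus: no driver–suppressor systems, no multiple drivers, no
  linkage to the mating-type locus.
- No mutation, migration, spatial structure, or overlapping generations;
  one mating round per generation.
- The clonal-copy interpretation of same-clone mating and the binomial
  decimation of gametic products are documented modelling choices where
  the verbal description of the process is ambiguous; alternatives sit
  behind flags (`pairing`, `deterministic_thinning`).
- The likelihood for (c, h) treats technical replicates as independent
  binomial observations; real cytometry replicates share culture effects
  that would inflate the true uncertainty.
- Confidence intervals for (c, h) by profile likelihood are not
  implemented; bootstrap over replicates can be built from the
  `bootstrap_ci` pattern.
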