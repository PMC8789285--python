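"""Deterministic drive-with-inbreeding model: examples, invariants, oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wtfdrive.core_model import (
    FREQ_TOL,
    DriveParams,
    InfeasibleFrequencyWarning,
    Trajectory,
    delta_p,
    fitness_from_costs,
    genotype_frequencies,
    heterozygote_drive_fitness,
    iterate,
    mean_fitness,
    next_frequency,
)

DRIVE = DriveParams(k=0.98, w11=1.0, w12=0.51, w22=1.0, F=0.0)


def spore_pool_oracle(p, params):
    """Brute-force next-generation frequency by explicit spore accounting.

    Each mating class produces four spores scaled by its fitness; of a
    heterozygote's surviving spores, the fraction k carries the driver.
    """
    q = 1 - p
    f11 = p * p + params.F * p * q
    f12 = 2 * p * q * (1 - params.F)
    f22 = q * q + params.F * p * q
    driver_spores = 4 * f11 * params.w11 + 4 * f12 * params.w12 * params.k
    other_spores = 4 * f22 * params.w22 + 4 * f12 * params.w12 * (1 - params.k)
    return driver_spores / (driver_spores + other_spores)


feasible = st.tuples(
    st.floats(0.01, 0.99), st.floats(0.0, 1.0)
)  # (p, F >= 0) always feasible


class TestGenotypeFrequencies:
    @pytest.mark.parametrize(
        "p,F,expected",
        [
            (0.5, 0.0, (0.25, 0.5, 0.25)),
            (0.5, 1.0, (0.5, 0.0, 0.5)),
            (0.3, 0.5, (0.195, 0.21, 0.595)),
        ],
    )
    def test_examples(self, p, F, expected):
        f = genotype_frequencies(p, F)
        assert tuple(f) == pytest.approx(expected, abs=FREQ_TOL)

    @given(feasible)
    @settings(derandomize=True, max_examples=200)
    def test_sum_to_one_nonnegative(self, pF):
        p, F = pF
        f = genotype_frequencies(p, F)
        assert f.f11 >= 0 and f.f12 >= 0 and f.f22 >= 0
        assert f.f11 + f.f12 + f.f22 == pytest.approx(1.0, abs=FREQ_TOL)

    def test_negative_F_clamps_with_warning(self):
        # p=0.1, F=-0.5: f11 = 0.01 - 0.045 < 0
        with pytest.warns(InfeasibleFrequencyWarning):
            f = genotype_frequencies(0.1, -0.5)
        assert f.f11 == 0.0
        assert f.f11 + f.f12 + f.f22 == pytest.approx(1.0, abs=FREQ_TOL)

    def test_strict_mode_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            genotype_frequencies(0.1, -0.5, strict=True)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            genotype_frequencies(1.2, 0.0)
        with pytest.raises(ValueError):
            genotype_frequencies(0.5, -1.5)


class TestMeanFitness:
    def test_printed_example(self):
        assert mean_fitness(0.5, DRIVE) == pytest.approx(0.755)

    def test_neutral_normalisation(self):
        assert mean_fitness(0.37, DriveParams(k=0.5, F=0.3)) == pytest.approx(1.0)

    def test_full_inbreeding_no_hets(self):
        assert mean_fitness(0.5, DRIVE.with_F(1.0)) == pytest.approx(1.0)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(derandomize=True, max_examples=100)
    def test_equals_weighted_sum(self, p, F):
        params = DriveParams(k=0.9, w11=0.8, w12=0.4, w22=1.0, F=F)
        f = genotype_frequencies(p, F)
        expected = f.f11 * 0.8 + f.f12 * 0.4 + f.f22 * 1.0
        assert mean_fitness(p, params) == pytest.approx(expected, abs=FREQ_TOL)

    def test_degenerate_fitness_raises(self):
        with pytest.raises(ValueError):
            DriveParams(k=0.98, w11=0.0, w12=0.0, w22=0.0)


class TestNextFrequency:
    def test_hand_evaluated_recursion(self):
        assert next_frequency(0.5, DRIVE) == pytest.approx(
            (0.25 + 0.5 * 0.98 * 0.51) / 0.755
        )

    @pytest.mark.parametrize("p", [0.05, 0.3, 0.9])
    def test_full_inbreeding_is_identity(self, p):
        assert next_frequency(p, DRIVE.with_F(1.0)) == pytest.approx(p, abs=FREQ_TOL)

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.77])
    @pytest.mark.parametrize("F", [0.0, 0.5, 1.0])
    def test_neutral_is_identity(self, p, F):
        assert next_frequency(p, DriveParams(k=0.5, F=F)) == pytest.approx(p, abs=FREQ_TOL)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_boundaries_fixed(self, p):
        assert next_frequency(p, DRIVE) == p
        assert delta_p(p, DRIVE) == 0.0

    @given(st.floats(0.001, 0.999), st.floats(0.0, 1.0), st.floats(0.5, 1.0))
    @settings(derandomize=True, max_examples=200)
    def test_matches_spore_pool_oracle(self, p, F, k):
        params = DriveParams(k=k, w11=1.0, w12=1 / (2 * k), w22=1.0, F=F)
        assert next_frequency(p, params) == pytest.approx(
            spore_pool_oracle(p, params), abs=1e-12
        )

    @given(st.floats(0.0, 1.0))
    @settings(derandomize=True, max_examples=100)
    def test_maps_unit_interval_to_itself(self, p):
        assert 0.0 <= next_frequency(p, DRIVE) <= 1.0


class TestDeltaP:
    def test_single_meiosis_gain(self):
        expected = (0.25 + 0.5 * 0.98 * 0.51) / 0.755 - 0.5
        assert delta_p(0.5, DRIVE) == pytest.approx(expected, abs=1e-12)

    def test_no_gain_at_full_inbreeding(self):
        assert delta_p(0.5, DRIVE.with_F(1.0)) == pytest.approx(0.0, abs=FREQ_TOL)

    def test_positive_at_all_frequencies_without_costs(self):
        # drive with w12 = 1/(2k) and F < 1 spreads from any p in (0, 1)
        for F in (0.0, 0.5, 0.95):
            params = DRIVE.with_F(F)
            for p in np.linspace(0.01, 0.99, 99):
                assert delta_p(p, params) > 0


class TestIterate:
    def test_zero_generations(self):
        traj = iterate(0.05, DRIVE, 0)
        assert len(traj) == 1 and traj.frequencies[0] == 0.05

    def test_full_inbreeding_constant_30_generations(self):
        traj = iterate(0.05, DRIVE.with_F(1.0), 30)
        np.testing.assert_allclose(traj.frequencies, 0.05, atol=FREQ_TOL)

    def test_random_mating_monotone_spread_to_fixation(self):
        traj = iterate(0.05, DRIVE, 30)
        assert np.all(np.diff(traj.frequencies) > 0)
        assert traj.frequencies[-1] > 0.99

    def test_trajectory_roundtrip(self, tmp_path):
        traj = iterate(0.05, DRIVE, 10)
        path = tmp_path / "traj.tsv"
        traj.to_tsv(path)
        back = Trajectory.from_tsv(path)
        np.testing.assert_array_equal(back.generations, traj.generations)
        np.testing.assert_allclose(back.frequencies, traj.frequencies)


class TestFitnessConstructions:
    @pytest.mark.parametrize("k,expected", [(0.98, 0.51), (0.5, 1.0), (1.0, 0.5)])
    def test_heterozygote_drive_fitness(self, k, expected):
        assert round(heterozygote_drive_fitness(k), 2) == expected

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            heterozygote_drive_fitness(0.3)

    def test_fitted_marker_costs(self):
        w11, w12, w22 = fitness_from_costs(0.234, 0.083, k=0.5)
        assert w11 == pytest.approx(0.766)
        assert round(w12, 2) == 0.98
        assert w22 == 1.0

    def test_cost_on_other_allele(self):
        w11, w12, w22 = fitness_from_costs(0.234, 0.083, k=0.5,
                                           driver_linked_to_costly_marker=False)
        assert (w11, w22) == (1.0, 0.766)

    def test_zero_cost_only_drive_acts(self):
        w11, w12, w22 = fitness_from_costs(0.0, 0.7, k=0.98)
        assert w11 == 1.0 and w22 == 1.0
        assert w12 == pytest.approx(heterozygote_drive_fitness(0.98))
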