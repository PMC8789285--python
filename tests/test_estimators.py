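"""Count-data estimators: inbreeding coefficients, mating efficiency,
mixed-cross expectations, bootstrap intervals."""

import numpy as np
import pytest

from wtfdrive.core_model import genotype_frequencies
from wtfdrive.estimators import (
    CellCensus,
    MixedCrossParams,
    ProgenyTable,
    ZygoteCounts,
    bootstrap_ci,
    expected_mixed_cross,
    inbreeding_from_genetic,
    inbreeding_from_zygotes,
    mating_efficiency,
    outcross_fraction_from_recombinants,
)


class TestInbreedingFromZygotes:
    def test_hardy_weinberg_gives_zero(self):
        counts = ZygoteCounts(25, 50, 25, p_initial=0.5)
        assert inbreeding_from_zygotes(counts) == pytest.approx(0.0)

    def test_no_heterozygotes_gives_one(self):
        assert inbreeding_from_zygotes(ZygoteCounts(30, 0, 70, 0.3)) == 1.0

    def test_half_expected_heterozygotes(self):
        # het freq 0.25 vs expected 0.5 at p = 0.5
        assert inbreeding_from_zygotes(ZygoteCounts(30, 10, 0, 0.5)) == pytest.approx(0.5)

    def test_excess_heterozygosity_negative(self):
        assert inbreeding_from_zygotes(ZygoteCounts(10, 80, 10, 0.5)) < 0

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            inbreeding_from_zygotes(ZygoteCounts(0, 0, 0, 0.5))
        with pytest.raises(ValueError):
            inbreeding_from_zygotes(ZygoteCounts(5, 5, 5, 0.0))


class TestMatingEfficiency:
    def test_nothing_mated(self):
        assert mating_efficiency(CellCensus(V=100, Z=0, A=0, S=0)) == 0.0

    def test_everything_mated(self):
        assert mating_efficiency(CellCensus(V=0, Z=5, A=3, S=8)) == 100.0

    def test_printed_weighting(self):
        # (2+2+1)/(4+2+2+1) * 100
        assert mating_efficiency(CellCensus(V=2, Z=1, A=1, S=2)) == pytest.approx(
            100 * 5 / 9
        )

    def test_scale_invariance(self):
        a = mating_efficiency(CellCensus(V=3, Z=2, A=1, S=4))
        b = mating_efficiency(CellCensus(V=30, Z=20, A=10, S=40))
        assert a == pytest.approx(b)

    def test_vegetative_weight_configurable(self):
        census = CellCensus(V=2, Z=1, A=1, S=2)
        assert mating_efficiency(census, vegetative_weight=1.0) == pytest.approx(
            100 * 5 / 7
        )


class TestRecombinantCorrection:
    def test_three_marker_divisor(self):
        assert outcross_fraction_from_recombinants(0.375, 3) == pytest.approx(0.5)

    def test_two_marker_divisor(self):
        assert outcross_fraction_from_recombinants(0.125, 2) == pytest.approx(0.25)

    def test_divisors_by_exhaustive_enumeration(self):
        import itertools

        for n in (2, 3):
            genotypes = list(itertools.product((1, 2), repeat=n))
            parental = sum(1 for g in genotypes if len(set(g)) == 1)
            detectable = (len(genotypes) - parental) / len(genotypes)
            assert outcross_fraction_from_recombinants(detectable, n) == pytest.approx(1.0)

    def test_overshoot_caps_with_warning(self):
        with pytest.warns(UserWarning, match="capping"):
            assert outcross_fraction_from_recombinants(0.9, 2) == 1.0

    def test_single_marker_rejected(self):
        with pytest.raises(ValueError):
            outcross_fraction_from_recombinants(0.1, 1)


class TestInbreedingFromGenetic:
    def test_no_recombinants_full_inbreeding(self):
        assert inbreeding_from_genetic(0.0, 3, 0.5) == 1.0

    def test_three_marker_random_mating(self):
        assert inbreeding_from_genetic(0.375, 3, 0.5) == pytest.approx(0.0)

    def test_two_marker_half_inbreeding(self):
        assert inbreeding_from_genetic(0.125, 2, 0.5) == pytest.approx(0.5)


class TestExpectedMixedCross:
    def test_symmetric_full_mating_reduces_to_genotype_frequencies(self):
        for F in (0.0, 0.5, 1.0):
            mc = expected_mixed_cross(MixedCrossParams(0.5, F, F, 1.0, 1.0))
            ref = genotype_frequencies(0.5, F)
            assert tuple(mc) == pytest.approx(tuple(ref))

    def test_printed_model_evaluation(self):
        mc = expected_mixed_cross(MixedCrossParams(0.5, 0.5, 0.0, 0.4, 0.5))
        assert mc.f11 == pytest.approx(0.15)
        assert mc.f12 == pytest.approx(0.16875)
        assert mc.f22 == pytest.approx(0.68125)

    def test_both_parents_fully_inbreeding_no_hets(self):
        mc = expected_mixed_cross(MixedCrossParams(0.5, 1.0, 1.0, 0.7, 0.3))
        assert mc.f12 == 0.0

    def test_sums_to_one_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p, f1, f2, m1, m2 = rng.uniform(0, 1, 5)
            try:
                mc = expected_mixed_cross(MixedCrossParams(p, f1, f2, m1, m2))
            except ValueError:
                continue
            assert mc.f11 + mc.f12 + mc.f22 == pytest.approx(1.0, abs=1e-15)


class TestBootstrapCI:
    def test_collapsed_interval_at_boundary(self):
        point, lo, hi = bootstrap_ci(
            inbreeding_from_zygotes, ZygoteCounts(100, 0, 0, 0.5), n_boot=200, seed=1
        )
        assert point == lo == hi == 1.0

    def test_covers_truth_on_synthetic_counts(self):
        from wtfdrive.synthetic_data import gen_zygote_counts

        counts = gen_zygote_counts(0.5, 0.5, 10_000, seed=4)
        point, lo, hi = bootstrap_ci(inbreeding_from_zygotes, counts, n_boot=500, seed=5)
        assert lo <= 0.5 <= hi
        assert hi - lo < 0.1

    def test_too_few_resamples_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(inbreeding_from_zygotes, ZygoteCounts(10, 10, 10, 0.5), n_boot=0)
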