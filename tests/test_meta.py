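"""Tests for the ratio-of-means meta-analysis engine."""

import math

import numpy as np
import pytest
from statsmodels.stats.meta_analysis import combine_effects

from ventcontrol import (
    PooledResult,
    StudyEffect,
    StudySummary,
    absolute_difference,
    leave_one_out,
    meta_regress,
    pool,
    rom_effect,
    smd_effect,
    weighted_control_stats,
)


def make_study(study_id="s", mean_t=8.0, sd_t=2.0, n_t=10, mean_c=10.0, sd_c=2.0,
               n_c=10, **moderators):
    return StudySummary(study_id=study_id, mean_t=mean_t, sd_t=sd_t, n_t=n_t,
                        mean_c=mean_c, sd_c=sd_c, n_c=n_c, moderators=moderators)


class TestRomEffect:
    def test_equal_means_give_null_effect(self):
        eff = rom_effect(make_study(mean_t=10.0, mean_c=10.0, sd_t=3.0, sd_c=1.0))
        assert eff.effect == 0.0

    def test_hand_computed_effect_and_variance(self):
        eff = rom_effect(make_study())
        assert eff.effect == pytest.approx(-0.22314, abs=1e-5)
        assert eff.variance == pytest.approx(0.01025, abs=1e-5)

    def test_scale_equivariance(self):
        a = rom_effect(make_study())
        b = rom_effect(make_study(mean_t=8e3, sd_t=2e3, mean_c=10e3, sd_c=2e3))
        assert a.effect == pytest.approx(b.effect, rel=1e-12)
        assert a.variance == pytest.approx(b.variance, rel=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="positive arm means"):
            rom_effect(make_study(mean_t=-1.0))

    def test_invalid_summary_rejected(self):
        with pytest.raises(ValueError, match="SDs"):
            make_study(sd_t=0.0)
        with pytest.raises(ValueError, match="n >= 2"):
            make_study(n_c=1)


class TestSmdEffect:
    def test_equal_means_give_zero(self):
        assert smd_effect(make_study(mean_t=10.0, mean_c=10.0)).effect == 0.0

    def test_hedges_corrected_unit_effect(self):
        # raw d = -1; Hedges correction J(18) = 1 - 3/71
        eff = smd_effect(make_study())
        assert eff.effect == pytest.approx(-(1 - 3 / 71), rel=1e-12)
        assert eff.effect == pytest.approx(-0.96, abs=5e-3)

    def test_large_sample_unit_effect_limit(self):
        eff = smd_effect(make_study(mean_t=8.0, mean_c=10.0, sd_t=2.0, sd_c=2.0,
                                    n_t=5000, n_c=5000))
        assert eff.effect == pytest.approx(-1.0, abs=1e-3)


class TestPool:
    def test_single_study_identity(self):
        eff = StudyEffect(effect=-0.2, variance=0.01, study_id="only")
        res = pool([eff])
        assert res.effect == eff.effect
        assert res.se == pytest.approx(math.sqrt(eff.variance))
        assert res.q == 0.0 and res.i2 == 0.0 and res.tau2 == 0.0
        assert res.method == "fixed"

    def test_homogeneous_effects_pool_to_common_value(self):
        effs = [StudyEffect(effect=0.1, variance=0.04) for _ in range(4)]
        res = pool(effs)
        assert res.effect == pytest.approx(0.1)
        assert res.se == pytest.approx(math.sqrt(0.04 / 4))
        assert res.q == pytest.approx(0.0, abs=1e-12)
        assert res.i2 == 0.0 and res.method == "fixed"

    def test_hand_computed_heterogeneity(self):
        effs = [StudyEffect(effect=e, variance=0.01) for e in (0.0, 0.2, 0.4)]
        res = pool(effs)
        assert res.q == pytest.approx(8.0)
        assert res.i2 == pytest.approx(75.0)
        assert res.tau2 == pytest.approx(0.03)
        assert res.method == "random"  # auto: I2 > 30

    def test_matches_statsmodels_random_effects(self):
        rng = np.random.default_rng(5)
        y = rng.normal(-0.15, 0.2, size=8)
        v = rng.uniform(0.005, 0.05, size=8)
        ours = pool([StudyEffect(effect=a, variance=b) for a, b in zip(y, v)],
                    method="random")
        ref = combine_effects(y, v, method_re="dl")
        assert ours.tau2 == pytest.approx(ref.tau2, rel=1e-10)
        assert ours.effect == pytest.approx(ref.mean_effect_re, rel=1e-10)
        assert ours.se == pytest.approx(ref.sd_eff_w_re, rel=1e-10)
        assert ours.q == pytest.approx(ref.q, rel=1e-10)

    def test_equal_variances_give_arithmetic_mean(self):
        effs = [StudyEffect(effect=e, variance=0.02) for e in (-0.3, -0.1, 0.05)]
        res = pool(effs, method="fixed")
        assert res.effect == pytest.approx(np.mean([-0.3, -0.1, 0.05]))

    def test_zero_tau2_makes_random_equal_fixed(self):
        effs = [StudyEffect(effect=0.1, variance=v) for v in (0.01, 0.02, 0.05)]
        fe = pool(effs, method="fixed")
        re = pool(effs, method="random")
        assert re.tau2 == 0.0
        assert re.effect == pytest.approx(fe.effect)
        assert re.se == pytest.approx(fe.se)

    def test_ci_back_transform_preserves_ordering(self):
        effs = [StudyEffect(effect=e, variance=0.01) for e in (-0.2, -0.1, -0.3)]
        res = pool(effs)
        assert res.ci_low < res.effect < res.ci_high
        lo, hi = res.rom_ci
        assert lo < res.rom < hi
        assert math.log(res.rom) == pytest.approx(res.effect, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool([])


class TestWeightedControlStats:
    def test_equal_weights_give_arithmetic_mean(self):
        studies = [make_study("a", mean_c=30.0), make_study("b", mean_c=40.0)]
        mean_wt, _ = weighted_control_stats(studies, [0.5, 0.5])
        assert mean_wt == pytest.approx(35.0)

    def test_unequal_weights(self):
        studies = [make_study("a", mean_c=40.0), make_study("b", mean_c=32.0)]
        mean_wt, _ = weighted_control_stats(studies, [0.75, 0.25])
        assert mean_wt == pytest.approx(38.0)

    def test_single_study_returns_own_stats(self):
        studies = [make_study("a", mean_c=38.2, sd_c=3.7)]
        assert weighted_control_stats(studies, [1.0]) == pytest.approx((38.2, 3.7))

    def test_sd_modes_differ_unless_sds_equal(self):
        studies = [make_study("a", sd_c=2.0), make_study("b", sd_c=6.0)]
        _, sd_avg = weighted_control_stats(studies, [0.5, 0.5])
        _, sd_pooled = weighted_control_stats(studies, [0.5, 0.5], sd_mode="pooled")
        assert sd_avg == pytest.approx(4.0)
        assert sd_pooled == pytest.approx(math.sqrt(20.0))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            weighted_control_stats([make_study()], [0.5, 0.5])


class TestAbsoluteDifference:
    def test_control_scale_mean_difference(self):
        assert absolute_difference(0.89, 38.2) == pytest.approx(-4.2, abs=0.01)

    def test_null_ratio_gives_zero(self):
        assert absolute_difference(1.0, 38.2) == 0.0

    def test_triple_mapped_elementwise(self):
        point, lo, hi = absolute_difference((1.5, 1.2, 1.8), 10.0)
        assert (point, lo, hi) == pytest.approx((5.0, 2.0, 8.0))


class TestMetaRegress:
    def test_exact_fit_when_effects_linear_in_moderator(self):
        effs = [StudyEffect(effect=0.1 + 0.002 * d, variance=0.01)
                for d in (250.0, 500.0, 1000.0)]
        res = meta_regress(effs, [250.0, 500.0, 1000.0])
        # 3 collinear points: exact interpolation regardless of weighting
        assert res.slope == pytest.approx(0.002, rel=1e-9)
        assert res.intercept == pytest.approx(0.1, rel=1e-9)

    def test_translation_invariance_of_slope(self):
        rng = np.random.default_rng(9)
        effs = [StudyEffect(effect=e, variance=v)
                for e, v in zip(rng.normal(0, 0.2, 5), rng.uniform(0.01, 0.03, 5))]
        mod = [1.0, 2.0, 3.0, 4.0, 5.0]
        a = meta_regress(effs, mod)
        b = meta_regress(effs, [m + 100.0 for m in mod])
        assert a.slope == pytest.approx(b.slope, rel=1e-9)
        assert a.se == pytest.approx(b.se, rel=1e-9)

    def test_null_moderator_ci_coverage(self):
        """With a moderator unrelated to the effects, the slope CI covers 0 ~95% of the time."""
        rng = np.random.default_rng(2024)
        mod = np.linspace(0.0, 10.0, 12)
        hits = 0
        reps = 400
        for _ in range(reps):
            effs = [StudyEffect(effect=float(rng.normal(0.0, math.sqrt(0.01))),
                                variance=0.01) for _ in mod]
            res = meta_regress(effs, mod, tau2=0.0)
            hits += res.ci_low <= 0.0 <= res.ci_high
        assert 0.92 <= hits / reps <= 0.98

    def test_constant_moderator_rejected(self):
        effs = [StudyEffect(effect=0.1, variance=0.01) for _ in range(4)]
        with pytest.raises(ValueError, match="rank-deficien"):
            meta_regress(effs, [500.0] * 4)

    def test_too_few_studies_rejected(self):
        effs = [StudyEffect(effect=0.1, variance=0.01) for _ in range(2)]
        with pytest.raises(ValueError, match="at least 3"):
            meta_regress(effs, [1.0, 2.0])


class TestLeaveOneOut:
    def test_two_studies_each_row_is_the_other(self):
        studies = [make_study("a", mean_t=8.0), make_study("b", mean_t=9.0)]
        loo = leave_one_out(studies)
        assert loo["a"].effect == pytest.approx(rom_effect(studies[1]).effect)
        assert loo["b"].effect == pytest.approx(rom_effect(studies[0]).effect)

    def test_homogeneous_set_gives_identical_rows(self):
        studies = [make_study(f"s{i}") for i in range(4)]
        roms = {r.rom for r in leave_one_out(studies).values()}
        assert len(roms) == 1

    def test_omitting_the_outlier_minimizes_heterogeneity(self):
        studies = [make_study(f"s{i}", mean_t=8.0, sd_t=1.0, sd_c=1.0, n_t=40, n_c=40)
                   for i in range(4)]
        studies.append(make_study("outlier", mean_t=14.0, sd_t=1.0, sd_c=1.0,
                                  n_t=40, n_c=40))
        loo = leave_one_out(studies)
        i2_by_omitted = {k: v.i2 for k, v in loo.items()}
        assert min(i2_by_omitted, key=i2_by_omitted.get) == "outlier"
        assert i2_by_omitted["outlier"] == pytest.approx(0.0, abs=1e-9)

    def test_requires_two_studies(self):
        with pytest.raises(ValueError):
            leave_one_out([make_study()])


class TestPooledResultInvariants:
    def test_i2_bounded_and_tau2_nonnegative_under_random_inputs(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            k = int(rng.integers(2, 12))
            effs = [StudyEffect(effect=float(rng.normal(0, 0.3)),
                                variance=float(rng.uniform(0.001, 0.1)))
                    for _ in range(k)]
            res = pool(effs)
            assert 0.0 <= res.i2 <= 100.0
            assert res.tau2 >= 0.0
            assert res.q >= 0.0
            assert res.ci_low <= res.effect <= res.ci_high
            assert np.isclose(res.weights.sum(), 1.0)
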