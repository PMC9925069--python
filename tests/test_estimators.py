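"""Wald ratio, IVW, MR-Egger, weighted median and fixed-effects meta-analysis."""

import math

import numpy as np
import pandas as pd
import pytest

from cismr.estimators import (
    CohortEffect,
    Z95,
    ivw,
    meta_fixed,
    mr_egger,
    or_ci_to_log,
    unweighted_ivw,
    wald_ratio,
    weighted_median,
)

from conftest import random_harmonised


def frame(gamma, se_gamma, beta_out, se_out):
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    return pd.DataFrame(
        {
            "variant_id": [f"rs{i}" for i in range(len(gamma))],
            "gamma": gamma,
            "se_gamma": np.broadcast_to(se_gamma, gamma.shape),
            "beta_out": np.broadcast_to(beta_out, gamma.shape),
            "se_out": np.broadcast_to(se_out, gamma.shape),
        }
    )


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(0.1, 0.01, -0.05, 0.02)
        assert est.beta == pytest.approx(-0.5)
        assert est.se == pytest.approx(0.2)
        assert est.ci_low == pytest.approx(-0.5 - Z95 * 0.2)

    def test_null_outcome_gives_p_one(self):
        est = wald_ratio(0.1, 0.01, 0.0, 0.02)
        assert est.beta == 0.0 and est.pvalue == pytest.approx(1.0)

    def test_joint_negation_invariance(self):
        a = wald_ratio(0.1, 0.01, -0.05, 0.02)
        b = wald_ratio(-0.1, 0.01, 0.05, 0.02)
        assert (a.beta, a.se) == (b.beta, b.se)

    def test_zero_gamma_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)


class TestIVW:
    def test_single_snp_equals_wald_ratio_bitwise(self):
        w = wald_ratio(0.07, 0.01, -0.03, 0.015)
        v = ivw(frame(0.07, 0.01, -0.03, 0.015))
        assert (v.beta, v.se, v.ci_low, v.ci_high, v.pvalue) == (
            w.beta,
            w.se,
            w.ci_low,
            w.ci_high,
            w.pvalue,
        )

    def test_equal_weights_average_ratios(self):
        df = frame([0.1, 0.1], 0.01, 0.0, 0.02)
        df["beta_out"] = [-0.04, -0.06]  # ratios -0.4, -0.6
        assert ivw(df).beta == pytest.approx(-0.5)

    def test_matches_zero_intercept_wls_on_random_inputs(self, rng):
        """IVW is algebraically a zero-intercept WLS of Gamma on gamma."""
        for i in range(100):
            df = random_harmonised(rng, n=int(rng.integers(2, 30)), seed_offset=i)
            est = ivw(df)
            w = 1.0 / df["se_out"] ** 2
            x = (df["gamma"] * np.sqrt(w)).to_numpy()[:, None]
            y = (df["beta_out"] * np.sqrt(w)).to_numpy()
            slope = np.linalg.lstsq(x, y, rcond=None)[0][0]
            assert est.beta == pytest.approx(slope, rel=1e-10)

    def test_multiplicative_shares_point_estimate_with_wider_se(self, rng):
        for i in range(20):
            df = random_harmonised(rng, n=12, seed_offset=100 + i)
            fixed = ivw(df, "fixed")
            mre = ivw(df, "multiplicative")
            assert mre.beta == fixed.beta
            assert mre.se >= fixed.se

    def test_scale_equivariance(self, rng):
        df = random_harmonised(rng, n=8)
        c = 3.7
        scaled = df.assign(gamma=df["gamma"] * c, se_gamma=df["se_gamma"] * c)
        assert ivw(scaled).beta == pytest.approx(ivw(df).beta / c, rel=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            ivw(frame(np.array([]), 0.01, 0.0, 0.02))


class TestMREgger:
    def test_exact_linear_data_recovered(self):
        g = np.array([0.02, 0.05, 0.08, 0.11, 0.14])
        a, b = 0.013, -0.4
        df = frame(g, 0.01, a + b * g, 0.02)
        slope, intercept = mr_egger(df)
        assert slope.beta == pytest.approx(b, rel=1e-9)
        assert intercept.beta == pytest.approx(a, rel=1e-9)
        # exact fit: residual scale below 1 must not shrink the SEs
        assert slope.se >= 0

    def test_orientation_of_inputs_is_irrelevant(self, rng):
        df = random_harmonised(rng, n=10)
        flip = df.copy()
        flip["gamma"] *= -1
        flip["beta_out"] *= -1
        s1, i1 = mr_egger(df)
        s2, i2 = mr_egger(flip)
        assert s1.beta == pytest.approx(s2.beta, rel=1e-12)
        assert i1.beta == pytest.approx(i2.beta, rel=1e-12)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            mr_egger(frame([0.1, 0.2], 0.01, 0.0, 0.02))


class TestWeightedMedian:
    def test_equal_weights_reduce_to_simple_median(self):
        df = frame([0.1, 0.1, 0.1], 0.01, 0.0, 0.02)
        df["beta_out"] = np.array([-0.7, -0.5, -0.1]) * 0.1
        est = weighted_median(df, seed=1)
        assert est.beta == pytest.approx(-0.5)

    def test_order_invariance(self, rng):
        df = random_harmonised(rng, n=9)
        perm = df.sample(frac=1, random_state=3).reset_index(drop=True)
        a = weighted_median(df, seed=11)
        b = weighted_median(perm, seed=11)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)

    def test_resists_single_pleiotropic_outlier(self):
        """One wild SNP with ~20% weight barely moves the median; IVW shifts."""
        g = np.full(5, 0.1)
        ratios = np.array([-0.50, -0.52, -0.48, -0.51, 3.0])
        df = frame(g, 0.01, ratios * g, 0.02)
        clean = df.iloc[:4]
        wm_all = weighted_median(df, seed=5).beta
        wm_clean = weighted_median(clean, seed=5).beta
        assert abs(wm_all - wm_clean) < 0.05
        assert abs(ivw(df).beta - ivw(clean).beta) > 0.3

    def test_seed_is_mandatory(self, rng):
        with pytest.raises(ValueError, match="seed"):
            weighted_median(random_harmonised(rng, n=5))


class TestUnweightedIVW:
    def test_identical_outcome_betas_pool_exactly(self):
        df = frame([0.1, 0.2, 0.3, 0.4], 0.01, 0.02, 0.01)
        est = unweighted_ivw(df)
        assert est.beta == pytest.approx(0.02)
        assert est.se == pytest.approx(0.01 / 2.0)

    def test_single_snp_passthrough(self):
        est = unweighted_ivw(frame(0.1, 0.01, 0.02, 0.015))
        assert (est.beta, est.se) == (pytest.approx(0.02), pytest.approx(0.015))

    def test_reduces_to_ivw_with_unit_exposure(self, rng):
        df = random_harmonised(rng, n=7)
        unit = df.assign(gamma=1.0, se_gamma=0.0)
        assert unweighted_ivw(df).beta == pytest.approx(ivw(unit).beta, rel=1e-12)
        assert unweighted_ivw(df).se == pytest.approx(ivw(unit).se, rel=1e-12)


class TestORConversions:
    def test_printed_sepsis_row_converts(self):
        beta, se = or_ci_to_log(CohortEffect("UKB", "sepsis", 0.80, 0.66, 0.96))
        assert beta == pytest.approx(-0.2231, abs=5e-5)
        assert se == pytest.approx(0.0956, abs=5e-5)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            or_ci_to_log(CohortEffect("X", "y", 1.0, 1.0, 1.0))

    def test_round_trip_stability(self):
        beta, se = or_ci_to_log(CohortEffect("X", "y", 0.73, 0.52, 1.02))
        eff = CohortEffect(
            "X",
            "y",
            math.exp(beta),
            math.exp(beta - Z95 * se),
            math.exp(beta + Z95 * se),
        )
        beta2, se2 = or_ci_to_log(eff)
        assert beta2 == pytest.approx(beta, abs=1e-12)
        assert se2 == pytest.approx(se, abs=1e-12)

    def test_inconsistent_interval_rejected(self):
        with pytest.raises(ValueError):
            CohortEffect("X", "y", 0.8, 0.9, 1.1)


class TestMetaFixed:
    UKB = CohortEffect("UK Biobank", "sepsis", 0.80, 0.66, 0.96)

    @pytest.mark.parametrize(
        "other, expected",
        [
            (CohortEffect("FinnGen", "streptococcal sepsis", 0.79, 0.48, 1.31), (0.80, 0.67, 0.95)),
            (CohortEffect("FinnGen", "respiratory sepsis", 0.63, 0.29, 1.35), (0.79, 0.66, 0.95)),
        ],
    )
    def test_published_cross_cohort_poolings(self, other, expected):
        """Pooling the printed cohort ORs reproduces the published summaries."""
        res = meta_fixed([self.UKB, other])
        assert round(res.pooled_or, 2) == expected[0]
        assert round(res.ci_low, 2) == expected[1]
        assert round(res.ci_high, 2) == expected[2]

    def test_replicated_cohort_shrinks_se_by_sqrt2(self):
        res = meta_fixed([self.UKB, CohortEffect("copy", "sepsis", 0.80, 0.66, 0.96)])
        _, se1 = or_ci_to_log(self.UKB)
        assert res.pooled_or == pytest.approx(0.80, abs=1e-9)
        assert res.se == pytest.approx(se1 / math.sqrt(2), rel=1e-9)

    def test_pooled_log_or_within_cohort_range(self, rng):
        for _ in range(20):
            ors = rng.uniform(0.5, 1.5, size=3)
            effs = [
                CohortEffect(f"c{i}", "o", o, o * rng.uniform(0.6, 0.95), o * rng.uniform(1.05, 1.6))
                for i, o in enumerate(ors)
            ]
            res = meta_fixed(effs)
            assert min(ors) - 1e-12 <= res.pooled_or <= max(ors) + 1e-12
            assert all(w > 0 and np.isfinite(w) for w in res.weights.values())

    def test_fewer_than_two_cohorts_rejected(self):
        with pytest.raises(ValueError):
            meta_fixed([self.UKB])
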