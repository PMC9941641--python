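"""MR estimators, heterogeneity, pleiotropy diagnostics, power, FDR and
the discovery-replication rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import protmr as pm
from protmr.mr import (MRResult, _weighted_median_estimate, bh_fdr,
                       cochran_q, discover_replicate, egger, ivw,
                       leave_one_out, mr_power_binary, mr_presso, steiger,
                       wald_ratio, weighted_median)
from conftest import make_pairs


class TestWaldRatio:
    def test_direct_quotient(self):
        p = make_pairs([0.5], 0.05, [-0.10], 0.02)
        r = wald_ratio(p)
        assert r.beta_mr == pytest.approx(-0.20)
        assert r.se_mr == pytest.approx(0.04)
        assert r.method == "wald_ratio" and r.n_snps == 1

    def test_null_outcome_gives_p_one(self):
        r = wald_ratio(make_pairs([0.5], 0.05, [0.0], 0.02))
        assert r.beta_mr == 0.0 and r.pval == pytest.approx(1.0)

    def test_unit_exposure_se_equals_outcome_se(self):
        r = wald_ratio(make_pairs([1.0], 0.05, [0.3], 0.1))
        assert r.se_mr == pytest.approx(0.1)

    def test_zero_exposure_beta_raises(self):
        with pytest.raises(ValueError):
            wald_ratio(make_pairs([0.0], 0.05, [0.1], 0.02))

    def test_or_ci_transform(self):
        r = MRResult("wald_ratio", 1, -0.2, 0.05, 1e-4)
        assert r.or_ == pytest.approx(np.exp(-0.2))
        assert r.or_lci == pytest.approx(np.exp(-0.2 - 1.959964 * 0.05), rel=1e-5)
        assert r.or_uci == pytest.approx(np.exp(-0.2 + 1.959964 * 0.05), rel=1e-5)


class TestIvw:
    def test_single_pair_equals_wald_ratio(self):
        p = make_pairs([0.4], 0.03, [-0.08], 0.02)
        a, b = ivw(p, "auto"), wald_ratio(p)
        assert (a.beta_mr, a.se_mr, a.pval) == (b.beta_mr, b.se_mr, b.pval)

    def test_two_identical_pairs(self):
        p = make_pairs([0.4, 0.4], 0.03, [-0.08, -0.08], 0.02)
        r = ivw(p, "fixed")
        single = wald_ratio(p.iloc[[0]])
        assert r.beta_mr == pytest.approx(single.beta_mr)
        assert r.se_mr == pytest.approx(single.se_mr / np.sqrt(2))
        assert r.q_stat == pytest.approx(0.0, abs=1e-12)

    def test_multiplicative_se_never_below_fixed(self, rng):
        for _ in range(20):
            L = int(rng.integers(2, 15))
            p = make_pairs(rng.uniform(0.1, 0.5, L), 0.02,
                           rng.normal(0, 0.1, L), rng.uniform(0.01, 0.05, L))
            assert ivw(p, "multiplicative").se_mr >= ivw(p, "fixed").se_mr - 1e-15

    def test_sign_flip_equivariance(self, rng):
        L = 10
        bx = rng.uniform(0.1, 0.5, L)
        by = -0.2 * bx + rng.normal(0, 0.01, L)
        p = make_pairs(bx, 0.02, by, 0.02)
        flipped = p.copy()
        flip = rng.choice([-1.0, 1.0], L)
        flipped["beta_exp"] *= flip
        flipped["beta_out"] *= flip
        for fn in (lambda d: ivw(d, "fixed"), egger,
                   lambda d: weighted_median(d, n_boot=50, seed=0)):
            assert fn(p).beta_mr == pytest.approx(fn(flipped).beta_mr, rel=1e-9)

    def test_auto_switches_to_mre_under_heterogeneity(self, rng):
        L = 20
        bx = rng.uniform(0.2, 0.5, L)
        by = -0.2 * bx + rng.normal(0, 0.2, L)  # gross extra dispersion
        r = ivw(make_pairs(bx, 0.01, by, 0.02), "auto")
        assert r.method == "ivw_mre" and r.q_pval < 0.05

    def test_parameter_recovery(self):
        """IVW recovers theta on clean simulated instruments."""
        sim = pm.simulate_mr_instruments(pm.SimConfig(true_theta=-0.2, seed=4))
        r = ivw(sim["discovery"], "auto")
        assert abs(r.beta_mr - (-0.2)) < 3 * r.se_mr


class TestCochranQ:
    def test_homogeneous_ratios_give_zero_q(self):
        p = make_pairs([0.2, 0.4, 0.5], 0.02, [-0.04, -0.08, -0.10], 0.02)
        q, pv = cochran_q(p, ivw(p, "fixed").beta_mr)
        assert q == pytest.approx(0.0, abs=1e-10) and pv == pytest.approx(1.0)

    def test_planted_outlier_detected(self, rng):
        L = 15
        bx = rng.uniform(0.2, 0.5, L)
        by = -0.2 * bx + rng.normal(0, 0.01, L)
        by[0] += 0.3
        p = make_pairs(bx, 0.005, by, 0.01)
        r = ivw(p, "fixed")
        assert r.q_pval < 0.05


class TestEgger:
    def test_too_few_instruments_refused(self):
        with pytest.raises(ValueError):
            egger(make_pairs([0.1, 0.2], 0.01, [0.0, 0.0], 0.01))

    def test_planted_intercept_recovered(self):
        """A constant directional-pleiotropy offset lands in the intercept."""
        ints = []
        for s in range(100):
            sim = pm.simulate_mr_instruments(
                pm.SimConfig(true_theta=-0.2, seed=300 + s,
                             pleiotropy_frac=1.0, pleiotropy_shift=0.05))
            ints.append(egger(sim["discovery"]).egger_intercept)
        assert np.mean(ints) == pytest.approx(0.05, abs=0.01)

    def test_slope_recovery_without_pleiotropy(self):
        sim = pm.simulate_mr_instruments(pm.SimConfig(true_theta=-0.2, seed=9))
        r = egger(sim["discovery"])
        assert abs(r.beta_mr - (-0.2)) < 3 * r.se_mr
        assert r.egger_intercept_p > 0.05


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        est = _weighted_median_estimate(np.array([1.0, 2.0, 3.0]),
                                        np.ones(3))
        assert est == pytest.approx(2.0)

    def test_interpolation_with_unequal_weights(self):
        est = _weighted_median_estimate(np.array([1.0, 2.0, 100.0]),
                                        np.array([0.45, 0.45, 0.10]))
        # cumulative midpoints 0.225 / 0.675 / 0.95 -> interpolate at 0.5
        assert est == pytest.approx(1.0 + 0.275 / 0.45)
        assert 1.0 < est < 2.0

    def test_robust_to_half_invalid_instruments(self):
        """With ~50% invalid weight, the weighted median stays closer to
        the truth than IVW."""
        wm_err, ivw_err = [], []
        for s in range(60):
            sim = pm.simulate_mr_instruments(
                pm.SimConfig(true_theta=-0.2, seed=7000 + s,
                             pleiotropy_frac=0.45, pleiotropy_shift=0.08))
            d = sim["discovery"]
            wm_err.append(abs(weighted_median(d, n_boot=50, seed=s).beta_mr + 0.2))
            ivw_err.append(abs(ivw(d, "fixed").beta_mr + 0.2))
        assert np.mean(wm_err) < np.mean(ivw_err)

    def test_seeded_determinism(self):
        sim = pm.simulate_mr_instruments(pm.SimConfig(seed=5))
        a = weighted_median(sim["discovery"], n_boot=100, seed=42)
        b = weighted_median(sim["discovery"], n_boot=100, seed=42)
        assert a.se_mr == b.se_mr


class TestMrPresso:
    def test_skipped_below_four_instruments(self):
        assert mr_presso(make_pairs([0.1] * 3, 0.01, [0.0] * 3, 0.01)) is None

    def test_deterministic_under_seed(self):
        sim = pm.simulate_mr_instruments(pm.SimConfig(seed=8, n_instruments=10))
        a = mr_presso(sim["discovery"], n_sim=999, seed=13)
        b = mr_presso(sim["discovery"], n_sim=999, seed=13)
        assert a.global_p == b.global_p
        assert a.outlier_pvals == b.outlier_pvals
        assert 1 / 1000 <= a.global_p <= 1.0

    def test_planted_outlier_flagged(self):
        flagged = 0
        for s in range(20):
            sim = pm.simulate_mr_instruments(
                pm.SimConfig(seed=900 + s, n_instruments=20, true_theta=-0.2))
            d = sim["discovery"].copy()
            d.loc[0, "beta_out"] += 10 * d.loc[0, "se_out"]
            res = mr_presso(d, n_sim=500, seed=s)
            flagged += d.loc[0, "snp_id"] in res.outlier_snps
        assert flagged > 18  # > 90%

    def test_outliers_subset_of_instruments(self):
        sim = pm.simulate_mr_instruments(pm.SimConfig(seed=8, n_instruments=12))
        res = mr_presso(sim["discovery"], n_sim=200, seed=1)
        assert set(res.outlier_snps) <= set(sim["discovery"]["snp_id"])


class TestSteiger:
    def test_exposure_dominant_direction(self):
        # exposure z=20 at n=30000 -> r2 ~ 0.013; outcome z=2 -> ~2e-4
        p = make_pairs([0.2], 0.01, [0.02], 0.01)
        correct, pval = steiger(p, 30_000, 20_000)
        assert correct and pval < 1e-10

    def test_equal_r2_boundary(self):
        p = make_pairs([0.2], 0.01, [0.2], 0.01)
        correct, pval = steiger(p, 30_000, 30_000)
        assert not correct and pval == pytest.approx(1.0)

    def test_simulated_direction_almost_always_correct(self):
        ok = 0
        for s in range(100):
            sim = pm.simulate_mr_instruments(
                pm.SimConfig(seed=1200 + s, n_instruments=1, true_theta=-0.2))
            d = sim["discovery"]
            correct, _ = steiger(d, d["n_exp"].iloc[0], d["n_out"].iloc[0])
            ok += correct
        assert ok >= 99


class TestLeaveOneOut:
    def test_identical_pairs_give_identical_fits(self):
        p = make_pairs([0.3] * 4, 0.02, [-0.06] * 4, 0.02)
        full = ivw(p, "fixed").beta_mr
        for _, r in leave_one_out(p, mode="fixed"):
            assert r.beta_mr == pytest.approx(full)

    def test_two_pairs_reduce_to_wald(self):
        p = make_pairs([0.3, 0.5], 0.02, [-0.06, -0.11], 0.02)
        res = leave_one_out(p)
        assert all(r.method == "wald_ratio" for _, r in res)

    def test_outlier_shifts_exactly_one_fit(self, rng):
        L = 10
        bx = rng.uniform(0.2, 0.5, L)
        by = -0.2 * bx
        by[3] += 0.25
        p = make_pairs(bx, 0.01, by, 0.02)
        res = leave_one_out(p, mode="fixed")
        errs = {snp: abs(r.beta_mr + 0.2) for snp, r in res}
        best = min(errs, key=errs.get)
        assert best == p["snp_id"].iloc[3]
        assert errs[best] < 0.01


class TestPower:
    def test_null_or_gives_alpha(self):
        assert mr_power_binary(0.1, 1.0, 24_510, 0.3) == pytest.approx(0.05)

    @given(st.floats(0.01, 0.5), st.floats(0.01, 0.5))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_r2(self, a, b):
        lo, hi = sorted((a, b))
        assert mr_power_binary(hi, 0.85, 24_510, 0.33) >= \
            mr_power_binary(lo, 0.85, 24_510, 0.33)

    @given(st.integers(1_000, 300_000), st.integers(1_000, 300_000))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_n(self, a, b):
        lo, hi = sorted((a, b))
        assert mr_power_binary(0.1, 0.85, hi, 0.33) >= \
            mr_power_binary(0.1, 0.85, lo, 0.33)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_log_or(self, a, b):
        lo, hi = sorted((a, b))
        assert mr_power_binary(0.1, np.exp(-hi), 24_510, 0.33) >= \
            mr_power_binary(0.1, np.exp(-lo), 24_510, 0.33) - 1e-12

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            mr_power_binary(0.0, 0.9, 1000, 0.3)
        with pytest.raises(ValueError):
            mr_power_binary(0.1, -1.0, 1000, 0.3)
        with pytest.raises(ValueError):
            mr_power_binary(0.1, 0.9, 1000, 1.5)


def _brute_force_bh(p):
    """Textbook step-up: p_(i) * m / i with cumulative minimum from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBhFdr:
    def test_worked_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    @given(st.lists(st.floats(1e-10, 1.0, exclude_min=False), min_size=1,
                    max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_and_dominates_raw(self, pvals):
        adj = bh_fdr(pvals)
        assert np.allclose(adj, _brute_force_bh(pvals), rtol=1e-12)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        assert (adj <= 1.0 + 1e-15).all()
        # adjusted values preserve the ordering of the raw p-values
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()


def _res(pid, group, beta, p):
    return MRResult("ivw_fe", 5, beta, 0.05, p, protein_id=pid, group=group)


class TestDiscoverReplicate:
    def test_pass_requires_fdr_replication_and_direction(self):
        disc = [_res("prot1", "A", -0.2, 1e-5),
                _res("prot2", "A", -0.3, 1e-4),
                _res("prot3", "A", 0.1, 0.9)]
        rep = [_res("prot1", "A", -0.1, 0.01),
               _res("prot2", "A", +0.2, 0.01),  # discordant direction
               _res("prot3", "A", 0.1, 0.5)]
        out = discover_replicate(disc, rep)
        assert out["passing"] == ["prot1"]
        tab = out["table"].set_index("protein_id")
        assert tab.loc["prot2", "status"] == "discovery_only"
        assert tab.loc["prot3", "status"] == "not_significant"

    def test_high_fdr_fails_regardless_of_replication(self):
        # identical p-values -> FDR = p * m / m = p ... use p just over 0.05
        disc = [_res(f"p{i}", "A", -0.2, 0.06) for i in range(4)]
        rep = [_res(f"p{i}", "A", -0.2, 1e-4) for i in range(4)]
        assert discover_replicate(disc, rep)["passing"] == []

    def test_missing_replication_is_untestable(self):
        disc = [_res("prot1", "A", -0.2, 1e-6)]
        out = discover_replicate(disc, [])
        assert out["passing"] == [] and out["untestable"] == ["prot1"]
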