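"""Interaction model, Levene test, weighting scheme and scan behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirqtl.interaction import (
    InteractionScan,
    MiSnpUnit,
    ScanDimensions,
    UtrTestUnit,
    compute_weights,
    interaction_model,
    levene_test,
    replicate_interactions,
    weighted_decision,
)
from mirqtl.regression import DegeneratePredictorError
from mirqtl.simulate import (
    InteractionEffect,
    ProbeSpec,
    ScenarioConfig,
    SnpSpec,
    VariancePlan,
    simulate_bundle,
)

from conftest import make_covariates, make_expression, make_genotypes


class TestInteractionModel:
    def test_exact_product_construction(self):
        combos = np.array([(a, b) for a in (0, 1, 2) for b in (0, 1, 2)] * 2, float)
        g_u, g_m = combos[:, 0], combos[:, 1]
        y = g_u * g_m
        b, se, p, n = interaction_model(y, g_u, g_m)
        assert b == pytest.approx(1.0, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-10)
        assert n == 18

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        n = 300
        g_u = rng.binomial(2, 0.3, n).astype(float)
        g_m = rng.binomial(2, 0.4, n).astype(float)
        cov = np.column_stack([rng.uniform(35, 74, n), rng.integers(0, 2, n)])
        y = 0.2 * g_u + 0.1 * g_m + 0.3 * g_u * g_m + rng.normal(0, 1, n)
        b, se, p, _ = interaction_model(y, g_u, g_m, cov)
        X = sm.add_constant(np.column_stack([g_u, g_m, g_u * g_m, cov]))
        fit = sm.OLS(y, X).fit()
        assert b == pytest.approx(fit.params[3], rel=1e-8)
        assert se == pytest.approx(fit.bse[3], rel=1e-8)
        assert p == pytest.approx(fit.pvalues[3], rel=1e-8)

    def test_robust_se_matches_statsmodels_hc3(self, rng):
        import statsmodels.api as sm

        n = 250
        g_u = rng.binomial(2, 0.3, n).astype(float)
        g_m = rng.binomial(2, 0.4, n).astype(float)
        y = rng.normal(0, 1 + g_u, n)
        b, se, p, _ = interaction_model(y, g_u, g_m, se="hc3")
        X = sm.add_constant(np.column_stack([g_u, g_m, g_u * g_m]))
        fit = sm.OLS(y, X).fit(cov_type="HC3")
        assert se == pytest.approx(fit.bse[3], rel=1e-8)

    def test_perfect_ld_is_degenerate(self, rng):
        g = rng.binomial(2, 0.4, 100).astype(float)
        with pytest.raises(DegeneratePredictorError):
            interaction_model(rng.normal(0, 1, 100), g, g.copy())

    def test_type_one_error_calibrated(self, rng):
        """Null interaction, homoskedastic: rejection rate at alpha = 0.05
        stays within the binomial 99% envelope."""
        n, reps, alpha = 300, 2000, 0.05
        rejections = 0
        for r in range(reps):
            g_u = rng.binomial(2, 0.3, n).astype(float)
            g_m = rng.binomial(2, 0.4, n).astype(float)
            y = 0.2 * g_u + 0.1 * g_m + rng.normal(0, 1, n)
            _, _, p, _ = interaction_model(y, g_u, g_m)
            rejections += p < alpha
        margin = 2.576 * math.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rejections / reps - alpha) < margin


class TestLevene:
    def test_worked_example_and_scipy_oracle(self):
        y = np.array([1, 3, 0, 4, 2], float)
        groups = np.array([0, 0, 1, 1, 1], float)
        F, q = levene_test(y, groups)
        assert F == pytest.approx(0.15, abs=1e-12)
        assert q == pytest.approx(0.72, abs=0.01)
        F_sp, q_sp = stats.levene(y[:2], y[2:], center="mean")
        assert F == pytest.approx(F_sp, rel=1e-10)
        assert q == pytest.approx(q_sp, rel=1e-10)

    def test_scale_invariance(self):
        y = np.array([1, 3, 0, 4, 2], float)
        groups = np.array([0, 0, 1, 1, 1], float)
        _, q1 = levene_test(y, groups)
        _, q2 = levene_test(7.3 * y, groups)
        assert q1 == pytest.approx(q2, rel=1e-12)

    def test_median_center_matches_brown_forsythe(self, rng):
        y = rng.normal(0, 1, 90)
        groups = rng.integers(0, 3, 90).astype(float)
        F, q = levene_test(y, groups, center="median")
        parts = [y[groups == v] for v in np.unique(groups)]
        F_sp, q_sp = stats.levene(*parts, center="median")
        assert F == pytest.approx(F_sp, rel=1e-10)
        assert q == pytest.approx(q_sp, rel=1e-10)

    def test_covariate_residualization_removes_covariate_signal(self, rng):
        n = 400
        groups = rng.binomial(2, 0.5, n).astype(float)
        age = rng.uniform(35, 74, n)
        y = 0.5 * age + rng.normal(0, 1, n)
        _, q_adj = levene_test(y, groups, covariates=age.reshape(-1, 1))
        assert q_adj > 0.001  # no genuine variance heterogeneity

    def test_power_under_variance_heterogeneity(self, rng):
        """Group variances 1 vs 4 at n = 200 per group: q < 0.01 almost always."""
        reps, hits = 300, 0
        for r in range(reps):
            y = np.concatenate([rng.normal(0, 1, 200), rng.normal(0, 2, 200)])
            groups = np.repeat([0.0, 1.0], 200)
            _, q = levene_test(y, groups)
            hits += q < 0.01
        assert hits / reps >= 0.95

    def test_fewer_than_two_groups_undefined(self):
        with pytest.raises(ValueError, match="<2"):
            levene_test(np.arange(5.0), np.zeros(5))


class TestWeights:
    def test_all_equal_q_reduce_to_bonferroni(self):
        q = {u: 0.3 for u in "abc"}
        tests = ["a", "a", "b", "c"]
        w = compute_weights(q, tests)
        assert all(v == pytest.approx(1.0) for v in w.values())

    def test_all_q_one_falls_back_to_uniform(self):
        w = compute_weights({"a": 1.0, "b": 1.0}, ["a", "b"])
        assert w == {"a": 1.0, "b": 1.0}

    @given(
        st.dictionaries(
            st.sampled_from(list("abcdefgh")),
            st.floats(1e-300, 1.0, exclude_min=False),
            min_size=2,
            max_size=8,
        ),
        st.integers(1, 5),
    )
    @settings(max_examples=150, deadline=None)
    def test_weights_sum_to_n_over_executed_tests(self, qs, tests_per_unit):
        tests = [u for u in qs for _ in range(tests_per_unit)]
        w = compute_weights(qs, tests)
        total = sum(w[u] for u in tests)
        assert total == pytest.approx(len(tests), rel=1e-9)

    def test_log_base_cancels(self):
        qs = {"a": 1e-6, "b": 0.3, "c": 0.9}
        tests = ["a", "b", "b", "c"]
        w_ln = compute_weights(qs, tests)
        neglog10 = {u: -math.log10(q) for u, q in qs.items()}
        total = sum(neglog10[u] for u in tests)
        w_log10 = {u: v * len(tests) / total for u, v in neglog10.items()}
        for u in qs:
            assert w_ln[u] == pytest.approx(w_log10[u], rel=1e-12)

    def test_weighted_decision(self):
        wp, sig = weighted_decision(1e-6, 1.0, alpha=0.05, n_tests=1000)
        assert wp == 1e-6 and sig
        wp, sig = weighted_decision(1e-4, 1.0, alpha=0.05, n_tests=1000)
        assert not sig
        wp, _ = weighted_decision(4e-4, 8.0, alpha=0.05, n_tests=1000)
        assert wp == pytest.approx(5e-5)


def _recovery_bundle(seed, n_samples=800, beta=0.5, n_units=10, n_misnp=20,
                     het_at_true_unit=False):
    rng = np.random.default_rng(seed + 77_000)
    snps = [
        SnpSpec(f"mi{i}", str(1 + i % 22), 10_000 + i, float(rng.uniform(0.2, 0.5)))
        for i in range(n_misnp)
    ]
    probes = []
    for u in range(n_units):
        snps.append(SnpSpec(f"utr{u}", str(1 + u), 50_000 + u, float(rng.uniform(0.2, 0.5))))
        probes.append(ProbeSpec(f"P{u}", f"G{u}", str(1 + u), 40_000, 49_000))
    config = ScenarioConfig(
        n_samples=n_samples,
        snps=snps,
        probes=probes,
        interactions=[InteractionEffect("utr0", "mi0", "P0", beta)],
        variance_plans=(
            [VariancePlan("utr0", "P0", (1.0, 1.5, 2.0))] if het_at_true_unit else []
        ),
        seed=seed,
    )
    return simulate_bundle(config)


def _scan(bundle, weighting="levene", alpha=0.05):
    units = [UtrTestUnit(f"G{u}", f"P{u}", f"utr{u}", f"utr{u}") for u in range(10)]
    mis = [MiSnpUnit(f"mi{i}", f"mi{i}") for i in range(20)]
    return InteractionScan(
        bundle.expression, bundle.genotypes, bundle.covariates, units, mis,
        weighting=weighting,
    ).fit(alpha=alpha)


class TestScan:
    def test_planted_interaction_recovered_without_false_positives(self):
        """One planted interaction among 200 tests: the planted pair tops the
        ranking and is significant in >= 95% of replicates, and false
        positives occur in <= 5% of replicates (family-wise control)."""
        reps = 60
        recovered = 0
        fp_reps = 0
        for r in range(reps):
            res = _scan(_recovery_bundle(seed=40_000 + r))
            top = res.records[0]
            sig = {(s.utr_proxy, s.mi_proxy) for s in res.significant()}
            if (top.utr_proxy, top.mi_proxy) == ("utr0", "mi0") and ("utr0", "mi0") in sig:
                recovered += 1
            fp_reps += bool(sig - {("utr0", "mi0")})
        assert recovered / reps >= 0.95
        assert fp_reps / reps <= 0.05 + 2.576 * math.sqrt(0.05 * 0.95 / reps)

    def test_weighted_power_at_least_unweighted(self):
        """With genuine variance heterogeneity at the true unit the Levene
        weight exceeds 1 there, so the weighted decision detects the planted
        pair whenever flat Bonferroni does — and strictly more often."""
        reps, w_hits, b_hits = 30, 0, 0
        for r in range(reps):
            bundle = _recovery_bundle(
                seed=62_000 + r, n_samples=400, beta=0.30, het_at_true_unit=True
            )
            res = _scan(bundle)
            planted = [
                rec for rec in res.records
                if (rec.utr_proxy, rec.mi_proxy) == ("utr0", "mi0")
            ][0]
            assert planted.weight > 1.0  # genuine heterogeneity is prioritized
            w_hits += planted.significant
            b_hits += planted.p_interaction < res.alpha / res.dimensions.n_tests
        assert w_hits >= b_hits
        assert w_hits > 0

    def test_empty_selection_gives_empty_scan(self, rng):
        E = make_expression({"P": rng.normal(0, 1, 30)})
        G = make_genotypes({"g": rng.binomial(2, 0.4, 30).astype(float)})
        res = InteractionScan(E, G, None, [], []).fit()
        assert res.records == [] and res.dimensions.n_tests == 0
        assert math.isnan(res.threshold)

    def test_all_q_equal_matches_bonferroni_set(self, rng):
        bundle = _recovery_bundle(seed=90_001, n_samples=400)
        weighted = _scan(bundle, weighting="levene")
        flat = _scan(bundle, weighting="none")
        # same executed tests; flat weights give the plain Bonferroni set
        bonf = {
            (r.utr_proxy, r.mi_proxy)
            for r in flat.records
            if r.p_interaction < flat.alpha / flat.dimensions.n_tests
        }
        assert {(r.utr_proxy, r.mi_proxy) for r in flat.significant()} == bonf
        assert weighted.dimensions.n_tests == flat.dimensions.n_tests

    def test_deterministic_ordering_and_repeatability(self):
        res1 = _scan(_recovery_bundle(seed=123))
        res2 = _scan(_recovery_bundle(seed=123))
        key = lambda res: [(r.probe_id, r.utr_snp, r.mi_snp, r.weighted_p) for r in res.records]
        assert key(res1) == key(res2)
        wps = [r.weighted_p for r in res1.records]
        assert wps == sorted(wps)

    def test_scan_dimensions_invariant(self):
        with pytest.raises(ValueError):
            ScanDimensions(n_utr=2, n_misnp=3, n_tests=7)


class TestReplication:
    def test_bonferroni_threshold_from_replicable_count(self):
        """k = 8 replicable hits at alpha = 0.05 -> threshold 6.25e-3."""
        rng = np.random.default_rng(5)
        n = 700
        g = {f"u{i}": rng.binomial(2, 0.4, n).astype(float) for i in range(8)}
        g.update({f"m{i}": rng.binomial(2, 0.4, n).astype(float) for i in range(8)})
        G = make_genotypes(g)
        E = make_expression({f"P{i}": rng.normal(0, 1, n) for i in range(8)})
        C = make_covariates(n, rng, status=True)
        hits = [_fake_hit(f"u{i}", f"m{i}", f"P{i}") for i in range(8)]
        df = replicate_interactions(hits, E, G, C)
        assert df["k"].iloc[0] == 8
        assert df["threshold"].iloc[0] == pytest.approx(6.25e-3)

    def test_true_interaction_replicates_and_missing_proxy_excluded(self):
        rng = np.random.default_rng(9)
        n = 700
        gu = rng.binomial(2, 0.4, n).astype(float)
        gm = rng.binomial(2, 0.4, n).astype(float)
        y = 0.2 * gu + 0.1 * gm + 0.5 * gu * gm + rng.normal(0, 1, n)
        G = make_genotypes({"u0": gu, "m0": gm})
        E = make_expression({"P0": y})
        C = make_covariates(n, rng, status=True)
        hits = [_fake_hit("u0", "m0", "P0"), _fake_hit("u_absent", "m0", "P0")]
        df = replicate_interactions(hits, E, G, C)
        assert df["k"].iloc[0] == 1  # absent proxy excluded from k
        row = df[df.utr_proxy == "u0"].iloc[0]
        assert row.replicated
        assert not df[df.utr_proxy == "u_absent"].iloc[0].replicable

    def test_sign_inconsistency_blocks_replication(self):
        rng = np.random.default_rng(11)
        n = 700
        gu = rng.binomial(2, 0.4, n).astype(float)
        gm = rng.binomial(2, 0.4, n).astype(float)
        y = -0.5 * gu * gm + rng.normal(0, 1, n)  # sign flipped vs discovery
        G = make_genotypes({"u0": gu, "m0": gm})
        E = make_expression({"P0": y})
        df = replicate_interactions([_fake_hit("u0", "m0", "P0")], E, G, None)
        assert not df["replicated"].iloc[0]
        df2 = replicate_interactions(
            [_fake_hit("u0", "m0", "P0")], E, G, None, check_sign=False
        )
        assert df2["replicated"].iloc[0]


def _fake_hit(utr, mi, probe, beta=0.5):
    from mirqtl.interaction import InteractionRecord

    return InteractionRecord(
        gene="G", probe_id=probe, utr_snp=utr, utr_proxy=utr,
        mi_snp=mi, mi_proxy=mi, mirna="mir-x",
        beta_int=beta, se_int=0.1, p_interaction=1e-10,
        levene_q=0.5, weight=1.0, weighted_p=1e-10, significant=True, n_used=800,
    )
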