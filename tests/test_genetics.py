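"""QC, HWE exact test, two-locus haplotype EM, LD and proxy selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from mirqtl.genetics import (
    HaplotypeFreqs,
    QcThresholds,
    _loglik,
    em_haplotype_frequencies,
    hwe_exact_test,
    ld_from_haplotypes,
    qc_filter_snps,
    select_proxy,
)

from conftest import make_genotypes, snp_record


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def hwe_exact_oracle(n_aa, n_ab, n_bb):
    """Exact HWE p by direct enumeration with binomial coefficients."""
    n = n_aa + n_ab + n_bb
    n_b = 2 * n_bb + n_ab
    n_b = min(n_b, 2 * n - n_b)
    if n_b == 0 or n == 0:
        return 1.0

    def prob(h):  # P(het = h | allele counts), unnormalized
        bb = (n_b - h) // 2
        aa = n - h - bb
        return comb(n, aa, exact=True) * comb(n - aa, bb, exact=True) * 2**h

    hets = range(n_b % 2, n_b + 1, 2)
    probs = {h: prob(h) for h in hets}
    total = sum(probs.values())
    p_obs = probs[n_ab]
    return sum(v for v in probs.values() if v <= p_obs) / total


def em_grid_oracle(g1, g2, n_grid=200_001):
    """Two-locus ML haplotype frequencies via 1-D likelihood grid search.

    With allele frequencies fixed at their MLEs, the only free parameter is
    the double-heterozygote phase fraction, parameterized by f_AB.
    """
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    m = np.isfinite(g1) & np.isfinite(g2)
    g1, g2 = g1[m], g2[m]
    q1, q2 = g1.mean() / 2, g2.mean() / 2
    p1, p2 = 1 - q1, 1 - q2
    counts = np.zeros((3, 3))
    np.add.at(counts, (g1.astype(int), g2.astype(int)), 1.0)
    lo = max(0.0, p1 + p2 - 1.0)
    hi = min(p1, p2)
    fab = np.linspace(lo, hi, n_grid)
    f = np.stack([fab, p1 - fab, p2 - fab, 1 - p1 - p2 + fab])  # 4 x grid
    f = np.clip(f, 0.0, 1.0)
    # genotype-pair probabilities per grid point
    probs = np.empty((3, 3, n_grid))
    pair_of = {
        (0, 0): (0, 0), (0, 1): (0, 1), (0, 2): (1, 1),
        (1, 0): (0, 2), (1, 2): (1, 3),
        (2, 0): (2, 2), (2, 1): (2, 3), (2, 2): (3, 3),
    }
    for (d1, d2), (i, j) in pair_of.items():
        probs[d1, d2] = (1 if i == j else 2) * f[i] * f[j]
    probs[1, 1] = 2 * f[0] * f[3] + 2 * f[1] * f[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(
            counts[..., None] > 0, counts[..., None] * np.log(probs), 0.0
        ).sum(axis=(0, 1))
    return f[:, np.argmax(ll)]


# ---------------------------------------------------------------------------
# HWE exact test and QC
# ---------------------------------------------------------------------------

class TestHweExact:
    @pytest.mark.parametrize(
        "counts",
        [(25, 50, 25), (50, 0, 50), (10, 5, 1), (0, 10, 0), (3, 0, 0), (40, 20, 40)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(hwe_exact_oracle(*counts), rel=1e-10)

    def test_equilibrium_counts_give_p_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_no_heterozygotes_is_extreme(self):
        assert hwe_exact_test(50, 0, 50) < 1e-4

    @given(
        n_aa=st.integers(0, 40), n_ab=st.integers(0, 40), n_bb=st.integers(0, 40)
    )
    @settings(max_examples=150, deadline=None)
    def test_is_a_valid_p_value_matching_oracle(self, n_aa, n_ab, n_bb):
        p = hwe_exact_test(n_aa, n_ab, n_bb)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(hwe_exact_oracle(n_aa, n_ab, n_bb), rel=1e-9)


class TestQcFilter:
    def test_filters_and_attribution(self):
        G = make_genotypes(
            {
                "ok": [0] * 25 + [1] * 50 + [2] * 25,
                "hwe_fail": [0] * 50 + [2] * 50,
                "mono": [0] * 100,
                "low_call": [0, 1] * 10 + [np.nan] * 80,
            }
        )
        res = qc_filter_snps(G, QcThresholds())
        assert list(res.genotypes.snp_ids) == ["ok"]
        assert res.removed["hwe"] == ["hwe_fail"]
        assert "mono" in res.removed["maf"]
        assert "low_call" in res.removed["call_rate"]

    def test_zero_called_snp_removed(self):
        G = make_genotypes({"all_missing": [np.nan] * 10, "ok": [0, 1, 2, 1, 0, 1, 2, 1, 0, 1]})
        res = qc_filter_snps(G, QcThresholds(call_rate_min=0.5, hwe_p_min=1e-6))
        assert "all_missing" in res.removed["maf"]

    def test_idempotent(self, rng):
        g = rng.binomial(2, 0.3, size=(200, 8)).astype(float)
        G = make_genotypes({f"rs{i}": g[:, i] for i in range(8)})
        once = qc_filter_snps(G, QcThresholds())
        twice = qc_filter_snps(once.genotypes, QcThresholds())
        assert twice.n_removed == 0
        assert list(twice.genotypes.snp_ids) == list(once.genotypes.snp_ids)

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            QcThresholds(maf_min=-0.1)


# ---------------------------------------------------------------------------
# EM haplotype frequencies
# ---------------------------------------------------------------------------

def _dosages_from_hap_pairs(pairs):
    """pairs: list of (d1, d2) tuples -> two dosage arrays."""
    arr = np.array(pairs, dtype=float)
    return arr[:, 0], arr[:, 1]


class TestEmHaplotypes:
    def test_direct_counting_when_no_double_heterozygotes(self):
        g1, g2 = _dosages_from_hap_pairs([(0, 0)] * 2 + [(2, 2)] * 2)
        h = em_haplotype_frequencies(g1, g2)
        assert np.allclose(h.as_array(), [0.5, 0, 0, 0.5], atol=1e-9)

    def test_matches_grid_oracle_with_double_heterozygotes(self):
        g1, g2 = _dosages_from_hap_pairs([(1, 1)] * 4 + [(0, 0)] * 2 + [(2, 2)] * 2)
        h = em_haplotype_frequencies(g1, g2)
        oracle = em_grid_oracle(g1, g2)
        assert np.allclose(h.as_array(), oracle, atol=1e-5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_random_data_matches_grid_oracle_and_sums_to_one(self, seed):
        r = np.random.default_rng(seed)
        g1 = r.binomial(2, r.uniform(0.15, 0.5), 60).astype(float)
        g2 = r.binomial(2, r.uniform(0.15, 0.5), 60).astype(float)
        if g1.std() == 0 or g2.std() == 0:
            return
        h = em_haplotype_frequencies(g1, g2)
        assert h.as_array().sum() == pytest.approx(1.0, abs=1e-9)
        if not h.degenerate:
            oracle = em_grid_oracle(g1, g2, n_grid=50_001)
            assert np.allclose(h.as_array(), oracle, atol=1e-4)

    def test_loglik_monotone_over_iterations(self):
        r = np.random.default_rng(7)
        g1 = r.binomial(2, 0.4, 80).astype(float)
        g2 = np.where(r.random(80) < 0.8, g1, r.binomial(2, 0.4, 80)).astype(float)
        counts = np.zeros((3, 3))
        np.add.at(counts, (g1.astype(int), g2.astype(int)), 1.0)
        lls = []
        for it in range(1, 30):
            h = em_haplotype_frequencies(g1, g2, tol=0.0, max_iter=it)
            lls.append(_loglik(counts, h.as_array()))
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_linkage_equilibrium_r2_near_zero(self):
        r = np.random.default_rng(123)
        g1 = r.binomial(2, 0.3, 5000).astype(float)
        g2 = r.binomial(2, 0.4, 5000).astype(float)
        h = em_haplotype_frequencies(g1, g2)
        assert ld_from_haplotypes(h).r2 < 0.01

    def test_monomorphic_locus_flagged_degenerate(self):
        h = em_haplotype_frequencies(np.zeros(10), np.array([0, 1, 2, 1, 0, 1, 2, 0, 1, 1], float))
        assert h.degenerate

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">=2"):
            em_haplotype_frequencies(np.array([1.0]), np.array([1.0]))


# ---------------------------------------------------------------------------
# LD statistics
# ---------------------------------------------------------------------------

class TestLd:
    @pytest.mark.parametrize(
        "freqs, expect",
        [
            ((0.5, 0.0, 0.0, 0.5), (0.25, 1.0, 1.0)),
            ((0.4, 0.1, 0.1, 0.4), (0.15, 0.6, 0.36)),
            ((0.25, 0.25, 0.25, 0.25), (0.0, 0.0, 0.0)),
        ],
    )
    def test_closed_forms(self, freqs, expect):
        ld = ld_from_haplotypes(HaplotypeFreqs(*freqs))
        assert ld.D == pytest.approx(expect[0], abs=1e-12)
        assert ld.D_prime == pytest.approx(expect[1], abs=1e-12)
        assert ld.r2 == pytest.approx(expect[2], abs=1e-12)

    def test_monomorphic_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ld_from_haplotypes(HaplotypeFreqs(0.6, 0.4, 0.0, 0.0))

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4).map(
            lambda v: tuple(np.array(v) / sum(v))
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_perfect_ld_characterization(self, freqs):
        h = HaplotypeFreqs(*freqs)
        if min(h.p_A, 1 - h.p_A, h.p_B, 1 - h.p_B) <= 1e-9:
            return
        ld = ld_from_haplotypes(h)
        assert 0.0 <= ld.D_prime <= 1.0
        assert 0.0 <= ld.r2 <= 1.0
        two_complementary = (
            np.sort(np.asarray(freqs))[:2].sum() < 1e-12
            and freqs[0] + freqs[3] > 1 - 1e-12
            or freqs[1] + freqs[2] > 1 - 1e-12
        )
        if ld.r2 > 1 - 1e-9:
            assert two_complementary


# ---------------------------------------------------------------------------
# proxy selection
# ---------------------------------------------------------------------------

def _ld_pair_dosages(rng, freqs, n):
    haps = rng.choice(4, size=(n, 2), p=np.asarray(freqs))
    d1 = np.isin(haps, (2, 3)).sum(axis=1).astype(float)
    d2 = np.isin(haps, (1, 3)).sum(axis=1).astype(float)
    return d1, d2


class TestSelectProxy:
    def test_target_is_its_own_proxy(self):
        G = make_genotypes({"rs_t": [0, 1, 2, 1]})
        prox = select_proxy(snp_record("rs_t"), ["rs_t"], G)
        assert prox.proxy_id == "rs_t" and prox.r2 == 1.0

    def test_highest_r2_candidate_wins(self, rng):
        n = 600
        d_t1, d_c1 = _ld_pair_dosages(rng, (0.5, 0.0, 0.0, 0.5), n)  # r2 = 1
        _, d_c2 = _ld_pair_dosages(rng, (0.4, 0.1, 0.1, 0.4), n)     # r2 ~ 0.36
        G = make_genotypes(
            {"rs_t": d_t1, "rs_good": d_c1, "rs_weak": d_c2},
            snps={
                "rs_t": snp_record("rs_t", pos=100),
                "rs_good": snp_record("rs_good", pos=200),
                "rs_weak": snp_record("rs_weak", pos=150),
            },
        )
        prox = select_proxy(snp_record("rs_t", pos=100), ["rs_good", "rs_weak"], G)
        assert prox.proxy_id == "rs_good"
        assert prox.r2 == pytest.approx(1.0, abs=1e-6)

    def test_none_when_below_threshold(self, rng):
        n = 600
        d_t, d_c = _ld_pair_dosages(rng, (0.4, 0.1, 0.1, 0.4), n)
        G = make_genotypes({"rs_t": d_t, "rs_c": d_c})
        assert select_proxy(snp_record("rs_t"), ["rs_c"], G, r2_min=0.90) is None

    def test_no_candidates(self):
        G = make_genotypes({"rs_t": [0, 1, 2, 1]})
        assert select_proxy(snp_record("rs_t"), [], G) is None
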