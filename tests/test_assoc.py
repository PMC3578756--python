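"""Association tests: logistic scan, Fisher exact, ESM, rank-sum,
Hotelling T^2 and the permutation framework — each checked against an
independent oracle where one exists."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ralesim import assoc
from ralesim import panels as pn


def make_panel(H, status):
    """Panel from raw haplotypes + status (metadata derived)."""
    H = np.asarray(H, np.uint8)
    dc = H.sum(axis=0)
    n = status.size
    f = dc / (2 * n)
    ctrl = np.repeat(status == 0, 2)
    cf = H[ctrl].sum(axis=0) / ctrl.sum()
    mid = f <= 0.5
    markers = pd.DataFrame({
        "position": np.linspace(0.01, 0.99, H.shape[1]),
        "effect": 0.0, "is_causative": False, "origin_generation": 0,
        "derived_count": dc, "panel_maf": np.minimum(f, 1 - f),
        "control_maf": np.where(mid, cf, 1 - cf), "minor_is_derived": mid,
    })
    return pn.CaseControlPanel(H, status.astype(np.uint8), markers)


def exact_fisher_two_sided(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration with exact
    rational arithmetic (margins fixed; sums P(table') <= P(table))."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if pk <= p_obs:
            total += pk
    return float(total)


class TestLogistic:
    def test_agrees_with_statsmodels(self, tiny_panel):
        import statsmodels.api as sm
        from scipy.stats import chi2

        pv = assoc.logistic_scan(tiny_panel, pn.RESEQ)
        y = tiny_panel.case_mask.astype(float)
        rng = np.random.default_rng(0)
        checked = 0
        for j in rng.choice(tiny_panel.n_markers, 12, replace=False):
            X = sm.add_constant(tiny_panel.dosages[:, j].astype(float))
            try:
                full = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=200)
            except Exception:
                continue  # quasi-separated marker: statsmodels Newton fails
            null = sm.Logit(y, np.ones((y.size, 1))).fit(disp=0)
            p_sm = chi2.sf(2 * (full.llf - null.llf), 1)
            assert pv[j] == pytest.approx(p_sm, rel=1e-6, abs=1e-12)
            checked += 1
        assert checked >= 5

    def test_identical_case_control_dosages_null(self):
        H = np.zeros((40, 1), np.uint8)
        H[::4] = 1  # same pattern in cases and controls
        status = np.repeat([1, 0], 10).astype(np.uint8)
        panel = make_panel(H, status)
        p = assoc.logistic_single_marker(panel, 0)
        assert p > 0.9

    def test_perfect_separation_handled(self):
        # carried by every case, absent from every control
        status = np.repeat([1, 0], 10).astype(np.uint8)
        H = np.zeros((40, 1), np.uint8)
        H[:20] = 1
        panel = make_panel(H, status)
        p = assoc.logistic_single_marker(panel, 0)
        assert np.isfinite(p)
        assert p < 1e-6

    def test_monomorphic_marker_rejected(self):
        status = np.repeat([1, 0], 5).astype(np.uint8)
        H = np.ones((20, 1), np.uint8)
        panel = make_panel(H, status)
        panel.dosages[:] = 2
        with pytest.raises(ValueError):
            assoc.logistic_single_marker(panel, 0)


class TestFisher:
    def test_balanced_table_p_one(self):
        # table [[10,10],[10,10]]
        assert exact_fisher_two_sided(10, 10, 10, 10) == pytest.approx(1.0)

    def test_worked_table(self):
        # allele table [[12,388],[3,397]]: enumeration oracle vs scipy
        p = exact_fisher_two_sided(12, 388, 3, 397)
        assert p == pytest.approx(0.0335006093, abs=1e-9)
        from scipy.stats import fisher_exact
        assert p == pytest.approx(fisher_exact([[12, 388], [3, 397]])[1], rel=1e-9)

    def test_scan_matches_enumeration_oracle(self, tiny_panel):
        idx = np.arange(min(tiny_panel.n_markers, 25))
        pv = assoc.fisher_scan(tiny_panel, idx)
        case = tiny_panel.case_mask
        n1a = 2 * int(case.sum())
        n0a = 2 * int((~case).sum())
        D = tiny_panel.dosages
        for i, j in enumerate(idx):
            k1 = int(D[case, j].sum())
            k0 = int(D[~case, j].sum())
            oracle = exact_fisher_two_sided(k1, n1a - k1, k0, n0a - k0)
            assert pv[i] == pytest.approx(oracle, rel=1e-6)

    def test_symmetric_under_label_swap(self, tiny_panel):
        j = 0
        p1 = assoc.fisher_exact_allele_test(tiny_panel, j)
        flipped = pn.CaseControlPanel(tiny_panel.haplotypes,
                                      1 - tiny_panel.status,
                                      tiny_panel.markers)
        p2 = assoc.fisher_exact_allele_test(flipped, j)
        assert p1 == pytest.approx(p2)


class TestESM:
    def test_null_expectation_identity(self):
        L = 9
        p = np.arange(1, L + 1) / (L + 1)
        assert assoc.esm_statistic(p, M=5) == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        # L=9 unique markers, two signals at 0.001 and 0.01, the rest at
        # their null-expected order statistics
        p = np.array([0.001, 0.01] + [i / 10 for i in range(3, 10)])
        z2 = assoc.esm_statistic(p, M=2)
        assert z2 == pytest.approx(3.3010, abs=1e-4)

    def test_monotone_in_each_pvalue(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(0.01, 1, 12))
        base = assoc.esm_statistic(p, M=5)
        p2 = p.copy()
        p2[3] = p2[3] / 2
        assert assoc.esm_statistic(p2, M=5) > base

    def test_invariant_to_marker_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.001, 1, 20)
        z = assoc.esm_statistic(p, M=7)
        assert assoc.esm_statistic(rng.permutation(p), M=7) == pytest.approx(z)

    @given(st.integers(min_value=1, max_value=20))
    @settings(max_examples=30, derandomize=True)
    def test_m_truncation(self, M):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.001, 1, 10)
        z = assoc.esm_statistic(p, M=M)
        assert np.isfinite(z)

    def test_empty_pvector_rejected(self):
        with pytest.raises(ValueError):
            assoc.esm_statistic(np.array([]), M=5)


class TestMadsenBrowning:
    def test_all_zero_dosages_tie_average(self):
        D = np.zeros((10, 3))
        case = np.repeat([True, False], 5)
        stat = assoc.madsen_browning_ranksum(D, case)
        # all scores tie -> every rank is (n+1)/2 -> case sum = n1(n+1)/2
        assert stat == pytest.approx(5 * 11 / 2)

    def test_case_only_variant_raises_rank_sum(self):
        case = np.repeat([True, False], 10)
        D = np.zeros((20, 1))
        D[:4, 0] = 1  # four case carriers
        stat = assoc.madsen_browning_ranksum(D, case)
        assert stat > 10 * 21 / 2

    def test_batch_matches_single(self, tiny_panel):
        t = assoc.MadsenBrowningTest(tiny_panel, pn.RESEQ)
        rng = np.random.default_rng(3)
        perms = rng.permuted(np.tile(tiny_panel.status, (5, 1)), axis=1)
        batch = t.batch(perms)
        for i in range(5):
            assert batch[i] == pytest.approx(t.observed(perms[i].astype(bool)))


class TestLiLeal:
    def test_identical_groups_zero_statistic(self):
        rng = np.random.default_rng(0)
        block = (rng.random((10, 4)) < 0.3).astype(float)
        D = np.vstack([block, block])  # cases exactly mirror controls
        case = np.repeat([True, False], 10)
        assert assoc.li_leal_hotelling(D, case) == pytest.approx(0.0, abs=1e-9)

    def test_k1_reduces_to_squared_t_statistic(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, 30).astype(float)
        case = rng.random(30) < 0.5
        if case.sum() in (0, 30):
            case[0] = ~case[0]
        t2 = assoc.li_leal_hotelling(d[:, None], case)
        x1, x0 = d[case] - 1, d[~case] - 1
        n1, n0 = x1.size, x0.size
        sp2 = ((n1 - 1) * x1.var(ddof=1) + (n0 - 1) * x0.var(ddof=1)) / (n1 + n0 - 2)
        t_sq = (x1.mean() - x0.mean()) ** 2 / (sp2 * (1 / n1 + 1 / n0))
        assert t2 == pytest.approx(t_sq, rel=1e-9)

    def test_batch_matches_single(self, tiny_panel):
        t = assoc.LiLealTest(tiny_panel, K=10, flt=pn.RESEQ)
        rng = np.random.default_rng(4)
        perms = rng.permuted(np.tile(tiny_panel.status, (5, 1)), axis=1)
        batch = t.batch(perms)
        for i in range(5):
            assert batch[i] == pytest.approx(t.observed(perms[i].astype(bool)), rel=1e-8)

    def test_uses_rarest_markers(self, tiny_panel):
        t = assoc.LiLealTest(tiny_panel, K=5, flt=pn.RESEQ)
        maf = tiny_panel.markers["panel_maf"].to_numpy()
        assert maf[t._idx].max() <= np.sort(maf)[4] + 1e-12


class TestESMBatchConsistency:
    def test_batch_matches_single(self, tiny_panel):
        t = assoc.ESMTest(tiny_panel, pn.RESEQ, assoc.ESMConfig(M=10))
        rng = np.random.default_rng(5)
        perms = rng.permuted(np.tile(tiny_panel.status, (5, 1)), axis=1)
        batch = t.batch(perms)
        for i in range(5):
            assert batch[i] == pytest.approx(t.observed(perms[i].astype(bool)), rel=1e-6)

    def test_observed_equals_direct_fisher_esm(self, tiny_panel):
        """ESM machinery (lookup tables) reproduces the statistic computed
        from scratch with per-marker Fisher tests."""
        cfg = assoc.ESMConfig(M=10)
        t = assoc.ESMTest(tiny_panel, pn.RESEQ, cfg)
        flt = pn.MarkerFilter(study_type="resequencing",
                              min_minor_count=cfg.min_minor_count)
        idx = pn.filter_markers(tiny_panel, flt, collapse_redundant=True)
        pv = np.array([assoc.fisher_exact_allele_test(tiny_panel, j) for j in idx])
        direct = assoc.esm_statistic(pv, M=10)
        assert t.observed(tiny_panel.case_mask) == pytest.approx(direct, rel=1e-6)


class TestPermutationFramework:
    def test_label_invariant_statistic_gives_null(self, tiny_panel):
        class Constant:
            name = "const"
            def observed(self, mask):
                return 42.0
            def batch(self, masks):
                return np.full(masks.shape[0], 42.0)

        res = assoc.permutation_test(tiny_panel, Constant(), n_perm=50,
                                     rng=np.random.default_rng(0))
        assert res.z == 0.0
        assert res.p == 1.0

    def test_deterministic_given_seed(self, tiny_panel):
        t = assoc.ESMTest(tiny_panel, pn.RESEQ, assoc.ESMConfig(M=10))
        r1 = assoc.permutation_test(tiny_panel, t, n_perm=100,
                                    rng=np.random.default_rng(7))
        r2 = assoc.permutation_test(tiny_panel, t, n_perm=100,
                                    rng=np.random.default_rng(7))
        assert r1 == r2

    def test_result_invariants(self, tiny_panel):
        t = assoc.MadsenBrowningTest(tiny_panel, pn.RESEQ)
        res = assoc.permutation_test(tiny_panel, t, n_perm=200,
                                     rng=np.random.default_rng(8))
        assert res.z == pytest.approx((res.observed - res.perm_mean) / res.perm_sd)
        from scipy.stats import norm
        assert res.p == pytest.approx(2 * norm.sf(abs(res.z)))
        assert 0 < res.p <= 1
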