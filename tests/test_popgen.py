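import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rainpop.popgen import (
    allele_stats,
    holm_adjust,
    hwe_test,
    jackknife_ci,
    ld_test,
    multilocus_theta,
    sex_ratio_test,
    wc_components,
    wc_fst,
)
from tests.conftest import make_gm


# ---------------------------------------------------------------------------
# diversity summaries
# ---------------------------------------------------------------------------

def test_allele_stats_all_heterozygotes():
    # 10 individuals all Aa: H_O = 1, unbiased H_E = 2n/(2n-1)*(1-0.5) = 10/19
    gm = make_gm({"s": [[(1, 2)]] * 10})
    row = allele_stats(gm, by_site=False).iloc[0]
    assert row.h_obs == 1.0
    assert row.h_exp == pytest.approx(10 / 19)
    assert row.f_is == pytest.approx(1 - 1 / (10 / 19))
    assert row.f_is < 0


def test_allele_stats_monomorphic_fis_missing():
    gm = make_gm({"s": [[(1, 1)]] * 8})
    row = allele_stats(gm, by_site=False).iloc[0]
    assert row.n_alleles == 1 and row.h_exp == 0.0
    assert np.isnan(row.f_is)


def test_allele_stats_excludes_missing():
    gm = make_gm({"s": [[(1, 2)]] * 4 + [[(0, 0)]] * 3})
    row = allele_stats(gm, by_site=False).iloc[0]
    assert row.n_typed == 4


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _hand_theta_two_site_biallelic(n, p, h):
    """Independent arithmetic for the 1984 components: 2 sites, 1 biallelic locus.

    n, p, h: per-site sample sizes, allele-A frequencies, observed het freqs.
    """
    r = 2
    nbar = sum(n) / r
    nc = (sum(n) - sum(x * x for x in n) / sum(n)) / (r - 1)
    total_a = total_b = total_c = 0.0
    for p_i, h_i in (((p[0], p[1]), (h[0], h[1])), ((1 - p[0], 1 - p[1]), (h[0], h[1]))):
        pbar = sum(n[i] * p_i[i] for i in range(r)) / (r * nbar)
        s2 = sum(n[i] * (p_i[i] - pbar) ** 2 for i in range(r)) / ((r - 1) * nbar)
        hbar = sum(n[i] * h_i[i] for i in range(r)) / (r * nbar)
        a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        total_a += a
        total_b += b
        total_c += c
    return total_a / (total_a + total_b + total_c)


def test_theta_matches_hand_oracle(two_site_toy):
    theta = wc_fst(two_site_toy, ci=False).theta
    oracle = _hand_theta_two_site_biallelic(n=(10, 10), p=(0.75, 0.25), h=(0.5, 0.5))
    assert theta == pytest.approx(oracle, abs=1e-10)


def test_theta_fixed_difference_is_one():
    gm = make_gm({"A": [[(1, 1)]] * 10, "B": [[(2, 2)]] * 10})
    assert wc_fst(gm, ci=False).theta == pytest.approx(1.0)


def test_theta_identical_collections_nonpositive():
    block = [[(1, 1)]] * 5 + [[(1, 2)]] * 5
    gm = make_gm({"A": block, "B": block})
    assert wc_fst(gm, ci=False).theta <= 0


def test_theta_invariant_to_allele_relabeling_and_site_order(two_site_toy):
    base = wc_fst(two_site_toy, ci=False).theta
    relabeled = two_site_toy.subset(np.ones(two_site_toy.n_individuals, bool))
    g = relabeled.genotypes.copy()
    g[g == 1], g[g == 2] = 7, 3  # swap labels to arbitrary codes
    relabeled.genotypes = np.sort(g, axis=2)
    assert wc_fst(relabeled, ci=False).theta == pytest.approx(base, abs=1e-12)
    flipped = wc_fst(two_site_toy, sites=["B", "A"], ci=False).theta
    assert flipped == pytest.approx(base, abs=1e-12)


def test_theta_monomorphic_undefined():
    gm = make_gm({"A": [[(1, 1)]] * 5, "B": [[(1, 1)]] * 5})
    assert np.isnan(wc_fst(gm, ci=False).theta)


def test_missing_handled_locus_wise():
    # locus 2 entirely missing in site B must not poison locus 1
    gm = make_gm(
        {
            "A": [[(1, 1), (1, 2)]] * 6,
            "B": [[(2, 2), (0, 0)]] * 6,
        }
    )
    res = wc_fst(gm, ci=False)
    assert res.components.loc[0, "theta"] == pytest.approx(1.0)
    assert np.isnan(res.components.loc[1, "theta"]) or res.components.loc[1, ["a", "b", "c"]].sum() == 0


# ---------------------------------------------------------------------------
# jackknife
# ---------------------------------------------------------------------------

def test_jackknife_identical_loci_zero_width():
    comp = np.tile([[0.02, 0.1, 0.3]], (5, 1))
    lo, hi = jackknife_ci(comp)
    theta = multilocus_theta(comp)
    assert lo == pytest.approx(theta, abs=1e-12)
    assert hi == pytest.approx(theta, abs=1e-12)


def test_jackknife_contains_full_estimate():
    rng = np.random.default_rng(3)
    comp = np.abs(rng.normal(0.05, 0.02, size=(10, 3))) + 0.01
    lo, hi = jackknife_ci(comp)
    assert lo < multilocus_theta(comp) < hi


def test_jackknife_requires_three_loci():
    with pytest.raises(ValueError):
        jackknife_ci(np.array([[0.1, 0.2, 0.3], [0.1, 0.2, 0.3]]))


def test_delete_one_matches_recompute(two_site_toy):
    # jackknife leave-one-out equals recomputation without the locus
    gm = make_gm(
        {
            "A": [[(1, 1), (1, 2), (2, 2)]] * 5 + [[(1, 2), (1, 1), (1, 2)]] * 5,
            "B": [[(1, 2), (2, 2), (1, 2)]] * 5 + [[(2, 2), (1, 2), (1, 1)]] * 5,
        }
    )
    pops = np.array([0] * 10 + [1] * 10)
    comp = wc_components(gm.genotypes, pops)
    for drop in range(3):
        keep = [j for j in range(3) if j != drop]
        direct = multilocus_theta(wc_components(gm.genotypes[:, keep, :], pops))
        loo = multilocus_theta(comp[keep])
        assert direct == pytest.approx(loo, abs=1e-12)


# ---------------------------------------------------------------------------
# HWE / LD permutation tests
# ---------------------------------------------------------------------------

def test_hwe_extreme_heterozygote_excess():
    gm = make_gm({"s": [[(1, 2)]] * 50})
    rec = hwe_test(gm, "L1", "s", n_perm=2000, seed=7)
    assert rec.p < 0.01


def test_hwe_proportioned_table_large_p():
    gm = make_gm({"s": [[(1, 1)]] * 25 + [[(1, 2)]] * 50 + [[(2, 2)]] * 25})
    rec = hwe_test(gm, "L1", "s", n_perm=2000, seed=7)
    assert rec.p > 0.5


def test_hwe_skips_monomorphic_and_tiny():
    gm = make_gm({"s": [[(1, 1)]] * 10})
    assert hwe_test(gm, "L1", "s").skipped
    gm2 = make_gm({"s": [[(1, 2)]] * 3})
    assert hwe_test(gm2, "L1", "s").skipped


def _enumerate_pairings(copies):
    """All perfect matchings of the allele copies (uniform over matchings)."""
    idx = list(range(len(copies)))

    def rec(remaining):
        if not remaining:
            yield []
            return
        first, rest = remaining[0], remaining[1:]
        for k, other in enumerate(rest):
            for tail in rec(rest[:k] + rest[k + 1:]):
                yield [(first, other)] + tail

    for matching in rec(idx):
        yield [tuple(sorted((copies[i], copies[j]))) for i, j in matching]


def test_hwe_monte_carlo_matches_enumeration():
    # n = 5, two alleles: exhaustive oracle over all 9!! = 945 re-pairings
    genos = [[(1, 1)], [(1, 2)], [(1, 2)], [(2, 2)], [(1, 2)]]
    gm = make_gm({"s": genos})
    from scipy.special import gammaln

    copies = [a for g in genos for a in g[0]]
    counts = np.bincount(copies)[1:]
    n = len(genos)

    def log_prob(pairs):
        from collections import Counter

        c = Counter(pairs)
        het = sum(v for k, v in c.items() if k[0] != k[1])
        lognab = sum(float(gammaln(v + 1)) for v in c.values())
        return (
            float(gammaln(n + 1) + gammaln(counts + 1).sum())
            + het * np.log(2.0)
            - float(gammaln(2 * n + 1))
            - lognab
        )

    obs = log_prob([tuple(sorted(g[0])) for g in genos])
    all_lp = [log_prob(p) for p in _enumerate_pairings(copies)]
    p_exact = np.mean([lp <= obs + 1e-12 for lp in all_lp])
    rec = hwe_test(gm, "L1", "s", n_perm=20000, seed=11)
    assert rec.p == pytest.approx(p_exact, abs=0.02)


def test_ld_perfect_association():
    rng = np.random.default_rng(5)
    genos = []
    for _ in range(40):
        g = tuple(sorted(rng.integers(1, 4, size=2)))
        genos.append([g, g])  # locus B copies locus A
    gm = make_gm({"s": genos})
    rec = ld_test(gm, "L1", "L2", "s", n_perm=2000, seed=2)
    assert rec.p < 0.01


def test_ld_skips_tiny_sample():
    gm = make_gm({"s": [[(1, 2), (1, 2)]] * 2})
    assert ld_test(gm, "L1", "L2", "s").skipped


# ---------------------------------------------------------------------------
# Holm and sex ratio
# ---------------------------------------------------------------------------

def test_holm_sequential_rule():
    rejects = holm_adjust([0.001, 0.04], alpha=0.05)
    assert rejects.tolist() == [True, True]  # 0.001 < 0.025 then 0.04 < 0.05
    rejects = holm_adjust([0.04, 0.03], alpha=0.05)
    assert rejects.tolist() == [False, False]  # 0.03 >= 0.025 stops the scan


def test_holm_single_and_degenerate():
    assert holm_adjust([0.04]).tolist() == [True]
    assert holm_adjust([1.0, 1.0, 1.0]).tolist() == [False, False, False]
    assert holm_adjust([]).tolist() == []


@given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=20))
def test_holm_rejections_have_small_p(pvals):
    rejects = holm_adjust(pvals, alpha=0.05)
    m = len(pvals)
    # any rejected p must be below its own sequential threshold
    order = np.argsort(pvals, kind="stable")
    for rank, idx in enumerate(order):
        if rejects[idx]:
            assert pvals[idx] < 0.05 / (m - rank)


@pytest.mark.parametrize(
    "nm,nf,expect", [(50, 50, 0.0), (60, 40, 4.0), (75, 25, 25.0)]
)
def test_sex_ratio_chi_square(nm, nf, expect):
    stat, p = sex_ratio_test(nm, nf)
    assert stat == pytest.approx(expect)
    if expect == 0.0:
        assert p == pytest.approx(1.0)


def test_sex_ratio_requires_counts():
    with pytest.raises(ValueError):
        sex_ratio_test(0, 0)
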