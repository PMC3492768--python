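"""Classical population-genetic statistics on codominant genotype matrices.

Implements per-locus diversity summaries (N_A, H_E, H_O, F_IS), Monte-Carlo
exact tests of Hardy-Weinberg equilibrium and genotypic linkage
disequilibrium, the Weir & Cockerham (1984) variance-component estimator of
F_ST (theta) with a delete-one-locus jackknife confidence interval, and
sequential-Bonferroni (Holm) multiple-testing decisions.

Missing data are handled locus-wise: an individual missing at a locus is
excluded from that locus only, so sample sizes vary across loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .datatypes import GenotypeMatrix

__all__ = [
    "allele_stats",
    "hwe_test",
    "ld_test",
    "wc_fst",
    "pairwise_fst",
    "jackknife_ci",
    "holm_adjust",
    "sex_ratio_test",
    "FstResult",
    "TestRecord",
]


# ---------------------------------------------------------------------------
# diversity summaries
# ---------------------------------------------------------------------------

def _locus_summary(genos: np.ndarray) -> dict:
    """Summaries for one locus: genos is (n, 2) with 0 = missing."""
    typed = (genos > 0).all(axis=1)
    g = genos[typed]
    n = len(g)
    if n == 0:
        return dict(n_typed=0, n_alleles=0, h_exp=np.nan, h_obs=np.nan, f_is=np.nan)
    alleles, counts = np.unique(g.ravel(), return_counts=True)
    p = counts / counts.sum()
    h_obs = float((g[:, 0] != g[:, 1]).mean())
    # unbiased gene diversity: 2n/(2n-1) * (1 - sum p^2)
    h_exp = float(2 * n / (2 * n - 1) * (1.0 - (p**2).sum())) if n > 0 else np.nan
    if h_exp > 0:
        f_is = 1.0 - h_obs / h_exp
    else:
        f_is = np.nan  # monomorphic: F_IS undefined, not zero
    return dict(
        n_typed=n, n_alleles=len(alleles), h_exp=h_exp, h_obs=h_obs, f_is=f_is
    )


def allele_stats(gm: GenotypeMatrix, by_site: bool = True) -> pd.DataFrame:
    """Per-locus N_A, H_E (unbiased), H_O and F_IS, by site and globally.

    Returns a tidy frame with one row per locus x site plus a ``"global"``
    row per locus.  F_IS is reported as 1 - H_O/H_E (Nei's form) and is NaN
    for monomorphic cells.
    """
    rows = []
    scopes: list[tuple[str, np.ndarray]] = [("global", np.ones(gm.n_individuals, bool))]
    if by_site:
        scopes += [(s, gm.sites == s) for s in gm.site_names]
    for scope, mask in scopes:
        for j, locus in enumerate(gm.locus_names):
            rows.append(
                dict(locus=locus, site=scope, **_locus_summary(gm.genotypes[mask, j, :]))
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation test records
# ---------------------------------------------------------------------------

@dataclass
class TestRecord:
    """Outcome of one permutation test (add-one p estimator, p > 0)."""

    name: str
    unit: str
    p: float
    n_permutations: int
    statistic: float = np.nan
    skipped: bool = False
    reason: str = ""


def _log_table_prob(geno_counts: np.ndarray, allele_counts: np.ndarray, n: int) -> float:
    """Log conditional probability of a genotype table given allele counts.

    Levene's formula: P = n! * prod(m_a!) * 2^H / ((2n)! * prod(n_ab!)),
    with H the number of heterozygotes.
    """
    het = int(geno_counts["het"])
    return float(
        gammaln(n + 1)
        + gammaln(allele_counts + 1).sum()
        + het * np.log(2.0)
        - gammaln(2 * n + 1)
        - geno_counts["lognab"]
    )


def _geno_table_stats(pairs: np.ndarray, n_alleles: int) -> dict:
    """pairs: (n, 2) sorted allele indices.  Returns het count and sum log n_ab!."""
    codes = pairs[:, 0] * n_alleles + pairs[:, 1]
    counts = np.bincount(codes, minlength=n_alleles * n_alleles)
    return dict(
        het=int((pairs[:, 0] != pairs[:, 1]).sum()),
        lognab=float(gammaln(counts + 1).sum()),
    )


def hwe_test(
    gm: GenotypeMatrix,
    locus: str,
    site: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> TestRecord:
    """Monte-Carlo exact test of Hardy-Weinberg equilibrium at one locus/site.

    The test statistic is the conditional probability of the observed
    genotype table given the allele counts; the null distribution is built
    by shuffling the 2n allele copies and re-pairing them.  The p-value uses
    the add-one estimator (1 + k) / (1 + n_perm).
    """
    unit = f"{locus}@{site}"
    mask = gm.sites == site
    j = int(np.flatnonzero(gm.locus_names == locus)[0])
    genos = gm.genotypes[mask, j, :]
    genos = genos[(genos > 0).all(axis=1)]
    n = len(genos)
    if n < 5:
        return TestRecord("hwe", unit, np.nan, 0, skipped=True, reason="fewer than 5 typed individuals")
    alleles = np.unique(genos.ravel())
    if len(alleles) < 2:
        return TestRecord("hwe", unit, np.nan, 0, skipped=True, reason="monomorphic locus")
    # map to 0..A-1 indices
    lut = {a: i for i, a in enumerate(alleles)}
    idx = np.vectorize(lut.get)(genos)
    idx = np.sort(idx, axis=1)
    n_all = len(alleles)
    allele_counts = np.bincount(idx.ravel(), minlength=n_all)

    obs = _log_table_prob(_geno_table_stats(idx, n_all), allele_counts, n)
    copies = idx.ravel()
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_perm):
        perm = rng.permutation(copies).reshape(n, 2)
        perm.sort(axis=1)
        lp = _log_table_prob(_geno_table_stats(perm, n_all), allele_counts, n)
        if lp <= obs + 1e-12:
            k += 1
    p = (1 + k) / (1 + n_perm)
    return TestRecord("hwe", unit, p, n_perm, statistic=obs)


def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio G for independence on a contingency table."""
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    n = table.sum()
    if n == 0 or min(table.shape) < 2:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    obs = table[table > 0]
    exp = expected[table > 0]
    return float(2.0 * (obs * np.log(obs / exp)).sum())


def ld_test(
    gm: GenotypeMatrix,
    locus_a: str,
    locus_b: str,
    site: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> TestRecord:
    """Genotypic linkage-disequilibrium test for a locus pair within a site.

    Statistic is the G (log-likelihood-ratio) on the genotype x genotype
    contingency table; the null distribution permutes one locus's genotypes
    across individuals within the site.
    """
    unit = f"{locus_a}x{locus_b}@{site}"
    mask = gm.sites == site
    ja = int(np.flatnonzero(gm.locus_names == locus_a)[0])
    jb = int(np.flatnonzero(gm.locus_names == locus_b)[0])
    ga = gm.genotypes[mask, ja, :]
    gb = gm.genotypes[mask, jb, :]
    ok = (ga > 0).all(axis=1) & (gb > 0).all(axis=1)
    ga, gb = ga[ok], gb[ok]
    n = len(ga)
    if n < 5:
        return TestRecord("ld", unit, np.nan, 0, skipped=True, reason="fewer than 5 individuals typed at both loci")

    def _codes(g: np.ndarray) -> np.ndarray:
        pairs = [tuple(r) for r in g]
        uniq = sorted(set(pairs))
        lut = {u: i for i, u in enumerate(uniq)}
        return np.array([lut[p] for p in pairs]), len(uniq)

    ca, ka = _codes(ga)
    cb, kb = _codes(gb)
    if ka < 2 or kb < 2:
        return TestRecord("ld", unit, np.nan, 0, skipped=True, reason="fewer than 2 distinct genotypes at a locus")

    def _g(cb_perm: np.ndarray) -> float:
        table = np.zeros((ka, kb))
        np.add.at(table, (ca, cb_perm), 1.0)
        return _g_statistic(table)

    obs = _g(cb)
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_perm):
        if _g(rng.permutation(cb)) >= obs - 1e-12:
            k += 1
    p = (1 + k) / (1 + n_perm)
    return TestRecord("ld", unit, p, n_perm, statistic=obs)


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    """Weir-Cockerham variance components and theta estimates."""

    scope: str
    locus_names: list[str]
    components: pd.DataFrame  # locus, a, b, c, theta
    theta: float
    ci: tuple[float, float] | None = None

    def linearized(self) -> float:
        return self.theta / (1.0 - self.theta)


def wc_components(genotypes: np.ndarray, pops: np.ndarray) -> np.ndarray:
    """Per-locus Weir-Cockerham variance components.

    Parameters
    ----------
    genotypes : int array (n, L, 2), allele codes > 0, 0 = missing
    pops : int array (n,), population index 0..r-1

    Returns
    -------
    (L, 3) array of per-locus components (a, b, c) summed over alleles.
    Loci where fewer than 2 populations have typed individuals, or where the
    locus is monomorphic, yield components that sum to 0 (theta undefined).
    """
    n, L, _ = genotypes.shape
    r = int(pops.max()) + 1 if n else 0
    amax = int(genotypes.max()) if n else 0
    if amax == 0:
        return np.zeros((L, 3))
    typed = (genotypes > 0).all(axis=2)  # (n, L)

    # allele-copy counts per (pop, locus, allele) and het-carrier counts
    counts = np.zeros((r, L, amax))
    hets = np.zeros((r, L, amax))
    ii, jj = np.nonzero(typed)
    pp = pops[ii]
    a1 = genotypes[ii, jj, 0] - 1
    a2 = genotypes[ii, jj, 1] - 1
    np.add.at(counts, (pp, jj, a1), 1.0)
    np.add.at(counts, (pp, jj, a2), 1.0)
    is_het = a1 != a2
    np.add.at(hets, (pp[is_het], jj[is_het], a1[is_het]), 1.0)
    np.add.at(hets, (pp[is_het], jj[is_het], a2[is_het]), 1.0)

    n_il = np.zeros((r, L))  # typed individuals per pop x locus
    np.add.at(n_il, (pp, jj), 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        p_ila = counts / (2.0 * n_il)[:, :, None]  # freq per pop/locus/allele
        h_ila = hets / n_il[:, :, None]  # observed het freq carrying allele

    present = n_il > 0  # (r, L)
    r_l = present.sum(axis=0).astype(float)  # pops with data per locus
    nsum = n_il.sum(axis=0)  # (L,)
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = nsum / r_l
        nc = (nsum - (n_il**2).sum(axis=0) / nsum) / (r_l - 1.0)

        w = np.where(present, n_il, 0.0)[:, :, None]  # weights, zero for absent pops
        p_ila = np.where(present[:, :, None], p_ila, 0.0)
        h_ila = np.where(present[:, :, None], h_ila, 0.0)

        pbar = (w * p_ila).sum(axis=0) / (r_l * nbar)[:, None]  # (L, A)
        s2 = (w * (p_ila - pbar[None]) ** 2).sum(axis=0) / ((r_l - 1.0) * nbar)[:, None]
        hbar = (w * h_ila).sum(axis=0) / (r_l * nbar)[:, None]

        rl = r_l[:, None]
        nb = nbar[:, None]
        ncc = nc[:, None]
        inner = pbar * (1 - pbar) - (rl - 1.0) / rl * s2 - hbar / 4.0
        a = nb / ncc * (s2 - inner / (nb - 1.0))
        b = nb / (nb - 1.0) * (pbar * (1 - pbar) - (rl - 1.0) / rl * s2
                               - (2 * nb - 1) / (4 * nb) * hbar)
        c = hbar / 2.0

    # zero out undefined loci (fewer than 2 pops with data, or nbar <= 1)
    bad = (r_l < 2) | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    for comp in (a, b, c):
        comp[bad, :] = 0.0
        comp[~np.isfinite(comp)] = 0.0
    return np.stack([a.sum(axis=1), b.sum(axis=1), c.sum(axis=1)], axis=1)


def multilocus_theta(components: np.ndarray) -> float:
    """Ratio-of-sums theta = sum(a) / sum(a+b+c); NaN when denominator is 0."""
    num = components[:, 0].sum()
    den = components.sum()
    return float(num / den) if den != 0 else float("nan")


def jackknife_ci(components: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Delete-one-locus jackknife CI for the multi-locus theta.

    Pseudovalues ``L*theta - (L-1)*theta_(-l)`` are formed from the
    delete-one ratio-of-sums estimates; the interval is their mean
    +/- z * jackknife SE.  Requires >= 3 informative loci.
    """
    keep = components.sum(axis=1) != 0
    comp = components[keep]
    L = len(comp)
    if L < 3:
        raise ValueError("jackknife CI requires >= 3 loci with defined components")
    theta_all = multilocus_theta(comp)
    tot = comp.sum(axis=0)
    loo = np.array(
        [
            (tot[0] - comp[l, 0]) / (tot.sum() - comp[l].sum())
            if (tot.sum() - comp[l].sum()) != 0
            else np.nan
            for l in range(L)
        ]
    )
    pseudo = L * theta_all - (L - 1) * loo
    mean = float(np.nanmean(pseudo))
    se = float(np.sqrt(np.nanvar(pseudo, ddof=1) / L))
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    return (mean - z * se, mean + z * se)


def wc_fst(
    gm: GenotypeMatrix,
    sites: list[str] | None = None,
    loci: list[str] | None = None,
    ci: bool = True,
) -> FstResult:
    """Multi-locus Weir-Cockerham theta over the selected sites and loci.

    Individuals missing at a locus are dropped from that locus only; the
    95% CI jackknifes over loci when at least 3 are informative.
    """
    if sites is None:
        sites = gm.site_names
    mask = np.isin(gm.sites, sites)
    if loci is not None:
        lidx = np.array([int(np.flatnonzero(gm.locus_names == l)[0]) for l in loci])
        sub = gm.subset(mask, lidx)
    else:
        sub = gm.subset(mask)
    site_lut = {s: i for i, s in enumerate(sites)}
    pops = np.array([site_lut[s] for s in sub.sites])
    per_site_n = np.bincount(pops, minlength=len(sites))
    if (per_site_n >= 2).sum() < 2:
        raise ValueError("need >= 2 sites with >= 2 typed individuals")
    comp = wc_components(sub.genotypes, pops)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_locus_theta = np.where(
            comp.sum(axis=1) != 0, comp[:, 0] / comp.sum(axis=1), np.nan
        )
    df = pd.DataFrame(
        dict(
            locus=list(sub.locus_names),
            a=comp[:, 0],
            b=comp[:, 1],
            c=comp[:, 2],
            theta=per_locus_theta,
        )
    )
    theta = multilocus_theta(comp)
    interval = None
    if ci and (comp.sum(axis=1) != 0).sum() >= 3:
        interval = jackknife_ci(comp)
    scope = "global" if set(sites) == set(gm.site_names) else "+".join(sites)
    return FstResult(scope, list(sub.locus_names), df, theta, interval)


def pairwise_fst(gm: GenotypeMatrix, ci: bool = False) -> pd.DataFrame:
    """Theta for every site pair; tidy frame (site_i, site_j, theta)."""
    names = gm.site_names
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = wc_fst(gm, sites=[names[i], names[j]], ci=ci)
            rows.append(dict(site_i=names[i], site_j=names[j], theta=res.theta))
    return pd.DataFrame(rows)


def pairwise_fst_matrix(gm: GenotypeMatrix) -> tuple[list[str], np.ndarray]:
    """Square symmetric matrix of pairwise theta (diagonal 0)."""
    names = gm.site_names
    k = len(names)
    m = np.zeros((k, k))
    tidy = pairwise_fst(gm)
    lut = {n: i for i, n in enumerate(names)}
    for _, row in tidy.iterrows():
        i, j = lut[row.site_i], lut[row.site_j]
        m[i, j] = m[j, i] = row.theta
    return names, m


# ---------------------------------------------------------------------------
# multiple testing & counts
# ---------------------------------------------------------------------------

def holm_adjust(p_values, alpha: float = 0.05) -> np.ndarray:
    """Sequential Bonferroni (Holm/Rice) reject decisions, input order preserved.

    Sort p ascending; compare p_(k) to alpha/(m-k+1); stop at the first
    failure — everything after it is retained.
    """
    p = np.asarray(list(p_values), dtype=float)
    m = len(p)
    reject = np.zeros(m, dtype=bool)
    if m == 0:
        return reject
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    for k, idx in enumerate(order):
        if p[idx] < alpha / (m - k):
            reject[idx] = True
        else:
            break
    return reject


def sex_ratio_test(n_male: int, n_female: int) -> tuple[float, float]:
    """Chi-square goodness of fit against a 1:1 sex ratio (1 df)."""
    total = n_male + n_female
    if total <= 0:
        raise ValueError("total count must be positive")
    expected = total / 2.0
    stat = (n_male - expected) ** 2 / expected + (n_female - expected) ** 2 / expected
    return float(stat), float(chi2.sf(stat, df=1))
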