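"""Sex-biased dispersal tests and isolation-by-distance inference.

Assignment indices (AI/AIc) follow the corrected assignment-index approach:
AI is the log10 probability of an individual's multilocus genotype under its
own site's allele frequencies (leave-one-out, with a floor for unseen
alleles), AIc centers AI within each site.  Sex-bias tests permute sex
labels within sites.  Isolation by distance uses the Rousset linearization
theta/(1-theta) against log distance with a Mantel permutation test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix
from .popgen import multilocus_theta, wc_components

__all__ = [
    "assignment_index",
    "sex_bias_test",
    "linearize_fst",
    "mantel",
    "SexBiasTestResult",
    "MantelResult",
]


def assignment_index(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-individual assignment index AI and its site-centered AIc.

    AI sums, over the individual's non-missing loci, log10 of the expected
    genotype frequency at its own site (p^2 for homozygotes, 2pq for
    heterozygotes).  Frequencies are computed leave-one-out (the focal
    individual's two allele copies are removed); a frequency of zero after
    removal is floored at 1/(2*n_site + 1), where n_site counts individuals
    typed at that locus in the site.  Individuals typed at no locus are
    excluded.
    """
    rows = []
    amax = int(gm.genotypes.max())
    for site in gm.site_names:
        mask = gm.sites == site
        idxs = np.flatnonzero(mask)
        genos = gm.genotypes[mask]  # (m, L, 2)
        typed = (genos > 0).all(axis=2)
        # allele-copy counts per locus x allele, and typed n per locus
        counts = np.zeros((gm.n_loci, amax + 1))
        ii, jj = np.nonzero(typed)
        np.add.at(counts, (jj, genos[ii, jj, 0]), 1.0)
        np.add.at(counts, (jj, genos[ii, jj, 1]), 1.0)
        n_typed = typed.sum(axis=0)  # (L,)
        for local, gi in enumerate(idxs):
            if not typed[local].any():
                continue  # all loci missing: no assignment index
            ai = 0.0
            for j in np.flatnonzero(typed[local]):
                n_site = int(n_typed[j])
                a, b = genos[local, j]
                # leave-one-out removal of the focal copies
                ca = counts[j, a] - 2.0 if a == b else counts[j, a] - 1.0
                cb = counts[j, b] - 2.0 if a == b else counts[j, b] - 1.0
                denom = 2.0 * (n_site - 1)
                floor = 1.0 / (2.0 * n_site + 1.0)
                if denom <= 0:
                    pa = pb = floor
                else:
                    pa = max(ca / denom, floor)
                    pb = max(cb / denom, floor)
                f = pa * pb if a == b else 2.0 * pa * pb
                ai += np.log10(f)
            rows.append(
                dict(individual_id=gm.individual_ids[gi], sex=gm.sexes[gi],
                     site=site, AI=ai)
            )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no individual typed at any locus")
    df["AIc"] = df["AI"] - df.groupby("site")["AI"].transform("mean")
    return df


@dataclass
class SexBiasTestResult:
    statistic: str
    male_value: float
    female_value: float
    p: float
    n_permutations: int
    direction: str  # hypothesis about the male value relative to the female


def _per_sex_theta(genotypes: np.ndarray, pops: np.ndarray, is_male: np.ndarray) -> tuple[float, float]:
    tm = multilocus_theta(wc_components(genotypes[is_male], pops[is_male]))
    tf = multilocus_theta(wc_components(genotypes[~is_male], pops[~is_male]))
    return tm, tf


def sex_bias_test(
    gm: GenotypeMatrix,
    statistic: str = "vAIc",
    n_perm: int = 1000,
    seed: int = 0,
    direction: str = "male_lower",
) -> SexBiasTestResult:
    """One-sided permutation test for sex-biased dispersal.

    statistic : {"vAIc", "mean_AIc", "fst"}
        vAIc — variance of AIc pooled across sites, compared between sexes
        as a ratio; mean_AIc — difference of sex means of AIc; fst —
        difference of per-sex multi-locus Weir-Cockerham theta.
    direction : {"male_lower", "male_higher"}
        The alternative hypothesis about the male value relative to the
        female value.  The philopatric sex is expected to show higher theta
        and lower vAIc than the dispersing sex; the caller states the
        direction explicitly.

    The null distribution permutes sex labels within sites (sites with a
    single sex contribute no permutable labels).  Individuals of unknown sex
    are excluded.
    """
    if statistic not in ("vAIc", "mean_AIc", "fst"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if direction not in ("male_lower", "male_higher"):
        raise ValueError(f"unknown direction {direction!r}")
    keep = np.isin(gm.sexes, ("male", "female"))
    sub = gm.subset(keep)
    is_male = sub.sexes == "male"
    if is_male.all() or (~is_male).all():
        raise ValueError("both sexes must be present")
    sites_with_both = {
        s
        for s in sub.site_names
        if len(set(sub.sexes[sub.sites == s])) == 2
    }
    if len(sites_with_both) < 2:
        raise ValueError("both sexes must be present at >= 2 sites")

    site_lut = {s: i for i, s in enumerate(sub.site_names)}
    pops = np.array([site_lut[s] for s in sub.sites])

    if statistic in ("vAIc", "mean_AIc"):
        aic = assignment_index(sub)
        # align AIc values to sub's row order (excluded all-missing rows get NaN)
        lut = dict(zip(aic["individual_id"], aic["AIc"]))
        values = np.array([lut.get(i, np.nan) for i in sub.individual_ids])
        ok = np.isfinite(values)

        def stat_fn(male_mask: np.ndarray) -> tuple[float, float]:
            m = values[male_mask & ok]
            f = values[~male_mask & ok]
            if statistic == "vAIc":
                return float(np.var(m, ddof=1)), float(np.var(f, ddof=1))
            return float(m.mean()), float(f.mean())

    else:

        def stat_fn(male_mask: np.ndarray) -> tuple[float, float]:
            return _per_sex_theta(sub.genotypes, pops, male_mask)

    def score(male_mask: np.ndarray) -> float:
        m, f = stat_fn(male_mask)
        return m / f if statistic == "vAIc" else m - f

    obs_m, obs_f = stat_fn(is_male)
    obs = obs_m / obs_f if statistic == "vAIc" else obs_m - obs_f

    rng = np.random.default_rng(seed)
    site_indices = [np.flatnonzero(pops == site_lut[s]) for s in sub.site_names]
    k = 0
    for _ in range(n_perm):
        perm_mask = is_male.copy()
        for idx in site_indices:
            perm_mask[idx] = is_male[rng.permutation(idx)]
        s = score(perm_mask)
        if direction == "male_lower":
            k += s <= obs + 1e-12
        else:
            k += s >= obs - 1e-12
    p = (1 + k) / (1 + n_perm)
    return SexBiasTestResult(statistic, obs_m, obs_f, p, n_perm, direction)


def linearize_fst(theta: np.ndarray) -> np.ndarray:
    """Rousset linearization x/(1-x), elementwise; theta = 1 maps to inf.

    Negative estimates pass through (small negative linearized values);
    infinite entries should be excluded from downstream Mantel tests.
    """
    theta = np.asarray(theta, dtype=float)
    with np.errstate(divide="ignore"):
        out = theta / (1.0 - theta)
    return out


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    method: str
    transform_b: str


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel(
    mat_a: np.ndarray,
    mat_b: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
    transform_b: str = "none",
    method: str = "auto",
) -> MantelResult:
    """Mantel test of matrix association (one-sided, positive).

    r is the Pearson correlation over the upper-triangle entries after
    applying ``transform_b`` (``"log"`` = natural log) to ``mat_b``.  The
    null permutes rows+columns of ``mat_b`` simultaneously.  ``method``:
    ``"exact"`` enumerates all n! permutations (p = fraction with
    r_perm >= r_obs, the identity included), ``"mc"`` samples with the
    add-one estimator, ``"auto"`` picks exact for n <= 6.
    """
    a = np.asarray(mat_a, dtype=float)
    b = np.asarray(mat_b, dtype=float)
    n = a.shape[0]
    if a.shape != (n, n) or b.shape != (n, n) or n < 3:
        raise ValueError("matrices must be square, same size, n >= 3")
    if not (np.allclose(a, a.T) and np.allclose(b, b.T)):
        raise ValueError("matrices must be symmetric")
    if transform_b == "log":
        b = b.copy()
        off = ~np.eye(n, dtype=bool)
        if (b[off] <= 0).any():
            raise ValueError("log transform requires positive off-diagonal entries")
        b[off] = np.log(b[off])
    elif transform_b != "none":
        raise ValueError(f"unknown transform {transform_b!r}")

    xa = _upper(a)
    if not np.all(np.isfinite(xa)) or not np.all(np.isfinite(_upper(b))):
        raise ValueError("non-finite entries in a matrix triangle")
    if np.std(xa) == 0 or np.std(_upper(b)) == 0:
        raise ValueError("zero variance in a matrix triangle; r undefined")

    def corr(perm: np.ndarray) -> float:
        xb = _upper(b[np.ix_(perm, perm)])
        return float(np.corrcoef(xa, xb)[0, 1])

    ident = np.arange(n)
    r_obs = corr(ident)

    if method == "auto":
        method = "exact" if n <= 6 else "mc"
    if method == "exact":
        total = factorial(n)
        k = 0
        for perm in itertools.permutations(range(n)):
            if corr(np.array(perm)) >= r_obs - 1e-12:
                k += 1
        return MantelResult(r_obs, k / total, total, "exact", transform_b)
    if method != "mc":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_perm):
        if corr(rng.permutation(n)) >= r_obs - 1e-12:
            k += 1
    return MantelResult(r_obs, (1 + k) / (1 + n_perm), n_perm, "mc", transform_b)
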