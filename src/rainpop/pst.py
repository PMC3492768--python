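"""Phenotypic divergence (P_ST) from one-way ANOVA variance components.

P_ST is the phenotypic analog of Q_ST: with between- and within-population
phenotypic variance components sigma2_B and sigma2_W,

    P_ST = (r * sigma2_B) / (r * sigma2_B + 2 * sigma2_W)

where r = c/h^2 scales the fraction of between-population variance assumed
additive-genetic; r = 1 reduces to sigma2_B / (sigma2_B + 2*sigma2_W).
Components come from the one-way method of moments: sigma2_W = MS_within and
sigma2_B = max(0, (MS_between - MS_within)/n0) with n0 the effective
per-group size for unbalanced designs.

P_ST is computed between all site pairs per trait and sex; the spread of
the pairwise estimates (mean +/- one SD, clamped to [0, 1]) is used as a
conservative interval for comparison with the neutral F_ST jackknife CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popgen import FstResult

__all__ = [
    "anova_components",
    "pst",
    "pairwise_pst",
    "compare_pst_fst",
    "VarianceComponents",
    "PstResult",
    "PstFstVerdict",
]


@dataclass
class VarianceComponents:
    ms_between: float
    ms_within: float
    n0: float
    sigma2_between: float  # truncated at 0
    sigma2_within: float
    n_groups: int
    n_total: int
    truncated: bool  # MS_between < MS_within, sigma2_between clipped to 0


def anova_components(values, groups) -> VarianceComponents:
    """One-way ANOVA mean squares and method-of-moments variance components.

    Groups with fewer than 2 observations are excluded; at least two usable
    groups are required.  ``n0 = (N - sum(n_i^2)/N) / (k - 1)``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    labels, inv = np.unique(groups, return_inverse=True)
    sizes = np.bincount(inv)
    usable = sizes >= 2
    if usable.sum() < 2:
        raise ValueError("need >= 2 groups with >= 2 observations each")
    keep = usable[inv]
    values, inv = values[keep], inv[keep]
    labels2, inv = np.unique(inv, return_inverse=True)
    k = len(labels2)
    n_i = np.bincount(inv).astype(float)
    N = float(n_i.sum())
    means = np.bincount(inv, weights=values) / n_i
    grand = values.mean()
    ss_between = float((n_i * (means - grand) ** 2).sum())
    ss_within = float(((values - means[inv]) ** 2).sum())
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    n0 = (N - (n_i**2).sum() / N) / (k - 1)
    raw = (ms_between - ms_within) / n0
    return VarianceComponents(
        ms_between=ms_between,
        ms_within=ms_within,
        n0=float(n0),
        sigma2_between=max(0.0, raw),
        sigma2_within=ms_within,
        n_groups=k,
        n_total=int(N),
        truncated=raw < 0,
    )


def pst(sigma2_between: float, sigma2_within: float, ratio_c_h2: float = 1.0) -> float:
    """P_ST = (r*s2B) / (r*s2B + 2*s2W); requires s2B >= 0, s2W > 0."""
    if sigma2_within <= 0:
        raise ValueError("sigma2_within must be > 0")
    if sigma2_between < 0:
        raise ValueError("sigma2_between must be >= 0")
    num = ratio_c_h2 * sigma2_between
    return float(num / (num + 2.0 * sigma2_within))


@dataclass
class PstResult:
    trait: str
    sex: str
    pairwise: pd.DataFrame  # site_i, site_j, sigma2_between, sigma2_within, pst
    mean: float
    sd: float
    interval: tuple[float, float]  # mean +/- SD, clamped to [0, 1]
    ratio_c_h2: float


def pairwise_pst(
    morph: pd.DataFrame,
    trait: str,
    sex: str,
    ratio_c_h2: float = 1.0,
    min_per_site: int = 2,
) -> PstResult:
    """P_ST for every site pair for one trait and sex.

    Each pairwise ANOVA uses only the two sites in the pair.  Sites with
    fewer than ``min_per_site`` non-missing values of the trait are skipped.
    """
    sub = morph[morph["sex"] == sex]
    sites = []
    for s, grp in sub.groupby("site", sort=False):
        if grp[trait].notna().sum() >= min_per_site:
            sites.append(s)
    if len(sites) < 2:
        raise ValueError(f"fewer than 2 usable sites for {trait}/{sex}")
    rows = []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            pair = sub[sub["site"].isin((sites[i], sites[j]))]
            vc = anova_components(pair[trait], pair["site"])
            val = pst(vc.sigma2_between, vc.sigma2_within, ratio_c_h2)
            rows.append(
                dict(
                    site_i=sites[i],
                    site_j=sites[j],
                    sigma2_between=vc.sigma2_between,
                    sigma2_within=vc.sigma2_within,
                    pst=val,
                )
            )
    df = pd.DataFrame(rows)
    mean = float(df["pst"].mean())
    sd = float(df["pst"].std(ddof=1)) if len(df) > 1 else 0.0
    interval = (max(0.0, mean - sd), min(1.0, mean + sd))
    return PstResult(trait, sex, df, mean, sd, interval, ratio_c_h2)


@dataclass
class PstFstVerdict:
    trait: str
    sex: str
    verdict: str  # exceeds | overlaps | below | indeterminate
    pst_lower: float
    pst_upper: float
    fst_lower: float
    fst_upper: float


def compare_pst_fst(pst_result: PstResult, fst_result: FstResult) -> PstFstVerdict:
    """Compare the P_ST interval with the F_ST jackknife CI.

    "exceeds": the P_ST lower bound lies above the theta CI upper bound —
    divergence beyond what drift alone explains.  "below": the P_ST upper
    bound lies under the theta CI lower bound.  Otherwise "overlaps";
    "indeterminate" when either interval is undefined.
    """
    if fst_result.ci is None or not np.isfinite(pst_result.mean):
        return PstFstVerdict(
            pst_result.trait, pst_result.sex, "indeterminate",
            np.nan, np.nan, np.nan, np.nan,
        )
    p_lo, p_hi = pst_result.interval
    f_lo, f_hi = fst_result.ci
    if p_lo > f_hi:
        verdict = "exceeds"
    elif p_hi < f_lo:
        verdict = "below"
    else:
        verdict = "overlaps"
    return PstFstVerdict(pst_result.trait, pst_result.sex, verdict, p_lo, p_hi, f_lo, f_hi)
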