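"""Body-condition index, rainfall regressions, and the selection-mode scan.

The condition index (CI) is the standardized residual of an ordinary
least-squares regression of body mass on tarsus length, fitted per sex; it
serves as a proxy for individual fitness.  The selection scan bins each
trait (tarsus excluded) into {small, mean, large} z-score categories within
each sex x rainfall-category stratum, runs a one-way ANOVA of CI across the
bins, applies sequential Bonferroni across the scan, and classifies the
significant cells:

* mean bin highest            -> stabilizing
* both extremes above mean    -> disruptive
* one extreme highest (or an extreme tied with the mean) -> directional
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import f_oneway

from .datatypes import TRAITS, rainfall_category
from .popgen import holm_adjust

__all__ = [
    "condition_index",
    "condition_rainfall_regression",
    "bin_traits",
    "selection_scan",
    "site_trait_anova",
    "rainfall_morphology_regression",
    "RegressionResult",
]

#: traits eligible for the selection scan (tarsus builds the CI; mass is the
#: CI's response variable, so the scan covers the five externally measured
#: traits the bin figures use)
SCAN_TRAITS = (
    "bill_head_length",
    "bill_nostril_length",
    "bill_depth",
    "bill_width",
    "wing_length",
)


def condition_index(morph: pd.DataFrame, stratify: str = "by_sex") -> pd.DataFrame:
    """Condition index: standardized residuals of OLS mass ~ tarsus length.

    ``stratify="by_sex"`` fits one regression per sex (the default, since
    the sexes are size-dimorphic); ``"pooled"`` fits a single regression.
    Residuals are divided by their sample SD, so each stratum has mean 0 and
    SD 1.  Requires >= 3 complete (mass, tarsus) pairs and positive tarsus
    and residual variance per stratum.
    """
    if stratify not in ("by_sex", "pooled"):
        raise ValueError(f"unknown stratification {stratify!r}")
    ok = morph["mass"].notna() & morph["tarsus_length"].notna()
    df = morph[ok].copy()
    groups = df.groupby("sex", sort=False) if stratify == "by_sex" else [("all", df)]
    out = []
    for label, grp in groups:
        if len(grp) < 3:
            raise ValueError(f"stratum {label!r} has fewer than 3 complete records")
        x = grp["tarsus_length"].to_numpy(float)
        y = grp["mass"].to_numpy(float)
        if np.var(x) == 0:
            raise ValueError(f"zero tarsus variance in stratum {label!r}")
        beta, alpha = np.polyfit(x, y, 1)
        resid = y - (alpha + beta * x)
        sd = resid.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero residual variance in stratum {label!r}")
        rec = grp[["individual_id", "sex", "site"]].copy()
        rec["CI"] = resid / sd
        out.append(rec)
    return pd.concat(out, ignore_index=True)


@dataclass
class RegressionResult:
    response: str
    predictors: list[str]
    coefficients: pd.DataFrame  # term, estimate, se, p (two-sided)
    r2: float
    r2_adjusted: float
    p_overall: float
    sidedness: str  # "two-sided" | "one-sided-positive"
    n: int


def condition_rainfall_regression(
    ci_records: pd.DataFrame,
    sites: pd.DataFrame,
    sex: str | None = None,
    level: str = "individual",
) -> RegressionResult:
    """OLS of condition index on site mean-monthly rainfall (mm).

    The test of the slope is one-sided for a positive association (wetter
    sites -> higher condition).  ``level="individual"`` regresses every CI
    record on its site's rainfall; ``level="site"`` regresses site mean CI
    on rainfall (3 sites minimum either way).
    """
    df = ci_records if sex is None else ci_records[ci_records["sex"] == sex]
    rain = dict(zip(sites["site"], sites["rainfall_mm"]))
    df = df[df["site"].isin(rain)]
    if level == "site":
        df = df.groupby("site", as_index=False)["CI"].mean()
    elif level != "individual":
        raise ValueError(f"unknown level {level!r}")
    if df["site"].nunique() < 3:
        raise ValueError("need >= 3 sites")
    x = df["site"].map(rain).to_numpy(float)
    if np.unique(x).size < 2:
        raise ValueError("rainfall must vary across sites")
    y = df["CI"].to_numpy(float)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    slope = fit.params[1]
    p_two = fit.pvalues[1]
    p_one = p_two / 2.0 if slope > 0 else 1.0 - p_two / 2.0
    coef = pd.DataFrame(
        dict(
            term=["intercept", "rainfall_mm"],
            estimate=fit.params,
            se=fit.bse,
            p=fit.pvalues,
        )
    )
    return RegressionResult(
        response="CI",
        predictors=["rainfall_mm"],
        coefficients=coef,
        r2=float(fit.rsquared),
        r2_adjusted=float(fit.rsquared_adj),
        p_overall=float(p_one),
        sidedness="one-sided-positive",
        n=int(fit.nobs),
    )


def bin_traits(values) -> np.ndarray:
    """Z-score bin labels {small, mean, large, excluded} within one stratum.

    |z| <= 1 -> "mean"; -2 <= z < -1 -> "small"; 1 < z <= 2 -> "large";
    |z| > 2 (or missing) -> "excluded".  Strata with fewer than 3 finite
    values, or zero SD, are entirely excluded.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, "excluded", dtype=object)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        return out
    mu = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if sd == 0:
        return out
    z = (x - mu) / sd
    out[finite & (np.abs(z) <= 1)] = "mean"
    out[finite & (z >= -2) & (z < -1)] = "small"
    out[finite & (z > 1) & (z <= 2)] = "large"
    return out


def _classify(mean_small: float, mean_mid: float, mean_large: float, eps: float) -> str:
    d_s = mean_small - mean_mid
    d_l = mean_large - mean_mid
    if d_s > eps and d_l > eps:
        return "disruptive"
    if d_s < -eps and d_l < -eps:
        return "stabilizing"
    # one extreme at or above the mean bin: directional toward the higher extreme
    return "directional_up" if mean_large >= mean_small else "directional_down"


def selection_scan(
    morph: pd.DataFrame,
    ci_records: pd.DataFrame,
    sites: pd.DataFrame,
    traits=SCAN_TRAITS,
    alpha: float = 0.05,
    tie_eps: float = 0.05,
) -> pd.DataFrame:
    """Condition-index selection scan over trait x sex x rainfall category.

    For each cell, individuals are binned on the trait's within-stratum
    z-score, condition index is compared across the three bins by one-way
    ANOVA, and sequential Bonferroni is applied across all tested cells.
    Cells that are adjusted-significant and have all three bins populated
    receive a mode call; everything else is "none".

    Returns a tidy frame: trait, sex, rainfall_category, bin means/SEs and
    counts, F, p, adjusted decision, mode.
    """
    if "tarsus_length" in traits:
        raise ValueError("tarsus length builds the condition index; exclude it from the scan")
    cat = dict(zip(sites["site"], sites["rainfall_mm"].map(rainfall_category)))
    df = morph.merge(
        ci_records[["individual_id", "CI"]], on="individual_id", how="inner"
    )
    df["rainfall_category"] = df["site"].map(cat)
    rows = []
    for (sex, rc), stratum in df.groupby(["sex", "rainfall_category"], sort=False):
        for trait in traits:
            bins = bin_traits(stratum[trait])
            rec = dict(trait=trait, sex=sex, rainfall_category=rc)
            groups = {}
            for name in ("small", "mean", "large"):
                ci_vals = stratum.loc[bins == name, "CI"].to_numpy(float)
                groups[name] = ci_vals
                rec[f"n_{name}"] = len(ci_vals)
                rec[f"ci_mean_{name}"] = ci_vals.mean() if len(ci_vals) else np.nan
                rec[f"ci_se_{name}"] = (
                    ci_vals.std(ddof=1) / np.sqrt(len(ci_vals)) if len(ci_vals) > 1 else np.nan
                )
            if all(len(g) >= 2 for g in groups.values()):
                f_stat, p = f_oneway(groups["small"], groups["mean"], groups["large"])
                rec["F"] = float(f_stat)
                rec["p"] = float(min(max(p, np.nextafter(0, 1)), 1.0))
            else:
                rec["F"] = np.nan
                rec["p"] = np.nan
            rows.append(rec)
    out = pd.DataFrame(rows)
    testable = out["p"].notna()
    out["significant"] = False
    if testable.any():
        out.loc[testable, "significant"] = holm_adjust(out.loc[testable, "p"], alpha)
    modes = []
    for _, rec in out.iterrows():
        if not rec["significant"] or not np.isfinite(rec["p"]):
            modes.append("none")
        else:
            modes.append(
                _classify(
                    rec["ci_mean_small"], rec["ci_mean_mean"], rec["ci_mean_large"], tie_eps
                )
            )
    out["mode"] = modes
    return out


def site_trait_anova(
    morph: pd.DataFrame, sex: str, traits=TRAITS, alpha: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA of each trait across sites, per sex, Holm-adjusted.

    Mirrors an across-site trait screen: one row per trait with F, raw p
    and the sequential-Bonferroni decision over the trait family.
    """
    sub = morph[morph["sex"] == sex]
    if sub["site"].nunique() < 2:
        raise ValueError("need >= 2 sites")
    rows = []
    for trait in traits:
        groups = [
            g[trait].dropna().to_numpy(float)
            for _, g in sub.groupby("site", sort=False)
        ]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            rows.append(dict(trait=trait, F=np.nan, p=np.nan))
            continue
        f_stat, p = f_oneway(*groups)
        rows.append(dict(trait=trait, F=float(f_stat), p=float(p)))
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["significant"] = False
    if ok.any():
        out.loc[ok, "significant"] = holm_adjust(out.loc[ok, "p"], alpha)
    return out


def rainfall_morphology_regression(
    morph: pd.DataFrame,
    sites: pd.DataFrame,
    sex: str,
    traits=TRAITS,
    alpha: float = 0.05,
    cond_threshold: float = 1e8,
) -> RegressionResult:
    """Multiple regression of site rainfall on the individual trait vector.

    Rainfall (mm) is the response; the seven traits are the predictors.
    Per-coefficient two-sided p-values receive sequential Bonferroni across
    the trait coefficients.  Warns on near-collinear predictors.
    """
    import warnings

    rain = dict(zip(sites["site"], sites["rainfall_mm"]))
    sub = morph[(morph["sex"] == sex) & morph["site"].isin(rain)].dropna(
        subset=list(traits)
    )
    if len(sub) < len(traits) + 2:
        raise ValueError("need at least 2 more individuals than predictors")
    y = sub["site"].map(rain).to_numpy(float)
    X = sub[list(traits)].to_numpy(float)
    Xc = sm.add_constant(X)
    if np.linalg.cond(Xc) > cond_threshold:
        warnings.warn("near-collinear predictors in rainfall regression", stacklevel=2)
    fit = sm.OLS(y, Xc).fit()
    coef = pd.DataFrame(
        dict(
            term=["intercept"] + list(traits),
            estimate=fit.params,
            se=fit.bse,
            p=fit.pvalues,
        )
    )
    coef["significant"] = False
    coef.loc[1:, "significant"] = holm_adjust(coef["p"].iloc[1:], alpha)
    return RegressionResult(
        response="rainfall_mm",
        predictors=list(traits),
        coefficients=coef,
        r2=float(fit.rsquared),
        r2_adjusted=float(fit.rsquared_adj),
        p_overall=float(fit.f_pvalue),
        sidedness="two-sided",
        n=int(fit.nobs),
    )
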