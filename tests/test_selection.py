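import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rainpop.datatypes import validate_sites
from rainpop.selection import (
    _classify,
    bin_traits,
    condition_index,
    condition_rainfall_regression,
    rainfall_morphology_regression,
    selection_scan,
    site_trait_anova,
)


# ---------------------------------------------------------------------------
# condition index
# ---------------------------------------------------------------------------

def test_ci_standardization_invariants(morph_frame):
    ci = condition_index(morph_frame)
    for _, grp in ci.groupby("sex"):
        assert abs(grp["CI"].mean()) < 1e-9
        assert grp["CI"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)


def test_ci_five_point_hand_fit():
    # tarsus 20..24, mass 18,19,21,20,23: closed-form simple regression
    x = np.array([20, 21, 22, 23, 24], float)
    y = np.array([18, 19, 21, 20, 23], float)
    beta = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    alpha = y.mean() - beta * x.mean()
    resid = y - alpha - beta * x
    expect = resid / resid.std(ddof=1)
    df = pd.DataFrame(
        dict(
            individual_id=[f"i{k}" for k in range(5)],
            site="s",
            sex="male",
            bill_head_length=41.0, bill_nostril_length=10.0, bill_depth=5.0,
            bill_width=5.0, wing_length=78.0,
            tarsus_length=x, mass=y,
        )
    )
    ci = condition_index(df)
    np.testing.assert_allclose(ci["CI"].to_numpy(), expect, atol=1e-12)


def test_ci_outlier_has_largest_value():
    x = np.linspace(20, 25, 12)
    y = 2.0 + 0.8 * x
    y[5] += 3.0
    df = pd.DataFrame(
        dict(individual_id=[f"i{k}" for k in range(12)], site="s", sex="female",
             bill_head_length=41.0, bill_nostril_length=10.0, bill_depth=5.0,
             bill_width=5.0, wing_length=78.0, tarsus_length=x, mass=y)
    )
    ci = condition_index(df)
    assert ci["CI"].idxmax() == 5


def test_ci_degenerate_errors():
    df = pd.DataFrame(
        dict(individual_id=["a", "b", "c"], site="s", sex="male",
             bill_head_length=41.0, bill_nostril_length=10.0, bill_depth=5.0,
             bill_width=5.0, wing_length=78.0,
             tarsus_length=[23.0, 23.0, 23.0], mass=[20.0, 21.0, 22.0])
    )
    with pytest.raises(ValueError):
        condition_index(df)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def test_bin_rule_application():
    # construct values with known mean 0, SD 1 (ddof=1) then check labels
    base = np.array([-1.5, -0.5, 0.0, 0.5, 1.5, 2.4, -2.4])
    # normalize so sample stats are exact
    z = (base - base.mean()) / base.std(ddof=1)
    labels = bin_traits(z * 1.0)
    lut = dict(zip(np.round(z, 6), labels))
    for zi, lab in zip(z, labels):
        if abs(zi) <= 1:
            assert lab == "mean"
        elif -2 <= zi < -1:
            assert lab == "small"
        elif 1 < zi <= 2:
            assert lab == "large"
        else:
            assert lab == "excluded"


def test_bin_small_stratum_excluded():
    assert list(bin_traits([1.0, 2.0])) == ["excluded", "excluded"]
    assert list(bin_traits([1.0, 1.0, 1.0])) == ["excluded"] * 3


@given(st.floats(0.1, 10), st.floats(-5, 5))
def test_bin_affine_invariance(a, b):
    rng = np.random.default_rng(12)
    x = rng.normal(0, 1, 60)
    assert list(bin_traits(x)) == list(bin_traits(a * x + b))


def test_bin_normal_proportions():
    rng = np.random.default_rng(123)
    labels = bin_traits(rng.normal(0, 1, 10_000))
    frac = {k: (labels == k).mean() for k in ("small", "mean", "large")}
    assert frac["mean"] == pytest.approx(0.683, abs=0.015)
    assert frac["small"] == pytest.approx(0.136, abs=0.015)
    assert frac["large"] == pytest.approx(0.136, abs=0.015)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "means,mode",
    [
        ((-0.3, 0.4, -0.3), "stabilizing"),
        ((-0.4, 0.0, 0.5), "directional_up"),
        ((0.5, 0.0, -0.4), "directional_down"),
        ((0.4, -0.3, 0.4), "disruptive"),
        ((-0.4, 0.02, 0.0), "directional_up"),  # extreme tied with mean
    ],
)
def test_classify_rules(means, mode):
    assert _classify(*means, eps=0.05) == mode


def test_classify_symmetry_under_trait_negation():
    rng = np.random.default_rng(3)
    for _ in range(200):
        s, m, l = rng.normal(0, 0.5, 3)
        direct = _classify(s, m, l, 0.05)
        flipped = _classify(l, m, s, 0.05)
        swap = {"directional_up": "directional_down",
                "directional_down": "directional_up"}
        assert flipped == swap.get(direct, direct)


# ---------------------------------------------------------------------------
# scan and regressions
# ---------------------------------------------------------------------------

def _sites_df():
    return validate_sites(pd.DataFrame(dict(site=["low", "high"], rainfall_mm=[28.0, 50.0])))


def test_selection_scan_rejects_tarsus(morph_frame):
    ci = condition_index(morph_frame)
    with pytest.raises(ValueError):
        selection_scan(morph_frame, ci, _sites_df(), traits=("tarsus_length",))


def test_selection_scan_detects_planted_stabilizing():
    rng = np.random.default_rng(7)
    n = 600
    z = rng.normal(0, 1, n)
    tarsus = 23.5 + rng.normal(0, 0.8, n)
    mass = 2.0 + 0.8 * tarsus - 0.8 * z**2 + rng.normal(0, 0.3, n)
    df = pd.DataFrame(
        dict(individual_id=[f"i{k}" for k in range(n)], site="low", sex="male",
             bill_head_length=41.0 + rng.normal(0, 1, n),
             bill_nostril_length=10.4 + rng.normal(0, 0.6, n),
             bill_depth=5.2 + 0.3 * z,
             bill_width=5.2 + rng.normal(0, 0.4, n),
             wing_length=78.0 + rng.normal(0, 2.5, n),
             tarsus_length=tarsus, mass=mass)
    )
    ci = condition_index(df)
    scan = selection_scan(df, ci, _sites_df())
    cell = scan[(scan.trait == "bill_depth")].iloc[0]
    assert cell["mode"] == "stabilizing"
    # null traits stay quiet
    others = scan[scan.trait != "bill_depth"]
    assert (others["mode"] == "none").mean() >= 0.75


def test_site_trait_anova_separates_shifted_trait(morph_frame):
    res = site_trait_anova(morph_frame, "male")
    row = res[res.trait == "bill_head_length"].iloc[0]
    assert row.significant  # 1 SD mean shift at n=30/site
    assert res["p"].between(0, 1).all()


def test_site_trait_anova_single_site_errors(morph_frame):
    single = morph_frame[morph_frame.site == "low"]
    with pytest.raises(ValueError):
        site_trait_anova(single, "male")


def test_condition_rainfall_regression_needs_three_sites(morph_frame):
    ci = condition_index(morph_frame)
    with pytest.raises(ValueError):
        condition_rainfall_regression(ci, _sites_df())


def test_condition_rainfall_regression_one_sided():
    rng = np.random.default_rng(11)
    sites = validate_sites(
        pd.DataFrame(dict(site=["a", "b", "c"], rainfall_mm=[28.0, 40.0, 50.0]))
    )
    rows = []
    for s, rain in zip(("a", "b", "c"), (28, 40, 50)):
        for k in range(40):
            rows.append(dict(individual_id=f"{s}{k}", sex="male", site=s,
                             CI=0.05 * rain + rng.normal(0, 1)))
    ci = pd.DataFrame(rows)
    res = condition_rainfall_regression(ci, sites)
    assert res.p_overall < 0.05
    assert res.sidedness == "one-sided-positive"
    # negative association: one-sided p near 1
    ci_neg = ci.assign(CI=-ci["CI"])
    res_neg = condition_rainfall_regression(ci_neg, sites)
    assert res_neg.p_overall > 0.5


def test_rainfall_morphology_regression_recovers_sign(morph_frame):
    sites = _sites_df()
    res = rainfall_morphology_regression(morph_frame, sites, "male")
    coef = res.coefficients.set_index("term")
    # bill_head_length was simulated 1 mm larger at the wet site
    assert coef.loc["bill_head_length", "estimate"] > 0
    assert 0 <= res.r2 <= 1


def test_rainfall_morphology_regression_needs_n(morph_frame):
    tiny = morph_frame.head(6)
    with pytest.raises(ValueError):
        rainfall_morphology_regression(tiny, _sites_df(), "male")
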