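"""End-to-end orchestration: simulate/load -> popgen -> dispersal -> IBD ->
P_ST vs F_ST -> selection scan, with per-stage CSV outputs, a machine-readable
summary and a run manifest.

Configuration is a plain nested dict (usually loaded from YAML); every
stochastic stage takes an explicit seed derived from the top-level seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import io as rio
from .datatypes import DistanceMatrix, GenotypeMatrix, TRAITS
from .dispersal import assignment_index, linearize_fst, mantel, sex_bias_test
from .popgen import allele_stats, hwe_test, ld_test, pairwise_fst_matrix, wc_fst
from .pst import compare_pst_fst, pairwise_pst
from .selection import (
    SCAN_TRAITS,
    condition_index,
    condition_rainfall_regression,
    rainfall_morphology_regression,
    selection_scan,
    site_trait_anova,
)
from .simulate import ConditionModel, SimulationConfig, TraitEffect, simulate_dataset

log = logging.getLogger("rainpop")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "output_dir": "rainpop_out",
    "inputs": {},  # genotypes / morphology / sites / distances paths
    "simulate": {},  # SimulationConfig overrides when inputs are absent
    "permutations": {"hwe": 1000, "ld": 1000, "sex_bias": 1000, "mantel": 9999},
    "alpha": {"hwe_ld": 0.01, "traits": 0.05},
    "pst_ratio": 1.0,
    "philopatric_sex": "male",  # tested direction for the sex-bias tests
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def build_sim_config(block: dict, seed: int) -> SimulationConfig:
    """SimulationConfig from a config-file block (plain scalars/lists)."""
    block = dict(block or {})
    block.setdefault("seed", seed)
    if "trait_model" in block:
        block["trait_model"] = {
            t: TraitEffect(**v) if isinstance(v, dict) else v
            for t, v in block["trait_model"].items()
        }
    if "condition_model" in block and isinstance(block["condition_model"], dict):
        block["condition_model"] = ConditionModel(**block["condition_model"])
    for key in ("site_positions", "rainfall_per_site"):
        if key in block:
            block[key] = tuple(block[key])
    return SimulationConfig(**block)


def load_inputs(config: dict, outdir: Path):
    """Load user inputs, or simulate them and write the files to outdir/data."""
    inputs = config.get("inputs") or {}
    if inputs.get("genotypes"):
        sexes = None
        if inputs.get("sex_labels"):
            sexes = pd.read_csv(inputs["sex_labels"])["sex"].tolist()
        gm = rio.read_genepop(inputs["genotypes"], site_names=inputs.get("site_names"), sexes=sexes)
        morph = rio.read_morphology(inputs["morphology"]) if inputs.get("morphology") else None
        sites = rio.read_sites(inputs["sites"]) if inputs.get("sites") else None
        dmat = rio.read_distances(inputs["distances"]) if inputs.get("distances") else None
        truth = None
    else:
        cfg = build_sim_config(config.get("simulate"), config["seed"])
        gm, morph, sites, dmat, truth = simulate_dataset(cfg)
        data_dir = outdir / "data"
        data_dir.mkdir(parents=True, exist_ok=True)
        rio.write_genepop(gm, data_dir / "genotypes.gen")
        pd.DataFrame({"individual_id": gm.individual_ids, "sex": gm.sexes}).to_csv(
            data_dir / "genotype_sexes.csv", index=False
        )
        morph.to_csv(data_dir / "morphology.csv", index=False)
        sites.to_csv(data_dir / "sites.csv", index=False)
        rio.write_distances(dmat, data_dir / "distances.csv")
        log.info("simulated inputs written to %s", data_dir)
    return gm, morph, sites, dmat, truth


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_popgen(gm: GenotypeMatrix, config: dict, outdir: Path) -> dict:
    n_perm = config["permutations"]["hwe"]
    stats = allele_stats(gm)
    stats.to_csv(outdir / "allele_stats.csv", index=False)
    seed = config["seed"]
    records = []
    for si, site in enumerate(gm.site_names):
        for li, locus in enumerate(gm.locus_names):
            rec = hwe_test(gm, locus, site, n_perm=n_perm, seed=seed + 1000 + si * 100 + li)
            records.append(dict(test="hwe", unit=rec.unit, p=rec.p, n_perm=rec.n_permutations,
                                skipped=rec.skipped, reason=rec.reason))
    n_perm_ld = config["permutations"]["ld"]
    loci = list(gm.locus_names)
    for si, site in enumerate(gm.site_names):
        for a in range(len(loci)):
            for b in range(a + 1, len(loci)):
                rec = ld_test(gm, loci[a], loci[b], site, n_perm=n_perm_ld,
                              seed=seed + 20000 + si * 1000 + a * 30 + b)
                records.append(dict(test="ld", unit=rec.unit, p=rec.p,
                                    n_perm=rec.n_permutations, skipped=rec.skipped,
                                    reason=rec.reason))
    tests = pd.DataFrame(records)
    alpha = config["alpha"]["hwe_ld"]
    tests["significant"] = False
    for name in ("hwe", "ld"):
        mask = (tests["test"] == name) & ~tests["skipped"]
        # the printed family alpha (already Bonferroni-style conservative)
        tests.loc[mask, "significant"] = tests.loc[mask, "p"] < alpha
    tests.to_csv(outdir / "hwe_ld_tests.csv", index=False)

    fst = wc_fst(gm)
    fst.components.to_csv(outdir / "fst_components.csv", index=False)
    per_sex = {}
    for sex in ("male", "female"):
        mask = gm.sexes == sex
        if mask.sum() >= 4:
            per_sex[sex] = wc_fst(gm.subset(mask))
    total = gm.n_individuals * gm.n_loci
    summary = dict(
        n_individuals=gm.n_individuals,
        n_loci=gm.n_loci,
        n_missing=gm.n_missing(),
        missing_percent=round(100.0 * gm.n_missing() / total, 1),
        global_theta=fst.theta,
        global_theta_ci=list(fst.ci) if fst.ci else None,
        per_sex_theta={s: r.theta for s, r in per_sex.items()},
    )
    return dict(summary=summary, fst=fst, per_sex_fst=per_sex)


def stage_dispersal(gm: GenotypeMatrix, config: dict, outdir: Path) -> dict:
    aic = assignment_index(gm)
    aic.to_csv(outdir / "assignment_index.csv", index=False)
    n_perm = config["permutations"]["sex_bias"]
    phil = config["philopatric_sex"]
    # philopatric sex: lower vAIc, higher per-sex theta
    dir_vaic = "male_lower" if phil == "male" else "male_higher"
    dir_fst = "male_higher" if phil == "male" else "male_lower"
    res = {}
    for stat, direction in (("vAIc", dir_vaic), ("fst", dir_fst)):
        r = sex_bias_test(gm, statistic=stat, n_perm=n_perm,
                          seed=config["seed"] + 31, direction=direction)
        res[stat] = r
    df = pd.DataFrame(
        [dataclasses.asdict(r) for r in res.values()]
    )
    df.to_csv(outdir / "sex_bias_tests.csv", index=False)
    return dict(
        summary={
            s: dict(male=r.male_value, female=r.female_value, p=r.p,
                    direction=r.direction)
            for s, r in res.items()
        }
    )


def stage_ibd(gm: GenotypeMatrix, dmat: DistanceMatrix, config: dict, outdir: Path) -> dict:
    n_perm = config["permutations"]["mantel"]
    out = {}
    rows = []
    for sex in ("male", "female"):
        sub = gm.subset(gm.sexes == sex)
        names, theta = pairwise_fst_matrix(sub)
        lin = linearize_fst(theta)
        np.fill_diagonal(lin, 0.0)
        if not np.isfinite(lin).all():
            log.warning("infinite linearized theta for %s; pair excluded", sex)
        dm = dmat.reorder(names)
        res = mantel(lin, dm.values, n_perm=n_perm, seed=config["seed"] + 71,
                     transform_b="log", method="mc")
        out[sex] = res
        iu = np.triu_indices(len(names), k=1)
        for i, j in zip(*iu):
            rows.append(dict(sex=sex, site_i=names[i], site_j=names[j],
                             linearized_theta=lin[i, j], distance_km=dm.values[i, j]))
    pd.DataFrame(rows).to_csv(outdir / "ibd_pairs.csv", index=False)
    summary = {s: dict(r=r.r, p=r.p, n_permutations=r.n_permutations) for s, r in out.items()}
    pd.DataFrame(summary).T.to_csv(outdir / "mantel_tests.csv")
    return dict(summary=summary)


def stage_pst(gm: GenotypeMatrix, morph: pd.DataFrame, config: dict, outdir: Path,
              per_sex_fst: dict) -> dict:
    rows, verdicts = [], {}
    ratio = config.get("pst_ratio", 1.0)
    for sex in ("male", "female"):
        fst = per_sex_fst.get(sex)
        for trait in TRAITS:
            res = pairwise_pst(morph, trait, sex, ratio_c_h2=ratio)
            for _, r in res.pairwise.iterrows():
                rows.append(dict(trait=trait, sex=sex, **r.to_dict()))
            if fst is not None:
                v = compare_pst_fst(res, fst)
                verdicts[f"{trait}/{sex}"] = v.verdict
                rows.append(dict(trait=trait, sex=sex, site_i="(aggregate)",
                                 site_j="", sigma2_between=np.nan, sigma2_within=np.nan,
                                 pst=res.mean, verdict=v.verdict,
                                 pst_lower=v.pst_lower, pst_upper=v.pst_upper,
                                 fst_lower=v.fst_lower, fst_upper=v.fst_upper))
    pd.DataFrame(rows).to_csv(outdir / "pst.csv", index=False)
    return dict(summary=verdicts)


def stage_selection(morph: pd.DataFrame, sites: pd.DataFrame, config: dict,
                    outdir: Path) -> dict:
    alpha = config["alpha"]["traits"]
    ci = condition_index(morph)
    ci.to_csv(outdir / "condition_index.csv", index=False)
    reg_rows = []
    for sex in ("male", "female"):
        reg = condition_rainfall_regression(ci, sites, sex=sex)
        slope = reg.coefficients.loc[reg.coefficients["term"] == "rainfall_mm", "estimate"].iloc[0]
        reg_rows.append(dict(sex=sex, slope=slope, r2=reg.r2,
                             r2_adjusted=reg.r2_adjusted, p_one_sided=reg.p_overall))
    pd.DataFrame(reg_rows).to_csv(outdir / "condition_rainfall.csv", index=False)

    anova_rows = []
    for sex in ("male", "female"):
        a = site_trait_anova(morph, sex, alpha=alpha)
        a.insert(0, "sex", sex)
        anova_rows.append(a)
    pd.concat(anova_rows).to_csv(outdir / "site_trait_anova.csv", index=False)

    multireg = {}
    for sex in ("male", "female"):
        r = rainfall_morphology_regression(morph, sites, sex, alpha=alpha)
        r.coefficients.insert(0, "sex", sex)
        multireg[sex] = r
    pd.concat([r.coefficients for r in multireg.values()]).to_csv(
        outdir / "rainfall_morphology_regression.csv", index=False
    )

    scan = selection_scan(morph, ci, sites, alpha=alpha)
    scan.to_csv(outdir / "selection_scan.csv", index=False)
    modes = {
        f"{r.trait}/{r.sex}/{r.rainfall_category}": r.mode
        for r in scan.itertuples()
        if r.mode != "none"
    }
    summary = dict(
        condition_rainfall={row["sex"]: row["p_one_sided"] for row in reg_rows},
        selection_modes=modes,
    )
    return dict(summary=summary)


def run_pipeline(config: dict | None = None) -> dict:
    """Run every stage in dependency order; returns the summary dict.

    Writes per-stage CSVs, ``summary.json`` and ``manifest.txt`` under
    ``config["output_dir"]``.  A stage failure aborts the run with the stage
    name in the exception and leaves a ``FAILED`` marker next to the partial
    outputs.  Stages whose inputs are absent (e.g. no distance matrix) are
    recorded as skipped and the rest of the pipeline completes.
    """
    config = _merge(DEFAULT_CONFIG, config or {})
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"stages": {}}
    stage = "load_inputs"
    try:
        gm, morph, sites, dmat, truth = load_inputs(config, outdir)
        if truth is not None:
            summary["simulation_truth"] = truth

        stage = "popgen"
        pg = stage_popgen(gm, config, outdir)
        summary["stages"]["popgen"] = pg["summary"]

        stage = "dispersal"
        disp = stage_dispersal(gm, config, outdir)
        summary["stages"]["dispersal"] = disp["summary"]

        stage = "ibd"
        if dmat is None:
            summary["stages"]["ibd"] = {"skipped": "no distances"}
        else:
            summary["stages"]["ibd"] = stage_ibd(gm, dmat, config, outdir)["summary"]

        stage = "pst"
        if morph is None:
            summary["stages"]["pst"] = {"skipped": "no morphology"}
        else:
            summary["stages"]["pst"] = stage_pst(
                gm, morph, config, outdir, pg["per_sex_fst"]
            )["summary"]

        stage = "selection"
        if morph is None or sites is None:
            summary["stages"]["selection"] = {"skipped": "no morphology or sites"}
        else:
            summary["stages"]["selection"] = stage_selection(
                morph, sites, config, outdir
            )["summary"]
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    write_report(summary, config, outdir)
    return summary


def write_report(summary: dict, config: dict, outdir: Path) -> None:
    def _clean(obj):
        if isinstance(obj, dict):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, float)):
            f = float(obj)
            return f if np.isfinite(f) else None
        if isinstance(obj, (np.integer,)):
            return int(obj)
        return obj

    (outdir / "summary.json").write_text(json.dumps(_clean(summary), indent=2) + "\n")
    manifest = [
        f"rainpop version: {__version__}",
        f"seed: {config['seed']}",
        f"permutations: {config['permutations']}",
        f"alpha: {config['alpha']}",
        f"pst ratio (c/h^2): {config.get('pst_ratio', 1.0)}",
    ]
    (outdir / "manifest.txt").write_text("\n".join(manifest) + "\n")
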