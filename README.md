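# rainpop

Joint analysis of **neutral genetic structure** and **adaptive phenotypic
divergence** for a songbird (or any diploid, codominant-marker system)
sampled along an environmental gradient. The package asks the classic
question: do populations differ in morphology *more than genetic drift can
explain*, and if so, what mode of selection is acting?

It is aimed at population / evolutionary ecologists working with
microsatellite genotypes plus individual morphometrics from a handful of
sites — the typical landscape-genetics field design (here: six sites spread
across a rainfall gradient, two per rainfall category).

## What it computes

* **Diversity and HWE/LD screening** — per-locus N_A, unbiased H_E, H_O,
  F_IS (= 1 − H_O/H_E), Monte-Carlo exact Hardy–Weinberg tests (Levene
  table probability, allele re-pairing null) and genotypic
  linkage-disequilibrium G-tests, with sequential-Bonferroni (Holm/Rice)
  correction.
* **F_ST** — the Weir & Cockerham (1984) variance-component estimator θ
  (components a, b, c per allele per locus; multi-locus θ = Σa/Σ(a+b+c)),
  global, pairwise, and per sex, with 95% CIs from a delete-one-locus
  jackknife. Missing genotypes are handled locus-wise.
* **Sex-biased dispersal** — corrected assignment indices (AIc, with
  leave-one-out site frequencies) and per-sex θ, compared between sexes by
  permuting sex labels within sites (one-sided, direction stated by the
  caller).
* **Isolation by distance** — Rousset's linearization θ/(1−θ) regressed on
  log geographic distance, tested with a Mantel permutation test (exact
  enumeration for ≤ 6 sites, Monte-Carlo otherwise).
* **P_ST vs F_ST** — phenotypic divergence per trait, sex, and site pair
  from one-way ANOVA variance components,

      P_ST = (c/h² · σ²_B) / (c/h² · σ²_B + 2 σ²_W),

  with σ²_B = max(0, (MS_B − MS_W)/n₀) and σ²_W = MS_W; the spread of the
  pairwise estimates (mean ± 1 SD) is compared against the θ jackknife CI
  to call "exceeds" / "overlaps" / "below".
* **Condition-index selection scan** — condition index = standardized
  residual of OLS mass ~ tarsus per sex (a fitness proxy); traits are
  binned into {small, mean, large} z-score classes (|z| ≤ 1; 1 < |z| ≤ 2)
  within sex × rainfall category, condition is compared across bins by
  one-way ANOVA, and significant cells are classified as stabilizing,
  directional (up/down), or disruptive selection.
* **Synthetic data with known truth** — a stepping-stone genotype generator
  (Balding–Nichols Dirichlet chain, sex-specific adjacent-site migration,
  configurable missingness) and a rainfall-driven morphology generator with
  injectable selection on condition, so every stage is testable against
  ground truth.

## Worked example

```python
import numpy as np
from rainpop import SimulationConfig, simulate_dataset
from rainpop.popgen import allele_stats, wc_fst, pairwise_fst_matrix
from rainpop.dispersal import linearize_fst, mantel

cfg = SimulationConfig(seed=1)          # 6 sites x 2 sexes x 28, 10 loci
gm, morph, sites, dmat, truth = simulate_dataset(cfg)

stats = allele_stats(gm, by_site=False)
print(f"{gm.n_individuals} individuals, {gm.n_loci} loci, "
      f"{gm.n_missing()} missing entries "
      f"({100 * gm.n_missing() / (gm.n_individuals * gm.n_loci):.1f}%)")
print(f"H_E range: {stats.h_exp.min():.2f}-{stats.h_exp.max():.2f}")

fst = wc_fst(gm)
print(f"global theta = {fst.theta:.4f}, 95% CI ({fst.ci[0]:.4f}, {fst.ci[1]:.4f})")

names, theta = pairwise_fst_matrix(gm)
lin = linearize_fst(theta); np.fill_diagonal(lin, 0.0)
res = mantel(lin, dmat.reorder(names).values, n_perm=9999, seed=2,
             transform_b="log", method="mc")
print(f"IBD Mantel: r = {res.r:.2f}, one-sided p = {res.p:.4f}")
```

prints

```
336 individuals, 10 loci, 192 missing entries (5.7%)
H_E range: 0.75-0.87
global theta = 0.0187, 95% CI (0.0143, 0.0232)
IBD Mantel: r = 0.93, one-sided p = 0.0023
```

i.e. a weakly but significantly structured system (θ ≈ 0.02) whose
pairwise differentiation increases strongly with distance — exactly the
structure the generator injected (`truth` records the injected parameters).

The same analysis is available from the shell:

```bash
rainpop run --seed 1 --out out/          # full pipeline, writes CSVs + summary.json
rainpop simulate --seed 1 --out data/    # just the synthetic dataset
rainpop popgen data/genotypes.gen --sexes data/genotype_sexes.csv --out pg/
rainpop report out/                      # re-print a finished run's summary
```

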