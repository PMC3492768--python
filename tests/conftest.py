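import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rainpop.datatypes import GenotypeMatrix

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_gm(site_genos, sexes=None, locus_names=None):
    """Build a GenotypeMatrix from {site: [per-individual list of (a, b) per locus]}."""
    ids, sites, rows = [], [], []
    for site, individuals in site_genos.items():
        for k, genos in enumerate(individuals):
            ids.append(f"{site}_i{k}")
            sites.append(site)
            rows.append([list(g) for g in genos])
    n = len(ids)
    n_loci = len(rows[0])
    if locus_names is None:
        locus_names = [f"L{j + 1}" for j in range(n_loci)]
    if sexes is None:
        sexes = ["unknown"] * n
    return GenotypeMatrix(
        individual_ids=np.array(ids, dtype=object),
        sites=np.array(sites, dtype=object),
        sexes=np.array(sexes, dtype=object),
        genotypes=np.array(rows, dtype=np.int64),
        locus_names=np.array(locus_names, dtype=object),
    )


@pytest.fixture
def two_site_toy():
    """2 sites, 1 biallelic locus: site A {5 AA, 5 Aa}, site B {5 Aa, 5 aa}."""
    return make_gm(
        {
            "A": [[(1, 1)]] * 5 + [[(1, 2)]] * 5,
            "B": [[(1, 2)]] * 5 + [[(2, 2)]] * 5,
        }
    )


@pytest.fixture
def morph_frame():
    """Small two-site morphology table with a known mass/tarsus relation."""
    rng = np.random.default_rng(42)
    rows = []
    for site, rain_shift in (("low", 0.0), ("high", 1.0)):
        for k in range(30):
            for sex in ("male", "female"):
                tarsus = 23.5 + rng.normal(0, 0.8)
                rows.append(
                    dict(
                        individual_id=f"{site}_{sex}_{k}",
                        site=site,
                        sex=sex,
                        bill_head_length=41 + rain_shift + rng.normal(0, 1),
                        bill_nostril_length=10.4 + rng.normal(0, 0.6),
                        bill_depth=5.2 + rng.normal(0, 0.3),
                        bill_width=5.2 + rng.normal(0, 0.4),
                        wing_length=78 + rng.normal(0, 2.5),
                        tarsus_length=tarsus,
                        mass=2.2 + 0.8 * tarsus + rng.normal(0, 1),
                    )
                )
    return pd.DataFrame(rows)
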