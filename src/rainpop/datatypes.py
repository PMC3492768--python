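"""Core in-memory containers shared by every analysis stage.

The central object is :class:`GenotypeMatrix`, a dense individuals x loci
array of codominant allele pairs (microsatellite-style integer allele codes,
0 = missing) annotated with site and sex labels.  Morphology, site and
distance tables are validated :class:`pandas.DataFrame` / array wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical trait panel, in measurement order; all in mm except mass (g)
TRAITS = (
    "bill_head_length",
    "bill_nostril_length",
    "bill_depth",
    "bill_width",
    "wing_length",
    "tarsus_length",
    "mass",
)

SEXES = ("male", "female", "unknown")

#: mean monthly rainfall (mm) category bounds: low [0,32), moderate [32,44],
#: high (44, inf) — every value maps to exactly one category
RAIN_LOW_UPPER = 32.0
RAIN_MODERATE_UPPER = 44.0


def rainfall_category(rainfall_mm: float) -> str:
    """Classify mean monthly rainfall (mm) into low / moderate / high."""
    if rainfall_mm < 0:
        raise ValueError(f"rainfall must be non-negative, got {rainfall_mm}")
    if rainfall_mm < RAIN_LOW_UPPER:
        return "low"
    if rainfall_mm <= RAIN_MODERATE_UPPER:
        return "moderate"
    return "high"


class FormatError(ValueError):
    """A file violates the expected dialect (structure-level problem)."""


class RecordError(ValueError):
    """A single record within a file is malformed."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci codominant genotypes with site/sex labels.

    Parameters
    ----------
    individual_ids : array of str, shape (n,)
    sites : array of str, shape (n,)
    sexes : array of str, shape (n,), values in {male, female, unknown}
    genotypes : int array, shape (n, n_loci, 2)
        Allele codes > 0; 0 encodes a missing allele.  A genotype entry is
        treated as missing if either allele is 0.  Pairs are stored sorted so
        (a, b) and (b, a) compare equal.
    locus_names : array of str, shape (n_loci,)
    """

    individual_ids: np.ndarray
    sites: np.ndarray
    sexes: np.ndarray
    genotypes: np.ndarray
    locus_names: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.sites = np.asarray(self.sites, dtype=object)
        self.sexes = np.asarray(self.sexes, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        self.locus_names = np.asarray(self.locus_names, dtype=object)
        n = len(self.individual_ids)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must have shape (n, n_loci, 2)")
        if self.genotypes.shape[0] != n or len(self.sites) != n or len(self.sexes) != n:
            raise ValueError("individual annotation lengths disagree")
        if self.genotypes.shape[1] != len(self.locus_names):
            raise ValueError("locus_names length disagrees with genotype array")
        if (self.genotypes < 0).any():
            raise ValueError("allele codes must be >= 0 (0 = missing)")
        bad = ~np.isin(self.sexes, SEXES)
        if bad.any():
            raise ValueError(f"unknown sex labels: {set(self.sexes[bad])}")
        # canonicalize: any zero allele -> fully missing entry; sort pairs
        miss = (self.genotypes == 0).any(axis=2)
        self.genotypes[miss] = 0
        self.genotypes = np.sort(self.genotypes, axis=2)

    # -- basic queries -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def site_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s)
        return list(seen)

    def typed_mask(self) -> np.ndarray:
        """Boolean (n, n_loci) mask of non-missing genotype entries."""
        return (self.genotypes > 0).all(axis=2)

    def n_missing(self) -> int:
        return int((~self.typed_mask()).sum())

    def subset(self, mask: np.ndarray, loci: np.ndarray | None = None) -> "GenotypeMatrix":
        """Row (and optionally locus) subset; mask is boolean or index array."""
        geno = self.genotypes[mask]
        names = self.locus_names
        if loci is not None:
            geno = geno[:, loci, :]
            names = self.locus_names[loci]
        return GenotypeMatrix(
            individual_ids=self.individual_ids[mask],
            sites=self.sites[mask],
            sexes=self.sexes[mask],
            genotypes=geno,
            locus_names=names,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.individual_ids, other.individual_ids)
            and np.array_equal(self.sites, other.sites)
            and np.array_equal(self.sexes, other.sexes)
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.locus_names, other.locus_names)
        )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise geographic distances (km) between sites."""

    sites: list[str]
    values: np.ndarray
    atol: float = field(default=1e-9, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.sites)
        if self.values.shape != (k, k):
            raise ValueError("distance matrix shape disagrees with site list")
        if not np.allclose(self.values, self.values.T, atol=self.atol, rtol=0):
            raise FormatError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=self.atol):
            raise FormatError("distance matrix diagonal must be zero")
        off = self.values[~np.eye(k, dtype=bool)]
        if (off <= 0).any():
            raise FormatError("off-diagonal distances must be > 0")
        # exact symmetry after validation
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def reorder(self, sites: list[str]) -> "DistanceMatrix":
        idx = [self.sites.index(s) for s in sites]
        return DistanceMatrix(list(sites), self.values[np.ix_(idx, idx)])


def validate_sites(df: pd.DataFrame) -> pd.DataFrame:
    """Validate/complete a site table (site, rainfall_mm[, rainfall_category])."""
    for col in ("site", "rainfall_mm"):
        if col not in df.columns:
            raise FormatError(f"site table missing required column {col!r}")
    out = df.copy()
    out["rainfall_mm"] = pd.to_numeric(out["rainfall_mm"], errors="raise").astype(float)
    if (out["rainfall_mm"] < 0).any():
        raise ValueError("rainfall_mm must be non-negative")
    computed = out["rainfall_mm"].map(rainfall_category)
    if "rainfall_category" in out.columns:
        mismatch = out["rainfall_category"].astype(str) != computed
        if mismatch.any():
            bad = out.loc[mismatch, "site"].tolist()
            raise ValueError(
                f"rainfall_category inconsistent with rainfall_mm for sites {bad}"
            )
    out["rainfall_category"] = computed
    out["site"] = out["site"].astype(str)
    if out["site"].duplicated().any():
        raise ValueError("duplicate site labels in site table")
    return out


def validate_morphology(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-individual morphology table.

    Requires individual_id, site, sex plus the seven-trait panel; traits must
    be numeric and strictly positive where present.
    """
    required = ("individual_id", "site", "sex") + TRAITS
    for col in required:
        if col not in df.columns:
            raise FormatError(f"morphology table missing required column {col!r}")
    out = df.copy()
    for t in TRAITS:
        out[t] = pd.to_numeric(out[t], errors="raise").astype(float)
        present = out[t].notna()
        if (out.loc[present, t] <= 0).any():
            raise ValueError(f"trait {t!r} has non-positive values")
    bad = ~out["sex"].isin(("male", "female"))
    if bad.any():
        raise ValueError(f"morphology sex must be male/female; got {set(out.loc[bad, 'sex'])}")
    out["individual_id"] = out["individual_id"].astype(str)
    out["site"] = out["site"].astype(str)
    return out
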