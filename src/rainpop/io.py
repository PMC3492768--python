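"""Readers and writers for the formats the pipeline touches.

Genotypes travel as Genepop text (2- or 3-digit allele codes, ``Pop``
delimited blocks, all-zero genotype = missing); morphology, site and
distance tables are plain CSV with a header row.
"""

from __future__ import annotations

import io as _io
import sys
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DistanceMatrix,
    FormatError,
    GenotypeMatrix,
    RecordError,
    validate_morphology,
    validate_sites,
)

__all__ = [
    "read_genepop",
    "write_genepop",
    "read_morphology",
    "read_sites",
    "read_distances",
    "write_distances",
]


def _open_text(path_or_file, mode: str = "r") -> tuple[IO[str], bool]:
    if path_or_file == "-":
        return (sys.stdin if "r" in mode else sys.stdout), False
    if isinstance(path_or_file, (str, Path)):
        return open(path_or_file, mode), True
    return path_or_file, False


def read_genepop(
    path_or_file,
    site_names: Sequence[str] | str | None = None,
    sexes: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Parse a Genepop file into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path_or_file : str | Path | file-like
        ``"-"`` reads standard input.
    site_names : sequence of str, ``"from_ids"``, or None
        Labels for the population blocks, in order.  ``"from_ids"`` takes the
        last individual id of each block as its site label; None uses
        ``pop_1 .. pop_k``.
    sexes : sequence of str, optional
        Per-individual sex labels, in file order (Genepop itself carries no
        sex column); defaults to ``"unknown"``.

    Notes
    -----
    Allele-code width (2 or 3 digits) is auto-detected per file from the
    genotype token lengths; a file mixing 4- and 6-character genotypes is
    rejected.  A genotype with any zero allele is recorded as missing.
    """
    fh, owned = _open_text(path_or_file)
    try:
        lines = fh.read().splitlines()
    finally:
        if owned:
            fh.close()
    if not lines:
        raise FormatError("empty Genepop file")

    # title line, then locus names until the first Pop line
    idx = 1
    locus_names: list[str] = []
    while idx < len(lines) and lines[idx].strip().lower() != "pop":
        chunk = lines[idx].strip()
        if chunk:
            locus_names.extend(name.strip() for name in chunk.split(",") if name.strip())
        idx += 1
    if idx == len(lines):
        raise FormatError("no 'Pop' line found")
    if not locus_names:
        raise FormatError("no locus names before first 'Pop' line")
    n_loci = len(locus_names)

    ids: list[str] = []
    pop_of: list[int] = []
    rows: list[list[tuple[int, int]]] = []
    block_last_id: list[str] = []
    widths: set[int] = set()

    pop_index = -1
    block_count = 0
    for lineno in range(idx, len(lines)):
        raw = lines[lineno]
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            if pop_index >= 0 and block_count == 0:
                raise FormatError(f"empty population block before line {lineno + 1}")
            pop_index += 1
            block_count = 0
            block_last_id.append("")
            continue
        if "," not in line:
            raise RecordError(f"line {lineno + 1}: expected 'id , genotypes'")
        ind_id, _, geno_part = line.partition(",")
        ind_id = ind_id.strip()
        tokens = geno_part.split()
        if len(tokens) != n_loci:
            raise RecordError(
                f"line {lineno + 1}: individual {ind_id!r} has {len(tokens)} "
                f"genotypes, expected {n_loci}"
            )
        genos: list[tuple[int, int]] = []
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise RecordError(f"line {lineno + 1}: malformed genotype token {tok!r}")
            widths.add(len(tok) // 2)
            w = len(tok) // 2
            genos.append((int(tok[:w]), int(tok[w:])))
        if len(widths) > 1:
            raise FormatError("mixed 2- and 3-digit allele codes within one file")
        ids.append(ind_id)
        pop_of.append(pop_index)
        rows.append(genos)
        block_last_id[pop_index] = ind_id
        block_count += 1

    if pop_index < 0:
        raise FormatError("no population blocks found")
    if block_count == 0:
        raise FormatError("trailing empty population block")

    n_pops = pop_index + 1
    if site_names is None:
        labels = [f"pop_{k + 1}" for k in range(n_pops)]
    elif site_names == "from_ids":
        labels = block_last_id
    else:
        if len(site_names) != n_pops:
            raise ValueError(
                f"{len(site_names)} site names supplied for {n_pops} population blocks"
            )
        labels = [str(s) for s in site_names]

    n = len(ids)
    sex_arr = np.array(
        ["unknown"] * n if sexes is None else list(sexes), dtype=object
    )
    if len(sex_arr) != n:
        raise ValueError("sexes length disagrees with individual count")
    return GenotypeMatrix(
        individual_ids=np.array(ids, dtype=object),
        sites=np.array([labels[p] for p in pop_of], dtype=object),
        sexes=sex_arr,
        genotypes=np.array(rows, dtype=np.int64),
        locus_names=np.array(locus_names, dtype=object),
    )


def write_genepop(
    gm: GenotypeMatrix,
    path_or_file,
    code_width: int = 3,
    title: str = "rainpop genotypes",
) -> None:
    """Write a :class:`GenotypeMatrix` as Genepop text.

    Individuals are grouped into ``Pop`` blocks by site, in first-appearance
    order; missing entries are written as all-zero codes.  Raises if any
    allele code does not fit in ``code_width`` digits.
    """
    if code_width not in (2, 3):
        raise ValueError("code_width must be 2 or 3")
    limit = 10**code_width
    if (gm.genotypes >= limit).any():
        raise ValueError(
            f"allele code >= {limit} cannot be encoded with code_width={code_width}"
        )
    buf = _io.StringIO()
    buf.write(title + "\n")
    for name in gm.locus_names:
        buf.write(str(name) + "\n")
    for site in gm.site_names:
        buf.write("Pop\n")
        for i in np.flatnonzero(gm.sites == site):
            toks = [
                f"{a:0{code_width}d}{b:0{code_width}d}" for a, b in gm.genotypes[i]
            ]
            buf.write(f"{gm.individual_ids[i]} , " + " ".join(toks) + "\n")
    fh, owned = _open_text(path_or_file, "w")
    try:
        fh.write(buf.getvalue())
    finally:
        if owned:
            fh.close()


def read_morphology(path_or_file) -> pd.DataFrame:
    """Read and validate a per-individual morphology CSV."""
    fh, owned = _open_text(path_or_file)
    try:
        df = pd.read_csv(fh)
    finally:
        if owned:
            fh.close()
    return validate_morphology(df)


def read_sites(path_or_file) -> pd.DataFrame:
    """Read a site table CSV (site, rainfall_mm); recompute rainfall_category."""
    fh, owned = _open_text(path_or_file)
    try:
        df = pd.read_csv(fh)
    finally:
        if owned:
            fh.close()
    return validate_sites(df)


def read_distances(path_or_file) -> DistanceMatrix:
    """Read a square distance-matrix CSV (site labels as header row + first column)."""
    fh, owned = _open_text(path_or_file)
    try:
        df = pd.read_csv(fh, index_col=0)
    finally:
        if owned:
            fh.close()
    sites = [str(s) for s in df.columns]
    if [str(s) for s in df.index] != sites:
        raise FormatError("distance matrix row and column labels disagree")
    return DistanceMatrix(sites, df.to_numpy(dtype=float))


def write_distances(dm: DistanceMatrix, path_or_file) -> None:
    df = pd.DataFrame(dm.values, index=dm.sites, columns=dm.sites)
    fh, owned = _open_text(path_or_file, "w")
    try:
        df.to_csv(fh)
    finally:
        if owned:
            fh.close()
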