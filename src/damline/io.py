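"""Readers and writers for PED/MAP panels and the auxiliary text tables.

Formats
-------
PED/MAP are the familiar whitespace-delimited genotype files: six leading
PED columns (family, id, sire, dam, sex, phenotype) followed by two allele
tokens per SNP.  The MAP file is written with six columns — chromosome,
SNP id, genetic position (cM), physical position, allele1, allele2 — where
allele1 is the counted (reference) allele.  A plain four-column MAP is
also accepted; the reference allele is then the alphabetically first
allele observed at each SNP.

Line labels travel in a separate two-column table (animal_id, line)
because PED family fields are unreliable in practice.  Missing genotypes
("0 0") are rejected by default; per-SNP within-line mean imputation can
be requested explicitly.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (CROSSBRED, MISSING_PARENT, ORIGIN_CHARS, ORIGIN_CODES,
                        DamlineError, GenotypePanel, MarkerMap, OriginMatrix,
                        Pedigree, ProportionEstimates, PUREBRED_LINES)

__all__ = [
    "read_pedmap", "write_pedmap", "maf_filter",
    "read_line_table", "write_line_table",
    "read_pedigree", "write_pedigree",
    "read_origins", "write_origins",
    "read_estimates", "write_estimates",
]


class ParseError(DamlineError):
    """Malformed input file; message names the offending line."""


def read_map(map_path) -> MarkerMap:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) == 4:
                rows.append((tok[0], tok[1], float(tok[2]), int(tok[3]), None, None))
            elif len(tok) == 6:
                rows.append((tok[0], tok[1], float(tok[2]), int(tok[3]), tok[4], tok[5]))
            else:
                raise ParseError(f"{map_path}:{lineno}: expected 4 or 6 columns, got {len(tok)}")
    if not rows:
        raise ParseError(f"{map_path}: empty map file")
    table = pd.DataFrame(rows, columns=["chrom", "snp", "cm", "bp", "a1", "a2"])
    return table


def read_pedmap(ped_path, map_path, line_table: Mapping[str, str],
                impute_missing: bool = False) -> GenotypePanel:
    """Read a PED/MAP pair into a :class:`GenotypePanel`.

    ``line_table`` maps animal id to line label ({A, B, C, ABC}).
    Genotypes are counts of the reference allele (MAP ``a1``).  Missing
    genotypes raise unless ``impute_missing`` is set, in which case they
    are replaced by the per-SNP mean allele count within the animal's
    line (rounded to the nearest legal count) and a note is attached.
    """
    table = read_map(map_path)
    m = len(table)
    ids, lines, geno_alleles = [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} columns, got {len(tok)}")
            animal = tok[1]
            if animal not in line_table:
                raise ParseError(f"{ped_path}:{lineno}: animal {animal!r} missing from line table")
            ids.append(animal)
            lines.append(line_table[animal])
            geno_alleles.append(tok[6:])
    alleles = np.array(geno_alleles, dtype=object).reshape(len(ids), m, 2) if ids else \
        np.empty((0, m, 2), dtype=object)

    # resolve reference alleles for 4-column maps
    a1 = table["a1"].to_numpy(object).copy()
    a2 = table["a2"].to_numpy(object).copy()
    for j in range(m):
        if a1[j] is None:
            seen = sorted(set(alleles[:, j, :].ravel()) - {"0"}) if len(ids) else []
            if not seen:
                raise ParseError(f"{map_path}: SNP {table['snp'][j]}: no alleles observed "
                                 "and none declared in the map")
            a1[j] = seen[0]
            a2[j] = seen[1] if len(seen) > 1 else seen[0]
    table = table.assign(a1=a1, a2=a2)

    genotypes = np.zeros((len(ids), m), dtype=np.int8)
    missing = np.zeros((len(ids), m), dtype=bool)
    for j in range(m):
        col = alleles[:, j, :] if len(ids) else np.empty((0, 2), dtype=object)
        is_missing = (col == "0").any(axis=1) if len(ids) else np.zeros(0, bool)
        known = {a1[j], a2[j]}
        bad = ~is_missing & ~np.isin(col, list(known)).all(axis=1) if len(ids) else np.zeros(0, bool)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{ped_path}: animal {ids[i]}: allele not in map at SNP {table['snp'][j]}")
        genotypes[:, j] = (col == a1[j]).sum(axis=1)
        missing[:, j] = is_missing
    if missing.any():
        if not impute_missing:
            i, j = map(int, np.argwhere(missing)[0])
            raise ParseError(
                f"{ped_path}: animal {ids[i]}: missing genotype at SNP {table['snp'][j]} "
                "(pass impute_missing=True to mean-impute within line)")
        lines_arr = np.asarray(lines, dtype=object)
        for line_label in np.unique(lines_arr):
            rows = lines_arr == line_label
            for j in np.flatnonzero(missing[rows].any(axis=0)):
                obs = genotypes[rows, j][~missing[rows, j]]
                fill = int(round(obs.mean())) if obs.size else 1
                sub = genotypes[rows, j]
                sub[missing[rows, j]] = fill
                genotypes[rows, j] = sub

    markers = MarkerMap(table)
    return GenotypePanel(np.asarray(ids, object), np.asarray(lines, object),
                         genotypes, markers)


def write_pedmap(panel: GenotypePanel, out_prefix) -> tuple[str, str]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; returns the two paths."""
    out_prefix = os.fspath(out_prefix)
    ped_path, map_path = out_prefix + ".ped", out_prefix + ".map"
    tab = panel.markers.table
    with open(map_path, "w") as fh:
        for _, r in tab.iterrows():
            fh.write(f"{r['chrom']} {r['snp']} {r['cm']:.6f} {int(r['bp'])} "
                     f"{r['a1']} {r['a2']}\n")
    a1 = tab["a1"].to_numpy(object)
    a2 = tab["a2"].to_numpy(object)
    with open(ped_path, "w") as fh:
        for i in range(panel.n_animals):
            g = panel.genotypes[i]
            pairs = np.empty((panel.n_snps, 2), dtype=object)
            pairs[:, 0] = np.where(g >= 1, a1, a2)
            pairs[:, 1] = np.where(g == 2, a1, a2)
            fields = [str(panel.lines[i]), str(panel.ids[i]), "0", "0", "0", "-9"]
            fields.extend(pairs.ravel())
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def maf_filter(panel: GenotypePanel, threshold: float = 0.1) -> GenotypePanel:
    """Keep SNPs whose minor allele frequency over *all* animals exceeds ``threshold``.

    The frequency is computed jointly across every animal in the panel
    (purebreds and crossbreds alike); a SNP survives iff
    min(p, 1 - p) > threshold, strictly.
    """
    if not 0 <= threshold < 0.5:
        raise DamlineError("MAF threshold must be in [0, 0.5)")
    p = panel.allele_freqs()
    maf = np.minimum(p, 1.0 - p)
    return panel.subset_snps(np.flatnonzero(maf > threshold))


# ---------------------------------------------------------------------------
# auxiliary tables

def read_line_table(path) -> dict[str, str]:
    out: dict[str, str] = {}
    valid = set(PUREBRED_LINES) | {CROSSBRED}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if tok[0].lower() == "animal_id":
                continue
            if len(tok) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            if tok[1] not in valid:
                raise ParseError(f"{path}:{lineno}: unknown line label {tok[1]!r}")
            out[tok[0]] = tok[1]
    return out


def write_line_table(panel: GenotypePanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("animal_id\tline\n")
        for a, l in zip(panel.ids, panel.lines):
            fh.write(f"{a}\t{l}\n")


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return Pedigree(df)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.crossbreds.to_csv(path, sep="\t", index=False)


def write_origins(origins: OriginMatrix, path) -> None:
    """One row per crossbred: id, paternal origin string, maternal origin string."""
    with open(path, "w") as fh:
        fh.write("animal_id\tpaternal\tmaternal\n")
        for i, a in enumerate(origins.ids):
            pat = "".join(ORIGIN_CHARS[c] for c in origins.codes[i, :, 0])
            mat = "".join(ORIGIN_CHARS[c] for c in origins.codes[i, :, 1])
            fh.write(f"{a}\t{pat}\t{mat}\n")


def read_origins(path) -> OriginMatrix:
    ids, rows = [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("animal_id"):
            raise ParseError(f"{path}: missing origins header")
        for lineno, line in enumerate(fh, 2):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            animal, pat, mat = tok
            if len(pat) != len(mat):
                raise ParseError(f"{path}:{lineno}: haplotype length mismatch")
            try:
                codes = np.array([[ORIGIN_CODES[c] for c in pat],
                                  [ORIGIN_CODES[c] for c in mat]], dtype=np.int8).T
            except KeyError as e:
                raise ParseError(f"{path}:{lineno}: bad origin symbol {e.args[0]!r}") from None
            ids.append(animal)
            rows.append(codes)
    return OriginMatrix(np.asarray(ids, object), np.stack(rows) if rows
                        else np.empty((0, 0, 2), np.int8))


def write_estimates(estimates: ProportionEstimates, path) -> None:
    estimates.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_estimates(path) -> ProportionEstimates:
    df = pd.read_csv(path, sep="\t",
                     dtype={"animal": str, "method": str, "stage": str})
    method = df["method"].iloc[0] if len(df) else "UNKNOWN"
    stage = df["stage"].iloc[0] if len(df) else "raw"
    return ProportionEstimates(
        df["animal"].to_numpy(object), df["b_B"].to_numpy(float),
        df["b_C"].to_numpy(float), method, stage,
        q_a=df["q_A"].to_numpy(float) if "q_A" in df else None)
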