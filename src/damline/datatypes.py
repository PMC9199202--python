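"""Core containers for crossbred line-composition analysis.

The objects here are deliberately thin: numpy arrays for genotypes and
allele origins, a pandas table for the marker map, plus small dataclasses
that carry validation.  All estimators operate on these containers.

Line labels
-----------
``"A"`` is the sire line of the 3-way cross, ``"B"`` and ``"C"`` the two
dam lines (line-B maternal grandsire, line-C maternal granddam), and
``"ABC"`` marks the A(BC) crossbreds themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LINE_A = "A"
LINE_B = "B"
LINE_C = "C"
CROSSBRED = "ABC"
PUREBRED_LINES = (LINE_A, LINE_B, LINE_C)

#: integer codes used in :class:`OriginMatrix`
ORIGIN_A = 0
ORIGIN_B = 1
ORIGIN_C = 2
ORIGIN_UNASSIGNED = -1
ORIGIN_CHARS = {ORIGIN_A: "A", ORIGIN_B: "B", ORIGIN_C: "C", ORIGIN_UNASSIGNED: "U"}
ORIGIN_CODES = {v: k for k, v in ORIGIN_CHARS.items()}

MISSING_PARENT = "0"


class DamlineError(ValueError):
    """Base error for invalid inputs to the damline data model."""


@dataclass
class MarkerMap:
    """Per-SNP map: chromosome, genetic position (cM), allele codes.

    ``table`` columns: ``chrom``, ``snp``, ``cm``, ``bp``, ``a1``, ``a2``.
    The counted (reference) allele of every genotype is ``a1``.
    ``lengths`` holds the total genetic length of each chromosome in
    Morgan; it may exceed the span of the mapped SNPs.
    """

    table: pd.DataFrame
    lengths: dict[str, float] | None = None

    def __post_init__(self) -> None:
        required = ["chrom", "snp", "cm", "bp", "a1", "a2"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise DamlineError(f"marker map missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        for chrom, sub in self.table.groupby("chrom", sort=False):
            cm = sub["cm"].to_numpy(float)
            if np.any(np.diff(cm) < 0):
                raise DamlineError(f"positions decrease within chromosome {chrom}")
        for col in ("a1", "a2"):
            if self.table[col].astype(str).str.len().eq(0).any():
                raise DamlineError("empty allele code in marker map")
        if self.lengths is not None:
            for chrom, l in self.lengths.items():
                if not l > 0:
                    raise DamlineError(f"chromosome {chrom} length must be > 0")

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    def chromosome_lengths(self) -> dict[str, float]:
        """Chromosome lengths in Morgan; inferred from the SNP span if unset."""
        if self.lengths is not None:
            return dict(self.lengths)
        out = {}
        for chrom, sub in self.table.groupby("chrom", sort=False):
            out[chrom] = max(float(sub["cm"].max()) / 100.0, 1e-6)
        return out

    def chrom_slices(self) -> dict[str, np.ndarray]:
        """SNP index array per chromosome, in map order."""
        idx = {}
        chroms = self.table["chrom"].to_numpy()
        for chrom in self.chromosomes:
            idx[chrom] = np.flatnonzero(chroms == chrom)
        return idx

    def subset(self, indices: np.ndarray) -> "MarkerMap":
        indices = np.asarray(indices)
        return MarkerMap(self.table.iloc[indices].reset_index(drop=True),
                         lengths=None if self.lengths is None else dict(self.lengths))


@dataclass
class GenotypePanel:
    """Animals x SNPs matrix of reference-allele counts with line labels."""

    ids: np.ndarray
    lines: np.ndarray
    genotypes: np.ndarray
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.lines = np.asarray(self.lines, dtype=object)
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise DamlineError("genotypes must be a 2-D matrix")
        if len(self.ids) != self.genotypes.shape[0] or len(self.lines) != self.genotypes.shape[0]:
            raise DamlineError("ids/lines length does not match genotype rows")
        if self.genotypes.shape[1] != self.markers.n_snps:
            raise DamlineError("genotype columns do not match marker map")
        if self.genotypes.size and not np.isin(self.genotypes, (0, 1, 2)).all():
            raise DamlineError("genotype values must be in {0, 1, 2}")
        if len(set(self.ids)) != len(self.ids):
            raise DamlineError("duplicate animal ids")

    @property
    def n_animals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def line_mask(self, line: str) -> np.ndarray:
        return self.lines == line

    def genotypes_of(self, line: str) -> np.ndarray:
        return self.genotypes[self.line_mask(line)]

    def ids_of(self, line: str) -> np.ndarray:
        return self.ids[self.line_mask(line)]

    def allele_freqs(self) -> np.ndarray:
        """Reference-allele frequency per SNP over all animals."""
        if self.n_animals == 0:
            raise DamlineError("empty panel has no allele frequencies")
        return self.genotypes.mean(axis=0) / 2.0

    def subset_animals(self, mask_or_ids) -> "GenotypePanel":
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            mask = arr
        else:
            pos = {a: i for i, a in enumerate(self.ids)}
            mask = np.zeros(self.n_animals, dtype=bool)
            for a in arr:
                if a not in pos:
                    raise DamlineError(f"unknown animal id {a!r}")
                mask[pos[a]] = True
        return GenotypePanel(self.ids[mask], self.lines[mask],
                             self.genotypes[mask], self.markers)

    def subset_snps(self, indices: np.ndarray) -> "GenotypePanel":
        indices = np.asarray(indices)
        return GenotypePanel(self.ids, self.lines,
                             self.genotypes[:, indices], self.markers.subset(indices))

    def row(self, animal_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.ids == animal_id)
        if idx.size != 1:
            raise DamlineError(f"animal id {animal_id!r} not found")
        return self.genotypes[idx[0]]


@dataclass
class Pedigree:
    """Links each A(BC) crossbred to its sire, F1 dam and maternal grandparents.

    ``crossbreds`` columns: ``id``, ``sire``, ``dam``, ``mgs`` (line-B
    maternal grandsire), ``mgd`` (line-C maternal granddam).  ``"0"``
    marks an unknown/ungenotyped parent.
    """

    crossbreds: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["id", "sire", "dam", "mgs", "mgd"]
        missing = [c for c in required if c not in self.crossbreds.columns]
        if missing:
            raise DamlineError(f"pedigree missing columns: {missing}")
        self.crossbreds = self.crossbreds.reset_index(drop=True)
        tab = self.crossbreds
        for _, row in tab.iterrows():
            ancestors = {row["sire"], row["dam"], row["mgs"], row["mgd"]} - {MISSING_PARENT}
            if row["id"] in ancestors:
                raise DamlineError(f"animal {row['id']} is its own ancestor")

    def validate_lines(self, panel: GenotypePanel) -> None:
        """Check grandparent line labels against a genotype panel."""
        line_of = dict(zip(panel.ids, panel.lines))
        for _, row in self.crossbreds.iterrows():
            for col, want in (("mgs", LINE_B), ("mgd", LINE_C)):
                gp = row[col]
                if gp != MISSING_PARENT and gp in line_of and line_of[gp] != want:
                    raise DamlineError(
                        f"{col} {gp} of {row['id']} has line {line_of[gp]}, expected {want}")


@dataclass
class OriginMatrix:
    """Per-animal, per-SNP, per-haplotype line of origin.

    ``codes`` has shape (n_animals, n_snps, 2); axis 2 is
    (paternal, maternal) gamete.  Values are the ``ORIGIN_*`` codes.
    """

    ids: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 3 or self.codes.shape[2] != 2:
            raise DamlineError("origin codes must have shape (n, m, 2)")
        if len(self.ids) != self.codes.shape[0]:
            raise DamlineError("origin ids do not match code rows")
        valid = (ORIGIN_A, ORIGIN_B, ORIGIN_C, ORIGIN_UNASSIGNED)
        if self.codes.size and not np.isin(self.codes, valid).all():
            raise DamlineError("invalid origin code")

    @property
    def n_animals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def subset_snps(self, indices: np.ndarray) -> "OriginMatrix":
        return OriginMatrix(self.ids, self.codes[:, np.asarray(indices), :])

    def has_unassigned(self) -> bool:
        return bool((self.codes == ORIGIN_UNASSIGNED).any())


@dataclass
class ProportionEstimates:
    """Per-animal dam-line proportions for one method and stage.

    The sire-line proportion b_A is fixed at 0.5 by the cross design and
    is not stored.  ``stage`` is ``"raw"`` or ``"postprocessed"``; only
    the latter guarantees b_B, b_C in [0, 0.5] with b_B + b_C = 0.5.
    """

    ids: np.ndarray
    b_b: np.ndarray
    b_c: np.ndarray
    method: str
    stage: str = "raw"
    q_a: np.ndarray | None = None
    residual_norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.b_b = np.asarray(self.b_b, dtype=float)
        self.b_c = np.asarray(self.b_c, dtype=float)
        if not (len(self.ids) == len(self.b_b) == len(self.b_c)):
            raise DamlineError("estimate arrays have mismatched lengths")
        if self.stage not in ("raw", "postprocessed"):
            raise DamlineError(f"unknown stage {self.stage!r}")
        if self.stage == "postprocessed" and len(self.b_b):
            s = self.b_b + self.b_c
            inside = ((self.b_b >= -1e-12) & (self.b_b <= 0.5 + 1e-12)).all()
            if not inside or np.abs(s - 0.5).max() > 1e-9:
                raise DamlineError("postprocessed estimates violate constraints")

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"animal": self.ids, "method": self.method,
                           "stage": self.stage, "b_B": self.b_b, "b_C": self.b_c})
        if self.q_a is not None:
            df["q_A"] = self.q_a
        if self.residual_norm is not None:
            df["residual_norm"] = self.residual_norm
        return df

    def restrict(self, ids: Sequence) -> "ProportionEstimates":
        """Subset (and reorder) to the given animal ids."""
        pos = {a: i for i, a in enumerate(self.ids)}
        try:
            idx = np.array([pos[a] for a in ids], dtype=int)
        except KeyError as e:
            raise DamlineError(f"animal {e.args[0]!r} missing from estimates") from None
        return ProportionEstimates(
            self.ids[idx], self.b_b[idx], self.b_c[idx], self.method, self.stage,
            None if self.q_a is None else self.q_a[idx],
            None if self.residual_norm is None else self.residual_norm[idx])


@dataclass
class LineFrequencies:
    """Per-SNP reference-allele frequencies for the three purebred lines.

    ``p`` has shape (n_snps, 3) with columns (A, B, C).  Mean allele
    counts are x = 2p.  The crossbred blend is the expectation-weighted
    mixture 0.5 p_A + 0.25 p_B + 0.25 p_C.
    """

    p: np.ndarray
    provenance: str = "purebred-count"

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[1] != 3:
            raise DamlineError("line frequencies must have shape (m, 3)")
        if self.p.size and (self.p.min() < -1e-12 or self.p.max() > 1 + 1e-12):
            raise DamlineError("line frequencies outside [0, 1]")
        if self.provenance not in ("purebred-count", "regression"):
            raise DamlineError(f"unknown provenance {self.provenance!r}")

    @property
    def p_a(self) -> np.ndarray:
        return self.p[:, 0]

    @property
    def p_b(self) -> np.ndarray:
        return self.p[:, 1]

    @property
    def p_c(self) -> np.ndarray:
        return self.p[:, 2]

    @property
    def x(self) -> np.ndarray:
        """Mean allele counts per line, x = 2p, shape (m, 3)."""
        return 2.0 * self.p

    @property
    def blend(self) -> np.ndarray:
        return 0.5 * self.p_a + 0.25 * self.p_b + 0.25 * self.p_c

    def to_frame(self, markers: MarkerMap | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"p_A": self.p_a, "p_B": self.p_b, "p_C": self.p_c,
                           "blend": self.blend, "provenance": self.provenance})
        if markers is not None:
            df.insert(0, "snp", markers.table["snp"].to_numpy())
        return df

    def subset_snps(self, indices: np.ndarray) -> "LineFrequencies":
        return LineFrequencies(self.p[np.asarray(indices)], self.provenance)


@dataclass
class EvaluationReport:
    """Quality of one method's estimates against a reference."""

    method: str
    reference: str
    accuracy: float
    slope: float
    max_abs_error: float
    rmse: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DamlineError("evaluation needs at least 2 animals")
        if not -1 - 1e-9 <= self.accuracy <= 1 + 1e-9:
            raise DamlineError("correlation outside [-1, 1]")
        if self.max_abs_error < 0 or self.rmse < 0:
            raise DamlineError("errors must be non-negative")

    def to_dict(self) -> dict:
        return {"method": self.method, "reference": self.reference,
                "accuracy": self.accuracy, "dispersion_bias": self.slope,
                "max_error": self.max_abs_error, "rmse": self.rmse, "n": self.n}
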