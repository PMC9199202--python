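"""Forward-in-time simulation of a 3-way cross with allele-origin tracking.

The simulator reconstructs the study design: three purebred lines (A, B,
C) diverge from a common base population by pure drift (random mating,
no mutation, no selection), after which line-B sires are mated to line-C
dams to produce F1 dams, and line-A sires to those F1 dams to produce
A(BC) crossbreds.  Every crossbred allele carries a line-of-origin label
inherited segment-wise through meiosis, which yields the gold-standard
true dam-line proportions.

Recombination follows the Haldane model: the crossover count per
chromosome is Poisson with mean equal to the map length in Morgan,
crossover positions are uniform, and there is no interference.

Divergence presets are calibrated so that the realised between-line
F_ST matches the study conditions (0.04 / 0.12 / 0.22 for lines split
5 / 20 / 50 generations ago).  The per-line Ne values were calibrated
empirically against the realised mean-of-ratios Weir-Cockerham estimate
on the MAF-filtered panel, since the closed-form drift approximation
E[F_ST] ~ 1 - (1 - 1/(2 Ne))^t does not account for the estimator
convention or the filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import (CROSSBRED, LINE_A, LINE_B, LINE_C, ORIGIN_A, ORIGIN_B,
                        ORIGIN_C, DamlineError, GenotypePanel, MarkerMap,
                        OriginMatrix, Pedigree, ProportionEstimates)
from .io import maf_filter

import pandas as pd

__all__ = ["SimulationConfig", "PRESETS", "preset_config", "simulate_scenario",
           "meiosis", "true_proportions", "SimulationResult"]


@dataclass
class SimulationConfig:
    """Parameters of one simulated scenario.

    ``snps_per_chrom`` are the *target* segregating SNP counts after the
    joint MAF filter; the simulator oversamples by ``oversample`` and
    thins evenly so the final panel matches the intended marker density.
    """

    t: int = 50                       # generations of line divergence
    ne: int = 100                     # per-line effective size during divergence
    burnin: int = 100                 # base-population generations (builds LD)
    chrom_lengths: tuple = (3.20, 0.61)      # Morgan
    snps_per_chrom: tuple = (4800, 920)      # post-filter targets
    oversample: float = 2.2
    n_purebred: int = 1000            # genotyped purebreds per line
    n_sires_b: int = 25               # line-B maternal grandsires
    n_dams_c: int = 100               # line-C maternal granddams
    n_f1_dams: int = 200
    n_crossbred: int = 428
    grandparent_masking: float = 0.0  # P(a grandparent's genotype is unavailable)
    maf_threshold: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t < 0 or self.burnin < 0:
            raise DamlineError("generation counts must be non-negative")
        if self.ne < 2:
            raise DamlineError("Ne must be at least 2")
        if any(l <= 0 for l in self.chrom_lengths):
            raise DamlineError("chromosome lengths must be positive")
        if len(self.chrom_lengths) != len(self.snps_per_chrom):
            raise DamlineError("chrom_lengths and snps_per_chrom lengths differ")
        if not 0 <= self.grandparent_masking <= 1:
            raise DamlineError("masking probability must be in [0, 1]")
        if self.n_sires_b > self.n_purebred or self.n_dams_c > self.n_purebred:
            raise DamlineError("cannot draw more cross parents than genotyped purebreds")


#: divergence presets; Ne calibrated so the realised mean-of-ratios
#: Weir-Cockerham F_ST on the MAF-filtered panel matches 0.04/0.12/0.22
PRESETS = {
    "close": dict(t=5, ne=68),
    "distant": dict(t=20, ne=72),
    "unrelated": dict(t=50, ne=82),
}


def preset_config(name: str, **overrides) -> SimulationConfig:
    if name not in PRESETS:
        raise DamlineError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass
class SimulationResult:
    panel: GenotypePanel
    pedigree: Pedigree
    origins: OriginMatrix
    truth: ProportionEstimates
    config: SimulationConfig


def meiosis(parent_haplotypes: np.ndarray, markers: MarkerMap,
            rng: np.random.Generator,
            parent_origins: np.ndarray | None = None):
    """Produce one gamete from a parent's two haplotypes.

    ``parent_haplotypes`` has shape (2, m).  Crossovers per chromosome are
    Poisson(length in Morgan) at uniform positions; the starting haplotype
    is chosen with probability 1/2.  If ``parent_origins`` (2, m) is
    given, origin labels are inherited with the same segments and the
    gamete's origin vector is returned alongside.
    """
    haps = np.asarray(parent_haplotypes)
    if haps.shape != (2, markers.n_snps):
        raise DamlineError("haplotypes do not match marker map")
    source = _gamete_sources(markers, rng)
    gamete = haps[source, np.arange(haps.shape[1])]
    if parent_origins is None:
        return gamete
    origins = np.asarray(parent_origins)[source, np.arange(haps.shape[1])]
    return gamete, origins


def _gamete_sources(markers: MarkerMap, rng: np.random.Generator) -> np.ndarray:
    """Per-SNP parental haplotype index (0/1) for one meiosis."""
    lengths = markers.chromosome_lengths()
    out = np.empty(markers.n_snps, dtype=np.int8)
    for chrom, idx in markers.chrom_slices().items():
        l = lengths[chrom]
        cm = markers.table["cm"].to_numpy(float)[idx]
        k = rng.poisson(l)
        start = rng.integers(2)
        if k == 0:
            out[idx] = start
            continue
        xo = np.sort(rng.uniform(0.0, l, size=k)) * 100.0  # cM
        out[idx] = (start + np.searchsorted(xo, cm, side="right")) % 2
    return out


class _Mapper:
    """Precomputed per-chromosome positions for fast batched meiosis."""

    def __init__(self, markers: MarkerMap):
        self.lengths = markers.chromosome_lengths()
        self.chroms = []
        cm_all = markers.table["cm"].to_numpy(float)
        for chrom, idx in markers.chrom_slices().items():
            self.chroms.append((idx, self.lengths[chrom], cm_all[idx]))
        self.m = markers.n_snps

    def sources(self, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(self.m, dtype=np.intp)
        for idx, l, cm in self.chroms:
            k = rng.poisson(l)
            start = rng.integers(2)
            if k == 0:
                out[idx] = start
            else:
                xo = np.sort(rng.uniform(0.0, l, size=k)) * 100.0
                out[idx] = (start + np.searchsorted(xo, cm, side="right")) % 2
        return out


def _next_generation(haps: np.ndarray, n_off: int, mapper: _Mapper,
                     rng: np.random.Generator) -> np.ndarray:
    """Random mating: each offspring draws two distinct parents."""
    n = haps.shape[0]
    fathers = rng.integers(n, size=n_off)
    mothers = rng.integers(n, size=n_off)
    clash = fathers == mothers
    while clash.any():
        mothers[clash] = rng.integers(n, size=int(clash.sum()))
        clash = fathers == mothers
    cols = np.arange(mapper.m)
    out = np.empty((n_off, 2, mapper.m), dtype=haps.dtype)
    for i in range(n_off):
        out[i, 0] = haps[fathers[i], mapper.sources(rng), cols]
        out[i, 1] = haps[mothers[i], mapper.sources(rng), cols]
    return out


def true_proportions(origins: OriginMatrix) -> ProportionEstimates:
    """Gold-standard dam-line proportions from complete allele origins.

    b_line = (#alleles with that origin) / (2 * #SNPs).  Raises if any
    allele is unassigned (use :func:`damline.estimators.boa_proportions`
    for partial assignments).
    """
    if origins.has_unassigned():
        raise DamlineError("origins contain unassigned alleles; use boa_proportions")
    total = 2.0 * origins.n_snps
    b_b = (origins.codes == ORIGIN_B).sum(axis=(1, 2)) / total
    b_c = (origins.codes == ORIGIN_C).sum(axis=(1, 2)) / total
    return ProportionEstimates(origins.ids, b_b, b_c, method="TRUE", stage="raw")


def simulate_scenario(config: SimulationConfig) -> SimulationResult:
    """Run one full scenario; deterministic for a fixed config (incl. seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    # --- marker map (oversampled; thinned after the MAF filter) ---
    chroms, snps, cms, bps = [], [], [], []
    for c, (length, target) in enumerate(zip(config.chrom_lengths, config.snps_per_chrom), 1):
        m_c = max(int(round(target * config.oversample)), target)
        pos = np.sort(rng.uniform(0.0, length, size=m_c)) * 100.0  # cM
        chroms.extend([str(c)] * m_c)
        snps.extend(f"snp{c}_{j + 1}" for j in range(m_c))
        cms.extend(pos)
        bps.extend((pos * 1e4).astype(int) + 1)
    table = pd.DataFrame({"chrom": chroms, "snp": snps, "cm": cms, "bp": bps,
                          "a1": "A", "a2": "B"})
    markers = MarkerMap(table, lengths={str(c + 1): l
                                        for c, l in enumerate(config.chrom_lengths)})
    mapper = _Mapper(markers)
    m = markers.n_snps

    # --- base population and burn-in (builds LD) ---
    p0 = rng.uniform(0.05, 0.95, size=m)
    haps = (rng.random((config.ne, 2, m)) < p0).astype(np.int8)
    for _ in range(config.burnin):
        haps = _next_generation(haps, config.ne, mapper, rng)

    # --- line divergence: each line breeds separately from the shared base ---
    line_haps = {}
    for line in (LINE_A, LINE_B, LINE_C):
        lh = _next_generation(haps, config.ne, mapper, rng)
        for _ in range(config.t):
            lh = _next_generation(lh, config.ne, mapper, rng)
        # expansion: the genotyped purebred cohort
        line_haps[line] = _next_generation(lh, config.n_purebred, mapper, rng)

    ids = {line: np.array([f"{line}{i + 1:05d}" for i in range(config.n_purebred)],
                          dtype=object) for line in (LINE_A, LINE_B, LINE_C)}

    # --- the cross ---
    cols = np.arange(m)
    sires_b = rng.choice(config.n_purebred, size=config.n_sires_b, replace=False)
    dams_c = rng.choice(config.n_purebred, size=config.n_dams_c, replace=False)
    sires_a = rng.choice(config.n_purebred, size=config.n_sires_b, replace=False)

    f1_haps = np.empty((config.n_f1_dams, 2, m), dtype=np.int8)
    f1_orig = np.empty((config.n_f1_dams, 2, m), dtype=np.int8)
    f1_sire = rng.integers(config.n_sires_b, size=config.n_f1_dams)
    f1_dam = rng.integers(config.n_dams_c, size=config.n_f1_dams)
    for i in range(config.n_f1_dams):
        f1_haps[i, 0] = line_haps[LINE_B][sires_b[f1_sire[i]], mapper.sources(rng), cols]
        f1_haps[i, 1] = line_haps[LINE_C][dams_c[f1_dam[i]], mapper.sources(rng), cols]
    f1_orig[:, 0, :] = ORIGIN_B
    f1_orig[:, 1, :] = ORIGIN_C

    n_x = config.n_crossbred
    x_haps = np.empty((n_x, 2, m), dtype=np.int8)
    x_orig = np.empty((n_x, 2, m), dtype=np.int8)
    x_sire = rng.integers(config.n_sires_b, size=n_x)
    x_f1 = rng.integers(config.n_f1_dams, size=n_x)
    for i in range(n_x):
        x_haps[i, 0] = line_haps[LINE_A][sires_a[x_sire[i]], mapper.sources(rng), cols]
        src = mapper.sources(rng)
        x_haps[i, 1] = f1_haps[x_f1[i], src, cols]
        x_orig[i, 1] = f1_orig[x_f1[i], src, cols]
    x_orig[:, 0, :] = ORIGIN_A
    x_ids = np.array([f"X{i + 1:05d}" for i in range(n_x)], dtype=object)

    # --- optional grandparent masking (emulates incomplete genotyping) ---
    genotyped_b = np.ones(config.n_sires_b, dtype=bool)
    genotyped_c = np.ones(config.n_dams_c, dtype=bool)
    if config.grandparent_masking > 0:
        genotyped_b = rng.random(config.n_sires_b) >= config.grandparent_masking
        genotyped_c = rng.random(config.n_dams_c) >= config.grandparent_masking

    # --- assemble panel ---
    keep_mask = {LINE_A: np.ones(config.n_purebred, bool),
                 LINE_B: np.ones(config.n_purebred, bool),
                 LINE_C: np.ones(config.n_purebred, bool)}
    keep_mask[LINE_B][sires_b[~genotyped_b]] = False
    keep_mask[LINE_C][dams_c[~genotyped_c]] = False

    all_ids, all_lines, all_geno = [], [], []
    for line in (LINE_A, LINE_B, LINE_C):
        mask = keep_mask[line]
        all_ids.append(ids[line][mask])
        all_lines.append(np.full(int(mask.sum()), line, dtype=object))
        all_geno.append(line_haps[line][mask].sum(axis=1, dtype=np.int8))
    all_ids.append(x_ids)
    all_lines.append(np.full(n_x, CROSSBRED, dtype=object))
    all_geno.append(x_haps.sum(axis=1, dtype=np.int8))

    panel = GenotypePanel(np.concatenate(all_ids), np.concatenate(all_lines),
                          np.concatenate(all_geno), markers)

    # --- joint MAF filter, then even thinning to the target SNP counts ---
    panel = maf_filter(panel, config.maf_threshold)
    keep = []
    offset = 0
    chrom_idx = panel.markers.chrom_slices()
    for c, target in enumerate(config.snps_per_chrom, 1):
        idx = chrom_idx.get(str(c), np.array([], dtype=int))
        if len(idx) > target:
            sel = np.unique(np.round(np.linspace(0, len(idx) - 1, target)).astype(int))
            idx = idx[sel]
        keep.append(idx)
    keep = np.concatenate(keep)
    # map retained SNPs back to original columns for the origin matrix
    snp_names = panel.markers.table["snp"].to_numpy()
    panel = panel.subset_snps(keep)
    orig_pos = {s: j for j, s in enumerate(markers.table["snp"])}
    orig_cols = np.array([orig_pos[s] for s in snp_names[keep]], dtype=int)

    origins = OriginMatrix(x_ids, x_orig[:, :, orig_cols].transpose(0, 2, 1))
    truth = true_proportions(origins)

    ped = Pedigree(pd.DataFrame({
        "id": x_ids,
        "sire": ids[LINE_A][sires_a[x_sire]],
        "dam": np.array([f"F1{j + 1:04d}" for j in x_f1], dtype=object),
        "mgs": np.where(genotyped_b[f1_sire[x_f1]],
                        ids[LINE_B][sires_b[f1_sire[x_f1]]], "0"),
        "mgd": np.where(genotyped_c[f1_dam[x_f1]],
                        ids[LINE_C][dams_c[f1_dam[x_f1]]], "0"),
    }))
    return SimulationResult(panel, ped, origins, truth, config)
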