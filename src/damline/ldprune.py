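"""Windowed pairwise-r2 LD pruning of SNP panels.

Mirrors the familiar ``--indep-pairwise <window> <step> <threshold>``
behaviour: slide a window of ``window`` SNPs along each chromosome,
advancing ``step`` SNPs at a time; within each window, while any
surviving pair has r2 above the threshold, drop one member of the worst
pair.  The removal rule here is a fixed convention — drop the lower-MAF
member, breaking ties towards the later index — so the contract is the
post-condition (no surviving within-window pair above the threshold),
not index-level agreement with any particular external tool.
"""

from __future__ import annotations

import numpy as np

from .datatypes import DamlineError, GenotypePanel

__all__ = ["pairwise_r2", "indep_pairwise", "prune_panel"]


def pairwise_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two allele-count vectors.

    This is the composite-LD r2 on unphased genotypes.  A zero-variance
    vector yields 0 by convention (such SNPs never trigger pruning).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.ndim != 1 or len(g1) < 2:
        raise DamlineError("pairwise_r2 needs two equal-length vectors of length >= 2")
    v1 = g1.var()
    v2 = g2.var()
    if v1 == 0.0 or v2 == 0.0:
        return 0.0
    c = ((g1 - g1.mean()) * (g2 - g2.mean())).mean()
    return float(c * c / (v1 * v2))


def _window_r2(g: np.ndarray) -> np.ndarray:
    """r2 matrix of the columns of ``g``; zero-variance columns give 0."""
    gc = g - g.mean(axis=0)
    sd = gc.std(axis=0)
    cov = gc.T @ gc / g.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.outer(sd, sd)
    r[~np.isfinite(r)] = 0.0
    return r * r


def indep_pairwise(panel: GenotypePanel, window: int = 50, step: int = 10,
                   threshold: float = 0.5) -> np.ndarray:
    """Indices of SNPs surviving windowed pairwise-r2 pruning.

    Guarantees that no pair of surviving SNPs within any visited window
    has r2 strictly above ``threshold``.
    """
    if window < 2:
        raise DamlineError("window must be at least 2 SNPs")
    if not 1 <= step <= window:
        raise DamlineError("step must be in [1, window]")
    g = panel.genotypes.astype(float)
    p = panel.allele_freqs()
    maf = np.minimum(p, 1.0 - p)
    alive = np.ones(panel.n_snps, dtype=bool)
    for idx in panel.markers.chrom_slices().values():
        start = 0
        while True:
            win = idx[start:start + window]
            if len(win) >= 2:
                _prune_window(g, maf, alive, win, threshold)
            if start + window >= len(idx):
                break
            start += step
    return np.flatnonzero(alive)


def _prune_window(g, maf, alive, win, threshold) -> None:
    live = win[alive[win]]
    if len(live) < 2:
        return
    r2 = _window_r2(g[:, live])
    np.fill_diagonal(r2, 0.0)
    keep = np.ones(len(live), dtype=bool)
    while True:
        sub = np.where(np.outer(keep, keep), r2, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= threshold:
            break
        # drop the lower-MAF member; ties go to the later index
        mi, mj = maf[live[i]], maf[live[j]]
        drop = (i if mi < mj else j) if mi != mj else max(i, j)
        keep[drop] = False
    alive[live[~keep]] = False


def prune_panel(panel: GenotypePanel, window: int = 50, step: int = 10,
                threshold: float = 0.5) -> GenotypePanel:
    """Convenience wrapper returning the pruned panel itself."""
    return panel.subset_snps(indep_pairwise(panel, window, step, threshold))
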