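"""Evaluation metrics, the theoretical proportion distribution, and F_ST.

Accuracy is the Pearson correlation between estimated and reference
line-B proportions; dispersion bias is the slope of regressing the
*reference on the estimate* (1 = correctly scaled, < 1 = inflated
estimates); maximum absolute error and RMSE summarise the error
distribution.

The theoretical distribution of a dam-line proportion has mean 0.25 and
a variance that follows from the variance of grandparent-grand-offspring
genome sharing for a non-inbred grandparent: along a chromosome of
genetic length l Morgan the origin of a gamete's alleles switches at
crossovers (Haldane model), giving a per-chromosome gamete-fraction
variance

    v(l) = (1 / (2 l^2)) * (l/2 - (1 - exp(-2 l)) / 4),

combined across chromosomes with length-squared weights, and divided by
4 because the dam-line proportion is half the maternal-gamete fraction.

F_ST uses the Weir-Cockerham (1984) theta estimator, averaged over loci
(mean of per-locus ratios), for any number of populations; a pairwise
mode returns the value for each pair of lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import (PUREBRED_LINES, DamlineError, EvaluationReport,
                        GenotypePanel, ProportionEstimates)

__all__ = ["evaluate", "theoretical_variance", "TheoreticalDistribution",
           "fst_wc", "method_correlation_table", "proportion_histogram_figure"]


def _aligned(est: ProportionEstimates, ref: ProportionEstimates):
    if set(est.ids) != set(ref.ids):
        raise DamlineError("estimate and reference cover different animals")
    ref = ref.restrict(est.ids)
    return est, ref


def evaluate(est: ProportionEstimates, ref: ProportionEstimates,
             line: str = "B") -> EvaluationReport:
    """Quality of ``est`` against ``ref`` on the common animal set."""
    est, ref = _aligned(est, ref)
    e = est.b_b if line == "B" else est.b_c
    r = ref.b_b if line == "B" else ref.b_c
    n = len(e)
    if n < 2:
        raise DamlineError("evaluation needs at least 2 animals")
    if e.var() == 0:
        raise DamlineError("estimates have zero variance; accuracy undefined")
    accuracy = float(np.corrcoef(e, r)[0, 1])
    slope = float(np.cov(r, e, ddof=1)[0, 1] / e.var(ddof=1))
    err = e - r
    return EvaluationReport(method=est.method, reference=ref.method,
                            accuracy=accuracy, slope=slope,
                            max_abs_error=float(np.abs(err).max()),
                            rmse=float(np.sqrt(np.mean(err ** 2))), n=n)


@dataclass
class TheoreticalDistribution:
    """Expected mean and variance of a dam-line proportion."""

    mean: float
    variance: float
    lengths: tuple

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))

    def density(self, x: np.ndarray) -> np.ndarray:
        """Normal approximation to the proportion density (for plotting)."""
        x = np.asarray(x, float)
        return np.exp(-0.5 * ((x - self.mean) / self.sd) ** 2) / \
            (self.sd * np.sqrt(2 * np.pi))


def _chrom_variance(l: float) -> float:
    """Variance of the fraction of one gamete (length l Morgan) from one parent."""
    if l < 1e-3:
        # series expansion: the closed form cancels catastrophically as l -> 0
        return 0.25 - l / 6.0 + l * l / 12.0
    return (1.0 / (2.0 * l * l)) * (l / 2.0 - (1.0 - np.exp(-2.0 * l)) / 4.0)


def theoretical_variance(lengths) -> TheoreticalDistribution:
    """Theoretical dam-line proportion distribution for a genome of given map lengths.

    ``lengths`` are per-chromosome genetic lengths in Morgan.  The
    genome-wide gamete-fraction variance combines chromosomes with
    length-squared weights; the line-proportion variance is a quarter of
    it (the proportion is half the maternal-gamete fraction).  As all
    lengths shrink to zero the variance tends to its single-locus limit
    of 1/16.
    """
    lengths = tuple(float(l) for l in np.atleast_1d(np.asarray(lengths, float)))
    if any(l <= 0 for l in lengths):
        raise DamlineError("chromosome lengths must be positive")
    l = np.array(lengths)
    v = np.array([_chrom_variance(li) for li in l])
    gamete_var = float((l ** 2 * v).sum() / l.sum() ** 2)
    return TheoreticalDistribution(mean=0.25, variance=gamete_var / 4.0,
                                   lengths=lengths)


def fst_wc(panel: GenotypePanel, lines=PUREBRED_LINES, pairwise: bool = False):
    """Weir-Cockerham F_ST among the given lines, averaged across loci.

    With ``pairwise=True`` returns ``{(line1, line2): theta}`` for every
    pair; otherwise the multi-population estimate over all ``lines``.
    Loci whose estimator denominator is zero are ignored.
    """
    if pairwise:
        return {pair: _wc_theta([panel.genotypes_of(x) for x in pair])
                for pair in combinations(lines, 2)}
    return _wc_theta([panel.genotypes_of(x) for x in lines])


def _wc_theta(genos) -> float:
    r = len(genos)
    if r < 2:
        raise DamlineError("F_ST needs at least two populations")
    for g in genos:
        if g.shape[0] < 2:
            raise DamlineError("each population needs at least 2 animals")
    n_i = np.array([g.shape[0] for g in genos], dtype=float)
    p_i = np.stack([g.mean(axis=0) / 2.0 for g in genos])          # (r, m)
    h_i = np.stack([(g == 1).mean(axis=0) for g in genos])         # observed het
    n_bar = n_i.mean()
    n_c = (n_i.sum() - (n_i ** 2).sum() / n_i.sum()) / (r - 1)
    p_bar = (n_i[:, None] * p_i).sum(axis=0) / (r * n_bar)
    s2 = (n_i[:, None] * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i[:, None] * h_i).sum(axis=0) / (r * n_bar)

    a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4)
                         / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2.0
    denom = a + b + c
    ok = denom != 0.0
    if not ok.any():
        raise DamlineError("F_ST undefined: all loci monomorphic across populations")
    return float((a[ok] / denom[ok]).mean())


def method_correlation_table(estimates: list[ProportionEstimates]) -> pd.DataFrame:
    """Pearson correlations of line-B proportions between all method pairs."""
    if not estimates:
        raise DamlineError("no estimates given")
    ids = estimates[0].ids
    aligned = [e.restrict(ids) for e in estimates]
    names = [e.method for e in aligned]
    mat = np.corrcoef(np.stack([e.b_b for e in aligned]))
    mat = np.atleast_2d(mat)
    return pd.DataFrame(mat, index=names, columns=names)


def proportion_histogram_figure(est: ProportionEstimates, lengths, path=None):
    """Histogram of line-B proportions with the theoretical density overlaid.

    Returns the matplotlib figure; saves to ``path`` when given.
    Requires matplotlib (optional dependency).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dist = theoretical_variance(lengths)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(est.b_b, bins=30, density=True, color="0.7", edgecolor="0.4")
    x = np.linspace(0.0, 0.5, 400)
    ax.plot(x, dist.density(x), color="red", lw=2,
            label=f"theory: mean 0.25, sd {dist.sd:.3f}")
    ax.set_xlabel("line B proportion")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
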