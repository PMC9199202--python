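"""Dam-line proportion estimators for A(BC) 3-way crossbreds.

Five methods are provided:

``BOA``
    Counting of alleles previously assigned a line of origin (the gold
    standard when origins are known or accurately estimated).
``LR``
    Sire-adjusted linear regression of a crossbred's allele counts on the
    per-line mean allele counts: since b_A = 0.5 exactly, the sire-line
    contribution 0.5 x_A is subtracted from the genotypes and the residual
    is regressed on [x_B, x_C] without intercept.
``ADM``
    Supervised maximum-likelihood admixture: with purebred allele
    frequencies fixed, each crossbred's ancestry vector q on the
    3-simplex maximises the binomial likelihood of its genotypes, fitted
    by EM.  Typically run on an LD-pruned panel.
``REL_GP`` / ``REL_GP_noF``
    The multi-population genomic relationship between a crossbred and its
    line-B maternal grandsire (line-C maternal granddam), which estimates
    the realised fraction of genome inherited from that grandparent —
    i.e. the dam-line proportion.  The ``noF`` variant divides by the
    grandparent's self-relationship G_jj (an estimator of 1 + F) to drop
    the assumption that the grandparent is not inbred.

The estimator classes follow the scikit-learn protocol (``fit`` on a
reference panel of genotypes X with line labels y, ``predict`` on
crossbred genotypes); the module-level functions are thin wrappers that
speak the :class:`~damline.datatypes.GenotypePanel` vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import (CROSSBRED, MISSING_PARENT, ORIGIN_A, ORIGIN_B, ORIGIN_C,
                        ORIGIN_UNASSIGNED, DamlineError, GenotypePanel,
                        LineFrequencies, OriginMatrix, Pedigree,
                        ProportionEstimates)
from .freqs import purebred_line_freqs, regression_line_freqs

__all__ = [
    "RelationshipEntry",
    "LinearRegressionAncestry", "SupervisedAdmixture", "GrandparentRelationship",
    "boa_proportions", "lr_estimate", "admixture_supervised_em",
    "grm_cross", "rel_gp_estimate",
]


@dataclass
class RelationshipEntry:
    """One crossbred-grandparent genomic relationship."""

    crossbred: str
    grandparent: str
    g_ij: float
    g_jj: float

    def __post_init__(self) -> None:
        if not self.g_jj > 0:
            raise DamlineError("grandparent self-relationship must be positive")


def _check_genotypes(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise DamlineError("genotypes must be a 2-D array")
    if X.size and not np.isin(X, (0, 1, 2)).all():
        raise DamlineError("genotype values must be in {0, 1, 2}")
    return X


def _fit_frequencies(X, y, source: str) -> LineFrequencies:
    X = _check_genotypes(X)
    y = np.asarray(y, dtype=object)
    if len(y) != X.shape[0]:
        raise DamlineError("X and y have different lengths")
    from .datatypes import MarkerMap
    table = pd.DataFrame({"chrom": "1", "snp": [f"m{j}" for j in range(X.shape[1])],
                          "cm": np.arange(X.shape[1], dtype=float), "bp": 1,
                          "a1": "A", "a2": "B"})
    panel = GenotypePanel(np.array([f"r{i}" for i in range(X.shape[0])], object),
                          y, X.astype(np.int8), MarkerMap(table))
    if source == "purebred":
        return purebred_line_freqs(panel)
    if source == "regression":
        return regression_line_freqs(panel)
    raise DamlineError(f"unknown freq_source {source!r}")


class _FrequencyBasedAncestry(BaseEstimator):
    """Shared fit logic: learn per-line allele frequencies from a reference panel."""

    freq_source = "purebred"

    def fit(self, X, y):
        """Learn line frequencies from reference genotypes X with line labels y."""
        self.freqs_ = _fit_frequencies(X, y, self.freq_source)
        self.n_features_in_ = self.freqs_.p.shape[0]
        return self

    @classmethod
    def from_frequencies(cls, freqs: LineFrequencies, **params):
        """Build an already-fitted estimator from precomputed line frequencies."""
        est = cls(**params)
        est.freqs_ = freqs
        est.n_features_in_ = freqs.p.shape[0]
        return est

    def _check_fitted(self):
        if not hasattr(self, "freqs_"):
            raise DamlineError("estimator is not fitted")


class LinearRegressionAncestry(_FrequencyBasedAncestry):
    """Sire-adjusted linear regression on per-line mean allele counts.

    Parameters
    ----------
    freq_source : {"purebred", "regression"}
        How line frequencies are learned in ``fit``; the study default for
        this method is direct counting within purebred lines.
    """

    def __init__(self, freq_source: str = "purebred"):
        self.freq_source = freq_source

    def predict(self, X) -> np.ndarray:
        """Raw (b_B, b_C) per crossbred, shape (n, 2); also sets ``residual_norm_``."""
        self._check_fitted()
        G = _check_genotypes(X)
        x = self.freqs_.x  # mean allele counts, (m, 3)
        Z = x[:, 1:]       # regressors [x_B, x_C]
        a = Z.T @ Z
        if np.linalg.matrix_rank(a) < 2 or np.linalg.cond(a) > 1e12:
            raise DamlineError(
                "LR regressors are collinear: line B and C mean allele counts "
                "are proportional at every SNP")
        g_star = G - 0.5 * x[:, 0]
        b = np.linalg.solve(a, Z.T @ g_star.T).T  # (n, 2)
        resid = g_star - b @ Z.T
        self.residual_norm_ = np.linalg.norm(resid, axis=1)
        return b


class SupervisedAdmixture(_FrequencyBasedAncestry):
    """Supervised maximum-likelihood admixture estimation by EM.

    With line allele frequencies p fixed, each animal's ancestry vector q
    on the 3-simplex maximises

        sum_m [ g_m log(sum_k q_k p_mk) + (2 - g_m) log(sum_k q_k (1 - p_mk)) ].

    EM with responsibility-weighted allele shares; the log-likelihood is
    non-decreasing across iterations.  Frequencies are floored into
    [floor, 1 - floor] so the likelihood stays finite.
    """

    def __init__(self, max_iter: int = 1000, tol: float = 1e-7,
                 floor: float = 1e-6, freq_source: str = "purebred"):
        self.max_iter = max_iter
        self.tol = tol
        self.floor = floor
        self.freq_source = freq_source

    def predict_q(self, X) -> np.ndarray:
        """Full ancestry vectors (q_A, q_B, q_C), shape (n, 3)."""
        self._check_fitted()
        G = _check_genotypes(X)
        p = np.clip(self.freqs_.p, self.floor, 1.0 - self.floor)  # (m, 3)
        n, m = G.shape
        q = np.tile([0.5, 0.25, 0.25], (n, 1))
        ll = self._loglik(G, p, q)
        self.loglik_path_ = [ll.copy()]
        for it in range(self.max_iter):
            f = q @ p.T                      # (n, m) expected allele frequency
            f = np.clip(f, 1e-300, None)
            h = np.clip(1.0 - f, 1e-300, None)
            num = q * ((G / f) @ p + ((2.0 - G) / h) @ (1.0 - p))
            q_new = num / (2.0 * m)
            q_new /= q_new.sum(axis=1, keepdims=True)
            ll_new = self._loglik(G, p, q_new)
            if not np.isfinite(ll_new).all():
                raise DamlineError("non-finite admixture likelihood")
            delta = np.max(np.abs(ll_new - ll))
            q, ll = q_new, ll_new
            self.loglik_path_.append(ll.copy())
            if delta < self.tol:
                break
        self.n_iter_ = it + 1
        self.loglik_ = ll
        return q

    def predict(self, X) -> np.ndarray:
        """Raw (b_B, b_C) = (q_B, q_C) per crossbred."""
        return self.predict_q(X)[:, 1:]

    @staticmethod
    def _loglik(G, p, q) -> np.ndarray:
        f = np.clip(q @ p.T, 1e-300, 1.0 - 1e-16)
        return (G * np.log(f) + (2.0 - G) * np.log1p(-f)).sum(axis=1)


class GrandparentRelationship(_FrequencyBasedAncestry):
    """Dam-line proportions from crossbred-grandparent genomic relationships.

    ``fit`` learns line frequencies by regression on expected line
    proportions (the study convention for this method); ``predict`` takes
    the crossbred genotypes together with the genotypes of the matched
    maternal grandsire (line B) and granddam (line C).

    Parameters
    ----------
    adjust_inbreeding : bool
        If True (the ``REL_GP_noF`` variant), divide each relationship by
        the grandparent's self-relationship G_jj, an estimator of
        1 + F_grandparent; if False (``REL_GP``), use G_ij directly.
    """

    freq_source = "regression"

    def __init__(self, adjust_inbreeding: bool = False,
                 freq_source: str = "regression"):
        self.adjust_inbreeding = adjust_inbreeding
        self.freq_source = freq_source

    def predict(self, X, grandsire, granddam) -> np.ndarray:
        """Raw (b_B, b_C); row i of each argument refers to the same crossbred."""
        self._check_fitted()
        G = _check_genotypes(X)
        gs = _check_genotypes(grandsire)
        gd = _check_genotypes(granddam)
        if not (G.shape == gs.shape == gd.shape):
            raise DamlineError("crossbred and grandparent genotype shapes differ")
        blend = self.freqs_.blend
        b_b, self.rel_b_ = _grm_rows(G, gs, blend, self.freqs_.p_b,
                                     self.adjust_inbreeding)
        b_c, self.rel_c_ = _grm_rows(G, gd, blend, self.freqs_.p_c,
                                     self.adjust_inbreeding)
        return np.column_stack([b_b, b_c])


def _scale(p: np.ndarray) -> float:
    s = float(np.sum(2.0 * p * (1.0 - p)))
    if s <= 0:
        raise DamlineError("zero heterozygosity sum; cannot scale relationships")
    return s


def _grm_rows(G, gp, p_i, p_j, adjust):
    """Relationship of each crossbred row with its matched grandparent row."""
    s_i = _scale(p_i)
    s_j = _scale(p_j)
    zi = G - 2.0 * p_i
    zj = gp - 2.0 * p_j
    g_ij = (zi * zj).sum(axis=1) / np.sqrt(s_i * s_j)
    g_jj = (zj * zj).sum(axis=1) / s_j
    if (g_jj <= 0).any():
        raise DamlineError("non-positive grandparent self-relationship")
    est = g_ij / g_jj if adjust else g_ij
    return est, np.column_stack([g_ij, g_jj])


def grm_cross(g_i, g_j, p_i, p_j) -> tuple[float, float]:
    """Multi-population genomic relationship between two animals.

    G_ij = sum_m (g_im - 2 p_im)(g_jm - 2 p_jm)
           / sqrt( sum_m 2 p_im (1 - p_im) * sum_m 2 p_jm (1 - p_jm) )

    where p_i and p_j are the allele frequencies of the two animals'
    respective populations.  Returns (G_ij, G_jj), the latter computed
    with p_j on both sides.
    """
    g_i = np.asarray(g_i, float)
    g_j = np.asarray(g_j, float)
    p_i = np.asarray(p_i, float)
    p_j = np.asarray(p_j, float)
    s_i, s_j = _scale(p_i), _scale(p_j)
    g_ij = float(((g_i - 2 * p_i) * (g_j - 2 * p_j)).sum() / np.sqrt(s_i * s_j))
    g_jj = float(((g_j - 2 * p_j) ** 2).sum() / s_j)
    return g_ij, g_jj


# ---------------------------------------------------------------------------
# panel-level wrappers

def boa_proportions(origins: OriginMatrix) -> ProportionEstimates:
    """Dam-line proportions from (possibly partial) allele-origin assignments.

    b_line = (#alleles assigned to that line) / (#assigned alleles), which
    coincides with the true proportions when assignment is complete and is
    unbiased when alleles are unassigned uniformly at random.
    """
    assigned = (origins.codes != ORIGIN_UNASSIGNED).sum(axis=(1, 2))
    if (assigned == 0).any():
        bad = origins.ids[np.flatnonzero(assigned == 0)[0]]
        raise DamlineError(f"animal {bad} has no assigned alleles")
    b_b = (origins.codes == ORIGIN_B).sum(axis=(1, 2)) / assigned
    b_c = (origins.codes == ORIGIN_C).sum(axis=(1, 2)) / assigned
    return ProportionEstimates(origins.ids, b_b, b_c, method="BOA", stage="raw")


def lr_estimate(panel: GenotypePanel, freqs: LineFrequencies) -> ProportionEstimates:
    """Sire-adjusted LR estimates for the crossbreds in ``panel``."""
    est = LinearRegressionAncestry.from_frequencies(freqs)
    X = panel.genotypes_of(CROSSBRED)
    b = est.predict(X)
    return ProportionEstimates(panel.ids_of(CROSSBRED), b[:, 0], b[:, 1],
                               method="LR", stage="raw",
                               residual_norm=est.residual_norm_)


def admixture_supervised_em(panel: GenotypePanel, freqs: LineFrequencies,
                            max_iter: int = 1000, tol: float = 1e-7) -> ProportionEstimates:
    """Supervised-admixture estimates for the crossbreds in ``panel``."""
    est = SupervisedAdmixture.from_frequencies(freqs, max_iter=max_iter, tol=tol)
    q = est.predict_q(panel.genotypes_of(CROSSBRED))
    return ProportionEstimates(panel.ids_of(CROSSBRED), q[:, 1], q[:, 2],
                               method="ADM", stage="raw", q_a=q[:, 0])


def rel_gp_estimate(panel: GenotypePanel, pedigree: Pedigree,
                    freqs: LineFrequencies, adjust_inbreeding: bool = False):
    """Grandparent-relationship estimates for crossbreds with both grandparents genotyped.

    Returns ``(estimates, rel_b, rel_c, n_excluded)`` where ``rel_b`` and
    ``rel_c`` are DataFrames of :class:`RelationshipEntry` fields and
    ``n_excluded`` counts crossbreds skipped for lacking a genotyped
    maternal grandparent.
    """
    pedigree.validate_lines(panel)
    have = set(panel.ids)
    tab = pedigree.crossbreds
    usable = tab[(tab["id"].isin(have))
                 & (tab["mgs"] != MISSING_PARENT) & (tab["mgs"].isin(have))
                 & (tab["mgd"] != MISSING_PARENT) & (tab["mgd"].isin(have))]
    n_excluded = int(tab["id"].isin(have).sum() - len(usable))
    if len(usable) == 0:
        raise DamlineError("no crossbred has both maternal grandparents genotyped")

    pos = {a: i for i, a in enumerate(panel.ids)}
    xi = np.array([pos[a] for a in usable["id"]], dtype=int)
    si = np.array([pos[a] for a in usable["mgs"]], dtype=int)
    di = np.array([pos[a] for a in usable["mgd"]], dtype=int)

    est = GrandparentRelationship.from_frequencies(
        freqs, adjust_inbreeding=adjust_inbreeding)
    b = est.predict(panel.genotypes[xi], panel.genotypes[si], panel.genotypes[di])
    method = "REL_GP_noF" if adjust_inbreeding else "REL_GP"
    estimates = ProportionEstimates(usable["id"].to_numpy(object),
                                    b[:, 0], b[:, 1], method=method, stage="raw")
    rel_b = pd.DataFrame({"i": usable["id"].to_numpy(), "j": usable["mgs"].to_numpy(),
                          "G_ij": est.rel_b_[:, 0], "G_jj": est.rel_b_[:, 1]})
    rel_c = pd.DataFrame({"i": usable["id"].to_numpy(), "j": usable["mgd"].to_numpy(),
                          "G_ij": est.rel_c_[:, 0], "G_jj": est.rel_c_[:, 1]})
    return estimates, rel_b, rel_c, n_excluded
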