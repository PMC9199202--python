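"""Line-specific allele-frequency estimation.

Two routes:

* direct counting within each purebred line (used by the LR estimator);
* per-SNP least squares of all available genotypes (purebreds *and*
  crossbreds) on the expected line proportions, g = 2 Pi p + e, where a
  purebred of line A contributes the design row (1, 0, 0) and an A(BC)
  crossbred (0.5, 0.25, 0.25) (used by the grandparent-relationship
  estimators).

The crossbred reference frequency is the expectation-weighted blend
0.5 p_A + 0.25 p_B + 0.25 p_C.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (CROSSBRED, PUREBRED_LINES, DamlineError, GenotypePanel,
                        LineFrequencies)

__all__ = ["purebred_line_freqs", "regression_line_freqs", "crossbred_blend_freqs"]

#: expected line proportions of one animal of each category
DESIGN_ROWS = {
    "A": np.array([1.0, 0.0, 0.0]),
    "B": np.array([0.0, 1.0, 0.0]),
    "C": np.array([0.0, 0.0, 1.0]),
    CROSSBRED: np.array([0.5, 0.25, 0.25]),
}


def purebred_line_freqs(panel: GenotypePanel) -> LineFrequencies:
    """Counted reference-allele frequency per SNP within each purebred line."""
    cols = []
    for line in PUREBRED_LINES:
        g = panel.genotypes_of(line)
        if g.shape[0] == 0:
            raise DamlineError(f"no animals of line {line} in panel")
        cols.append(g.mean(axis=0) / 2.0)
    return LineFrequencies(np.column_stack(cols), provenance="purebred-count")


def regression_line_freqs(panel: GenotypePanel) -> LineFrequencies:
    """Per-SNP OLS of genotypes on expected line proportions, g = 2 Pi p + e.

    The design matrix has one row per animal taken from
    :data:`DESIGN_ROWS`; because rows repeat within a category the normal
    equations collapse to category counts and sums, shared by all SNPs.
    Solutions are clipped to [0, 1].
    """
    counts = {}
    sums = {}
    for cat in DESIGN_ROWS:
        g = panel.genotypes_of(cat)
        counts[cat] = g.shape[0]
        sums[cat] = g.sum(axis=0, dtype=float) if g.shape[0] else np.zeros(panel.n_snps)
    for line in PUREBRED_LINES:
        if counts[line] == 0:
            raise DamlineError(f"regression design rank-deficient: line {line} absent")

    a = np.zeros((3, 3))
    b = np.zeros((3, panel.n_snps))
    for cat, row in DESIGN_ROWS.items():
        a += counts[cat] * np.outer(row, row)
        b += np.outer(row, sums[cat])
    p = 0.5 * np.linalg.solve(a, b)  # factor 2 in the model makes p a frequency
    return LineFrequencies(np.clip(p.T, 0.0, 1.0), provenance="regression")


def crossbred_blend_freqs(freqs: LineFrequencies) -> np.ndarray:
    """Expectation-weighted crossbred frequency, 0.5 p_A + 0.25 p_B + 0.25 p_C."""
    return freqs.blend
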