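"""Constraint-enforcing post-processing of raw dam-line estimates.

For A(BC) crossbreds the dam-line proportions must lie in [0, 0.5], each
dam line averages 0.25 across a cross, and the two proportions sum to
0.5 within every animal.  Raw estimates are adjusted in four ordered
steps applied per method to one crossbred cohort:

1. clip b_B and b_C to [0, 0.5];
2. shift each dam line's estimates by (0.25 - cohort mean), B and C
   independently;
3. clip again;
4. per animal, rescale (b_B, b_C) by 0.5 / (b_B + b_C).

A consequence of step 4 is that b_C = 0.5 - b_B for every animal, so any
cohort-level evaluation metric computed on line B equals the one on
line C.  The procedure is a single pass and is not idempotent in general
(rescaling can move the cohort means off 0.25 again).
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import DamlineError, ProportionEstimates

__all__ = ["postprocess_estimates"]

log = logging.getLogger(__name__)


def postprocess_estimates(raw: ProportionEstimates) -> ProportionEstimates:
    """Apply the clip / centre / clip / rescale steps to a cohort of estimates."""
    if len(raw) == 0:
        raise DamlineError("cannot post-process an empty cohort")
    b = np.clip(raw.b_b, 0.0, 0.5)
    c = np.clip(raw.b_c, 0.0, 0.5)
    b = b + (0.25 - b.mean())
    c = c + (0.25 - c.mean())
    b = np.clip(b, 0.0, 0.5)
    c = np.clip(c, 0.0, 0.5)
    s = b + c
    degenerate = s == 0.0
    if degenerate.any():
        log.warning("%d animal(s) with b_B + b_C = 0 set to the expected (0.25, 0.25)",
                    int(degenerate.sum()))
        b = np.where(degenerate, 0.25, b)
        c = np.where(degenerate, 0.25, c)
        s = b + c
    scale = 0.5 / s
    return ProportionEstimates(raw.ids, b * scale, c * scale,
                               method=raw.method, stage="postprocessed",
                               q_a=raw.q_a, residual_norm=raw.residual_norm)
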