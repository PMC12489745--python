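"""Storey q-values for false-discovery-rate control.

pi0 (the proportion of true nulls) is estimated by evaluating
pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a grid
lambda = 0.05, 0.10, ..., 0.90 and smoothing with a cubic polynomial,
taking the fitted value at the largest lambda.  If the smoother
misbehaves (pi0 outside (0, 1]) the estimate falls back to pi0 = 1,
which reduces q-values to Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

import numpy as np


def estimate_pi0(pvalues: np.ndarray) -> float:
    p = np.asarray(pvalues, float)
    p = p[np.isfinite(p)]
    m = p.size
    lam = np.arange(0.05, 0.95, 0.05)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    try:
        coef = np.polyfit(lam, pi0_lam, 3)
        pi0 = float(np.polyval(coef, lam.max()))
    except np.linalg.LinAlgError:
        pi0 = 1.0
    if not (0.0 < pi0 <= 1.0):
        pi0 = 1.0
    return pi0


def qvalues(pvalues: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values; NaN p-values yield NaN q-values."""
    p = np.asarray(pvalues, float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    if pi0 is None:
        pi0 = estimate_pi0(pv)
    order = np.argsort(pv)
    ranked = pv[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    res = np.empty(m)
    res[order] = q
    out[ok] = res
    return out
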