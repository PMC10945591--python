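"""Thin statistical wrappers: exact binomial right tails and BH adjustment.

The exact tail goes through :func:`scipy.stats.binom.sf`; the step-up FDR
adjustment goes through statsmodels. Independent enumeration / hand step-up
oracles live in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["binom_right_tail", "bh_adjust"]


def binom_right_tail(k, n, p) -> np.ndarray | float:
    """Exact P(X >= k) for X ~ Binomial(n, p) (right-tailed test p-value).

    ``k``, ``n`` may be arrays. ``k <= 0`` gives 1 exactly.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    out = stats.binom.sf(k - 1, n, p)
    return out if out.shape else float(out)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (empty-safe)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
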