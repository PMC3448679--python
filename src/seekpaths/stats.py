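"""Shared nonparametric test helpers.

All group contrasts in the package use distribution-free tests (the
underlying day counts and view fractions are heavily skewed): the
two-sample Wilcoxon rank-sum test, the paired sign test, and the paired
Wilcoxon signed-rank test. Thin wrappers over scipy returning a uniform
``(statistic, p_value, n)`` shape, with ties and degenerate inputs
handled explicitly.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def rank_sum(x, y) -> tuple[float, float, int]:
    """Two-sided Wilcoxon rank-sum test between independent samples."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        return float("nan"), float("nan"), len(x) + len(y)
    res = sps.ranksums(x, y)
    return float(res.statistic), float(res.pvalue), len(x) + len(y)


def sign_test(x, y) -> tuple[float, float, int]:
    """Two-sided paired sign test; ties are discarded.

    Returns the count of positive differences as the statistic.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0, 0
    pos = int((d > 0).sum())
    res = sps.binomtest(pos, n, 0.5, alternative="two-sided")
    return float(pos), float(res.pvalue), n


def signed_rank(x, y) -> tuple[float, float, int]:
    """Two-sided Wilcoxon signed-rank test on paired samples."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    if len(d) < 2:
        return float("nan"), 1.0 if len(d) == 0 else float("nan"), len(d)
    res = sps.wilcoxon(d, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), len(d)
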