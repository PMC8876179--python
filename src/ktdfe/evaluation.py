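"""Confusion matrices and cross-dataset overlap statistics.

The overlap of two feature selections (e.g. the same gene universe selected
independently from two cohorts) is tested with Fisher's exact test; the
reported odds ratio is the *conditional* maximum-likelihood estimate under
the noncentral hypergeometric model with all margins fixed — the convention
of the standard statistical tooling for 2x2 tables — not the sample
cross-product ratio, which is also reported for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

__all__ = ["OverlapTestResult", "confusion_matrix", "fisher_exact_conditional", "overlap_summary"]


@dataclass
class OverlapTestResult:
    table: np.ndarray  # 2x2 counts
    odds_ratio: float  # conditional MLE
    sample_odds_ratio: float  # ad / bc
    p_value: float  # two-sided exact


def confusion_matrix(selected, truth, universe) -> tuple:
    """(TP, FN, FP, TN) of a selection against ground truth over a universe."""
    selected, truth, universe = set(selected), set(truth), set(universe)
    if not selected <= universe:
        raise ValueError("selected set contains items outside the universe")
    if not truth <= universe:
        raise ValueError("truth set contains items outside the universe")
    tp = len(selected & truth)
    fn = len(truth - selected)
    fp = len(selected - truth)
    tn = len(universe) - tp - fn - fp
    return (tp, fn, fp, tn)


def fisher_exact_conditional(table) -> OverlapTestResult:
    """Two-sided Fisher exact test with the conditional-MLE odds ratio.

    The P-value sums the probabilities of all tables (margins fixed) no more
    probable than the observed one; the odds ratio solves the conditional
    score equation E[X | margins, psi] = x_observed exactly (an infinite or
    zero estimate arises from a zero cell).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin")
    cond = _odds_ratio(t, kind="conditional").statistic
    _, p = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel()
    sample = np.inf if b * c == 0 else (a * d) / (b * c)
    return OverlapTestResult(
        table=t, odds_ratio=float(cond), sample_odds_ratio=float(sample), p_value=float(p)
    )


def overlap_summary(selected_a, selected_b, universe) -> OverlapTestResult:
    """Fisher test of the overlap between two selections from one universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    sa, sb = set(selected_a), set(selected_b)
    if not sa <= universe or not sb <= universe:
        raise ValueError("selections must lie within the universe")
    both = len(sa & sb)
    only_a = len(sa - sb)
    only_b = len(sb - sa)
    neither = len(universe) - both - only_a - only_b
    table = np.array([[neither, only_b], [only_a, both]])
    return fisher_exact_conditional(table)
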