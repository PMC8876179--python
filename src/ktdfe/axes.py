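"""Ranking of singular vectors against biological hypotheses.

After HOSVD of the kernel tensor the analyst must decide which singular
vector of each mode carries the structure of interest (dependence on time,
distinction between patient groups, constancy across omics types).  The
functions here score every candidate column and return ranked diagnostics;
all rankings are invariant to the sign ambiguity of singular vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AxisChoice", "rank_by_covariate", "rank_by_two_class", "constancy_score", "choose_axes"]


@dataclass
class AxisChoice:
    """Chosen 1-based singular-vector indices plus the ranking diagnostics."""

    sample_axes: tuple  # one ell per sample mode, 1-based
    omics_axis: int | None = None  # 1-based, None when the omics mode is unused
    diagnostics: dict = field(default_factory=dict)  # mode name -> DataFrame


def _as_factor(factor: np.ndarray) -> np.ndarray:
    factor = np.asarray(factor, dtype=float)
    if factor.ndim != 2:
        raise ValueError("factor must be a 2-D matrix (rows = mode entries, cols = ell)")
    return factor


def rank_by_covariate(factor, covariate) -> pd.DataFrame:
    """Rank factor columns by |Pearson r| against a numeric covariate.

    Returns a DataFrame with 1-based ``ell``, ``r`` and the two-sided
    correlation-test ``p``, sorted by descending |r|.
    """
    factor = _as_factor(factor)
    cov = np.asarray(covariate, dtype=float)
    if cov.shape[0] != factor.shape[0]:
        raise ValueError("covariate length must equal the mode size")
    if cov.shape[0] < 3:
        raise ValueError("need mode size >= 3 for a correlation test")
    if np.std(cov) == 0:
        raise ValueError("constant covariate")
    rows = []
    for ell in range(factor.shape[1]):
        col = factor[:, ell]
        if np.std(col) == 0:
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(col, cov)
        rows.append((ell + 1, float(r), float(p)))
    df = pd.DataFrame(rows, columns=["ell", "r", "p"])
    return df.reindex(df["r"].abs().sort_values(ascending=False, kind="stable").index).reset_index(drop=True)


def rank_by_two_class(factor, labels) -> pd.DataFrame:
    """Rank factor columns by Welch t statistic between two classes.

    ``labels`` is a binary vector over the mode entries; each class needs at
    least two members.  Returns 1-based ``ell``, ``t``, two-sided ``p``
    sorted by descending |t|.  Columns that separate the classes exactly
    (zero within-class variance, different means) get ``t = inf``, ``p = 0``.
    """
    factor = _as_factor(factor)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    a = factor[labels == classes[0]]
    b = factor[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs >= 2 members")
    rows = []
    for ell in range(factor.shape[1]):
        xa, xb = a[:, ell], b[:, ell]
        if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
            if np.isclose(xa.mean(), xb.mean()):
                t, p = 0.0, 1.0
            else:
                t, p = np.inf, 0.0
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append((ell + 1, float(t), float(p)))
    df = pd.DataFrame(rows, columns=["ell", "t", "p"])
    return df.reindex(df["t"].abs().sort_values(ascending=False, kind="stable").index).reset_index(drop=True)


def constancy_score(factor) -> pd.DataFrame:
    """Rank factor columns by coefficient of variation (most constant first).

    Score = sd / |mean| per column; a zero-mean column scores infinite and
    ranks last.  Used on the omics-mode factor to find the vector that
    weights all omics types (near-)equally.
    """
    factor = _as_factor(factor)
    if factor.shape[0] < 2:
        raise ValueError("need mode size >= 2")
    rows = []
    for ell in range(factor.shape[1]):
        col = factor[:, ell]
        mu = np.abs(col.mean())
        sd = col.std(ddof=1)
        score = np.inf if mu == 0 else float(sd / mu)
        rows.append((ell + 1, score))
    df = pd.DataFrame(rows, columns=["ell", "cv"])
    return df.sort_values("cv", kind="stable").reset_index(drop=True)


def choose_axes(
    result,
    covariate=None,
    labels=None,
    sample_criteria=None,
    pinned_sample_axes=None,
    pinned_omics_axis=None,
    use_omics_axis=True,
) -> AxisChoice:
    """Pick the ell indices for feature projection from an HOSVD result.

    Each sample mode is ranked against the covariate (Pearson), the binary
    labels (Welch t) or a constancy requirement; the omics mode by constancy.
    For m == 1 pass ``covariate=`` or ``labels=`` directly; for m > 1 pass
    ``sample_criteria``, a list of per-mode tuples among
    ``("covariate", vector)``, ``("two_class", labels)`` and
    ``("constant", None)``.  Explicit ``pinned_*`` indices override the
    rankings but diagnostics are still reported.
    """
    if result.mode_roles is None:
        raise ValueError("axis choice needs mode_roles on the HOSVD result")
    m = result.mode_roles.m
    if sample_criteria is None:
        if covariate is not None:
            sample_criteria = [("covariate", covariate)] * m
        elif labels is not None:
            sample_criteria = [("two_class", labels)] * m
        elif pinned_sample_axes is None:
            raise ValueError("need a covariate, labels, sample_criteria or pinned axes")
        else:
            sample_criteria = [("constant", None)] * m
    if len(sample_criteria) != m:
        raise ValueError(f"expected {m} sample criteria")
    diagnostics = {}
    sample_axes = []
    for s, (kind, arg) in zip(range(1, m + 1), sample_criteria):
        factor = result.factors[s]
        if kind == "covariate":
            diag = rank_by_covariate(factor, arg)
        elif kind == "two_class":
            diag = rank_by_two_class(factor, arg)
        elif kind == "constant":
            diag = constancy_score(factor)
        else:
            raise ValueError(f"unknown sample criterion {kind!r}")
        diagnostics[f"sample_mode_{s}"] = diag
        sample_axes.append(int(diag["ell"].iloc[0]))
    if pinned_sample_axes is not None:
        sample_axes = [int(e) for e in pinned_sample_axes]
        if len(sample_axes) != m:
            raise ValueError(f"expected {m} pinned sample axes")
    for s, ell in zip(range(1, m + 1), sample_axes):
        if not 1 <= ell <= result.factors[s].shape[1]:
            raise ValueError(f"sample mode {s}: ell={ell} out of range")
    omics_axis = None
    if use_omics_axis:
        if result.factors[0].shape[0] == 1:  # K=1: the omics mode is trivial
            diag = pd.DataFrame({"ell": [1], "cv": [0.0]})
        else:
            diag = constancy_score(result.factors[0])
        diagnostics["omics_mode"] = diag
        omics_axis = int(diag["ell"].iloc[0])
        if pinned_omics_axis is not None:
            omics_axis = int(pinned_omics_axis)
        if not 1 <= omics_axis <= result.factors[0].shape[1]:
            raise ValueError(f"omics mode: ell={omics_axis} out of range")
    return AxisChoice(sample_axes=tuple(sample_axes), omics_axis=omics_axis, diagnostics=diagnostics)
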