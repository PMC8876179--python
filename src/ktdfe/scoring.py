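"""Feature projection, chi-squared P-value attribution, BH correction, selection.

Features never enter the decomposition itself — only the sample-by-sample
kernels do.  Each feature is scored afterwards by projecting its raw profile
onto the chosen sample-mode singular vectors:

    u_i = sum_{j_1..j_m} x[i, j_1..j_m] * prod_s u_{ell_s}[j_s]

Under the null hypothesis that the projections are draws from a zero-mean
Gaussian, (u_i / sigma)^2 summed over the d chosen index combinations is
chi-squared with d degrees of freedom; sigma is the RMS of the scores about
zero (no centering — the null mean is zero by hypothesis).  Raw P-values are
corrected by Benjamini–Hochberg and features with adjusted P at or below the
per-block threshold are selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .omics import MultiOmicsBlock

__all__ = [
    "FeatureScoreTable",
    "project_features_per_omics",
    "project_features_shared",
    "estimate_sigma",
    "chi2_pvalues",
    "bh_adjust",
    "select_features",
    "score_block",
]


@dataclass
class FeatureScoreTable:
    """Per-feature scores, sigma, raw/adjusted P and selection flags."""

    data: pd.DataFrame  # columns: feature_id, omics_id, score, p, p_adj, selected
    sigma: dict = field(default_factory=dict)  # group -> sigma
    thresholds: dict = field(default_factory=dict)  # omics_id -> threshold
    df: int = 1  # chi-squared degrees of freedom used

    def counts(self) -> pd.Series:
        return self.data.groupby("omics_id", sort=False)["selected"].sum().astype(int)

    def selected_ids(self, omics_id=None) -> list:
        d = self.data
        if omics_id is not None:
            d = d[d["omics_id"] == omics_id]
        return d.loc[d["selected"], "feature_id"].tolist()


def _sample_vectors(factors, sample_axes, m):
    """1-based ell per sample mode -> list of chosen singular vectors."""
    vecs = []
    for s, ell in zip(range(1, m + 1), sample_axes):
        u = factors[s]
        if not 1 <= ell <= u.shape[1]:
            raise ValueError(f"sample mode {s}: ell={ell} out of range 1..{u.shape[1]}")
        vecs.append(u[:, ell - 1])
    return vecs


def project_features_per_omics(block, choice, factors) -> np.ndarray:
    """Project one block's features onto the chosen sample-mode vectors.

    No omics-mode weight enters: the features of a block are specific to it.
    """
    x = block.values if isinstance(block, MultiOmicsBlock) else np.asarray(block, float)
    m = x.ndim - 1
    vecs = _sample_vectors(factors, choice.sample_axes, m)
    for v in vecs:
        x = np.tensordot(x, v, axes=(1, 0))
    return x


def project_features_shared(x, choice, factors) -> np.ndarray:
    """Project shared features of an (N, M_1..M_m, K) tensor, weighting the
    omics slices by the chosen omics-mode singular vector."""
    x = np.asarray(x, dtype=float)
    m = x.ndim - 2
    if m < 1:
        raise ValueError("shared tensor needs shape (N, sample modes..., K)")
    vecs = _sample_vectors(factors, choice.sample_axes, m)
    if choice.omics_axis is None:
        raise ValueError("shared projection needs an omics-mode axis")
    uk = factors[0][:, choice.omics_axis - 1]
    if uk.shape[0] != x.shape[-1]:
        raise ValueError("omics factor size does not match the tensor's omics mode")
    out = np.tensordot(x, uk, axes=(x.ndim - 1, 0))
    for v in vecs:
        out = np.tensordot(out, v, axes=(1, 0))
    return out


def estimate_sigma(scores) -> float:
    """Null scale: root-mean-square of the scores about zero (not centered)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need >= 2 scores to estimate sigma")
    sigma = float(np.sqrt(np.mean(scores**2)))
    if sigma == 0:
        raise ValueError("all scores are zero; degenerate null")
    return sigma


def chi2_pvalues(scores, sigma, df: int = 1) -> np.ndarray:
    """Upper-tail chi-squared P-values for (scores/sigma)^2 with ``df`` dof.

    ``scores`` may be (n,) with scalar sigma (df combinations already summed
    is then df=1) or (n, d) with sigma of length d, in which case the d
    standardized squares are summed and df defaults to d.
    """
    scores = np.asarray(scores, dtype=float)
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if scores.ndim == 1:
        sigma = float(sigma)
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        stat = (scores / sigma) ** 2
    else:
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma <= 0):
            raise ValueError("sigma must be positive")
        stat = ((scores / sigma) ** 2).sum(axis=1)
    return stats.chi2.sf(stat, df)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted P-values, original order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("P-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_features(table: FeatureScoreTable, thresholds) -> FeatureScoreTable:
    """Flag features with adjusted P <= their block's threshold.

    ``thresholds`` is a scalar applied to every block or a mapping
    ``omics_id -> threshold``.
    """
    data = table.data.copy()
    if np.isscalar(thresholds):
        thr = {k: float(thresholds) for k in data["omics_id"].unique()}
    else:
        thr = {k: float(v) for k, v in dict(thresholds).items()}
    missing = [k for k in data["omics_id"].unique() if k not in thr]
    if missing:
        raise ValueError(f"no threshold for blocks: {missing}")
    bad = [k for k, v in thr.items() if not 0 < v < 1]
    if bad:
        raise ValueError(f"thresholds must lie in (0,1): {bad}")
    data["selected"] = data.apply(lambda r: r["p_adj"] <= thr[r["omics_id"]], axis=1)
    return FeatureScoreTable(data=data, sigma=table.sigma, thresholds=thr, df=table.df)


def score_block(block, choice, factors, threshold=0.01, df: int = 1) -> FeatureScoreTable:
    """Full per-omics scoring of one block: project, sigma, chi2, BH, select."""
    scores = project_features_per_omics(block, choice, factors)
    sigma = estimate_sigma(scores)
    p = chi2_pvalues(scores, sigma, df=df)
    p_adj = bh_adjust(p)
    oid = block.omics_id if isinstance(block, MultiOmicsBlock) else "block"
    fids = block.feature_ids if isinstance(block, MultiOmicsBlock) else list(range(1, len(scores) + 1))
    data = pd.DataFrame(
        {
            "feature_id": fids,
            "omics_id": oid,
            "score": scores,
            "p": p,
            "p_adj": p_adj,
            "selected": False,
        }
    )
    table = FeatureScoreTable(data=data, sigma={oid: sigma}, df=df)
    return select_features(table, {oid: threshold})
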