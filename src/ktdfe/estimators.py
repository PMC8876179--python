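"""Scikit-learn style estimators for KTD-based unsupervised feature extraction.

Two selectors cover the two data layouts:

:class:`KTDSharedSelector`
    Features shared across omics slices: one tensor ``X`` of shape
    (n_features, M_1..M_m, K) (or (n_features, M) for a single matrix).
    ``fit(X, y)`` takes the sample covariate (numeric) or two-class labels as
    ``y``; the omics mode is weighted by its most constant singular vector.

:class:`KTDMultiOmicsSelector`
    Block-specific features: fit on a :class:`~ktdfe.omics.MultiOmicsTensorSet`
    whose K blocks share sample modes but have their own feature lists.

Both follow the transformer protocol: fitted attributes carry trailing
underscores, ``get_support()`` returns the selection mask, ``transform(X)``
keeps the selected feature rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import axes as _axes
from . import hosvd as _hosvd
from . import kernels as _kernels
from . import scoring as _scoring
from .omics import MultiOmicsBlock, MultiOmicsTensorSet, standardize_samples

__all__ = ["KTDSharedSelector", "KTDMultiOmicsSelector"]


def _criterion_for(y, kind):
    if kind == "auto":
        y = np.asarray(y)
        uniq = np.unique(y)
        kind = "two_class" if (uniq.size == 2 and y.dtype.kind in "OUSb") else "covariate"
    return kind


class KTDSharedSelector(BaseEstimator):
    """Unsupervised feature selection for a shared-feature omics tensor.

    Parameters
    ----------
    kernel : {"linear"}
        Sample kernel; only the linear Gram kernel is implemented.
    sample_axis : "auto" or int
        1-based singular-vector index for the sample mode; "auto" picks the
        column most associated with ``y``.
    omics_axis : "auto" or int or None
        1-based index for the omics mode ("auto": most constant column).
        Ignored for 2-D input.
    criterion : {"auto", "covariate", "two_class"}
        How ``y`` ranks sample-mode singular vectors.
    threshold : float
        Adjusted-P selection threshold (default 0.01).
    standardize : bool
        Standardize each sample cell over features before the kernel
        (default False: the synthetic benchmark uses raw values).

    Attributes
    ----------
    kernel_ : ndarray of shape (K, M, M)
    factors_, core_ : HOSVD factor matrices and core tensor.
    axis_choice_ : AxisChoice with ranking diagnostics.
    scores_, sigma_, pvalues_, pvalues_adj_, support_ : per-feature results.
    """

    def __init__(
        self,
        kernel="linear",
        sample_axis="auto",
        omics_axis="auto",
        criterion="auto",
        threshold=0.01,
        standardize=False,
    ):
        self.kernel = kernel
        self.sample_axis = sample_axis
        self.omics_axis = omics_axis
        self.criterion = criterion
        self.threshold = threshold
        self.standardize = standardize

    def fit(self, X, y=None):
        """Fit on ``X`` of shape (n_features, M[, K]); ``y`` spans the M samples."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, :, None]
        if X.ndim != 3:
            raise ValueError("X must be (n_features, n_samples[, n_omics])")
        if y is None and self.sample_axis == "auto":
            raise ValueError("y is required to rank sample singular vectors (or pin sample_axis)")
        _kernels.KernelSpec(self.kernel)
        n, M, K = X.shape
        blocks = [
            MultiOmicsBlock(omics_id=f"slice{k+1}", values=X[:, :, k]) for k in range(K)
        ]
        if self.standardize:
            blocks = [standardize_samples(b) for b in blocks]
            X = np.stack([b.values for b in blocks], axis=2)
        tset = MultiOmicsTensorSet(blocks=blocks)
        kt = _kernels.stack_kernels(tset, _kernels.KernelSpec(self.kernel))
        self.kernel_ = kt.values
        res = _hosvd.hosvd(kt)
        self.factors_ = res.factors
        self.core_ = res.core
        kind = _criterion_for(y, self.criterion) if y is not None else "covariate"
        choice = _axes.choose_axes(
            res,
            covariate=np.asarray(y, float) if (y is not None and kind == "covariate") else None,
            labels=np.asarray(y) if (y is not None and kind == "two_class") else None,
            pinned_sample_axes=None if self.sample_axis == "auto" else (int(self.sample_axis),),
            pinned_omics_axis=None if self.omics_axis in ("auto", None) else int(self.omics_axis),
            use_omics_axis=self.omics_axis is not None,
        )
        self.axis_choice_ = choice
        if choice.omics_axis is None:
            scores = np.zeros(n)
            for k in range(K):
                scores += _scoring.project_features_per_omics(X[:, :, k], choice, res.factors)
        else:
            scores = _scoring.project_features_shared(X, choice, res.factors)
        self.scores_ = scores
        self.sigma_ = _scoring.estimate_sigma(scores)
        self.pvalues_ = _scoring.chi2_pvalues(scores, self.sigma_, df=1)
        self.pvalues_adj_ = _scoring.bh_adjust(self.pvalues_)
        self.support_ = self.pvalues_adj_ <= self.threshold
        self.n_features_in_ = n
        return self

    def get_support(self, indices=False):
        if indices:
            return np.flatnonzero(self.support_)
        return self.support_

    def transform(self, X):
        """Keep the selected feature rows of ``X``."""
        X = np.asarray(X)
        if X.shape[0] != self.support_.shape[0]:
            raise ValueError("X has a different number of features than at fit")
        return X[self.support_]

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def to_frame(self) -> pd.DataFrame:
        """Per-feature results as a DataFrame."""
        return pd.DataFrame(
            {
                "feature": np.arange(1, self.scores_.size + 1),
                "score": self.scores_,
                "p": self.pvalues_,
                "p_adj": self.pvalues_adj_,
                "selected": self.support_,
            }
        )


class KTDMultiOmicsSelector(BaseEstimator):
    """Unsupervised feature selection across K blocks with their own features.

    Fit input is a :class:`MultiOmicsTensorSet` (or list of blocks).  ``y``
    ranks the sample-mode singular vectors: a numeric covariate, binary
    labels, or — for multiple sample modes — via ``sample_criteria`` in
    ``fit``'s keyword.  Feature projection is per block (no omics weight);
    sigma and BH correction are per block; thresholds may differ per block.

    Attributes: ``kernel_``, ``factors_``, ``core_``, ``axis_choice_``,
    ``score_table_`` (:class:`~ktdfe.scoring.FeatureScoreTable`) and
    ``supports_`` (dict omics_id -> boolean mask).
    """

    def __init__(
        self,
        kernel="linear",
        sample_axes="auto",
        criterion="auto",
        thresholds=0.01,
        standardize=True,
    ):
        self.kernel = kernel
        self.sample_axes = sample_axes
        self.criterion = criterion
        self.thresholds = thresholds
        self.standardize = standardize

    def fit(self, X, y=None, sample_criteria=None):
        tset = X if isinstance(X, MultiOmicsTensorSet) else MultiOmicsTensorSet(blocks=list(X))
        if self.standardize:
            tset = MultiOmicsTensorSet(blocks=[standardize_samples(b) for b in tset.blocks])
        self.tensor_set_ = tset
        kt = _kernels.stack_kernels(tset, _kernels.KernelSpec(self.kernel))
        self.kernel_ = kt.values
        res = _hosvd.hosvd(kt)
        self.factors_ = res.factors
        self.core_ = res.core
        kind = _criterion_for(y, self.criterion) if y is not None else None
        choice = _axes.choose_axes(
            res,
            covariate=np.asarray(y, float) if kind == "covariate" else None,
            labels=np.asarray(y) if kind == "two_class" else None,
            sample_criteria=sample_criteria,
            pinned_sample_axes=None if self.sample_axes == "auto" else tuple(self.sample_axes),
            use_omics_axis=False,
        )
        self.axis_choice_ = choice
        tables = [
            _scoring.score_block(
                b,
                choice,
                res.factors,
                threshold=self.thresholds if np.isscalar(self.thresholds) else self.thresholds[b.omics_id],
            )
            for b in tset.blocks
        ]
        data = pd.concat([t.data for t in tables], ignore_index=True)
        sigma = {k: v for t in tables for k, v in t.sigma.items()}
        thr = {k: v for t in tables for k, v in t.thresholds.items()}
        self.score_table_ = _scoring.FeatureScoreTable(data=data, sigma=sigma, thresholds=thr, df=1)
        self.supports_ = {
            b.omics_id: self.score_table_.data.query("omics_id == @b.omics_id")["selected"].to_numpy()
            for b in tset.blocks
        }
        return self

    def get_support(self, omics_id, indices=False):
        mask = self.supports_[omics_id]
        return np.flatnonzero(mask) if indices else mask

    def selected_ids(self, omics_id=None):
        return self.score_table_.selected_ids(omics_id)
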