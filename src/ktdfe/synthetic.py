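"""Synthetic multi-omics benchmark: generator, KTD pipeline, baselines, ensembles.

The generator emulates a feature-by-sample-by-omics tensor ``x[i, j, k]`` of
shape (N, M, K): i.i.d. Uniform[0, 1) noise everywhere, plus a monotone
sample covariate ``a_j = 1 + (M - 1) * j / M`` (j = 1..M) added to

- the first ``N1`` features in *every* omics slice (the "common" signal), and
- features ``k*N1 < i <= (k+1)*N1`` in slice k only (omics-specific signal),

so each slice carries exactly ``2*N1`` signal features.  The KTD method is
scored against the N1 common features (its positives); the per-omics
baselines against each slice's 2*N1 signal features.  Performance is
averaged over seeded ensembles (ensemble e uses seed ``base_seed + e``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import lars_path

from .estimators import KTDSharedSelector
from .evaluation import confusion_matrix
from .scoring import bh_adjust

__all__ = [
    "SyntheticSpec",
    "SyntheticData",
    "ConfusionSummary",
    "sample_covariate",
    "generate_synthetic",
    "run_ktd_pipeline",
    "regression_baseline",
    "lasso_baseline",
    "rf_baseline",
    "run_ensemble",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Benchmark conditions: N features, N1 signal-block size, M samples,
    K omics, number of ensembles and the base seed."""

    n_features: int = 1000
    n_signal: int = 10
    n_samples: int = 10
    n_omics: int = 3
    n_ensembles: int = 100
    base_seed: int = 0
    amplitude: float = 1.0  # scales the a_j signal; 0 gives a pure-noise null

    def __post_init__(self):
        if (self.n_omics + 1) * self.n_signal > self.n_features:
            raise ValueError("(K+1)*N1 must not exceed N")
        if self.n_samples < 3:
            raise ValueError("need M >= 3 samples")
        if self.n_signal < 1 or self.n_omics < 1 or self.n_ensembles < 1:
            raise ValueError("N1, K and n_ensembles must be positive")


@dataclass
class SyntheticData:
    x: np.ndarray  # (N, M, K)
    a: np.ndarray  # (M,) monotone covariate
    common_mask: np.ndarray  # (N,) bool: signal in every slice
    per_omics_mask: np.ndarray  # (K, N) bool: slice-specific signal block
    seed: int = 0

    @property
    def signal_mask_per_k(self) -> np.ndarray:
        """(K, N) bool: the 2*N1 features carrying a_j in slice k."""
        return self.common_mask[None, :] | self.per_omics_mask


@dataclass
class ConfusionSummary:
    """Mean confusion-matrix cells over ensembles, per group (KTD: single
    group "common"; baselines: one group per omics slice)."""

    method: str
    table: pd.DataFrame  # index = group, columns = TP, FN, FP, TN
    n_ensembles: int
    n_failed: int = 0
    extra: dict = field(default_factory=dict)


def sample_covariate(M: int) -> np.ndarray:
    """a_j = 1 + (M-1) * j / M for j = 1..M (a_1 = 1.9 and a_M = M at M=10)."""
    j = np.arange(1, M + 1)
    return 1.0 + (M - 1) * j / M


def generate_synthetic(spec: SyntheticSpec, ensemble: int = 0) -> SyntheticData:
    """Draw one ensemble of the benchmark tensor with seed base_seed + ensemble."""
    n, n1, M, K = spec.n_features, spec.n_signal, spec.n_samples, spec.n_omics
    seed = spec.base_seed + ensemble
    rng = np.random.default_rng(seed)
    x = rng.random((n, M, K))
    a = sample_covariate(M)
    i = np.arange(1, n + 1)
    common = i <= n1
    per_omics = np.stack([(k * n1 < i) & (i <= (k + 1) * n1) for k in range(1, K + 1)])
    for k in range(K):
        x[common | per_omics[k], :, k] += spec.amplitude * a[None, :]
    return SyntheticData(x=x, a=a, common_mask=common, per_omics_mask=per_omics, seed=seed)


def run_ktd_pipeline(data: SyntheticData, threshold: float = 0.01) -> KTDSharedSelector:
    """Kernel -> HOSVD -> axis ranking -> shared projection -> chi2/BH -> select."""
    sel = KTDSharedSelector(criterion="covariate", threshold=threshold)
    return sel.fit(data.x, data.a)


def regression_baseline(data: SyntheticData, threshold: float = 0.01) -> pd.DataFrame:
    """Per-(feature, omics) OLS of x on the covariate; BH within each slice.

    Returns a tidy frame with slope, intercept, two-sided slope P, adjusted P
    and the selection flag at the given threshold.
    """
    x, a = data.x, data.a
    n, M, K = x.shape
    if M < 3:
        raise ValueError("need M >= 3 for a slope test")
    if np.var(a) == 0:
        raise ValueError("zero-variance regressor")
    ac = a - a.mean()
    sxx = float(ac @ ac)
    rows = []
    for k in range(K):
        y = x[:, :, k]
        yc = y - y.mean(axis=1, keepdims=True)
        slope = yc @ ac / sxx
        intercept = y.mean(axis=1) - slope * a.mean()
        resid = yc - np.outer(slope, ac)
        s2 = (resid**2).sum(axis=1) / (M - 2)
        se = np.sqrt(s2 / sxx)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, slope / se, np.inf * np.sign(slope))
        p = 2 * stats.t.sf(np.abs(t), M - 2)
        p_adj = bh_adjust(p)
        rows.append(
            pd.DataFrame(
                {
                    "feature": np.arange(1, n + 1),
                    "k": k + 1,
                    "slope": slope,
                    "intercept": intercept,
                    "p": p,
                    "p_adj": p_adj,
                    "selected": p_adj <= threshold,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def lasso_baseline(data: SyntheticData) -> dict:
    """Lasso path per omics slice; support of the path solution with the most
    nonzero coefficients.

    The path is traced with the LARS algorithm, whose active set can never
    exceed the (centered) sample rank — this realizes the lasso's saturation
    bound of at most M selected features exactly, which coordinate-descent
    grids only satisfy approximately.  Predictors are standardized and the
    response centered beforehand; ties in support size break toward the most
    regularized solution.  Returns ``{k: selected 1-based feature indices}``.
    """
    x, a = data.x, data.a
    n, M, K = x.shape
    out = {}
    for k in range(K):
        X = x[:, :, k].T  # M x N design, features as predictors
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        y = a - a.mean()
        _, _, coefs = lars_path(Xs, y, method="lasso")
        nnz = (coefs != 0).sum(axis=0)
        best = int(np.argmax(nnz))  # first max = most regularized among ties
        out[k + 1] = np.flatnonzero(coefs[:, best]) + 1
    return out


def rf_baseline(
    data: SyntheticData,
    mode: str = "nonzero",
    n_estimators: int = 100,
    seed: int = 0,
) -> dict:
    """Random-forest regression importance selection per omics slice.

    mode "nonzero": features with importance > 0; mode "top_2N1": the 2*N1
    features of largest importance, where N1 is inferred from the masks.
    Returns ``{k: selected feature indices (1-based)}``.
    """
    if mode not in ("nonzero", "top_2N1"):
        raise ValueError(f"unknown rf mode {mode!r}")
    x, a = data.x, data.a
    n, M, K = x.shape
    out = {}
    for k in range(K):
        X = x[:, :, k].T
        rf = RandomForestRegressor(n_estimators=n_estimators, random_state=seed + k)
        rf.fit(X, a)
        imp = rf.feature_importances_
        if mode == "nonzero":
            out[k + 1] = np.flatnonzero(imp > 0) + 1
        else:
            n_top = int(data.signal_mask_per_k[k].sum())
            order = np.argsort(-np.abs(imp), kind="stable")
            out[k + 1] = np.sort(order[:n_top]) + 1
    return out


def _confusion_means(cells: list) -> np.ndarray:
    return np.asarray(cells, dtype=float).mean(axis=0)


def run_ensemble(spec: SyntheticSpec, method: str = "ktd", threshold: float = 0.01, **kwargs) -> ConfusionSummary:
    """Run a method over all ensembles and average confusion matrices.

    method: "ktd", "regression", "lasso", "rf_nonzero" or "rf_top".
    KTD positives are the N1 common features; baseline positives (per slice
    k) are that slice's 2*N1 signal features.
    """
    per_group: dict = {}
    extra: dict = {"axis_sample": [], "axis_omics": [], "support_sizes": []}
    n_failed = 0
    universe = set(range(1, spec.n_features + 1))
    for e in range(spec.n_ensembles):
        data = generate_synthetic(spec, e)
        try:
            if method == "ktd":
                sel = run_ktd_pipeline(data, threshold=threshold)
                chosen = set((sel.get_support(indices=True) + 1).tolist())
                truth = set(np.flatnonzero(data.common_mask) + 1)
                cm = confusion_matrix(chosen, truth, universe)
                per_group.setdefault("common", []).append(cm)
                extra["axis_sample"].append(sel.axis_choice_.sample_axes[0])
                extra["axis_omics"].append(sel.axis_choice_.omics_axis)
            else:
                if method == "regression":
                    res = regression_baseline(data, threshold=threshold)
                    sel_per_k = {
                        k: res.query("k == @k and selected")["feature"].to_numpy()
                        for k in range(1, spec.n_omics + 1)
                    }
                elif method == "lasso":
                    sel_per_k = lasso_baseline(data, **kwargs)
                elif method in ("rf_nonzero", "rf_top"):
                    mode = "nonzero" if method == "rf_nonzero" else "top_2N1"
                    sel_per_k = rf_baseline(data, mode=mode, seed=data.seed, **kwargs)
                else:
                    raise ValueError(f"unknown method {method!r}")
                for k, chosen in sel_per_k.items():
                    truth = set(np.flatnonzero(data.signal_mask_per_k[k - 1]) + 1)
                    cm = confusion_matrix(set(int(i) for i in chosen), truth, universe)
                    per_group.setdefault(f"k={k}", []).append(cm)
                if method == "lasso":
                    extra["support_sizes"].append({k: len(v) for k, v in sel_per_k.items()})
        except (np.linalg.LinAlgError, ValueError) as err:  # pragma: no cover
            n_failed += 1
            extra.setdefault("failures", []).append(f"ensemble {e}: {err}")
    table = pd.DataFrame(
        {g: _confusion_means(cells) for g, cells in per_group.items()},
        index=["TP", "FN", "FP", "TN"],
    ).T
    return ConfusionSummary(
        method=method,
        table=table,
        n_ensembles=spec.n_ensembles,
        n_failed=n_failed,
        extra={k: v for k, v in extra.items() if v},
    )
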