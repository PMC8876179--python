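# ktdfe — kernel-tensor-decomposition unsupervised feature extraction

`ktdfe` selects features from **multi-omics datasets that share their samples
but not their features** — e.g. methylation (~7·10⁵ probes), gene expression
(~3.6·10⁴ genes) and two proteomes (~1.6·10³ proteins) measured on the same 15
individuals at 5 time points. This is the *large p, small n* regime, where
per-feature inference after multiple-testing correction is hard and most
supervised selectors cannot even be formulated (no categorical outcome, K
heterogeneous feature spaces).

## Method

Each omics block `x[i_k, j_1..j_m]` (feature mode first, m shared sample
modes of sizes M_1..M_m) is reduced to a **linear sample kernel**

    K^k(j_1..j_m, j'_1..j'_m) = Σ_{i_k} x[i_k, j..] · x[i_k, j'..]

and the K kernels are stacked into one tensor of shape
`K × M_1..M_m × M_1..M_m`, whose size is independent of every feature count
N_k — this is what lets arbitrarily many omics types of arbitrary
dimensionality be integrated on desktop memory. Classical **HOSVD** (Tucker
form: per-mode orthogonal factor `u_{ℓ j}` from the mode unfolding's SVD,
full core G) decomposes the stacked tensor. The analyst (or the ranking
helpers in `ktdfe.axes`) picks the singular vectors of interest: sample-mode
vectors correlated with a covariate such as time (Pearson) or separating two
classes (Welch t), and the omics-mode vector that weights all omics types
near-equally (smallest coefficient of variation). Features never enter the
decomposition; each is scored afterwards by projection

    u_{i_k} = Σ_{j_1..j_m} x[i_k, j..] · Π_s u_{ℓ_s j_s}

and, under a zero-mean Gaussian null with σ the RMS of the scores,

    P_{i_k} = P_{χ²}[ > (u_{i_k}/σ)² ]

is Benjamini–Hochberg corrected; features with adjusted P ≤ the per-block
threshold (0.01 typical, 0.05 for small proteomes) are selected.

The package is organised as scikit-learn style estimators:

- `KTDSharedSelector` — features shared across omics slices: fit an
  `(N, M, K)` tensor with the sample covariate as `y`; `get_support()` /
  `transform()` return the selection.
- `KTDMultiOmicsSelector` — K blocks with their own feature lists
  (`MultiOmicsTensorSet`), per-block σ, BH and thresholds.

plus modules mirroring the analysis stages (`omics`, `kernels`, `hosvd`,
`axes`, `scoring`, `synthetic`, `evaluation`) and a `ktdfe` CLI
(`run`, `simulate`, `overlap`, `report`).

## Worked example

The bundled generator builds the benchmark tensor `(N, M, K) = (1000, 10, 3)`:
uniform(0,1) noise, a monotone covariate `a_j = 1 + (M−1)j/M` added to the 10
common signal features (all slices) and to 10 slice-specific features per
omics type:

```python
import ktdfe

data = ktdfe.generate_synthetic(ktdfe.SyntheticSpec(), ensemble=0)
sel = ktdfe.run_ktd_pipeline(data)          # KTDSharedSelector under the hood
print(sel.axis_choice_.sample_axes, sel.axis_choice_.omics_axis)  # (1,) 1
print(round(sel.sigma_, 3))                 # 5.238
print(sel.get_support(indices=True) + 1)    # [ 1  2  3  4  5  6  7  8  9 10]
print(sel.to_frame().head(3).to_string(index=False))
```

```
 feature     score            p        p_adj  selected
       1 38.220976 2.948829e-13 4.516212e-11      True
       2 37.741774 5.794626e-13 5.794626e-11      True
       3 38.439794 2.160216e-13 4.516212e-11      True
```

All ten common signal features are recovered with zero false positives: their
projections (≈38) stand far above the pooled null scale σ ≈ 5.2, while the 30
omics-specific signal features score only ~a third as high (the constant
omics-mode vector down-weights single-slice signal) and stay below the BH
cut-off. The same run from the shell:

```sh
ktdfe simulate --n 1000 --n1 10 --m 10 --k 3 --ensembles 100 --method ktd -o out/
```

Cross-cohort concordance of two selections is tested with Fisher's exact
test, reporting the conditional-MLE odds ratio:

```python
res = ktdfe.fisher_exact_conditional([[17269, 101], [65, 5]])
print(round(res.odds_ratio, 4), res.p_value)   # 13.1441 6.670812616158283e-05
```

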