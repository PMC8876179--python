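import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ktdfe import (
    bh_adjust,
    chi2_pvalues,
    estimate_sigma,
    project_features_per_omics,
    project_features_shared,
    select_features,
)
from ktdfe.axes import AxisChoice
from ktdfe.scoring import FeatureScoreTable, score_block
import pandas as pd


def _choice(sample_axes, omics_axis=None):
    return AxisChoice(sample_axes=tuple(sample_axes), omics_axis=omics_axis)


class TestProjection:
    def test_basis_vector_projection_picks_corner(self, rng):
        # u_{ell_s} = e_1 in every sample mode extracts x[:, 0, 0]
        x = rng.normal(size=(5, 3, 4))
        factors = [None, np.eye(3), np.eye(4)]
        scores = project_features_per_omics(x, _choice((1, 1)), factors)
        np.testing.assert_allclose(scores, x[:, 0, 0], atol=1e-12)

    def test_constant_block_orthogonal_to_meanzero_vector(self):
        x = np.full((7, 5, 15), 3.0)
        u1 = np.zeros(5)
        u1[:2], u1[2:] = 3.0, -2.0  # mean zero
        u1 /= np.linalg.norm(u1)
        u2 = np.full(15, 1 / np.sqrt(15))
        factors = [None, np.column_stack([u1] * 5), np.column_stack([u2] * 15)]
        scores = project_features_per_omics(x, _choice((1, 1)), factors)
        np.testing.assert_allclose(scores, 0.0, atol=1e-10)

    def test_matches_triple_loop_oracle(self, rng):
        x = rng.normal(size=(4, 3, 3))
        u1, u2 = rng.normal(size=3), rng.normal(size=3)
        factors = [None, np.column_stack([u1, np.eye(3)[:, :2]]), np.column_stack([u2, np.eye(3)[:, :2]])]
        scores = project_features_per_omics(x, _choice((1, 1)), factors)
        oracle = np.zeros(4)
        for i in range(4):
            for j1 in range(3):
                for j2 in range(3):
                    oracle[i] += x[i, j1, j2] * u1[j1] * u2[j2]
        np.testing.assert_allclose(scores, oracle, atol=1e-12)

    def test_shared_matches_loop_oracle(self, rng):
        x = rng.normal(size=(6, 4, 3))
        uj, uk = rng.normal(size=4), rng.normal(size=3)
        factors = [np.column_stack([uk, np.eye(3)[:, :2]]), np.column_stack([uj, np.eye(4)[:, :3]])]
        scores = project_features_shared(x, _choice((1,), omics_axis=1), factors)
        oracle = np.zeros(6)
        for i in range(6):
            for j in range(4):
                for k in range(3):
                    oracle[i] += x[i, j, k] * uj[j] * uk[k]
        np.testing.assert_allclose(scores, oracle, atol=1e-12)

    def test_shared_identical_slices_factorizes_as_sqrt_k(self, rng):
        xmat = rng.normal(size=(6, 4))
        K = 3
        x = np.repeat(xmat[:, :, None], K, axis=2)
        uj = rng.normal(size=4)
        uk = np.full(K, 1 / np.sqrt(K))
        factors = [np.column_stack([uk, np.eye(K)[:, :2]]), np.column_stack([uj, np.eye(4)[:, :3]])]
        scores = project_features_shared(x, _choice((1,), omics_axis=1), factors)
        np.testing.assert_allclose(scores, np.sqrt(K) * (xmat @ uj), atol=1e-12)

    def test_shared_k1_reduces_to_per_omics(self, rng):
        x = rng.normal(size=(5, 4, 1))
        uj = rng.normal(size=4)
        factors = [np.array([[1.0]]), np.column_stack([uj, np.eye(4)[:, :3]])]
        shared = project_features_shared(x, _choice((1,), omics_axis=1), factors)
        per = project_features_per_omics(x[:, :, 0], _choice((1,)), factors)
        np.testing.assert_allclose(shared, per, atol=1e-12)


class TestSigma:
    def test_hand_computed_rms(self):
        assert estimate_sigma([3.0, 4.0]) == pytest.approx(3.535534, abs=1e-6)

    def test_repeated_constant(self):
        assert estimate_sigma([-2.0] * 5) == pytest.approx(2.0)

    def test_homogeneous_scaling(self, rng):
        s = rng.normal(size=50)
        assert estimate_sigma(3.5 * s) == pytest.approx(3.5 * estimate_sigma(s))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_sigma(np.zeros(10))


class TestChi2:
    def test_zero_score_p_one(self):
        assert chi2_pvalues(np.array([0.0]), 1.0, df=1)[0] == pytest.approx(1.0)

    def test_normal_quantile_squared_df1(self):
        # (1.959964)^2 is the 5% two-sided normal threshold
        p = chi2_pvalues(np.array([np.sqrt(3.841459)]), 1.0, df=1)[0]
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_df2_closed_form(self):
        # for df=2 the upper tail is exp(-x/2)
        p = chi2_pvalues(np.array([[1.0, 1.0]]), np.array([1.0, 1.0]), df=2)[0]
        assert p == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_sign_invariance(self, rng):
        s = rng.normal(size=30)
        np.testing.assert_allclose(chi2_pvalues(s, 2.0), chi2_pvalues(-s, 2.0))

    def test_bad_df(self):
        with pytest.raises(ValueError, match="degrees"):
            chi2_pvalues(np.array([1.0]), 1.0, df=0)


def _bh_oracle(p):
    """Independent step-up implementation straight from the definition."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestBH:
    def test_hand_computed_examples(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_adjust([0.001, 0.5]), [0.002, 0.5])
        np.testing.assert_allclose(bh_adjust([0.42]), [0.42])

    def test_matches_independent_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_bounded(self, rng):
        p = rng.random(200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=25))
    def test_step_up_properties_hold_on_arbitrary_inputs(self, p):
        adj = bh_adjust(p)
        assert (adj <= 1.0 + 1e-15).all() and (adj >= np.asarray(p) - 1e-15).all()
        np.testing.assert_allclose(adj, _bh_oracle(p), atol=1e-12)
        # order of the adjusted values follows the order of the raw values
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestSelect:
    def _table(self, p_adj, omics="b"):
        data = pd.DataFrame(
            {
                "feature_id": [f"f{i}" for i in range(len(p_adj))],
                "omics_id": omics,
                "score": 0.0,
                "p": p_adj,
                "p_adj": p_adj,
                "selected": False,
            }
        )
        return FeatureScoreTable(data=data, sigma={omics: 1.0})

    def test_nothing_selected_at_p_one(self):
        out = select_features(self._table([1.0, 1.0]), 0.01)
        assert out.data["selected"].sum() == 0

    def test_threshold_is_inclusive(self):
        out = select_features(self._table([0.005, 0.01, 0.02]), 0.01)
        assert out.data["selected"].tolist() == [True, True, False]

    def test_missing_threshold_rejected(self):
        with pytest.raises(ValueError, match="no threshold"):
            select_features(self._table([0.5]), {"other": 0.01})

    def test_per_block_thresholds(self):
        t1 = self._table([0.02], omics="expr").data
        t2 = self._table([0.02], omics="prot").data
        table = FeatureScoreTable(data=pd.concat([t1, t2], ignore_index=True), sigma={})
        out = select_features(table, {"expr": 0.01, "prot": 0.05})
        assert out.counts().to_dict() == {"expr": 0, "prot": 1}


class TestScoreBlock:
    def test_null_uniform_p_and_few_selections(self, rng):
        from ktdfe import MultiOmicsBlock
        from scipy.stats import kstest

        b = MultiOmicsBlock(omics_id="n", values=rng.normal(size=(400, 6)))
        u = rng.normal(size=6)
        u /= np.linalg.norm(u)
        factors = [None, np.column_stack([u, np.eye(6)[:, :5]])]
        out = score_block(b, _choice((1,)), factors, threshold=0.01)
        # Gaussian scores with RMS sigma: raw P approximately uniform
        assert kstest(out.data["p"], "uniform").statistic < 0.08
        assert out.data["selected"].sum() <= 2
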