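import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from zframan.features import split_features
from zframan.pls import (
    PLSFingerprint,
    PLSModel,
    cross_validate_q2,
    encode_stages,
    fit_pls,
    scalar_projections,
    select_components,
    vector_module,
    vip_scores,
)
from zframan.synth import simulate_features, null_trajectory_spec

from _oracles import svd_pls2_predict


def random_instance(rng, n=None, p=None, m=None):
    n = n or int(rng.integers(8, 21))
    p = p or int(rng.integers(3, 31))
    m = m or int(rng.integers(2, 8))
    X = rng.normal(size=(n, p))
    y = rng.integers(0, m, n)
    while np.unique(y).size < 2:
        y = rng.integers(0, m, n)
    return X, y


class TestNIPALS:
    def test_perfect_single_descriptor(self):
        y = np.array([24, 24, 48, 48, 72, 72])
        Y, _ = encode_stages(y)
        x = (Y[:, 0] - Y[:, 0].mean())[:, None]  # centred indicator of stage 24
        model = fit_pls(x, y, A_max=1)
        pred = model.predict(x, 1)
        np.testing.assert_allclose(pred[:, 0], Y[:, 0], atol=1e-10)

    def test_score_orthogonality(self, rng):
        X, y = random_instance(rng, n=16, p=12, m=4)
        model = fit_pls(X, y, A_max=5)
        T = model.x_scores
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_r2_nondecreasing(self, rng):
        X, y = random_instance(rng, n=18, p=10, m=4)
        model = fit_pls(X, y, A_max=6)
        assert np.all(np.diff(model.r2) >= -1e-12)

    def test_matches_svd_oracle(self, rng):
        for _ in range(20):
            X, y = random_instance(rng)
            Y, _ = encode_stages(y)
            a = int(min(3, np.linalg.matrix_rank(X - X.mean(0))))
            model = fit_pls(X, y, A_max=a)
            got = model.n_components
            if got == 0:
                continue
            mine = model.predict(X, got)
            Xc = X - X.mean(axis=0)
            Yc = Y - Y.mean(axis=0)
            oracle = svd_pls2_predict(Xc, Yc, Xc, got) + Y.mean(axis=0)
            rms = np.sqrt(np.mean((mine - oracle) ** 2))
            assert rms < 1e-6

    def test_single_stage_errors(self):
        with pytest.raises(ValueError, match="2 classes"):
            fit_pls(np.random.default_rng(0).normal(size=(6, 3)), [24] * 6, 2)

    def test_a_max_truncated_with_warning(self, rng):
        X, y = random_instance(rng, n=6, p=3, m=3)
        with pytest.warns(UserWarning, match="truncat"):
            model = fit_pls(X, y, A_max=10)
        assert model.n_components <= 5


class TestQ2:
    def test_strong_signal(self, rng):
        stages = np.repeat([24, 48, 72, 96], 6)
        groups = np.tile(np.arange(6), 4)
        u = (stages - 24) / 72.0
        X = np.column_stack(
            [10 * (2 * u - 1) + rng.normal(size=24) for _ in range(4)]
            + [rng.normal(size=24) for _ in range(4)]
        )
        q2 = cross_validate_q2(X, stages, 2, groups)
        assert q2[0] > 0.3

    def test_q2_below_r2(self, rng):
        for _ in range(10):
            X, y = random_instance(rng, n=18, p=8, m=3)
            groups = np.arange(18) % 6
            model = fit_pls(X, y, A_max=3)
            a = model.n_components
            if a == 0:
                continue
            q2 = cross_validate_q2(X, y, a, groups)
            assert np.all(q2 <= model.r2[:a] + 1e-9)

    def test_needs_three_groups(self, rng):
        X, y = random_instance(rng, n=8, p=4, m=2)
        with pytest.raises(ValueError, match="3 animals"):
            cross_validate_q2(X, y, 1, np.arange(8) % 2)


class TestSelectComponents:
    @pytest.mark.parametrize(
        "q2,expected",
        [
            ([0.5, 0.6, 0.61], 2),  # third gain is exactly 0.01, not strictly more
            ([-0.2], 1),  # floor at one component
            ([0.3, 0.5, 0.8], 3),
        ],
    )
    def test_examples(self, q2, expected):
        assert select_components([0.9] * len(q2), q2, q2_gain=0.01) == expected


def toy_model(P, Q, T=None):
    p, a = P.shape
    n = 6
    T = np.ones((n, a)) if T is None else T
    return PLSModel(
        x_weights=P.copy(),
        x_scores=T,
        x_loadings=P,
        y_loadings=Q,
        r2=np.linspace(0.5, 0.9, a),
        classes=np.arange(Q.shape[0]),
        x_mean=np.zeros(p),
        y_mean=np.zeros(Q.shape[0]),
        feature_names=[f"d{i}" for i in range(p)],
    )


class TestScalarProjections:
    def test_one_dimensional_reduces_to_signed_q(self):
        model = toy_model(P=np.array([[0.5]]), Q=np.array([[2.0]]))
        s = scalar_projections(model, 1, normalisation="loading")
        assert s.iloc[0, 0] == pytest.approx(2.0)

    def test_orthogonal_vectors_project_to_zero(self):
        model = toy_model(P=np.array([[1.0, 0.0]]), Q=np.array([[0.0, 3.0]]))
        s = scalar_projections(model, 2, normalisation="loading")
        assert s.iloc[0, 0] == pytest.approx(0.0, abs=1e-15)

    def test_cosine_identity(self, rng):
        P = rng.normal(size=(5, 3))
        Q = rng.normal(size=(4, 3))
        model = toy_model(P=P, Q=Q)
        S = scalar_projections(model, 3, normalisation="loading").to_numpy()
        for k in range(4):
            for j in range(5):
                cos = Q[k] @ P[j] / (np.linalg.norm(Q[k]) * np.linalg.norm(P[j]))
                expect = np.linalg.norm(Q[k]) * cos
                assert S[k, j] == pytest.approx(expect, abs=1e-12)

    def test_zero_norm_loading_warns(self):
        model = toy_model(P=np.array([[0.0, 0.0], [1.0, 0.0]]), Q=np.array([[1.0, 1.0]]))
        with pytest.warns(UserWarning, match="zero-norm"):
            s = scalar_projections(model, 2, normalisation="loading")
        assert s.iloc[0, 0] == 0.0

    def test_sign_flip_invariance(self, rng):
        # flipping one component's (w, t, p, q) together leaves projections
        # unchanged under every definition
        P = rng.normal(size=(6, 2))
        Q = rng.normal(size=(4, 2))
        T = rng.normal(size=(6, 2))
        for norm in ("covariance", "loading", "raw"):
            s0 = scalar_projections(toy_model(P, Q, T), 2, norm).to_numpy()
            P2, Q2, T2 = P.copy(), Q.copy(), T.copy()
            P2[:, 1] *= -1
            Q2[:, 1] *= -1
            T2[:, 1] *= -1
            s1 = scalar_projections(toy_model(P2, Q2, T2), 2, norm).to_numpy()
            np.testing.assert_allclose(s0, s1, atol=1e-12)


class TestVectorModule:
    def test_pythagoras(self):
        s = pd.DataFrame({"d": [3.0, 4.0]})
        assert vector_module(s)["d"] == pytest.approx(5.0)

    def test_all_zero(self):
        s = pd.DataFrame({"d": [0.0, 0.0, 0.0]})
        for definition in ("norm", "abs_sum", "sum_abs"):
            assert vector_module(s, definition)["d"] == 0.0

    def test_stage_permutation_invariant(self, rng):
        S = pd.DataFrame(rng.normal(size=(5, 7)))
        perm = rng.permutation(5)
        for definition in ("norm", "sum_abs"):
            m0 = vector_module(S, definition)
            m1 = vector_module(S.iloc[perm].reset_index(drop=True), definition)
            np.testing.assert_allclose(m0, m1)

    def test_normalised_max_is_one(self, rng):
        S = pd.DataFrame(rng.normal(size=(4, 6)))
        m = vector_module(S, normalise=True)
        assert m.max() == pytest.approx(1.0)


class TestFingerprint:
    def test_single_carrier_descriptor_attains_max_module(self):
        hits, rhos = 0, []
        for s in range(20):
            rng = np.random.default_rng(s)
            stages = np.repeat([24, 48, 72, 96], 6)
            groups = np.tile(np.arange(6), 4)
            u = (stages - 24) / 72.0
            X = rng.normal(size=(24, 12))
            X[:, 0] = 3 * (2 * u - 1) + 0.3 * rng.normal(size=24)
            Xdf = pd.DataFrame(X, columns=[f"d{i}" for i in range(12)])
            est = PLSFingerprint().fit(Xdf, stages, groups)
            hits += est.modules_.index[0] == "d0"
            rhos.append(spearmanr(est.modules_[est.vip_.index], est.vip_).statistic)
        assert hits >= 18
        assert np.mean(rhos) > 0.8

    def test_deterministic_repeat(self):
        mat = simulate_features("swim_bladder", seed=5)
        X, y, g = split_features(mat)
        t1 = PLSFingerprint().fit(X, y, g).fingerprint_table("swim_bladder")
        t2 = PLSFingerprint().fit(X, y, g).fingerprint_table("swim_bladder")
        pd.testing.assert_frame_equal(t1.to_frame(), t2.to_frame())
        assert t1.to_frame().equals(t2.to_frame())

    def test_null_top_module_below_planted_top_module(self):
        # removing the stage effect should clearly deflate the leading module
        null_tops, planted_tops = [], []
        for s in range(5):
            mat0 = simulate_features("iris", spec=null_trajectory_spec(), seed=100 + s)
            mat1 = simulate_features("iris", seed=100 + s)
            for mat, acc in ((mat0, null_tops), (mat1, planted_tops)):
                X, y, g = split_features(mat)
                acc.append(PLSFingerprint().fit(X, y, g).modules_.iloc[0])
        assert np.mean(null_tops) < 0.5 * np.mean(planted_tops)

    def test_modules_sorted_descending(self):
        mat = simulate_features("heart", seed=2)
        X, y, g = split_features(mat)
        est = PLSFingerprint().fit(X, y, g)
        assert list(est.modules_) == sorted(est.modules_, reverse=True)

    def test_pls1_mode_runs(self):
        mat = simulate_features("iris", seed=3)
        X, y, g = split_features(mat)
        est = PLSFingerprint(mode="pls1").fit(X, y, g)
        pred = est.predict(X)
        assert pred.shape == (len(y),)
        # numeric hpf prediction should correlate with truth
        assert np.corrcoef(pred, y)[0, 1] > 0.5

    def test_sklearn_get_set_params(self):
        est = PLSFingerprint(q2_gain=0.02)
        assert est.get_params()["q2_gain"] == 0.02
        est.set_params(module="sum_abs")
        assert est.module == "sum_abs"

    def test_vip_of_fitted_model(self):
        mat = simulate_features("muscle", seed=1)
        X, y, g = split_features(mat)
        est = PLSFingerprint().fit(X, y, g)
        vip = vip_scores(est.model_, est.n_components_)
        assert (vip >= 0).all()
        # mean squared VIP equals one by construction
        assert np.mean(vip**2) == pytest.approx(1.0, rel=1e-6)
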