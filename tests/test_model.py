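"""Model front-end: method configurations, extraction, regularization paths."""

import numpy as np
import pandas as pd
import pytest

from lscggm.admm import SolverOptions
from lscggm.core import Dataset, suff_stats
from lscggm.model import (
    LSCGGM,
    MethodConfig,
    fit_method,
    regularization_path,
    support_edges,
)
from lscggm.simulate import SimDesign, make_model, sample_dataset

FAST = SolverOptions(tol_primal=1e-6, tol_dual=1e-6, max_iter=800)


@pytest.fixture(scope="module")
def sparse_data():
    # no latent structure, sparse direct effects
    design = SimDesign(k=3, d_z=3, d_h=3, n=1500, seed=3)
    model = make_model(design)
    return model, sample_dataset(model, design.n, seed=4)


class TestMethodConfig:
    def test_rejects_unknown_method(self):
        with pytest.raises(ValueError, match="unknown method"):
            MethodConfig(method="ridge")

    def test_rejects_unsorted_lambdas(self):
        with pytest.raises(ValueError, match="decreasing"):
            MethodConfig(lambdas=(0.1, 0.5))

    def test_rejects_multiple_gammas_for_sparse_only(self):
        with pytest.raises(ValueError, match="singleton"):
            MethodConfig(method="scggm", gammas=(0.5, 0.9))

    def test_gamma_one_allowed_when_l_frozen(self):
        MethodConfig(method="glasso", gammas=(1.0,))
        with pytest.raises(ValueError):
            MethodConfig(method="lscggm", gammas=(1.0,))


class TestMethods:
    def test_scggm_support_shrinks_with_lambda(self, sparse_data):
        model, data = sparse_data
        mdl = LSCGGM(y_x=data.y_x, y_z=data.y_z, method="scggm")
        true = model.true_edges()
        sizes = []
        supports = []
        prev = None
        for lam in [0.02, 0.1, 0.4]:
            res = mdl.fit(lam, 1.0, options=FAST, warm_start=prev)
            prev = res.raw.params
            supports.append(res.support)
            sizes.append(len(res.support))
        assert supports[0] >= true  # moderate penalty keeps all true edges
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_glasso_lambda_zero_is_joint_precision(self, rng):
        n, m, p = 4000, 2, 3
        data = Dataset(y_z=rng.standard_normal((n, m)), y_x=rng.standard_normal((n, p)))
        stats = suff_stats(data)
        mdl = LSCGGM(y_x=data.y_x, y_z=data.y_z, method="glasso")
        res = mdl.fit(0.0, 1.0, options=FAST)
        joint_prec = np.linalg.inv(stats.joint())
        np.testing.assert_allclose(res.raw.params.s_x, joint_prec, atol=1e-5)
        # extracted X block = precision of X given Z (Schur identity)
        cond_prec = np.linalg.inv(
            stats.sigma_x - stats.sigma_zx.T @ np.linalg.solve(stats.sigma_z, stats.sigma_zx)
        )
        np.testing.assert_allclose(res.s_x, cond_prec, atol=1e-5)

    def test_lrps_on_inputless_data_equals_lscggm(self, rng):
        y_x = rng.standard_normal((300, 4))
        a = LSCGGM(y_x=y_x, method="lrps").fit(0.1, 0.5, options=FAST)
        b = LSCGGM(y_x=y_x, method="lscggm").fit(0.1, 0.5, options=FAST)
        np.testing.assert_allclose(a.s_x, b.s_x, atol=1e-6)
        np.testing.assert_allclose(a.l_x, b.l_x, atol=1e-6)

    def test_lscggm_small_gamma_behaves_like_sparse_conditional(self, sparse_data):
        model, data = sparse_data
        full = LSCGGM(y_x=data.y_x, y_z=data.y_z, method="lscggm").fit(
            0.5, 0.02, options=FAST
        )
        assert full.latent_rank == 0

    def test_joint_extraction_shapes(self, rng):
        data = Dataset(y_z=rng.standard_normal((200, 2)), y_x=rng.standard_normal((200, 3)))
        res = LSCGGM(y_x=data.y_x, y_z=data.y_z, method="lrps").fit(0.1, 0.5, options=FAST)
        assert res.s_x.shape == (3, 3)
        assert res.s_zx.shape == (2, 3)
        assert res.l_x.shape == (3, 3)


class TestPath:
    def test_first_entry_empty_at_lambda_max(self, sparse_data):
        _, data = sparse_data
        mdl = LSCGGM(y_x=data.y_x, y_z=data.y_z, method="scggm")
        path = mdl.fit_path(gammas=(1.0,), n_lambda=5, options=FAST)
        assert path.entries[0].support == set()

    def test_support_cardinality_mostly_monotone(self, sparse_data):
        _, data = sparse_data
        mdl = LSCGGM(y_x=data.y_x, y_z=data.y_z, method="lscggm")
        path = mdl.fit_path(gammas=(0.5,), n_lambda=10, options=FAST)
        sizes = [len(e.support) for e in path.entries]
        pairs = list(zip(sizes, sizes[1:]))
        frac = np.mean([b >= a for a, b in pairs])
        assert frac >= 0.95

    def test_warm_equals_cold_supports(self, rng):
        data = Dataset(y_z=rng.standard_normal((400, 2)),
                       y_x=rng.standard_normal((400, 8)))
        mdl = LSCGGM(y_x=data.y_x, y_z=data.y_z, method="lscggm")
        lams = np.geomspace(0.5, 0.05, 5)
        warm = mdl.fit_path(lambdas=lams, gammas=(0.5,), warm_start=True, options=FAST)
        cold = mdl.fit_path(lambdas=lams, gammas=(0.5,), warm_start=False, options=FAST)
        for a, b in zip(warm.entries, cold.entries):
            assert a.support == b.support

    def test_nonconvergence_recorded_and_path_continues(self, sparse_data):
        _, data = sparse_data
        mdl = LSCGGM(y_x=data.y_x, y_z=data.y_z, method="lscggm")
        tiny = SolverOptions(max_iter=3)
        path = mdl.fit_path(lambdas=(0.3, 0.1), gammas=(0.5,), options=tiny)
        assert len(path.entries) == 2
        assert not any(e.result.converged for e in path.entries)


class TestFrontEnd:
    def test_from_dataframe_with_prefix(self, rng):
        df = pd.DataFrame(
            rng.standard_normal((50, 4)), columns=["z1", "z2", "xA", "xB"]
        )
        mdl = LSCGGM.from_dataframe(df, z_prefix="z")
        assert mdl.stats.m == 2 and mdl.stats.p == 2
        assert mdl.data.x_labels == ["xA", "xB"]

    def test_functional_wrappers(self, rng):
        data = Dataset(y_z=rng.standard_normal((200, 2)), y_x=rng.standard_normal((200, 3)))
        cfg = MethodConfig(method="scggm", lambdas=(0.3, 0.1), gammas=(1.0,))
        res = fit_method(cfg, data, options=FAST)
        assert res.converged
        path = regularization_path(cfg, data, options=FAST)
        assert len(path.entries) == 2

    def test_summary_mentions_key_quantities(self, rng):
        data = Dataset(y_z=rng.standard_normal((200, 2)), y_x=rng.standard_normal((200, 3)))
        res = LSCGGM(y_x=data.y_x, y_z=data.y_z).fit(0.1, 0.5, options=FAST)
        text = res.summary()
        for token in ("lambda", "gamma", "objective", "edges in S_X", "rank of L"):
            assert token in text

    def test_support_edges_symmetrized_threshold(self):
        s = np.zeros((3, 3))
        s[0, 1] = 1e-9
        s[1, 0] = 0.5  # asymmetric solver noise: max(|.|,|.|^T) counts it
        s[2, 1] = 1e-9
        assert support_edges(s) == {(0, 1)}
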