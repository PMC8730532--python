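import numpy as np
import pytest

from herimap.greml import RemlOptions, fit_reml, fit_reml_batch, restricted_loglik
from herimap.greml import _EigenDesign, _eigen_quantities
from herimap.grm import make_covariates
from herimap.voxelmap import VoxelIndex, VoxelQTMatrix

from oracles import dense_reml_loglik, grid_search_reml


def _draw(family_sqrt, rng, h2, n=None):
    n = family_sqrt.shape[0] if n is None else n
    g = family_sqrt @ rng.standard_normal(family_sqrt.shape[0])
    return np.sqrt(h2) * g + np.sqrt(1 - h2) * rng.standard_normal(n)


class TestRestrictedLoglik:
    def test_identity_grm_collapses_to_total_variance(self):
        rng = np.random.default_rng(1)
        n = 30
        y = rng.normal(size=n)
        x = np.ones((n, 1))
        a = np.eye(n)
        assert restricted_loglik(y, x, a, 1.0, 1.0) == pytest.approx(
            restricted_loglik(y, x, a, 0.5, 1.5), abs=1e-10
        )

    def test_small_fixture_matches_dense_oracle(self):
        # frozen N = 5 instance
        y = np.array([0.3, -1.2, 0.7, 2.1, -0.4])
        x = np.column_stack([np.ones(5), [1.0, 2.0, 0.5, -1.0, 0.3]])
        a = np.array(
            [
                [1.0, 0.5, 0.0, 0.0, 0.1],
                [0.5, 1.1, 0.0, 0.1, 0.0],
                [0.0, 0.0, 0.9, 0.4, 0.0],
                [0.0, 0.1, 0.4, 1.2, 0.0],
                [0.1, 0.0, 0.0, 0.0, 0.8],
            ]
        )
        for sg, se in [(0.4, 0.6), (1.3, 0.2), (0.01, 2.0)]:
            assert restricted_loglik(y, x, a, sg, se) == pytest.approx(
                dense_reml_loglik(y, x, a, sg, se), abs=1e-9
            )

    def test_eigen_path_equals_dense_path(self, family_grm, intercept_only):
        rng = np.random.default_rng(2)
        eig = _EigenDesign(family_grm, intercept_only)
        for _ in range(5):
            y = rng.normal(size=family_grm.n_samples)
            sg, se = rng.uniform(0.1, 2.0, 2)
            ll_eig, _, _ = _eigen_quantities(eig, eig.rotate(y), sg, se)
            ll_dense = restricted_loglik(y, intercept_only, family_grm, sg, se)
            assert ll_eig == pytest.approx(ll_dense, abs=1e-8)

    def test_singular_v_raises(self):
        y = np.zeros(4) + [1, 2, 3, 4.0]
        x = np.ones((4, 1))
        with pytest.raises(ValueError):
            restricted_loglik(y, x, -np.eye(4), 1.0, 0.0)


class TestFitReml:
    def test_null_phenotype_hits_floor(self, family_grm, intercept_only):
        rng = np.random.default_rng(99)
        y = rng.normal(size=family_grm.n_samples)  # independent of the GRM
        r = fit_reml(y, intercept_only, family_grm)
        assert r.constrained
        assert r.sigma_g2 == pytest.approx(1e-6 * np.var(y, ddof=1), rel=1e-6)
        assert r.p_value >= 0.5

    def test_matches_grid_search_oracle(self, family_sqrt):
        rng = np.random.default_rng(12)
        n = 40
        sub = family_sqrt[:n, :n]
        a = sub @ sub.T
        d = np.diag(a).mean()
        a = a / d
        x = np.ones((n, 1))
        gsq = np.linalg.cholesky(a + 1e-8 * np.eye(n))
        y = 0.7 * (gsq @ rng.standard_normal(n)) + 0.5 * rng.standard_normal(n)
        r = fit_reml(y, x, a)
        h_grid, ll_grid = grid_search_reml(y, x, a)
        assert abs(r.h2 - h_grid) <= 0.002
        assert r.loglik_full >= ll_grid - 1e-6

    def test_scale_equivariance(self, family_grm, family_sqrt, intercept_only):
        rng = np.random.default_rng(5)
        y = _draw(family_sqrt, rng, 0.6)
        r1 = fit_reml(y, intercept_only, family_grm)
        r3 = fit_reml(3.0 * y, intercept_only, family_grm)
        assert r3.h2 == pytest.approx(r1.h2, abs=1e-6)
        assert r3.sigma_g2 == pytest.approx(9.0 * r1.sigma_g2, rel=1e-4)
        assert r3.sigma_e2 == pytest.approx(9.0 * r1.sigma_e2, rel=1e-4)

    def test_h2_identity_and_lrt_invariants(self, family_grm, family_sqrt, intercept_only):
        rng = np.random.default_rng(6)
        y = _draw(family_sqrt, rng, 0.5)
        r = fit_reml(y, intercept_only, family_grm)
        assert r.h2 == pytest.approx(r.sigma_g2 / (r.sigma_g2 + r.sigma_e2), abs=1e-12)
        assert r.lrt == pytest.approx(max(0.0, 2 * (r.loglik_full - r.loglik_null)), abs=1e-12)

    def test_lrt_invariant_to_affine_covariate_transform(self, family_grm, family_sqrt):
        rng = np.random.default_rng(14)
        n = family_grm.n_samples
        covar = rng.normal(size=n)
        x1 = np.column_stack([np.ones(n), covar])
        x2 = np.column_stack([np.ones(n), 5.0 * covar - 3.0])
        y = _draw(family_sqrt, rng, 0.5)
        r1 = fit_reml(y, x1, family_grm)
        r2 = fit_reml(y, x2, family_grm)
        assert r2.lrt == pytest.approx(r1.lrt, abs=1e-5)
        assert r2.h2 == pytest.approx(r1.h2, abs=1e-6)

    def test_p_value_half_at_floor(self, family_grm, intercept_only):
        rng = np.random.default_rng(99)
        y = rng.normal(size=family_grm.n_samples)
        r = fit_reml(y, intercept_only, family_grm)
        if r.constrained and r.lrt == 0.0:
            assert r.p_value == 0.5

    def test_constant_phenotype_raises(self, family_grm, intercept_only):
        with pytest.raises(ValueError, match="constant"):
            fit_reml(np.ones(family_grm.n_samples), intercept_only, family_grm)

    def test_parameter_recovery_family_design(self, family_sqrt, family_grm, intercept_only):
        rng = np.random.default_rng(2024)
        ests = []
        for _ in range(30):
            y = _draw(family_sqrt, rng, 0.8)
            ests.append(fit_reml(y, intercept_only, family_grm).h2)
        assert abs(np.mean(ests) - 0.8) < 0.08  # N = 80 fixture: modestly wider band


class TestBatch:
    def test_batch_equals_looped_fits(self, family_grm, family_sqrt, intercept_only):
        rng = np.random.default_rng(77)
        n = family_grm.n_samples
        ys = np.column_stack([_draw(family_sqrt, rng, h) for h in np.linspace(0.1, 0.9, 10)])
        batch = fit_reml_batch(ys, intercept_only, family_grm)
        for j, r in enumerate(batch):
            single = fit_reml(ys[:, j], intercept_only, family_grm)
            assert r.h2 == pytest.approx(single.h2, abs=1e-8)
            assert r.loglik_full == pytest.approx(single.loglik_full, abs=1e-8)

    def test_duplicate_columns_identical_results(self, family_grm, family_sqrt, intercept_only):
        rng = np.random.default_rng(78)
        y = _draw(family_sqrt, rng, 0.5)
        ys = np.column_stack([y, rng.normal(size=len(y)), y])
        batch = fit_reml_batch(ys, intercept_only, family_grm)
        assert batch[0].h2 == batch[2].h2
        assert batch[0].loglik_full == batch[2].loglik_full

    def test_constant_column_recorded_and_skipped(self, family_grm, family_sqrt, intercept_only):
        rng = np.random.default_rng(79)
        ys = np.column_stack(
            [_draw(family_sqrt, rng, 0.4), np.full(family_grm.n_samples, 3.0)]
        )
        batch = fit_reml_batch(ys, intercept_only, family_grm)
        assert batch[0].status == "ok"
        assert batch[1].status == "constant_phenotype"
        assert not batch[1].converged

    def test_sample_id_mismatch_raises(self, family_grm, intercept_only):
        n = family_grm.n_samples
        idx = VoxelIndex((2, 2, 2), [[0, 0, 0], [1, 1, 1]])
        vqt = VoxelQTMatrix(np.random.default_rng(0).normal(size=(n, 2)),
                            [f"X{i}" for i in range(n)], idx)
        with pytest.raises(ValueError, match="sample"):
            fit_reml_batch(vqt, intercept_only, family_grm)
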