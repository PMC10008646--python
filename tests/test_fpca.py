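import numpy as np
import pandas as pd
import pytest

import cytoflmm as cf
from cytoflmm.errors import CoverageError, IdentifiabilityError, ShapeError
from cytoflmm.fpca import FPCBlock, FPCModel, eigendecompose_cov_model
from cytoflmm.simulate import orthonormalize, trapezoid_weights
from tests.conftest import make_tiny_panel


class TestMeans:
    def test_identical_curves_recovered_exactly(self, grid):
        f = np.sin(grid / 9.0) + 1.0
        panel = make_tiny_panel([f, f, f], grid)
        mm = cf.estimate_means(panel)
        assert np.max(np.abs(mm.means["high"] - f)) < 1e-15

    def test_symmetric_curves_average_to_zero(self, grid):
        f = np.cos(grid / 5.0)
        panel = make_tiny_panel([f, -f], grid)
        mm = cf.estimate_means(panel)
        assert np.max(np.abs(mm.means["high"])) < 1e-15

    def test_unbinned_panel_rejected(self, grid):
        panel = make_tiny_panel([np.ones(72)], grid, levels=[None])
        with pytest.raises(CoverageError):
            cf.estimate_means(panel)

    def test_mean_recovery_on_simulator(self):
        design = cf.SimulationDesign(n_group1=700, n_group10=700, n_other=600, n_controls=50)
        truth = cf.make_truth(design, seed=31, margin=0.0)
        panel = cf.simulate_panel(truth, design, seed=31)
        mm = cf.estimate_means(panel)
        for level in ("high", "medium", "low", "none"):
            assert np.max(np.abs(mm.means[level] - truth.means[level])) < 0.05


class TestCovariances:
    def test_zero_residuals_give_zero_surfaces(self, grid):
        f = np.sin(grid / 7.0)
        panel = make_tiny_panel(
            [f, f, f, f], grid, chem_ids=["a", "a", "b", "b"], reps=[1, 2, 1, 2]
        )
        mm = cf.estimate_means(panel)
        cov = cf.estimate_covariances(panel, mm)
        assert np.max(np.abs(cov.k_b["high"])) == 0.0
        assert np.max(np.abs(cov.k_e)) < 1e-15
        assert cov.sigma2 == 0.0

    def test_unreplicated_cells_not_identifiable(self, grid):
        rng = np.random.default_rng(0)
        panel = make_tiny_panel(
            rng.normal(size=(3, 72)), grid, chem_ids=["a", "b", "c"], reps=[1, 1, 1]
        )
        mm = cf.estimate_means(panel)
        with pytest.raises(IdentifiabilityError):
            cf.estimate_covariances(panel, mm)

    def test_rank_one_recovery(self, grid, quad_weights):
        """Simulator with a rank-1 chemical covariance, no smooth error, no
        noise: the cross-replicate moment estimator recovers phi phi'."""
        design = cf.SimulationDesign(
            n_group1=500, n_group10=500, n_other=0, n_controls=1,
            n_concentrations=3, bin_map={1: "high", 2: "high", 3: "high"},
        )
        truth = cf.make_truth(
            design, n_fpc=1, seed=32, margin=0.0, sigma2=0.0,
            b_eigenvalues=(1.0,), e_eigenvalues=(0.0,),
        )
        panel = cf.simulate_panel(truth, design, seed=32)
        mm = cf.estimate_means(panel)
        cov = cf.estimate_covariances(panel, mm)
        phi = truth.b_eigenfunctions["high"][0]
        target = np.outer(phi, phi)
        rel = np.linalg.norm(cov.k_b["high"] - target) / np.linalg.norm(target)
        assert rel < 0.1


class TestEigendecompose:
    def test_rank_one_identity(self, grid, quad_weights):
        phi = orthonormalize(np.sin(np.pi * (grid - 1) / 71)[None, :], quad_weights)[0]
        block = cf.eigendecompose(2.0 * np.outer(phi, phi), grid, n_keep=3)
        assert block.eigenvalues[0] == pytest.approx(2.0, rel=1e-8)
        inner = abs(np.sum(quad_weights * block.eigenfunctions[0] * phi))
        assert inner > 0.999

    def test_zero_surface_keeps_nothing(self, grid):
        block = cf.eigendecompose(np.zeros((72, 72)), grid, n_keep=3)
        assert block.n_components == 0

    def test_full_reconstruction_matches_dense_solver(self, grid):
        rng = np.random.default_rng(33)
        A = rng.normal(size=(72, 10))
        K = A @ A.T  # random PSD surface of rank 10
        block = cf.eigendecompose(K, grid, n_keep=72)
        recon = block.covariance()
        assert np.max(np.abs(recon - K)) < 1e-8

    def test_orthonormality_and_proportions(self, grid, quad_weights):
        rng = np.random.default_rng(34)
        A = rng.normal(size=(72, 5))
        block = cf.eigendecompose(A @ A.T, grid, n_keep=4)
        phi = block.eigenfunctions
        gram = (phi * quad_weights) @ phi.T
        assert np.max(np.abs(gram - np.eye(4))) < 1e-6
        assert np.all(np.diff(block.var_explained) <= 1e-15)
        assert block.var_explained.sum() <= 1.0 + 1e-12

    def test_asymmetric_surface_rejected(self, grid):
        K = np.zeros((72, 72))
        K[0, 1] = 1.0
        with pytest.raises(ShapeError):
            cf.eigendecompose(K, grid)

    def test_sign_convention_nonnegative_integral(self, grid, quad_weights):
        rng = np.random.default_rng(35)
        A = rng.normal(size=(72, 6))
        block = cf.eigendecompose(A @ A.T, grid, n_keep=5)
        for k in range(block.n_components):
            integral = np.sum(quad_weights * block.eigenfunctions[k])
            assert integral >= -1e-8


def _single_block_model(grid, phi, lam, sigma2):
    block = FPCBlock(
        eigenvalues=np.asarray(lam, float),
        eigenfunctions=np.atleast_2d(phi),
        var_explained=np.ones(1),
    )
    empty = FPCBlock(
        eigenvalues=np.zeros(0), eigenfunctions=np.zeros((0, grid.size)),
        var_explained=np.zeros(0),
    )
    return FPCModel(grid=grid, b_blocks={"high": block}, e_block=empty, sigma2=sigma2)


class TestScores:
    def test_zero_residuals_zero_scores(self, grid):
        f = np.sin(grid / 6.0)
        panel = make_tiny_panel(
            [f, f, f, f], grid, chem_ids=["a", "a", "b", "b"], reps=[1, 2, 1, 2]
        )
        mm = cf.estimate_means(panel)
        cov = cf.estimate_covariances(panel, mm)
        fpc = eigendecompose_cov_model(cov, n_fpc=3)
        scores = cf.predict_scores(panel, mm, fpc, sigma2=0.01)
        vcols = [c for c in scores.columns if c.startswith("V")]
        if vcols:
            assert np.max(np.abs(scores[vcols].to_numpy())) < 1e-10

    def test_blup_limit_equals_projection(self, grid, quad_weights):
        """With sigma^2 -> 0 and data in the span of one eigenfunction the
        BLUP equals the replicate-averaged quadrature inner product."""
        phi = orthonormalize(np.sin(2 * np.pi * (grid - 1) / 71)[None, :], quad_weights)[0]
        a = (1.7, 0.9)  # per-replicate amplitudes
        mu = np.zeros(72)
        panel = make_tiny_panel(
            [mu + a[0] * phi, mu + a[1] * phi], grid,
            chem_ids=["c", "c"], reps=[1, 2],
        )
        mm = cf.MeanModel(grid=grid, means={"high": mu})
        fpc = _single_block_model(grid, phi, [1.0], sigma2=0.0)
        scores = cf.predict_scores(panel, mm, fpc, sigma2=1e-8)
        projection = np.mean([np.sum(quad_weights * a_i * phi * phi) for a_i in a])
        assert scores["V1"].iloc[0] == pytest.approx(projection, abs=1e-6)

    def test_shrinkage_single_curve(self, grid, quad_weights):
        phi = orthonormalize(np.cos(np.pi * (grid - 1) / 71)[None, :], quad_weights)[0]
        rng = np.random.default_rng(36)
        curve = 1.3 * phi + 0.05 * rng.normal(size=72)
        panel = make_tiny_panel([curve], grid, chem_ids=["c"], reps=[1])
        mm = cf.MeanModel(grid=grid, means={"high": np.zeros(72)})
        fpc = _single_block_model(grid, phi, [1.0], sigma2=0.2)
        scores = cf.predict_scores(panel, mm, fpc, sigma2=0.2)
        blup = scores["V1"].iloc[0]
        projection = np.sum(quad_weights * curve * phi)
        assert abs(blup) <= abs(projection) + 1e-12

    def test_missing_level_flagged_nan(self, grid, quad_weights):
        design = cf.SimulationDesign(n_group1=3, n_group10=3, n_other=0, n_controls=1)
        truth = cf.make_truth(design, seed=37)
        panel = cf.simulate_panel(truth, design, seed=37)
        # drop every "low" curve of one chemical
        drop = (
            (panel.obs["chemical_id"] == "chem001")
            & (panel.obs["binned_level"] == "low")
        ).to_numpy()
        sub = panel.subset(~drop)
        res = cf.fit_fpca(sub)
        row = res.scores.set_index("chemical_id").loc["chem001"]
        assert np.isnan(row["V7"]) and np.isnan(row["V9"])
        assert np.isfinite(row["V1"])


def test_reconstruction_error_monotone_in_components(grid, quad_weights):
    """Quadrature projections onto more eigenfunctions never fit worse."""
    rng = np.random.default_rng(38)
    shapes = np.array([np.sin((j + 1) * np.pi * (grid - 1) / 71) for j in range(5)])
    phi = orthonormalize(shapes, quad_weights)
    curve = rng.normal(size=5) @ phi + 0.1 * rng.normal(size=72)
    errors = []
    for k in range(1, 6):
        coef = (phi[:k] * quad_weights) @ curve
        recon = coef @ phi[:k]
        errors.append(np.sum(quad_weights * (curve - recon) ** 2))
    assert np.all(np.diff(errors) <= 1e-12)


def test_score_table_layout(small_panel):
    res = cf.fit_fpca(small_panel)
    vcols = [c for c in res.scores.columns if c.startswith("V")]
    assert vcols == [f"V{i}" for i in range(1, 10)]
    assert len(res.scores) == len(small_panel.chemicals())
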