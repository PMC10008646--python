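import numpy as np
import pytest
from scipy.integrate import quad
from statsmodels.stats.multitest import multipletests

import cytoflmm as cf
from cytoflmm import bspline as bsp
from cytoflmm.errors import ConfigError, CoverageError, DomainError


class TestBasis:
    def test_partition_of_unity(self, basis):
        t = np.linspace(0.0, 72.0, 301)
        vals = basis.evaluate(t)
        assert np.max(np.abs(vals.sum(axis=1) - 1.0)) < 1e-10
        assert np.all(vals >= -1e-12)

    def test_endpoint_interpolation(self, basis):
        assert basis.evaluate(0.0)[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert basis.evaluate(72.0)[0, -1] == pytest.approx(1.0, abs=1e-12)

    def test_gram_matrix_matches_numeric_integration(self, basis, grid, quad_weights):
        trap = (basis.matrix.T * quad_weights) @ basis.matrix
        exact = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                exact[i, j] = quad(
                    lambda t: basis.evaluate(t)[0, i] * basis.evaluate(t)[0, j],
                    grid[0], grid[-1], limit=200,
                )[0]
        # trapezoid on the hourly grid vs adaptive quadrature of the product
        assert np.max(np.abs(trap - exact)) < 1e-2
        # and the Bernstein-basis Gram on [0,72] has the closed form B[i,j] ∝ C(3,i)C(3,j)/C(6,i+j)
        full = np.zeros((4, 4))
        from math import comb
        for i in range(4):
            for j in range(4):
                full[i, j] = 72.0 * comb(3, i) * comb(3, j) / (comb(6, i + j) * 7)
        exact_full = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                exact_full[i, j] = quad(
                    lambda t: basis.evaluate(t)[0, i] * basis.evaluate(t)[0, j],
                    0.0, 72.0, limit=200,
                )[0]
        assert np.max(np.abs(full - exact_full)) < 1e-8

    def test_too_few_basis_functions(self):
        with pytest.raises(ConfigError):
            cf.make_bspline_basis(n_basis=3, degree=3)

    def test_interior_knots_for_larger_bases(self, grid):
        b7 = cf.make_bspline_basis(domain=(0.0, 72.0), n_basis=7, degree=3, grid=grid)
        assert np.max(np.abs(b7.matrix.sum(axis=1) - 1.0)) < 1e-10


class TestDesign:
    def _panel(self, basis, grid, n1=3, n2=2, seed=0, sigma2=0.01, **kw):
        rng = np.random.default_rng(seed)
        beta = {"MOA1": rng.normal(0, 1, (3, 4)), "MOA10": rng.normal(0, 1, (3, 4))}
        G = kw.get("G", [0.3 * np.eye(4) for _ in range(3)])
        W = kw.get("W", 0.05 * np.eye(4))
        panel = cf.simulate_spline_panel(
            basis.matrix, grid, beta, {"MOA1": n1, "MOA10": n2}, G, W,
            sigma2=sigma2, seed=seed,
        )
        return panel, beta

    def test_dimension_bookkeeping(self, basis, grid):
        panel, _ = self._panel(basis, grid)
        design = bsp.build_design(panel, basis, with_groups=True)
        chem = design.chemicals[0]
        assert design.y_length(chem) == 792  # 11 curves x 72 h
        assert design.z2_n_cols(chem) == 44  # 11 curves x 4 splines
        assert design.n_fixed == 24  # 2 groups x 3 levels x 4 splines
        design0 = bsp.build_design(panel, basis, with_groups=False)
        assert design0.n_fixed == 12

    def test_centering_by_grand_mean(self, basis, grid):
        panel, _ = self._panel(basis, grid)
        design = bsp.build_design(panel, basis)
        stacked = np.vstack([design.centered[c] for c in design.chemicals])
        assert np.max(np.abs(stacked.mean(axis=0))) < 1e-10

    def test_unbinned_panel_rejected(self, basis, grid):
        panel, _ = self._panel(basis, grid)
        panel.obs.loc[0, "binned_level"] = None
        with pytest.raises(CoverageError):
            bsp.build_design(panel, basis)


class TestFit:
    def test_noiseless_beta_recovery(self, basis, grid):
        rng = np.random.default_rng(10)
        beta = {"MOA1": rng.normal(0, 1, (3, 4)), "MOA10": rng.normal(0, 1, (3, 4))}
        zero = [np.zeros((4, 4))] * 3
        panel = cf.simulate_spline_panel(
            basis.matrix, grid, beta, {"MOA1": 3, "MOA10": 3}, zero,
            np.zeros((4, 4)), sigma2=1e-8, seed=10,
        )
        design = bsp.build_design(panel, basis, with_groups=True)
        fit = bsp.fit_lmm(design)
        # centering removes the curve-weighted grand mean of the fixed effects
        # (replicate counts 4/4/3 per level, equal group sizes here)
        reps = np.array([4.0, 4.0, 3.0])
        grand = sum(
            (beta[g] * reps[:, None]).sum(axis=0) for g in ("MOA1", "MOA10")
        ) / (2 * reps.sum())
        for g in ("MOA1", "MOA10"):
            for li, lv in enumerate(("high", "medium", "low")):
                est = np.array(
                    [fit.beta.loc[(g, lv, i + 1), "estimate"] for i in range(4)]
                )
                assert np.max(np.abs(est - (beta[g][li] - grand))) < 1e-3

    def test_gls_oracle_at_true_variance_components(self, grid):
        """With variance components fixed at truth the projected GLS equals a
        direct GLS on the raw per-observation model."""
        Tn = 12
        g = np.linspace(1.0, 12.0, Tn)
        basis = cf.make_bspline_basis(domain=(0.0, 12.0), n_basis=4, degree=3, grid=g)
        rng = np.random.default_rng(11)
        beta = {"A": rng.normal(0, 1, (3, 4)), "B": rng.normal(0, 1, (3, 4))}
        G = [0.4 * np.eye(4) + 0.1 for _ in range(3)]
        W = 0.1 * np.eye(4) + 0.02
        sigma2 = 0.05
        panel = cf.simulate_spline_panel(
            basis.matrix, g, beta, {"A": 3, "B": 2}, G, W, sigma2=sigma2, seed=11,
            rep_counts=(2, 2, 1),
        )
        design = bsp.build_design(panel, basis, with_groups=True)
        nb = 4
        params = np.concatenate(
            [bsp._cov_to_chol(G[i], nb) for i in range(3)]
            + [bsp._cov_to_chol(W, nb), [np.log(sigma2)]]
        )
        _, parts = bsp._neg2_reml(params, design, nb, 3)
        beta_proj = parts[3]

        # raw GLS oracle
        Phi = basis.matrix
        blocks_X, blocks_y, Vs = [], [], []
        labels = design.group_labels
        for chem in design.chemicals:
            lv_list = design.curve_levels[chem]
            n_c = len(lv_list)
            y = design.centered[chem].ravel()
            X = np.zeros((n_c * Tn, 24))
            V = np.kron(np.eye(n_c), Phi @ W @ Phi.T + sigma2 * np.eye(Tn))
            for i, lv in enumerate(lv_list):
                gi = labels.index(design.groups[chem])
                li = design.levels_present.index(lv)
                X[i * Tn : (i + 1) * Tn, gi * 12 + li * 4 : gi * 12 + li * 4 + 4] = Phi
                for j, lv2 in enumerate(lv_list):
                    if lv2 == lv:
                        li2 = design.levels_present.index(lv)
                        V[i * Tn : (i + 1) * Tn, j * Tn : (j + 1) * Tn] += (
                            Phi @ G[li2] @ Phi.T
                        )
            blocks_X.append(X)
            blocks_y.append(y)
            Vs.append(V)
        A = sum(X.T @ np.linalg.solve(V, X) for X, V in zip(blocks_X, Vs))
        b = sum(X.T @ np.linalg.solve(V, y) for X, V, y in zip(blocks_X, Vs, blocks_y))
        beta_raw = np.linalg.solve(A, b)
        assert np.max(np.abs(beta_proj - beta_raw)) < 1e-8

    def test_variance_component_recovery(self, basis, grid):
        rng = np.random.default_rng(12)
        beta = {"MOA1": rng.normal(0, 1, (3, 4)), "MOA10": rng.normal(0, 1, (3, 4))}
        G = [np.diag([0.5, 0.4, 0.3, 0.2]) + 0.1 for _ in range(3)]
        W = 0.08 * np.eye(4) + 0.02
        panel = cf.simulate_spline_panel(
            basis.matrix, grid, beta, {"MOA1": 100, "MOA10": 100}, G, W,
            sigma2=0.02, seed=12,
        )
        design = bsp.build_design(panel, basis, with_groups=True)
        fit = bsp.fit_lmm(design)
        for lv in ("high", "medium", "low"):
            rel = np.linalg.norm(fit.g_blocks[lv] - G[0]) / np.linalg.norm(G[0])
            assert rel < 0.25
        assert abs(fit.sigma2 - 0.02) / 0.02 < 0.05

    def test_criterion_improves_from_initialization(self, basis, grid):
        panel, _ = TestDesign()._panel(basis, grid, n1=4, n2=3, seed=13)
        design = bsp.build_design(panel, basis, with_groups=True)
        fit = bsp.fit_lmm(design)
        path = fit.criterion_path[np.isfinite(fit.criterion_path)]
        assert path[-1] <= path[0] + 1e-9  # -2*REML decreased (REML increased)

    def test_too_few_chemicals(self, basis, grid):
        panel, _ = TestDesign()._panel(basis, grid, n1=1, n2=0)
        design = bsp.build_design(panel, basis, with_groups=False)
        with pytest.raises(DomainError):
            bsp.fit_lmm(design)


class TestContrasts:
    def test_t_is_estimate_over_se(self, basis, grid):
        panel, _ = TestDesign()._panel(basis, grid, n1=4, n2=4, seed=14)
        design = bsp.build_design(panel, basis, with_groups=True)
        fit = bsp.fit_lmm(design)
        table = bsp.group_contrasts(fit, q=0.1)
        assert len(table) == 12
        assert np.max(np.abs(table["t"] - table["estimate"] / table["se"])) < 1e-10
        # BY decisions are monotone in the raw p-value
        sorted_tab = table.sort_values("p")
        sig = sorted_tab["significant"].to_numpy()
        assert np.all(sig[:-1] >= sig[1:])

    def test_by_is_subset_of_bh(self):
        rng = np.random.default_rng(15)
        p = rng.uniform(0, 1, size=12) ** 2
        by = multipletests(p, alpha=0.1, method="fdr_by")[0]
        bh = multipletests(p, alpha=0.1, method="fdr_bh")[0]
        assert np.all(bh | ~by)  # every BY rejection is a BH rejection

    def test_pooled_fit_has_no_contrasts(self, basis, grid):
        panel, _ = TestDesign()._panel(basis, grid)
        design = bsp.build_design(panel, basis, with_groups=False)
        fit = bsp.fit_lmm(design)
        with pytest.raises(DomainError):
            bsp.group_contrasts(fit)


class TestPrediction:
    def test_noiseless_prediction_matches_replicate_average(self, basis, grid):
        rng = np.random.default_rng(16)
        beta = {"MOA1": rng.normal(0, 1, (3, 4)), "MOA10": rng.normal(0, 1, (3, 4))}
        G = [0.3 * np.eye(4) for _ in range(3)]
        panel = cf.simulate_spline_panel(
            basis.matrix, grid, beta, {"MOA1": 4, "MOA10": 3}, G,
            np.zeros((4, 4)), sigma2=1e-10, seed=16,
        )
        design = bsp.build_design(panel, basis, with_groups=True)
        fit = bsp.fit_lmm(design)
        obs = panel.obs
        for chem in ("chem001", "chem005"):
            for lv in ("high", "low"):
                pred = bsp.predict_tcrc(fit, chem, lv)
                mask = (
                    (obs["chemical_id"] == chem) & (obs["binned_level"] == lv)
                ).to_numpy()
                avg = panel.values[mask].mean(axis=0)
                assert np.max(np.abs(pred - avg)) < 1e-4

    def test_unknown_chemical(self, basis, grid):
        panel, _ = TestDesign()._panel(basis, grid)
        fit = bsp.fit_lmm(bsp.build_design(panel, basis, with_groups=False))
        with pytest.raises(KeyError):
            bsp.predict_tcrc(fit, "nope", "high")
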