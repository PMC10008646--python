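"""B-spline mixed model for local-time group differences.

Each centered curve is modeled in a small cubic B-spline space:

    Y_tcok(t) = mu(t) + sum_i beta_{tau k i} phi_i(t) + sum_i u_{tau c i} phi_i(t)
                + sum_i w_{tau c o i} phi_i(t) + eps(t)

with tau the binned concentration level, c the chemical, o the replicate and
k the mode-of-action group; u are chemical random effects (an unstructured
4x4 covariance per level), w replicate random effects (one shared
unstructured 4x4 covariance) and eps iid white noise.  The fit maximizes the
REML criterion.  Because all systematic structure lives in the spline span,
the Gaussian likelihood factorizes exactly through the per-curve least-
squares spline coefficients: the projected 4-vectors carry all information
about beta, u, w, while the orthogonal residuals identify the noise
variance.  The REML criterion optimized here is the full-data criterion
written in that factorized form, so fits are equivalent to the raw
per-observation formulation but orders of magnitude faster.

Group contrasts (second group minus first, per level x spline) are Wald
tests with Benjamini-Yekutieli false-discovery-rate control, which remains
valid under the dependence among the contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline
from statsmodels.stats.multitest import multipletests

from .errors import (
    ConfigError,
    ConvergenceError,
    CoverageError,
    DomainError,
    ShapeError,
)
from .panel import BIN_LEVELS, CurvePanel


# ---------------------------------------------------------------------------
# basis
# ---------------------------------------------------------------------------

@dataclass
class BsplineBasis:
    degree: int
    n_basis: int
    knots: np.ndarray
    grid: np.ndarray
    matrix: np.ndarray  # (T, n_basis)

    def evaluate(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        cols = [
            BSpline.basis_element(self.knots[i : i + self.degree + 2], extrapolate=False)(t)
            for i in range(self.n_basis)
        ]
        out = np.nan_to_num(np.column_stack(cols))
        # right-endpoint support convention: last basis function equals 1 there
        at_end = np.isclose(t, self.knots[-1])
        out[at_end, -1] = 1.0
        return out


def make_bspline_basis(domain=(0.0, 72.0), n_basis: int = 4, degree: int = 3, grid=None) -> BsplineBasis:
    """Open-uniform cubic B-spline basis on ``domain`` evaluated on ``grid``.

    ``n_basis - degree - 1`` interior knots, equally spaced; the default
    (4 basis functions, degree 3) has none, giving the Bernstein-type cubic
    basis whose four functions form a partition of unity with endpoint
    interpolation (phi_1 = 1 at the left end, phi_n = 1 at the right end).
    """
    if n_basis < degree + 1:
        raise ConfigError(f"n_basis must be >= degree + 1, got {n_basis} < {degree + 1}")
    a, b = float(domain[0]), float(domain[1])
    n_interior = n_basis - degree - 1
    interior = np.linspace(a, b, n_interior + 2)[1:-1]
    knots = np.concatenate([[a] * (degree + 1), interior, [b] * (degree + 1)])
    if grid is None:
        grid = np.arange(a + 1.0, b + 1.0)
    grid = np.asarray(grid, dtype=float)
    basis = BsplineBasis(degree=degree, n_basis=n_basis, knots=knots, grid=grid, matrix=None)
    basis.matrix = basis.evaluate(grid)
    return basis


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class LmmDesign:
    """Sufficient statistics of the spline-projected mixed-model design.

    ``theta`` holds per-curve least-squares spline coefficients of the
    centered response; curves are grouped per chemical in (level, replicate)
    order.  Full-data bookkeeping (per-chemical response length, raw design
    column counts) is kept for contract checks and degrees of freedom.
    """

    basis: BsplineBasis
    mu_hat: np.ndarray  # (T,) pointwise grand mean over chemical curves
    chemicals: list
    groups: dict  # chemical -> group label (or None)
    with_groups: bool
    group_labels: list  # ordered distinct labels ([] when with_groups is False)
    levels_present: list
    theta: dict  # chemical -> (n_curves_c, n_basis)
    curve_levels: dict  # chemical -> list of level names per curve
    centered: dict  # chemical -> (n_curves_c, T) centered response curves
    rss_perp: float  # residual SS orthogonal to the spline span
    n_perp: int  # residual df orthogonal to the spline span
    n_obs: int  # total scalar observations
    q_noise: np.ndarray  # (ΦᵀΦ)^{-1}: noise covariance factor of theta

    @property
    def n_fixed(self) -> int:
        per = len(self.levels_present) * self.basis.n_basis
        return per * (len(self.group_labels) if self.with_groups else 1)

    def y_length(self, chemical) -> int:
        return len(self.curve_levels[chemical]) * self.basis.grid.size

    def z2_n_cols(self, chemical) -> int:
        return len(self.curve_levels[chemical]) * self.basis.n_basis


def build_design(panel: CurvePanel, basis: BsplineBasis, with_groups: bool = False) -> LmmDesign:
    """Project a binned panel onto the spline basis.

    The response is pre-centered by the pointwise grand mean over all
    chemical curves (the model's separate global mean term); control curves
    are excluded (the model has no concentration level for them).
    """
    if not panel.is_binned():
        raise CoverageError("panel must be binned before building the design")
    if not np.allclose(basis.grid, panel.grid):
        raise ShapeError("basis grid does not match panel grid")
    obs = panel.obs
    chem_mask = obs["concentration_index"].notna().to_numpy()
    values = panel.values[chem_mask]
    sub = obs[chem_mask].reset_index(drop=True)

    mu_hat = values.mean(axis=0)
    centered_all = values - mu_hat

    Phi = basis.matrix
    gram = Phi.T @ Phi
    q_noise = np.linalg.inv(gram)
    proj = q_noise @ Phi.T

    chemicals = list(dict.fromkeys(sub["chemical_id"]))
    levels_present = [l for l in BIN_LEVELS if (sub["binned_level"] == l).any()]

    theta, curve_levels, centered, groups = {}, {}, {}, {}
    rss_perp, n_perp, n_obs = 0.0, 0, 0
    T = panel.grid.size
    level_rank = {l: i for i, l in enumerate(BIN_LEVELS)}
    for chem in chemicals:
        sel = sub["chemical_id"] == chem
        g = sub[sel].copy()
        order = np.lexsort(
            (g["replicate_index"].to_numpy(), g["binned_level"].map(level_rank).to_numpy())
        )
        idx = g.index.to_numpy()[order]
        Y = centered_all[idx]
        th = Y @ proj.T
        fitted = th @ Phi.T
        rss_perp += float(((Y - fitted) ** 2).sum())
        n_perp += Y.shape[0] * (T - basis.n_basis)
        n_obs += Y.size
        theta[chem] = th
        centered[chem] = Y
        curve_levels[chem] = list(g["binned_level"].to_numpy()[order])
        moa = g["moa_label"].iloc[0]
        groups[chem] = None if pd.isna(moa) else moa

    group_labels = []
    if with_groups:
        labs = [groups[c] for c in chemicals]
        if any(l is None for l in labs):
            raise CoverageError("with_groups requires a MOA label for every chemical")
        group_labels = sorted(set(labs))

    return LmmDesign(
        basis=basis,
        mu_hat=mu_hat,
        chemicals=chemicals,
        groups=groups,
        with_groups=with_groups,
        group_labels=group_labels,
        levels_present=levels_present,
        theta=theta,
        curve_levels=curve_levels,
        centered=centered,
        rss_perp=rss_perp,
        n_perp=n_perp,
        n_obs=n_obs,
        q_noise=q_noise,
    )


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

def _chol_to_cov(params: np.ndarray, dim: int) -> np.ndarray:
    """Log-Cholesky parameter vector -> SPD matrix."""
    L = np.zeros((dim, dim))
    k = 0
    for i in range(dim):
        for j in range(i + 1):
            L[i, j] = np.exp(params[k]) if i == j else params[k]
            k += 1
    return L @ L.T


def _cov_to_chol(cov: np.ndarray, dim: int, floor: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    vals = np.clip(vals, floor, None)
    L = np.linalg.cholesky((vecs * vals) @ vecs.T)
    out = []
    for i in range(dim):
        for j in range(i + 1):
            out.append(np.log(max(L[i, i], floor)) if i == j else L[i, j])
    return np.array(out)


@dataclass
class LmmFit:
    """REML estimates, GLS fixed effects and BLUP random effects."""

    design: LmmDesign
    g_blocks: dict  # level -> (nb, nb) chemical covariance
    w_cov: np.ndarray  # (nb, nb) replicate covariance
    sigma2: float
    beta: pd.DataFrame  # index (group, level, spline), column estimate
    beta_cov: np.ndarray
    u: dict  # chemical -> level -> (nb,) BLUP
    w: dict  # chemical -> (n_curves_c, nb) BLUP
    reml: float
    converged: bool
    n_iter: int
    criterion_path: np.ndarray = field(default=None)

    @property
    def df_resid(self) -> int:
        return self.design.n_obs - self.beta.shape[0]


def _layout_key(levels: list) -> tuple:
    return tuple(levels)


def _build_v(levels: list, g_blocks: dict, w_cov: np.ndarray, sigma2: float, q_noise: np.ndarray):
    """Marginal covariance of the stacked per-curve spline coefficients of
    one chemical, and the u-design T mapping level effects to curves."""
    nb = w_cov.shape[0]
    n_c = len(levels)
    uniq = [l for l in BIN_LEVELS if l in levels]
    Tmat = np.zeros((n_c * nb, len(uniq) * nb))
    for i, lv in enumerate(levels):
        j = uniq.index(lv)
        Tmat[i * nb : (i + 1) * nb, j * nb : (j + 1) * nb] = np.eye(nb)
    G = np.zeros((len(uniq) * nb, len(uniq) * nb))
    for j, lv in enumerate(uniq):
        G[j * nb : (j + 1) * nb, j * nb : (j + 1) * nb] = g_blocks[lv]
    V = Tmat @ G @ Tmat.T
    noise = w_cov + sigma2 * q_noise
    for i in range(n_c):
        V[i * nb : (i + 1) * nb, i * nb : (i + 1) * nb] += noise
    return V, Tmat, G, uniq


def _fixed_design(levels: list, levels_present: list, nb: int) -> np.ndarray:
    """Per-chemical fixed design in the projected space: curve blocks x
    (level x spline) columns."""
    X = np.zeros((len(levels) * nb, len(levels_present) * nb))
    for i, lv in enumerate(levels):
        j = levels_present.index(lv)
        X[i * nb : (i + 1) * nb, j * nb : (j + 1) * nb] = np.eye(nb)
    return X


def _sufficient_stats(design: LmmDesign) -> dict:
    """Per (curve layout, group): count, sum and second moment of the stacked
    spline coefficients.  Parameter-independent, so cached on the design."""
    cached = getattr(design, "_suffstats", None)
    if cached is not None:
        return cached
    stats_ = {}
    for chem in design.chemicals:
        key = _layout_key(design.curve_levels[chem])
        group = design.groups[chem] if design.with_groups else None
        y = design.theta[chem].ravel()
        entry = stats_.setdefault(key, {}).setdefault(
            group, [0, np.zeros(y.size), np.zeros((y.size, y.size))]
        )
        entry[0] += 1
        entry[1] += y
        entry[2] += np.outer(y, y)
    design._suffstats = stats_
    return stats_


def _neg2_reml(params, design: LmmDesign, nb: int, n_levels: int):
    npc = nb * (nb + 1) // 2
    g_blocks = {
        lv: _chol_to_cov(params[i * npc : (i + 1) * npc], nb)
        for i, lv in enumerate(design.levels_present)
    }
    w_cov = _chol_to_cov(params[n_levels * npc : (n_levels + 1) * npc], nb)
    sigma2 = np.exp(params[-1])

    suff = _sufficient_stats(design)

    p = design.n_fixed
    A = np.zeros((p, p))
    bvec = np.zeros(p)
    quad_const = 0.0
    logdet = 0.0
    col_of_group = {g: i for i, g in enumerate(design.group_labels)} if design.with_groups else {}
    per = len(design.levels_present) * nb

    for key, by_group in suff.items():
        levels = list(key)
        V, _, _, _ = _build_v(levels, g_blocks, w_cov, sigma2, design.q_noise)
        try:
            cF = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf, None
        logdet_V = 2.0 * np.sum(np.log(np.diag(cF)))
        Xc = _fixed_design(levels, design.levels_present, nb)
        Vi_X = np.linalg.solve(V, Xc)
        XtViX = Xc.T @ Vi_X
        for group, (cnt, ysum, S) in by_group.items():
            logdet += cnt * logdet_V
            quad_const += float(np.trace(np.linalg.solve(V, S)))
            if design.with_groups:
                gidx = col_of_group[group]
                sl = slice(gidx * per, (gidx + 1) * per)
                A[sl, sl] += cnt * XtViX
                bvec[sl] += Vi_X.T @ ysum
            else:
                A += cnt * XtViX
                bvec += Vi_X.T @ ysum

    try:
        beta = np.linalg.solve(A, bvec)
    except np.linalg.LinAlgError:
        return np.inf, None
    quad = quad_const - 2.0 * beta @ bvec + beta @ A @ beta
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf, None
    crit = (
        logdet
        + quad
        + logdet_A
        + design.n_perp * np.log(sigma2)
        + design.rss_perp / sigma2
    )
    return crit, (g_blocks, w_cov, sigma2, beta, A)


def _initial_params(design: LmmDesign, nb: int):
    """Method-of-moments starting values in log-Cholesky coordinates."""
    sigma2_0 = max(design.rss_perp / max(design.n_perp, 1), 1e-10)
    # within-cell (level, chemical) scatter of theta -> W + sigma2 Q
    within = np.zeros((nb, nb))
    dof = 0
    cell_means = {lv: [] for lv in design.levels_present}
    for chem in design.chemicals:
        th = design.theta[chem]
        lv_arr = np.array(design.curve_levels[chem])
        for lv in design.levels_present:
            cell = th[lv_arr == lv]
            if cell.shape[0] == 0:
                continue
            m = cell.mean(axis=0)
            cell_means[lv].append(m)
            if cell.shape[0] > 1:
                d = cell - m
                within += d.T @ d
                dof += cell.shape[0] - 1
    w0 = within / dof - sigma2_0 * design.q_noise if dof else np.eye(nb) * 0.1
    g0 = {}
    for lv in design.levels_present:
        M = np.array(cell_means[lv])
        if M.shape[0] > 1:
            g0[lv] = np.cov(M.T) if M.shape[1] > 1 else np.atleast_2d(np.var(M))
        else:
            g0[lv] = np.eye(nb)
    params = np.concatenate(
        [_cov_to_chol(g0[lv], nb) for lv in design.levels_present]
        + [_cov_to_chol(w0, nb), [np.log(sigma2_0)]]
    )
    return params


def fit_lmm(
    design: LmmDesign,
    tol: float = 1e-8,
    maxiter: int = 500,
    seed: int = 0,
) -> LmmFit:
    """Maximize the REML criterion over the variance components.

    Covariance blocks use a log-Cholesky parameterization (positive
    semidefiniteness by construction); initialization is deterministic
    (method of moments), so the fit is reproducible.  Raises
    :class:`~cytoflmm.errors.ConvergenceError` carrying the best iterate if
    the optimizer hits the iteration cap without converging.
    """
    if len(design.chemicals) < 2:
        raise DomainError("need at least 2 chemicals to fit the mixed model")
    nb = design.basis.n_basis
    n_levels = len(design.levels_present)
    x0 = _initial_params(design, nb)

    path = []

    def objective(p):
        val, _ = _neg2_reml(p, design, nb, n_levels)
        path.append(val)
        return val

    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-6},
    )
    crit, parts = _neg2_reml(res.x, design, nb, n_levels)
    if parts is None:
        raise ConvergenceError("REML criterion undefined at the optimum", best=res)
    g_blocks, w_cov, sigma2, beta_vec, A = parts
    if not res.success and res.status != 1:  # status 1 = maxiter
        # treat precision-loss stops as converged if the criterion improved
        if not np.isfinite(crit):
            raise ConvergenceError(f"REML optimization failed: {res.message}", best=res)

    beta_cov = np.linalg.inv(A)
    idx = []
    if design.with_groups:
        for g in design.group_labels:
            for lv in design.levels_present:
                for i in range(nb):
                    idx.append((g, lv, i + 1))
    else:
        for lv in design.levels_present:
            for i in range(nb):
                idx.append(("(all)", lv, i + 1))
    beta = pd.DataFrame(
        {"estimate": beta_vec},
        index=pd.MultiIndex.from_tuples(idx, names=["group", "level", "spline"]),
    )

    # BLUPs at the REML estimates
    per = n_levels * nb
    col_of_group = {g: i for i, g in enumerate(design.group_labels)}
    u_hat, w_hat = {}, {}
    for chem in design.chemicals:
        levels = design.curve_levels[chem]
        V, Tmat, G, uniq = _build_v(levels, g_blocks, w_cov, sigma2, design.q_noise)
        Xc = _fixed_design(levels, design.levels_present, nb)
        if design.with_groups:
            sl = slice(col_of_group[design.groups[chem]] * per, (col_of_group[design.groups[chem]] + 1) * per)
            mean_c = Xc @ beta_vec[sl]
        else:
            mean_c = Xc @ beta_vec
        r = design.theta[chem].ravel() - mean_c
        Vi_r = np.linalg.solve(V, r)
        u_vec = G @ Tmat.T @ Vi_r
        u_hat[chem] = {lv: u_vec[j * nb : (j + 1) * nb] for j, lv in enumerate(uniq)}
        n_c = len(levels)
        w_c = np.zeros((n_c, nb))
        for i in range(n_c):
            w_c[i] = w_cov @ Vi_r[i * nb : (i + 1) * nb]
        w_hat[chem] = w_c

    if not (res.success or res.status == 1 or np.isfinite(crit)):
        raise ConvergenceError(f"REML optimization failed: {res.message}", best=res)

    return LmmFit(
        design=design,
        g_blocks=g_blocks,
        w_cov=w_cov,
        sigma2=float(sigma2),
        beta=beta,
        beta_cov=beta_cov,
        u=u_hat,
        w=w_hat,
        reml=-0.5 * crit,
        converged=bool(res.success),
        n_iter=int(res.nit),
        criterion_path=np.array(path),
    )


# ---------------------------------------------------------------------------
# contrasts and prediction
# ---------------------------------------------------------------------------

def group_contrasts(fit: LmmFit, q: float = 0.1) -> pd.DataFrame:
    """Wald contrasts (second group minus first) per (level, spline) with
    Benjamini-Yekutieli FDR control at level ``q``."""
    if not (0 < q < 1):
        raise ConfigError(f"FDR level q must be in (0, 1), got {q}")
    design = fit.design
    if not design.with_groups:
        raise DomainError("contrasts require a fit with group fixed effects")
    if len(design.group_labels) != 2:
        raise DomainError("contrasts are defined for exactly 2 groups")
    g1, g2 = design.group_labels
    nb = design.basis.n_basis
    index = list(fit.beta.index)
    rows = []
    for lv in design.levels_present:
        for i in range(1, nb + 1):
            cvec = np.zeros(len(index))
            cvec[index.index((g2, lv, i))] = 1.0
            cvec[index.index((g1, lv, i))] = -1.0
            est = float(cvec @ fit.beta["estimate"].to_numpy())
            se = float(np.sqrt(cvec @ fit.beta_cov @ cvec))
            t = est / se
            p = 2.0 * stats.t.sf(abs(t), df=fit.df_resid)
            rows.append(
                {
                    "level": lv,
                    "spline": i,
                    "contrast": f"{g2}-{g1}",
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "p": p,
                }
            )
    table = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(table["p"], alpha=q, method="fdr_by")
    table["p_adjusted"] = p_adj
    table["significant"] = reject
    return table


def predict_tcrc(fit: LmmFit, chemical, level: str) -> np.ndarray:
    """Predicted curve mu + Phi (beta_level + u_chemical,level): chemical-level
    prediction excluding replicate effects and noise."""
    design = fit.design
    if chemical not in design.theta:
        raise KeyError(f"unknown chemical {chemical!r}")
    if level not in design.levels_present:
        raise KeyError(f"unknown level {level!r}")
    group = design.groups[chemical] if design.with_groups else "(all)"
    nb = design.basis.n_basis
    beta_lv = np.array(
        [fit.beta.loc[(group, level, i + 1), "estimate"] for i in range(nb)]
    )
    u_lv = fit.u[chemical].get(level, np.zeros(nb))
    return design.mu_hat + design.basis.matrix @ (beta_lv + u_lv)
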