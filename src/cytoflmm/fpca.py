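"""Functional-principal-component fit of the curve mixed model.

Model per curve (chemical c, binned concentration level tau, replicate o):

    Y_tco(t) = mu_tau(t) + B_tc(t) + E_co(t) + eps_tco(t)

where B_tc is a concentration-specific functional random intercept for the
chemical, E_co a smooth error process per curve, and eps white noise.  The
fit is moment-based: level means by pointwise averaging; the B covariance
per level from cross-replicate residual products within (level, chemical)
cells; the smooth-error covariance from the pooled within-curve second
moment minus the B part (off-diagonal, with the diagonal interpolated along
the ridge to exclude the white-noise nugget); the nugget variance from the
leftover diagonal.  Karhunen-Loeve eigenpairs come from the
trapezoid-quadrature eigenproblem, and chemical scores (V1..V9 for three
components per level) are posterior means (BLUPs) under the working Gaussian
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, DomainError, IdentifiabilityError, ShapeError
from .panel import BIN_LEVELS, CurvePanel
from .simulate import trapezoid_weights


@dataclass
class MeanModel:
    """Estimated mean curve per binned level."""

    grid: np.ndarray
    means: dict  # level -> (T,)

    def residuals(self, panel: CurvePanel) -> np.ndarray:
        levels = panel.obs["binned_level"].to_numpy()
        return panel.values - np.array([self.means[l] for l in levels])


@dataclass
class CovModel:
    """Moment-estimated covariance surfaces and the white-noise variance."""

    grid: np.ndarray
    k_b: dict  # level -> (T, T) chemical-effect covariance
    k_e: np.ndarray  # (T, T) smooth-error covariance
    sigma2: float

    def __post_init__(self):
        for level, surf in self.k_b.items():
            if np.max(np.abs(surf - surf.T)) > 1e-10:
                raise ShapeError(f"covariance surface for {level!r} not symmetric")
        if np.max(np.abs(self.k_e - self.k_e.T)) > 1e-10:
            raise ShapeError("smooth-error surface not symmetric")
        if self.sigma2 < 0:
            raise DomainError("sigma2 must be >= 0")


@dataclass
class FPCBlock:
    """Eigenpairs of one covariance block (quadrature-orthonormal rows)."""

    eigenvalues: np.ndarray  # (K,) nonincreasing, > 0
    eigenfunctions: np.ndarray  # (K, T)
    var_explained: np.ndarray  # (K,) proportions of total positive variance

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size

    def covariance(self) -> np.ndarray:
        """Truncated reconstruction sum_k lambda_k phi_k phi_k'."""
        if self.n_components == 0:
            T = self.eigenfunctions.shape[1]
            return np.zeros((T, T))
        return (self.eigenfunctions.T * self.eigenvalues) @ self.eigenfunctions


@dataclass
class FPCModel:
    """Eigen-decomposed blocks: B per level plus the smooth error E."""

    grid: np.ndarray
    b_blocks: dict  # level -> FPCBlock
    e_block: FPCBlock
    sigma2: float


@dataclass
class FPCAResult:
    mean_model: MeanModel
    cov_model: CovModel
    fpc_model: FPCModel
    scores: pd.DataFrame = field(default=None)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def estimate_means(panel: CurvePanel, smoothing: float | None = None) -> MeanModel:
    """Pointwise average curve per binned level (optionally spline-smoothed)."""
    if not panel.is_binned():
        raise CoverageError("panel must be binned before mean estimation")
    means = {}
    levels = panel.obs["binned_level"]
    for level in levels.dropna().unique():
        mask = (levels == level).to_numpy()
        if mask.sum() == 0:
            raise CoverageError(f"no curves at level {level!r}")
        mu = panel.values[mask].mean(axis=0)
        if smoothing is not None:
            from scipy.interpolate import make_smoothing_spline

            mu = make_smoothing_spline(panel.grid, mu, lam=smoothing)(panel.grid)
        means[level] = mu
    return MeanModel(grid=panel.grid.copy(), means=means)


def _ridge_fill_diagonal(surface: np.ndarray) -> np.ndarray:
    """Replace the diagonal by linear extrapolation along the ridge from the
    first two off-diagonals (removes the white-noise nugget)."""
    out = surface.copy()
    T = surface.shape[0]
    d1 = np.diagonal(surface, offset=1)
    d2 = np.diagonal(surface, offset=2)
    for t in range(T):
        v1 = np.mean([d1[i] for i in (t - 1, t) if 0 <= i < d1.size])
        v2 = np.mean([d2[i] for i in (t - 2, t - 1, t) if 0 <= i < d2.size])
        out[t, t] = 2.0 * v1 - v2
    return out


def estimate_covariances(panel: CurvePanel, means: MeanModel) -> CovModel:
    """Separate chemical-effect and smooth-error covariances by moments.

    Requires replicated (level, chemical) cells somewhere in the panel;
    otherwise B and E are not separable and IdentifiabilityError is raised.
    Control curves ("none" level) contribute to the smooth-error and nugget
    estimates only.
    """
    resid = means.residuals(panel)
    obs = panel.obs
    T = panel.grid.size

    k_b = {}
    any_replicated = False
    chem_mask = obs["concentration_index"].notna().to_numpy()
    for level in BIN_LEVELS:
        lv_mask = (obs["binned_level"] == level).to_numpy() & chem_mask
        if lv_mask.sum() == 0:
            continue
        acc = np.zeros((T, T))
        n_pairs = 0
        for chem, g in obs[lv_mask].groupby("chemical_id"):
            R = resid[g.index.to_numpy()]
            m = R.shape[0]
            if m < 2:
                continue
            S = R.sum(axis=0)
            acc += np.outer(S, S) - R.T @ R
            n_pairs += m * (m - 1)
        if n_pairs == 0:
            raise IdentifiabilityError(
                f"no replicated (level, chemical) cells at level {level!r}"
            )
        any_replicated = True
        surf = acc / n_pairs
        k_b[level] = (surf + surf.T) / 2.0
    if not any_replicated:
        raise IdentifiabilityError("no replicated cells anywhere; B and E inseparable")

    # pooled within-curve second moment minus the B part, averaged over curves
    n_curves = panel.n_curves
    M = (resid.T @ resid) / n_curves
    kb_mean = np.zeros((T, T))
    for level, surf in k_b.items():
        n_lv = int(((obs["binned_level"] == level) & chem_mask).sum())
        kb_mean += surf * (n_lv / n_curves)
    k_e_raw = M - kb_mean
    k_e = _ridge_fill_diagonal((k_e_raw + k_e_raw.T) / 2.0)

    sigma2 = float(np.mean(np.diag(k_e_raw) - np.diag(k_e)))
    return CovModel(grid=panel.grid.copy(), k_b=k_b, k_e=k_e, sigma2=max(0.0, sigma2))


def eigendecompose(
    surface: np.ndarray, grid: np.ndarray, n_keep: int | float = 3
) -> FPCBlock:
    """Quadrature-weighted eigendecomposition of a covariance surface.

    Solves the symmetric problem W^{1/2} K W^{1/2} with trapezoid weights W,
    drops non-positive eigenvalues (PSD projection) and returns
    quadrature-orthonormal eigenfunctions with a fixed sign gauge: the
    integral of each eigenfunction is >= 0, falling back to a positive first
    non-negligible grid value when the integral is essentially zero.

    ``n_keep``: an int keeps that many leading components; a float in (0, 1)
    keeps enough components to explain that proportion of variance.
    """
    surface = np.asarray(surface, dtype=float)
    if np.max(np.abs(surface - surface.T)) > 1e-10:
        raise ShapeError("covariance surface must be symmetric")
    w = trapezoid_weights(grid)
    sw = np.sqrt(w)
    A = sw[:, None] * surface * sw[None, :]
    A = (A + A.T) / 2.0
    vals, vecs = np.linalg.eigh(A)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > max(1e-12, 1e-12 * max(vals.max(initial=0.0), 0.0))
    vals, vecs = vals[keep], vecs[:, keep]

    phi = (vecs / sw[:, None]).T  # rows quadrature-orthonormal
    for i in range(phi.shape[0]):
        integral = float(np.sum(w * phi[i]))
        if abs(integral) >= 1e-8:
            sign = np.sign(integral)
        else:
            nz = phi[i][np.abs(phi[i]) > 1e-8 * max(np.abs(phi[i]).max(), 1e-300)]
            sign = np.sign(nz[0]) if nz.size else 1.0
        phi[i] *= sign

    total = vals.sum()
    if isinstance(n_keep, float) and 0 < n_keep < 1:
        if vals.size:
            n = int(np.searchsorted(np.cumsum(vals) / total, n_keep) + 1)
        else:
            n = 0
    else:
        n = min(int(n_keep), vals.size)
    return FPCBlock(
        eigenvalues=vals[:n],
        eigenfunctions=phi[:n] if n else np.zeros((0, grid.size)),
        var_explained=(vals[:n] / total) if total > 0 else np.zeros(n),
    )


def eigendecompose_cov_model(
    cov: CovModel, n_fpc: int = 3, e_threshold: float = 0.95
) -> FPCModel:
    b_blocks = {
        level: eigendecompose(surf, cov.grid, n_keep=n_fpc)
        for level, surf in cov.k_b.items()
    }
    e_block = eigendecompose(cov.k_e, cov.grid, n_keep=e_threshold)
    return FPCModel(grid=cov.grid.copy(), b_blocks=b_blocks, e_block=e_block, sigma2=cov.sigma2)


# ---------------------------------------------------------------------------
# score prediction
# ---------------------------------------------------------------------------

def score_columns(fpc: FPCModel) -> list[tuple[str, str]]:
    """(column name, level) pairs in the canonical V1..V9 order:
    high components first, then medium, then low."""
    cols = []
    v = 0
    for level in BIN_LEVELS:
        block = fpc.b_blocks.get(level)
        if block is None:
            continue
        for _ in range(block.n_components):
            v += 1
            cols.append((f"V{v}", level))
    return cols


def predict_scores(
    panel: CurvePanel, means: MeanModel, fpc: FPCModel, sigma2: float | None = None
) -> pd.DataFrame:
    """BLUP chemical scores under the working Gaussian model.

    Per chemical the residual curves are stacked and the posterior mean of
    each B-block score is returned; the joint covariance uses the truncated
    eigen-expansions for B and E plus the nugget sigma^2.  Chemicals missing
    a level get NaN scores there (flagged, not imputed).
    """
    if sigma2 is None:
        sigma2 = fpc.sigma2
    resid = means.residuals(panel)
    obs = panel.obs
    T = panel.grid.size
    ke = fpc.e_block.covariance() + sigma2 * np.eye(T)
    kb = {level: blk.covariance() for level, blk in fpc.b_blocks.items()}

    cols = score_columns(fpc)
    rows = []
    chem_mask = obs["concentration_index"].notna().to_numpy()
    for chem in panel.chemicals():
        sel = (obs["chemical_id"] == chem).to_numpy() & chem_mask
        idx = np.flatnonzero(sel)
        lv = obs["binned_level"].to_numpy()[idx]
        n_c = idx.size
        Sigma = np.zeros((n_c * T, n_c * T))
        for i in range(n_c):
            for j in range(n_c):
                blk = np.zeros((T, T))
                if lv[i] == lv[j] and lv[i] in kb:
                    blk = blk + kb[lv[i]]
                if i == j:
                    blk = blk + ke
                Sigma[i * T : (i + 1) * T, j * T : (j + 1) * T] = blk
        r = resid[idx].ravel()
        alpha = np.linalg.solve(Sigma, r)

        row = {"chemical_id": chem, "moa_label": obs.loc[idx[0], "moa_label"]}
        for level in BIN_LEVELS:
            blk = fpc.b_blocks.get(level)
            if blk is None:
                continue
            in_level = np.flatnonzero(lv == level)
            for k in range(blk.n_components):
                name = next(
                    c for c, l in cols if l == level and c not in row
                )
                if in_level.size == 0:
                    row[name] = np.nan
                    continue
                cross = np.zeros(n_c * T)
                for i in in_level:
                    cross[i * T : (i + 1) * T] = blk.eigenvalues[k] * blk.eigenfunctions[k]
                row[name] = float(cross @ alpha)
        rows.append(row)
    return pd.DataFrame(rows)


def fit_fpca(
    panel: CurvePanel,
    n_fpc: int = 3,
    e_threshold: float = 0.95,
    mean_smoothing: float | None = None,
) -> FPCAResult:
    """Full moment-based fPCA pipeline: means, covariances, eigenpairs, scores."""
    means = estimate_means(panel, smoothing=mean_smoothing)
    cov = estimate_covariances(panel, means)
    fpc = eigendecompose_cov_model(cov, n_fpc=n_fpc, e_threshold=e_threshold)
    scores = predict_scores(panel, means, fpc)
    return FPCAResult(mean_model=means, cov_model=cov, fpc_model=fpc, scores=scores)
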