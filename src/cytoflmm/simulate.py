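"""Synthetic TCRC panels with known ground truth.

The study data this package is designed around (63 chemicals x 11
concentrations + 12 controls, hourly normalized cell index over 72 h) are
access-restricted, so this module generates panels with the exact statistical
structure the models assume:

    Y_tco(t) = mu_tau(t) + sum_k (delta_gk + b_tck) phi_Btk(t)
               + sum_k e_cok phi_Ek(t) + eps_tco(t)

with concentration-level mean functions mu_tau shaped like the four cell
growth phases (lag, log, plateau, decline), concentration-specific low-rank
chemical random effects b with quadrature-orthonormal eigenfunctions, a
smooth error process per curve, and iid white noise.  Mode-of-action groups
differ only through fixed score offsets delta, so group structure lives in
score space, matching what the downstream models estimate.

A second, "unbinned" generator gives every concentration index its own mean
and plants distinct chemical partitions per concentration regime; it exists
so the data-driven binning stage has structure to discover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError, ShapeError
from .panel import BIN_LEVELS, CurvePanel

DEFAULT_GRID = np.arange(1.0, 73.0)

DEFAULT_BIN_MAP = {
    **{j: "high" for j in (1, 2, 3, 4)},
    **{j: "medium" for j in (5, 6, 7, 8)},
    **{j: "low" for j in (9, 10, 11)},
}


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Trapezoid quadrature weights for a (possibly non-uniform) grid."""
    grid = np.asarray(grid, dtype=float)
    w = np.zeros_like(grid)
    w[:-1] += np.diff(grid) / 2
    w[1:] += np.diff(grid) / 2
    return w


def orthonormalize(shapes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Gram-Schmidt orthonormalization of rows under a quadrature inner product."""
    out = []
    for f in np.asarray(shapes, dtype=float):
        v = f.copy()
        for g in out:
            v -= np.sum(weights * v * g) * g
        nrm = np.sqrt(np.sum(weights * v * v))
        if nrm < 1e-10:
            raise DomainError("shape set is numerically linearly dependent")
        out.append(v / nrm)
    return np.array(out)


@dataclass
class SimulationDesign:
    """Panel layout: group sizes, concentrations, controls, bin map.

    Defaults reproduce the study layout: 20 chemicals in MOA group 1, 13 in
    MOA group 10, 30 in a remainder group, 11 concentrations each (1:3 serial
    dilution, index 1 strongest), 12 control curves, and concentration
    indices {1-4}->high, {5-8}->medium, {9-11}->low.
    """

    n_group1: int = 20
    n_group10: int = 13
    n_other: int = 30
    n_concentrations: int = 11
    n_controls: int = 12
    bin_map: dict = field(default_factory=lambda: dict(DEFAULT_BIN_MAP))
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        counts = (self.n_group1, self.n_group10, self.n_other, self.n_controls)
        if min(self.n_group1 + self.n_group10 + self.n_other, self.n_controls) <= 0 or any(
            c < 0 for c in counts
        ):
            raise ConfigError("chemical and control counts must be positive")
        if sorted(self.bin_map) != list(range(1, self.n_concentrations + 1)):
            raise ConfigError("bin map must partition concentration indices 1..n")

    @property
    def n_chemicals(self) -> int:
        return self.n_group1 + self.n_group10 + self.n_other

    def chemical_labels(self) -> tuple[list[str], list[str]]:
        ids = [f"chem{i + 1:03d}" for i in range(self.n_chemicals)]
        moa = (
            ["MOA1"] * self.n_group1
            + ["MOA10"] * self.n_group10
            + ["other"] * self.n_other
        )
        return ids, moa

    def replicate_index(self, conc: int) -> int:
        """Position (1-based) of a concentration index within its bin."""
        level = self.bin_map[conc]
        members = sorted(j for j, v in self.bin_map.items() if v == level)
        return members.index(conc) + 1


def _mean_functions(grid: np.ndarray) -> dict[str, np.ndarray]:
    """Growth-phase-like mean curves per binned level, anchored at 1 at t[0]."""
    u = grid - grid[0]
    s = u / u[-1]
    return {
        "high": np.exp(-u / 10.0),
        "medium": (1.0 + 1.6 * (1.0 - np.exp(-u / 10.0))) * np.exp(-2.2 * s**2),
        "low": 1.0 + 2.0 * (1.0 - np.exp(-u / 14.0)) - 0.9 * s**2,
        "none": 1.0 + 2.4 * (1.0 - np.exp(-u / 12.0)) - 0.5 * s**3,
    }


#: per-level scaling of the chemical-effect eigenvalues; stronger doses induce
#: more between-chemical variability
TAU_SCALE = {"high": 1.0, "medium": 0.8, "low": 0.5}

_MAX_B_SHAPES = 6

_GROUP_DIRECTIONS = {"MOA1": (0.5, 0.5), "MOA10": (-0.5, -0.5), "other": (-0.5, 0.5)}


@dataclass
class TruthModel:
    """Generative parameters: means, eigenpairs, noise, group score offsets."""

    grid: np.ndarray
    means: dict  # level -> (T,)
    b_eigenfunctions: dict  # level -> (K, T), quadrature-orthonormal rows
    b_eigenvalues: dict  # level -> (K,), nonincreasing
    e_eigenfunctions: np.ndarray  # (Ke, T)
    e_eigenvalues: np.ndarray  # (Ke,)
    sigma2: float
    group_offsets: dict  # (group, level) -> (K,)
    margin: float

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        w = trapezoid_weights(self.grid)
        for level, phi in self.b_eigenfunctions.items():
            gram = (phi * w) @ phi.T
            if np.max(np.abs(gram - np.eye(len(phi)))) > 1e-8:
                raise DomainError(f"eigenfunctions for {level!r} not orthonormal")
            lam = self.b_eigenvalues[level]
            if np.any(np.diff(lam) > 0) or np.any(lam < 0):
                raise DomainError("eigenvalues must be nonincreasing and >= 0")
        if self.sigma2 < 0:
            raise DomainError("sigma2 must be >= 0")
        for level in BIN_LEVELS + ("none",):
            if abs(self.means[level][0] - 1.0) > 1e-12:
                raise DomainError("mean functions must equal 1 at the first grid point")

    def covariance(self, level: str) -> np.ndarray:
        """True chemical-effect covariance surface sum_k lambda_k phi_k phi_k'."""
        phi = self.b_eigenfunctions[level]
        return (phi.T * self.b_eigenvalues[level]) @ phi


def make_truth(
    design: SimulationDesign,
    n_fpc: int = 3,
    seed: int = 0,
    margin: float = 3.0,
    sigma2: float = 0.01,
    b_eigenvalues: tuple = (4.0, 1.0, 0.25),
    e_eigenvalues: tuple = (0.5, 0.1),
) -> TruthModel:
    """Build a ground-truth generative model for :func:`simulate_panel`.

    ``margin`` is the pairwise distance between group score means in the
    first two score dimensions per level (0 makes groups indistinguishable).
    Eigenfunctions are smooth sinusoidal shapes orthonormalized under
    trapezoid quadrature, with a level-specific phase so the three
    concentration levels have genuinely different eigenbases.
    """
    if n_fpc < 1:
        raise ConfigError("n_fpc must be >= 1")
    if n_fpc > _MAX_B_SHAPES:
        raise ConfigError(f"at most {_MAX_B_SHAPES} eigenfunction shapes available")
    grid = design.grid
    w = trapezoid_weights(grid)
    s = (grid - grid[0]) / (grid[-1] - grid[0])

    lam = list(b_eigenvalues)
    while len(lam) < n_fpc:  # extend geometrically if more components asked for
        lam.append(lam[-1] / 4.0)
    lam = np.asarray(lam[:n_fpc], dtype=float)

    b_fun, b_val, offsets = {}, {}, {}
    for idx, level in enumerate(BIN_LEVELS):
        phase = 0.35 * idx
        shapes = np.array(
            [np.sin((j + 1) * np.pi * s + (j + 1) * phase) for j in range(n_fpc)]
        )
        b_fun[level] = orthonormalize(shapes, w)
        b_val[level] = np.sort(lam * TAU_SCALE[level])[::-1]
        for group, direction in _GROUP_DIRECTIONS.items():
            d = np.zeros(n_fpc)
            d[: min(2, n_fpc)] = np.array(direction[: min(2, n_fpc)]) * margin
            offsets[(group, level)] = d

    e_shapes = np.array(
        [np.cos((j + 1) * np.pi * s) for j in range(len(e_eigenvalues))]
    )
    e_fun = orthonormalize(e_shapes, w)

    return TruthModel(
        grid=grid,
        means=_mean_functions(grid),
        b_eigenfunctions=b_fun,
        b_eigenvalues=b_val,
        e_eigenfunctions=e_fun,
        e_eigenvalues=np.asarray(e_eigenvalues, dtype=float),
        sigma2=float(sigma2),
        group_offsets=offsets,
        margin=float(margin),
    )


def simulate_panel(truth: TruthModel, design: SimulationDesign, seed: int = 0) -> CurvePanel:
    """Draw a panel from the generative model.

    Returns a binned panel whose ``attrs`` carry the planted chemical scores
    (``true_scores``: one row per chemical x level x component, score =
    group offset + random effect) for parameter-recovery tests.
    """
    rng = np.random.default_rng(seed)
    grid = truth.grid
    T = grid.size
    ids, moa = design.chemical_labels()
    n_chem = design.n_chemicals
    levels = list(BIN_LEVELS)

    # chemical random-effect scores, one draw per (chemical, level)
    b_scores = {}
    for level in levels:
        lam = truth.b_eigenvalues[level]
        delta = np.array([truth.group_offsets[(g, level)] for g in moa])
        b_scores[level] = delta + rng.standard_normal((n_chem, lam.size)) * np.sqrt(lam)

    rows, values = [], []
    for conc in range(1, design.n_concentrations + 1):
        level = design.bin_map[conc]
        phi_b = truth.b_eigenfunctions[level]
        e = rng.standard_normal((n_chem, truth.e_eigenvalues.size)) * np.sqrt(
            truth.e_eigenvalues
        )
        eps = rng.standard_normal((n_chem, T)) * np.sqrt(truth.sigma2)
        curves = (
            truth.means[level]
            + b_scores[level] @ phi_b
            + e @ truth.e_eigenfunctions
            + eps
        )
        values.append(curves)
        rep = design.replicate_index(conc)
        rows.extend(
            {
                "chemical_id": ids[c],
                "moa_label": moa[c],
                "concentration_index": conc,
                "binned_level": level,
                "replicate_index": rep,
            }
            for c in range(n_chem)
        )

    # control curves: mean for "none" plus smooth error and noise, no chemical effect
    e = rng.standard_normal((design.n_controls, truth.e_eigenvalues.size)) * np.sqrt(
        truth.e_eigenvalues
    )
    eps = rng.standard_normal((design.n_controls, T)) * np.sqrt(truth.sigma2)
    values.append(truth.means["none"] + e @ truth.e_eigenfunctions + eps)
    rows.extend(
        {
            "chemical_id": "control",
            "moa_label": None,
            "concentration_index": None,
            "binned_level": "none",
            "replicate_index": o + 1,
        }
        for o in range(design.n_controls)
    )

    obs = pd.DataFrame(rows)
    values = np.vstack(values)
    # sort by (chemical, concentration, replicate); controls land last
    conc_sort = obs["concentration_index"].map(lambda c: 99 if pd.isna(c) else int(c))
    order = np.lexsort(
        (obs["replicate_index"].to_numpy(), conc_sort.to_numpy(), obs["chemical_id"].to_numpy())
    )
    panel = CurvePanel(grid=grid.copy(), values=values[order], obs=obs.iloc[order])

    score_rows = [
        {
            "chemical_id": ids[c],
            "moa_label": moa[c],
            "level": level,
            "component": k + 1,
            "score": b_scores[level][c, k],
        }
        for level in levels
        for c in range(n_chem)
        for k in range(b_scores[level].shape[1])
    ]
    panel.attrs["true_scores"] = pd.DataFrame(score_rows)
    panel.attrs["true_bin_map"] = dict(design.bin_map)
    return panel


def simulate_unbinned_panel(
    design: SimulationDesign,
    seed: int = 0,
    delta: float = 2.0,
    smooth_sd: float = 0.05,
    sigma2: float = 0.0025,
) -> CurvePanel:
    """Panel where each concentration index has its own mean (binning target).

    Concentration indices inside one planted bin share a mean regime and,
    crucially, the *same* planted binary partition of the chemicals, while
    different bins use different partitions (the high bin splits by MOA
    group, the other two by seeded balanced splits).  Per-concentration
    k-means therefore yields labelings that agree within a bin and are
    unrelated across bins, which is exactly the structure the ARI-based
    binning procedure detects.  ``delta`` is the between-subgroup curve
    offset; noise terms are kept small relative to it.
    """
    rng = np.random.default_rng(seed)
    grid = design.grid
    T = grid.size
    w = trapezoid_weights(grid)
    s = (grid - grid[0]) / (grid[-1] - grid[0])
    ids, moa = design.chemical_labels()
    n_chem = design.n_chemicals
    means = _mean_functions(grid)

    levels = list(BIN_LEVELS)
    shapes = orthonormalize(
        np.array([np.sin(np.pi * s), np.sin(2 * np.pi * s), np.sin(3 * np.pi * s)]), w
    )
    offset_shape = {level: shapes[i] for i, level in enumerate(levels)}

    sides = {"high": np.where(np.array(moa) == "MOA1", 1.0, -1.0)}
    for level in ("medium", "low"):
        half = rng.permutation(n_chem) < n_chem // 2
        sides[level] = np.where(half, 1.0, -1.0)

    n_conc = design.n_concentrations
    rows, values = [], []
    for conc in range(1, n_conc + 1):
        level = design.bin_map[conc]
        alpha = (conc - 1) / max(n_conc - 1, 1)  # dose ramp: strongest -> weakest
        base = (1 - alpha) * means["high"] + alpha * means["none"]
        offs = sides[level][:, None] * (delta / 2.0) * offset_shape[level]
        smooth = (
            rng.standard_normal((n_chem, 1)) * smooth_sd * np.sin(np.pi * s)
            + rng.standard_normal((n_chem, 1)) * smooth_sd * np.cos(np.pi * s)
        )
        eps = rng.standard_normal((n_chem, T)) * np.sqrt(sigma2)
        values.append(base + offs + smooth + eps)
        rows.extend(
            {
                "chemical_id": ids[c],
                "moa_label": moa[c],
                "concentration_index": conc,
                "binned_level": None,
                "replicate_index": design.replicate_index(conc),
            }
            for c in range(n_chem)
        )

    obs = pd.DataFrame(rows)
    values = np.vstack(values)
    order = np.lexsort(
        (obs["concentration_index"].to_numpy(), obs["chemical_id"].to_numpy())
    )
    panel = CurvePanel(grid=grid.copy(), values=values[order], obs=obs.iloc[order])
    panel.attrs["planted_bins"] = dict(design.bin_map)
    panel.attrs["planted_partitions"] = {k: v.copy() for k, v in sides.items()}
    return panel


def simulate_spline_panel(
    basis_matrix: np.ndarray,
    grid: np.ndarray,
    beta: dict,
    group_sizes: dict,
    g_blocks: list,
    w_cov: np.ndarray,
    sigma2: float,
    mu: np.ndarray | None = None,
    rep_counts: tuple = (4, 4, 3),
    seed: int = 0,
) -> CurvePanel:
    """Simulate directly from the B-spline mixed model (for model validation).

    ``beta`` maps group label -> (3, n_basis) fixed effects by level
    (high/medium/low order); ``g_blocks`` is a list of three per-level
    chemical covariance matrices; ``w_cov`` the replicate-effect covariance;
    curves are mu + Phi(beta + u + w) + white noise.
    """
    Phi = np.asarray(basis_matrix, dtype=float)
    T, nb = Phi.shape
    if mu is None:
        mu = np.zeros(T)
    rng = np.random.default_rng(seed)
    levels = list(BIN_LEVELS)
    if len(rep_counts) != 3:
        raise ShapeError("rep_counts must have one entry per binned level")
    # concentration indices per level consistent with the default bin map
    conc_of = {"high": [1, 2, 3, 4], "medium": [5, 6, 7, 8], "low": [9, 10, 11]}

    g_chol = [np.linalg.cholesky(np.asarray(g) + 1e-12 * np.eye(nb)) for g in g_blocks]
    w_chol = np.linalg.cholesky(np.asarray(w_cov) + 1e-12 * np.eye(nb))

    rows, values = [], []
    cid = 0
    for group, n_g in group_sizes.items():
        for _ in range(n_g):
            cid += 1
            name = f"chem{cid:03d}"
            for li, level in enumerate(levels):
                u = g_chol[li] @ rng.standard_normal(nb)
                theta_fixed = np.asarray(beta[group])[li]
                for o in range(rep_counts[li]):
                    wvec = w_chol @ rng.standard_normal(nb)
                    eps = rng.standard_normal(T) * np.sqrt(sigma2)
                    values.append(mu + Phi @ (theta_fixed + u + wvec) + eps)
                    rows.append(
                        {
                            "chemical_id": name,
                            "moa_label": group,
                            "concentration_index": conc_of[level][o],
                            "binned_level": level,
                            "replicate_index": o + 1,
                        }
                    )
    return CurvePanel(grid=np.asarray(grid, float), values=np.array(values), obs=pd.DataFrame(rows))
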