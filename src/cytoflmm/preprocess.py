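"""Raw impedance series -> analysis-ready normalized cell index curves.

The xCELLigence-style readout is an impedance ratio summarized as the Cell
Index CI = max_i (R_cell(f_i)/R_b(f_i) - 1) over measured frequencies.  After
chemical treatment the series is normalized by the pre-treatment value
(NCI[k] = CI[k]/CI[0], so every curve implicitly starts at one) and placed on
a common hourly grid with a cubic smoothing spline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .errors import DomainError, ExtrapolationError, IntegrityError, ShapeError


@dataclass
class RawSeries:
    """An irregularly sampled single-curve series on the CI or NCI scale."""

    times: np.ndarray
    values: np.ndarray
    chemical_id: str = ""
    moa_label: str | None = None
    concentration_index: int | None = None
    replicate_index: int = 1

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ShapeError("times and values must be equal-length 1-d arrays")
        if self.times.size < 4:
            raise ShapeError("need at least 4 points for cubic-spline handling")
        if np.any(np.diff(self.times) <= 0):
            raise IntegrityError("times must be strictly increasing")


def cell_index_from_impedance(r_cell, r_b) -> float:
    """CI from per-frequency impedance with (r_cell) and without (r_b) cells.

    Returns ``max_i(r_cell_i / r_b_i - 1)``.
    """
    r_cell = np.atleast_1d(np.asarray(r_cell, dtype=float))
    r_b = np.atleast_1d(np.asarray(r_b, dtype=float))
    if r_cell.shape != r_b.shape:
        raise ShapeError(f"length mismatch: {r_cell.shape} vs {r_b.shape}")
    if r_cell.size < 1:
        raise ShapeError("need at least one frequency")
    if np.any(r_b <= 0):
        raise DomainError("background impedance must be strictly positive")
    return float(np.max(r_cell / r_b - 1.0))


def normalize_nci(series: RawSeries, t0_value: float) -> RawSeries:
    """Divide a post-treatment CI series by the CI at treatment time.

    ``t0_value`` is CI[0], the value right before treatment; the returned
    series is NCI[k] = CI[k]/CI[0] at the original (post-treatment) times, so
    the implied anchor NCI[0] = 1 is not stored.
    """
    if not t0_value > 0:
        raise DomainError(f"CI at treatment time must be positive, got {t0_value}")
    return replace(series, values=series.values / float(t0_value))


def to_uniform_grid(series: RawSeries, grid, penalty: float | None = None) -> np.ndarray:
    """Evaluate a cubic smoothing spline of the series on a target grid.

    ``penalty`` is the roughness-penalty weight; 0 interpolates the
    observations exactly, ``None`` (default) selects the penalty by
    generalized cross-validation.  Extrapolation is never performed: a grid
    extending beyond the observed time range raises
    :class:`~cytoflmm.errors.ExtrapolationError`.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = series.times[0], series.times[-1]
    if grid.min() < lo - 1e-12 or grid.max() > hi + 1e-12:
        raise ExtrapolationError(
            f"grid [{grid.min()}, {grid.max()}] outside observed range [{lo}, {hi}]"
        )
    lam = None if penalty is None else float(penalty)
    spline = make_smoothing_spline(series.times, series.values, lam=lam)
    return np.asarray(spline(grid), dtype=float)
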