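"""Curve panels: the interchange object for time-dependent cellular response curves.

A :class:`CurvePanel` holds a set of curves sampled on one common, strictly
increasing hourly grid together with per-curve annotations (chemical, mode of
action, concentration index 1-11 with 1 the strongest dose, binned
concentration level, replicate index).  Panels move between every stage of the
pipeline; CSV in long format is the only on-disk representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError, ShapeError

#: canonical order of binned concentration levels, strongest dose first
BIN_LEVELS = ("high", "medium", "low")

#: annotation columns every panel carries
OBS_COLUMNS = (
    "chemical_id",
    "moa_label",
    "concentration_index",
    "binned_level",
    "replicate_index",
)

_LONG_REQUIRED = ("chemical_id", "concentration", "replicate", "time_h", "value")


@dataclass
class CurvePanel:
    """Curves on a common grid plus per-curve annotations.

    Parameters
    ----------
    grid
        Time points in hours, strictly increasing, shape ``(T,)``.
    values
        Curve values, shape ``(n_curves, T)``.
    obs
        One row per curve with the columns in :data:`OBS_COLUMNS`.
        ``concentration_index`` is an integer 1-11 or ``None`` for control
        curves; ``binned_level`` is one of ``high/medium/low/none`` or ``None``
        before binning; ``moa_label`` may be ``None``.
    attrs
        Free-form metadata (e.g. simulation ground truth).
    """

    grid: np.ndarray
    values: np.ndarray
    obs: pd.DataFrame
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.obs = self.obs.reset_index(drop=True)
        for col in OBS_COLUMNS:
            if col not in self.obs.columns:
                self.obs[col] = None
        self.validate()

    # -- basic properties -------------------------------------------------
    @property
    def n_curves(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.grid.size

    def validate(self, nci_anchored: bool = False) -> None:
        """Check panel invariants; raise ShapeError/IntegrityError on violation.

        With ``nci_anchored=True`` additionally require every curve to equal
        one at the first grid point (a property of noiseless normalized-cell-
        index data; simulated and measured curves carry noise there, so the
        check is opt-in).
        """
        if self.grid.ndim != 1 or self.values.ndim != 2:
            raise ShapeError("grid must be 1-d and values 2-d")
        if self.values.shape != (len(self.obs), self.grid.size):
            raise ShapeError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.obs)} curves x {self.grid.size} time points"
            )
        if self.grid.size and np.any(np.diff(self.grid) <= 0):
            raise IntegrityError("grid must be strictly increasing")
        conc = self.obs["concentration_index"]
        bad = conc.dropna().map(lambda c: not (1 <= int(c) <= 11))
        if bad.any():
            raise IntegrityError("concentration_index must be in 1..11 or none")
        if nci_anchored and self.n_curves:
            if np.max(np.abs(self.values[:, 0] - 1.0)) > 1e-12:
                raise IntegrityError("NCI-anchored panel must start at 1")

    def is_binned(self) -> bool:
        """True when every non-control curve has a binned level assigned."""
        chem = self.obs["concentration_index"].notna()
        return bool(self.obs.loc[chem, "binned_level"].notna().all())

    # -- selection --------------------------------------------------------
    def subset(self, mask) -> "CurvePanel":
        mask = np.asarray(mask)
        if mask.dtype == bool and mask.size != self.n_curves:
            raise ShapeError("boolean mask length must equal n_curves")
        return CurvePanel(
            grid=self.grid.copy(),
            values=self.values[mask].copy(),
            obs=self.obs.loc[np.arange(self.n_curves)[mask] if mask.dtype == bool else mask]
            .reset_index(drop=True)
            .copy(),
            attrs=dict(self.attrs),
        )

    def chemicals(self) -> list:
        """Distinct non-control chemical ids, in order of first appearance."""
        chem = self.obs.loc[self.obs["concentration_index"].notna(), "chemical_id"]
        return list(dict.fromkeys(chem))

    def with_bins(self, bin_map: Mapping[int, str]) -> "CurvePanel":
        """Return a copy with binned_level filled from a {conc_index: level} map."""
        out = self.subset(np.arange(self.n_curves))
        lev = [
            bin_map[int(c)] if pd.notna(c) else "none"
            for c in out.obs["concentration_index"]
        ]
        out.obs["binned_level"] = lev
        return out

    # -- long-format conversion -------------------------------------------
    def to_long(self) -> pd.DataFrame:
        n, t = self.values.shape
        rep = np.repeat(np.arange(n), t)
        df = pd.DataFrame(
            {
                "chemical_id": self.obs["chemical_id"].to_numpy()[rep],
                "moa": self.obs["moa_label"].to_numpy()[rep],
                "concentration": [
                    "none" if pd.isna(c) else int(c)
                    for c in self.obs["concentration_index"].to_numpy()[rep]
                ],
                "binned_level": self.obs["binned_level"].to_numpy()[rep],
                "replicate": self.obs["replicate_index"].to_numpy()[rep],
                "time_h": np.tile(self.grid, n),
                "value": self.values.ravel(),
            }
        )
        return df


def _parse_concentration(c):
    if isinstance(c, str) and c.strip().lower() == "none":
        return None
    if pd.isna(c):
        return None
    return int(c)


def read_curve_panel(path, schema: Mapping[str, str] | None = None) -> CurvePanel:
    """Read a long-format curve table into a :class:`CurvePanel`.

    Required columns (after applying ``schema``, a {canonical: file} column
    mapping): chemical_id, concentration, replicate, time_h, value.  Optional:
    moa, binned_level.  Curves are sorted by (chemical, concentration,
    replicate, time).  Curves missing time points present in other curves are
    flagged in ``attrs['needs_interpolation']`` and padded with NaN rather
    than silently filled.
    """
    df = pd.read_csv(path)
    schema = dict(schema or {})
    rename = {v: k for k, v in schema.items() if v in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in _LONG_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    key = ["chemical_id", "concentration", "replicate", "time_h"]
    if df.duplicated(subset=key).any():
        dup = df[df.duplicated(subset=key, keep=False)].iloc[0]
        raise IntegrityError(
            "duplicate (chemical, concentration, replicate, time) row, e.g. "
            f"{tuple(dup[k] for k in key)}"
        )
    df = df.copy()
    df["_conc"] = df["concentration"].map(_parse_concentration)
    df["_conc_sort"] = df["_conc"].map(lambda c: 99 if c is None else c)
    df = df.sort_values(["chemical_id", "_conc_sort", "replicate", "time_h"])

    grid = np.array(sorted(df["time_h"].unique()), dtype=float)
    curves, rows, incomplete = [], [], []
    for (chem, conc, conc_s, rep), g in df.groupby(
        ["chemical_id", "_conc", "_conc_sort", "replicate"], sort=True, dropna=False
    ):
        vals = np.full(grid.size, np.nan)
        idx = np.searchsorted(grid, g["time_h"].to_numpy())
        vals[idx] = g["value"].to_numpy()
        if np.isnan(vals).any():
            incomplete.append((chem, conc, rep))
        curves.append(vals)
        moa = g["moa"].iloc[0] if "moa" in g.columns else None
        lev = g["binned_level"].iloc[0] if "binned_level" in g.columns else None
        rows.append(
            {
                "chemical_id": chem,
                "moa_label": None if pd.isna(moa) else moa,
                "concentration_index": None if conc is None or pd.isna(conc) else int(conc),
                "binned_level": None if lev is None or pd.isna(lev) else lev,
                "replicate_index": rep,
            }
        )
    panel = CurvePanel(grid=grid, values=np.array(curves), obs=pd.DataFrame(rows))
    if incomplete:
        panel.attrs["needs_interpolation"] = incomplete
    return panel


def write_curve_panel(panel: CurvePanel, path) -> None:
    """Write a panel as long-format CSV (full float precision)."""
    panel.to_long().to_csv(path, index=False)


def write_table(rows: pd.DataFrame, path) -> None:
    """Write any result table as CSV with a header, floats at full precision."""
    pd.DataFrame(rows).to_csv(path, index=False)
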