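"""Data-driven binning of the 11 concentration levels into three.

The serial-dilution design gives 11 concentration indices per chemical, many
of which produce nearly interchangeable curves.  To gain replication for the
mixed models, indices are grouped: curves at each index are summarized by
level-4 discrete-wavelet-transform scaling coefficients, chemicals are split
in two by k-means independently per index, the 11 resulting labelings are
compared pairwise with the Adjusted Rand Index, and complete-linkage
hierarchical clustering of 1 - ARI cuts the indices into three bins named
high/medium/low by mean index (index 1 is the strongest dose).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .cluster import adjusted_rand_index
from .config import stage_seed
from .errors import ConfigError, DomainError, ShapeError
from .panel import BIN_LEVELS, CurvePanel


def dwt_scaling_coeffs(curve, level: int, wavelet: str = "db4", mode: str = "periodization") -> np.ndarray:
    """Approximation (scaling) coefficients after ``level`` cascaded DWTs.

    ``mode`` is the signal-extension mode; periodization keeps the
    coefficient count at ceil(n / 2**level) for non-power-of-two lengths.
    """
    if level < 1:
        raise ConfigError(f"decomposition level must be >= 1, got {level}")
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 1:
        raise ShapeError("curve must be 1-d")
    try:
        wav = pywt.Wavelet(wavelet)
    except ValueError as exc:
        raise ConfigError(f"unknown wavelet {wavelet!r}") from exc
    with warnings.catch_warnings():
        # deep decompositions of short curves are intentional here
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(curve, wav, mode=mode, level=level)
    return coeffs[0]


def chemical_wavelet_features(
    panel: CurvePanel, level: int, wavelet: str = "db4", mode: str = "periodization"
) -> pd.DataFrame:
    """One feature row per chemical: DWT scaling coefficients of its curves
    concatenated in concentration order 1 -> 11.

    Control curves are excluded.  Raises ShapeError on ragged panels
    (chemicals with unequal curve counts).
    """
    mask = panel.obs["concentration_index"].notna().to_numpy()
    obs = panel.obs[mask]
    values = panel.values[mask]
    feats, index = [], []
    n_curves = None
    for chem in dict.fromkeys(obs["chemical_id"]):
        sel = obs["chemical_id"] == chem
        sub = obs[sel].copy()
        sub["_v"] = list(values[sel.to_numpy()])
        sub = sub.sort_values(["concentration_index", "replicate_index"])
        if n_curves is None:
            n_curves = len(sub)
        elif len(sub) != n_curves:
            raise ShapeError(
                f"ragged panel: chemical {chem!r} has {len(sub)} curves, expected {n_curves}"
            )
        long_vec = np.concatenate(list(sub["_v"]))
        feats.append(dwt_scaling_coeffs(long_vec, level, wavelet, mode))
        index.append(chem)
    return pd.DataFrame(np.array(feats), index=pd.Index(index, name="chemical_id"))


@dataclass
class BinningResult:
    """Output of :func:`bin_concentrations`."""

    labelings: dict  # conc index -> np.ndarray of binary labels per chemical
    ari_matrix: pd.DataFrame  # 11x11, symmetric, unit diagonal
    merge_history: np.ndarray  # scipy linkage matrix on 1 - ARI
    bin_map: dict  # conc index -> level name
    ari_vs_truth: pd.DataFrame | None  # per-index ARI against MOA labels
    fallback_contiguous: bool = False

    def apply(self, panel: CurvePanel) -> CurvePanel:
        """Return a copy of ``panel`` with binned_level set from the bin map."""
        return panel.with_bins(self.bin_map)


def _contiguous_split(indices: list[int], k: int) -> dict[int, int]:
    parts = np.array_split(np.array(sorted(indices)), k)
    return {int(j): i for i, part in enumerate(parts) for j in part}


def bin_concentrations(
    panel: CurvePanel,
    k_bins: int = 3,
    level: int = 4,
    wavelet: str = "db4",
    seed: int = 0,
    n_start: int = 100,
    mode: str = "periodization",
) -> BinningResult:
    """Group concentration indices into ``k_bins`` levels (see module docs).

    Per index, chemicals are clustered with k = 2 Euclidean k-means on the
    scaling coefficients (``n_start`` restarts, best within-cluster sum of
    squares); indices whose labelings are similar (high pairwise ARI) merge
    under complete linkage.  If the ARI matrix is degenerate (fewer than
    ``k_bins`` distinct clusters at the cut), a contiguous index split is
    used as a fallback.  Deterministic given ``seed``.
    """
    obs = panel.obs
    conc_indices = sorted(int(c) for c in obs["concentration_index"].dropna().unique())
    if len(conc_indices) < k_bins:
        raise DomainError("fewer concentration indices than requested bins")

    labelings = {}
    chems = panel.chemicals()
    if len(chems) < 2:
        raise DomainError("need at least 2 chemicals to cluster per concentration")
    for j in conc_indices:
        sel = (obs["concentration_index"] == j).to_numpy()
        sub_obs = obs[sel]
        rows = []
        for chem in chems:
            m = (sub_obs["chemical_id"] == chem).to_numpy()
            if m.sum() == 0:
                raise DomainError(f"chemical {chem!r} has no curve at concentration {j}")
            rows.append(panel.values[sel][m].mean(axis=0))
        feats = np.array([dwt_scaling_coeffs(r, level, wavelet, mode) for r in rows])
        if len(feats) < 2:
            raise DomainError(f"concentration {j} has fewer curves than clusters")
        km = KMeans(
            n_clusters=2,
            n_init=n_start,
            init="random",
            algorithm="lloyd",
            random_state=stage_seed(seed, f"bin-conc-{j}"),
        ).fit(feats)
        labelings[j] = km.labels_

    n = len(conc_indices)
    ari = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            ari[a, b] = ari[b, a] = adjusted_rand_index(
                labelings[conc_indices[a]], labelings[conc_indices[b]]
            )
    ari_df = pd.DataFrame(ari, index=conc_indices, columns=conc_indices)

    dist = np.clip(1.0 - ari, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="complete")
    flat = fcluster(Z, t=k_bins, criterion="maxclust")

    fallback = False
    if len(set(flat)) < k_bins:
        assignment = _contiguous_split(conc_indices, k_bins)
        fallback = True
    else:
        assignment = {j: int(flat[i]) for i, j in enumerate(conc_indices)}

    # order clusters by mean concentration index; lowest mean = strongest dose
    clusters = sorted(
        set(assignment.values()),
        key=lambda c: np.mean([j for j, a in assignment.items() if a == c]),
    )
    if k_bins == 3:
        names = list(BIN_LEVELS)
    else:
        names = [f"bin{i + 1}" for i in range(k_bins)]
    bin_map = {j: names[clusters.index(a)] for j, a in assignment.items()}

    ari_truth = None
    moa = obs.drop_duplicates("chemical_id").set_index("chemical_id")["moa_label"]
    moa = moa.reindex(chems)
    if moa.notna().all() and moa.nunique() > 1:
        truth_codes = pd.factorize(moa)[0]
        ari_truth = pd.DataFrame(
            {
                "concentration_index": conc_indices,
                "ari_vs_moa": [
                    adjusted_rand_index(labelings[j], truth_codes) for j in conc_indices
                ],
            }
        )

    return BinningResult(
        labelings=labelings,
        ari_matrix=ari_df,
        merge_history=Z,
        bin_map=bin_map,
        ari_vs_truth=ari_truth,
        fallback_contiguous=fallback,
    )
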