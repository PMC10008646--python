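"""Clustering of projected curve features and cluster-quality evaluation.

Features may be wavelet coefficient vectors, functional-PC scores (V1-V9) or
B-spline chemical random effects; the clustering machinery does not care.
Two algorithms are provided: restarted Lloyd k-means and an online Kohonen
self-organizing map (SOM) supporting bubble/gaussian neighbourhoods,
rectangular/hexagonal topologies and planar/toroidal structures.  Evaluation
uses the pair-counting Adjusted Rand Index, permutation-matched accuracy with
confusion matrices, and the between-to-total sum-of-squares ratio (BSS/TSS).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .errors import ConfigError, DomainError, ShapeError


# ---------------------------------------------------------------------------
# Adjusted Rand Index
# ---------------------------------------------------------------------------

def adjusted_rand_index(a, b) -> float:
    """Pair-counting ARI = (Index - Expected) / (Max - Expected).

    Degenerate convention: when the formula is 0/0 (e.g. both labelings put
    everything in one cluster, or both are all singletons), return 1 if the
    two labelings induce the same partition and 0 otherwise.
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.size != b.size:
        raise ShapeError(f"labelings differ in length: {a.size} vs {b.size}")
    if a.size < 2:
        raise ShapeError("need at least 2 items")
    ca = pd.factorize(a)[0]
    cb = pd.factorize(b)[0]
    contingency = np.zeros((ca.max() + 1, cb.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ca, cb), 1)

    def comb2(x):
        return x * (x - 1) // 2

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    total = comb2(a.size)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if abs(max_index - expected) < 1e-12:
        return 1.0 if np.array_equal(ca, cb) else 0.0
    return float((sum_ij - expected) / (max_index - expected))


# ---------------------------------------------------------------------------
# Partition quality
# ---------------------------------------------------------------------------

def sum_of_squares(X: np.ndarray, labels) -> tuple[float, float, float]:
    """(TSS, WSS, BSS) for a partition; BSS + WSS = TSS by construction
    of both around cluster/grand means."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    grand = X.mean(axis=0)
    tss = float(((X - grand) ** 2).sum())
    wss = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        wss += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return tss, wss, tss - wss


def accuracy_from_confusion(confusion: np.ndarray) -> float:
    """Best-matching accuracy from a truth x assigned contingency table.

    Maximizes the matched diagonal over assignments of predicted to true
    labels (Hungarian algorithm; for square tables this equals the maximum
    over label permutations).  Non-square tables are padded with zeros.
    """
    conf = np.asarray(confusion, dtype=float)
    k = max(conf.shape)
    padded = np.zeros((k, k))
    padded[: conf.shape[0], : conf.shape[1]] = conf
    rows, cols = linear_sum_assignment(-padded)
    return float(padded[rows, cols].sum() / conf.sum())


def match_accuracy(labels, truth) -> tuple[float, pd.DataFrame]:
    """Permutation-matched accuracy and the confusion matrix (truth x assigned)."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.size != truth.size:
        raise ShapeError("labels and truth differ in length")
    t_codes, t_names = pd.factorize(truth)
    l_codes, l_names = pd.factorize(labels)
    if max(t_names.size, l_names.size) > 6:
        raise DomainError("permutation matching supported for at most 6 classes")
    conf = np.zeros((t_names.size, l_names.size), dtype=np.int64)
    np.add.at(conf, (t_codes, l_codes), 1)
    confusion = pd.DataFrame(conf, index=list(t_names), columns=list(l_names))
    return accuracy_from_confusion(conf), confusion


@dataclass
class ClusterReport:
    """Labels plus evaluation against an optional ground truth."""

    labels: np.ndarray
    bss_tss: float
    accuracy: float | None = None
    confusion: pd.DataFrame | None = None
    ari: float | None = None
    empty_clusters: bool = False

    @classmethod
    def build(cls, X, labels, truth=None, empty_clusters=False) -> "ClusterReport":
        tss, _, bss = sum_of_squares(X, labels)
        rep = cls(
            labels=np.asarray(labels),
            bss_tss=0.0 if tss == 0 else bss / tss,
            empty_clusters=empty_clusters,
        )
        if truth is not None:
            rep.accuracy, rep.confusion = match_accuracy(labels, truth)
            rep.ari = adjusted_rand_index(labels, truth)
        return rep


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

def kmeans_cluster(X, k: int, seed: int = 0, n_start: int = 100, truth=None) -> ClusterReport:
    """Restarted Lloyd k-means; the restart with the lowest within-cluster
    sum of squares wins."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise DomainError("features must be finite")
    if k > X.shape[0]:
        raise DomainError(f"k={k} exceeds number of samples {X.shape[0]}")
    km = KMeans(
        n_clusters=k, n_init=n_start, init="random", algorithm="lloyd", random_state=seed % (2**31)
    ).fit(X)
    return ClusterReport.build(X, km.labels_, truth=truth)


# ---------------------------------------------------------------------------
# Self-organizing map
# ---------------------------------------------------------------------------

@dataclass
class SomSpec:
    """Self-organizing map settings.

    The defaults mirror the configuration that works well for TCRC features:
    a k x 1 node grid (one node per cluster), bubble neighbourhood,
    rectangular topology, toroidal structure, 50 epochs, learning rate
    decaying linearly 0.05 -> 0.01 and radius decaying linearly from half the
    grid diameter to 0.
    """

    rows: int = 2
    cols: int = 1
    neighbourhood: str = "bubble"  # gaussian | bubble
    topology: str = "rectangular"  # rectangular | hexagonal
    structure: str = "toroidal"  # planar | toroidal
    epochs: int = 50
    lr_start: float = 0.05
    lr_end: float = 0.01
    radius_start: float | None = None  # None: half the grid diameter
    radius_end: float = 0.0

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ConfigError("SOM grid must have at least one node")
        if self.neighbourhood not in ("gaussian", "bubble"):
            raise ConfigError(f"unknown neighbourhood {self.neighbourhood!r}")
        if self.topology not in ("rectangular", "hexagonal"):
            raise ConfigError(f"unknown topology {self.topology!r}")
        if self.structure not in ("planar", "toroidal"):
            raise ConfigError(f"unknown structure {self.structure!r}")
        if self.lr_start <= 0 or self.lr_end <= 0 or self.lr_end > self.lr_start:
            raise ConfigError("learning-rate schedule must be positive and nonincreasing")

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols


def _hex_axial(r: int, c: int) -> tuple[float, float]:
    # odd-r offset -> axial coordinates
    q = c - (r - (r & 1)) // 2
    return q, r


def _hex_distance(a, b) -> float:
    aq, ar = a
    bq, br = b
    dq, dr = aq - bq, ar - br
    return (abs(dq) + abs(dr) + abs(dq + dr)) / 2.0


def som_grid_distances(spec: SomSpec) -> np.ndarray:
    """Pairwise node distances on the SOM grid under the configured topology
    and structure (wrapped offsets when toroidal)."""
    nodes = [(r, c) for r in range(spec.rows) for c in range(spec.cols)]
    n = len(nodes)
    if spec.structure == "toroidal":
        shifts = list(
            itertools.product(
                (-spec.rows, 0, spec.rows), (-spec.cols, 0, spec.cols)
            )
        )
    else:
        shifts = [(0, 0)]
    dist = np.zeros((n, n))
    for i, (ri, ci) in enumerate(nodes):
        for j, (rj, cj) in enumerate(nodes):
            best = np.inf
            for sr, sc in shifts:
                r2, c2 = rj + sr, cj + sc
                if spec.topology == "hexagonal":
                    d = _hex_distance(_hex_axial(ri, ci), _hex_axial(r2, c2))
                else:
                    d = np.hypot(ri - r2, ci - c2)
                best = min(best, d)
            dist[i, j] = best
    return dist


def som_cluster(X, spec: SomSpec, seed: int = 0, truth=None) -> ClusterReport:
    """Online Kohonen training; labels are each sample's winning node.

    Per step the best-matching (nearest) node and its grid neighbours move
    toward the sample, weighted by the neighbourhood kernel of grid distance.
    With radius 0 and a bubble kernel only the winner updates, which is
    online k-means.  Empty nodes at the end are reported via the
    ``empty_clusters`` flag, not an error.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise DomainError("features must be finite")
    n, _ = X.shape
    rng = np.random.default_rng(seed)
    grid_dist = som_grid_distances(spec)
    k = spec.n_nodes

    init_idx = rng.choice(n, size=k, replace=n < k)
    weights = X[init_idx].astype(float).copy()

    r0 = spec.radius_start
    if r0 is None:
        r0 = float(grid_dist.max()) / 2.0
    total_steps = max(spec.epochs * n - 1, 1)
    step = 0
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        for i in order:
            frac = step / total_steps
            alpha = spec.lr_start + frac * (spec.lr_end - spec.lr_start)
            radius = r0 + frac * (spec.radius_end - r0)
            x = X[i]
            bmu = int(np.argmin(((weights - x) ** 2).sum(axis=1)))
            d = grid_dist[bmu]
            if spec.neighbourhood == "bubble":
                h = (d <= radius + 1e-12).astype(float)
            else:
                if radius <= 1e-12:
                    h = (d == 0).astype(float)
                else:
                    h = np.exp(-(d**2) / (2.0 * radius**2))
            weights += (alpha * h)[:, None] * (x - weights)
            step += 1

    labels = np.array(
        [int(np.argmin(((weights - x) ** 2).sum(axis=1))) for x in X]
    )
    empty = len(np.unique(labels)) < k
    return ClusterReport.build(X, labels, truth=truth, empty_clusters=empty)


def som_parameter_sweep(
    X, truth, grid_sizes=((2, 1), (2, 2)), epochs: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Full-factorial sweep over kernel x topology x structure x grid size,
    reporting matched accuracy per cell."""
    records = []
    for nb, topo, struct, (rows, cols) in itertools.product(
        ("gaussian", "bubble"),
        ("rectangular", "hexagonal"),
        ("planar", "toroidal"),
        grid_sizes,
    ):
        spec = SomSpec(
            rows=rows, cols=cols, neighbourhood=nb, topology=topo,
            structure=struct, epochs=epochs,
        )
        rep = som_cluster(X, spec, seed=seed, truth=truth)
        records.append(
            {
                "neighbourhood": nb,
                "topology": topo,
                "structure": struct,
                "rows": rows,
                "cols": cols,
                "accuracy": rep.accuracy,
                "bss_tss": rep.bss_tss,
            }
        )
    return pd.DataFrame(records)
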