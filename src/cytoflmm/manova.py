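"""One-way MANOVA on score vectors.

Tests equality of multivariate group means (e.g. the fPCA scores V1..V9 of
two mode-of-action groups) via the four classical statistics - Wilks'
Lambda, Pillai's trace, the Hotelling-Lawley trace and Roy's largest root -
each with its standard approximate-F transformation (Rao's F for Wilks; the
upper-bound F for Roy).  With two groups all four reduce to Hotelling's T^2
and the F approximations are exact and identical.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import DomainError, RankDeficiencyError, ShapeError


def manova_oneway(X, groups) -> pd.DataFrame:
    """One-way MANOVA table for an n x p score matrix and group labels.

    Returns a DataFrame indexed by statistic name with columns
    ``statistic, approx_f, num_df, den_df, p_value, exact`` where ``exact``
    marks cases in which the approximate-F distribution is the exact null
    distribution (always true for two groups).
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    if X.ndim != 2:
        raise ShapeError("X must be 2-d (samples x variables)")
    n, p = X.shape
    if groups.size != n:
        raise ShapeError("groups length must match number of rows")
    labels = pd.unique(groups)
    g = labels.size
    if g < 2:
        raise DomainError("need at least 2 groups")
    if n <= p + g - 1:
        raise DomainError(
            f"n={n} too small for p={p} variables and {g} groups (need n > p + g - 1)"
        )

    grand = X.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for lab in labels:
        sub = X[groups == lab]
        m = sub.mean(axis=0)
        H += sub.shape[0] * np.outer(m - grand, m - grand)
        E += (sub - m).T @ (sub - m)

    if np.linalg.matrix_rank(E) < p:
        # name the offending columns: those whose within-group variance is
        # (numerically) linearly dependent on the others
        diag = np.diag(E)
        bad = [int(i) for i in np.flatnonzero(diag <= 1e-12 * max(diag.max(), 1.0))]
        raise RankDeficiencyError(
            f"within-group scatter is singular (suspect columns: {bad or 'collinear set'})"
        )

    # eigenvalues of E^{-1} H (real and >= 0 since E is SPD, H PSD)
    eig = np.clip(linalg.eigh(H, E, eigvals_only=True)[::-1], 0.0, None)

    q = g - 1  # hypothesis df
    v = n - g  # error df
    s = min(p, q)
    m_ = 0.5 * (abs(p - q) - 1)
    n_ = 0.5 * (v - p - 1)

    lam = eig[:s]
    wilks = float(np.prod(1.0 / (1.0 + eig)))
    pillai = float(np.sum(lam / (1.0 + lam)))
    hl = float(np.sum(lam))
    roy = float(eig[0]) if eig.size else 0.0

    rows = {}

    # Wilks via Rao's F
    denom = p * p + q * q - 5
    t = np.sqrt((p * p * q * q - 4.0) / denom) if denom > 0 else 1.0
    w = v + q - 0.5 * (p + q + 1)
    df1 = p * q
    df2 = w * t - 0.5 * (p * q - 2)
    lam_t = wilks ** (1.0 / t)
    f_wilks = (1.0 - lam_t) / lam_t * df2 / df1 if wilks > 0 else np.inf
    rows["Wilks"] = (wilks, f_wilks, df1, df2, min(p, q) <= 2)

    tmp1 = 2 * m_ + s + 1
    tmp2 = 2 * n_ + s + 1
    f_pillai = (tmp2 / tmp1) * pillai / (s - pillai) if s - pillai > 0 else np.inf
    rows["Pillai"] = (pillai, f_pillai, s * tmp1, s * tmp2, s == 1)

    tmp2h = 2.0 * (s * n_ + 1)
    f_hl = tmp2h * hl / (s * s * tmp1)
    rows["Hotelling-Lawley"] = (hl, f_hl, s * tmp1, tmp2h, s == 1)

    r = max(p, q)
    f_roy = (v - r + q) / r * roy
    rows["Roy"] = (roy, f_roy, r, v - r + q, s == 1)

    out = []
    for name, (statv, f, d1, d2, exact) in rows.items():
        pval = float(stats.f.sf(f, d1, d2)) if np.isfinite(f) else 0.0
        out.append(
            {
                "statistic_name": name,
                "statistic": statv,
                "approx_f": float(f),
                "num_df": float(d1),
                "den_df": float(d2),
                "p_value": pval,
                "exact": bool(exact),
            }
        )
    return pd.DataFrame(out).set_index("statistic_name")
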