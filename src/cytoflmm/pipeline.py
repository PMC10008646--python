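"""End-to-end orchestration: binning -> fPCA scores -> MANOVA -> B-spline
contrasts -> clustering, with deterministic per-stage seeding and CSV output.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bspline as bsp
from . import cluster as clu
from .binning import BinningResult, bin_concentrations, chemical_wavelet_features
from .config import PipelineConfig, stage_seed
from .errors import StageError
from .fpca import FPCAResult, fit_fpca, score_columns
from .manova import manova_oneway
from .panel import CurvePanel, write_table

log = logging.getLogger("cytoflmm")


@dataclass
class PipelineReport:
    """Everything the pipeline computes, as in-memory tables/objects."""

    panel: CurvePanel
    binning: BinningResult | None
    fpca: FPCAResult
    scores: pd.DataFrame
    manova_table: pd.DataFrame | None
    lmm_fit: object | None
    contrasts: pd.DataFrame | None
    cluster_reports: dict = field(default_factory=dict)

    def tables(self) -> dict:
        out = {"scores": self.scores}
        if self.binning is not None:
            out["ari_matrix"] = self.binning.ari_matrix.reset_index(names="concentration_index")
        if self.manova_table is not None:
            out["manova"] = self.manova_table.reset_index()
        if self.contrasts is not None:
            out["contrasts"] = self.contrasts
        for name, rep in self.cluster_reports.items():
            rows = {"labels": list(rep.labels), "bss_tss": rep.bss_tss}
            df = pd.DataFrame({"label": rep.labels})
            df["bss_tss"] = rep.bss_tss
            if rep.accuracy is not None:
                df["accuracy"] = rep.accuracy
            out[f"cluster_{name}"] = df
        return out


def _two_largest_groups(panel: CurvePanel, remainder_label: str = "other") -> tuple[CurvePanel, list] | None:
    """The two largest proper MOA groups; a remainder/catch-all label is only
    used when fewer than two proper groups exist."""
    moa = panel.obs.loc[panel.obs["concentration_index"].notna(), ["chemical_id", "moa_label"]]
    moa = moa.dropna().drop_duplicates("chemical_id")
    counts = moa["moa_label"].value_counts()
    proper = counts[counts.index != remainder_label]
    if proper.size >= 2:
        counts = proper
    if counts.size < 2:
        return None
    top = list(counts.index[:2])
    keep_chems = set(moa.loc[moa["moa_label"].isin(top), "chemical_id"])
    mask = panel.obs["chemical_id"].isin(keep_chems).to_numpy()
    return panel.subset(mask), sorted(top)


def run_pipeline(config: PipelineConfig, panel: CurvePanel, outdir=None) -> PipelineReport:
    """Run the full analysis; deterministic given ``config.seed``.

    Any stage failure is re-raised as :class:`StageError` naming the stage.
    Tables are written under ``outdir`` when given.
    """
    config.validate()
    t0 = time.time()

    def stage(name):
        log.info("[%7.2fs] stage %s", time.time() - t0, name)

    def run(name, fn):
        stage(name)
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    binning = None
    if not panel.is_binned():
        def _bin():
            res = bin_concentrations(
                panel,
                k_bins=config.k_bins,
                level=config.level,
                wavelet=config.wavelet,
                seed=stage_seed(config.seed, "binning"),
                n_start=config.kmeans_restarts,
            )
            return res

        binning = run("binning", _bin)
        panel = binning.apply(panel)

    fpca = run(
        "fpca",
        lambda: fit_fpca(panel, n_fpc=config.n_fpc, e_threshold=config.e_var_threshold),
    )
    scores = fpca.scores

    sub = _two_largest_groups(panel)
    manova_table = None
    lmm_fit = None
    contrasts = None
    reports = {}
    vcols = [c for c, _ in score_columns(fpca.fpc_model)]

    if sub is not None:
        pair_panel, top = sub
        pair_scores = scores[scores["moa_label"].isin(top)]
        X = pair_scores[vcols].to_numpy()
        truth = pair_scores["moa_label"].to_numpy()

        manova_table = run("manova", lambda: manova_oneway(X, truth))

        def _bspline():
            basis = bsp.make_bspline_basis(
                domain=(panel.grid[0] - 1.0, panel.grid[-1]),
                n_basis=config.n_basis,
                degree=config.spline_degree,
                grid=panel.grid,
            )
            design = bsp.build_design(pair_panel, basis, with_groups=True)
            fit = bsp.fit_lmm(design, seed=stage_seed(config.seed, "bspline"))
            table = bsp.group_contrasts(fit, q=config.fdr_q)
            design0 = bsp.build_design(pair_panel, basis, with_groups=False)
            fit0 = bsp.fit_lmm(design0, seed=stage_seed(config.seed, "bspline-pooled"))
            return fit, table, fit0

        lmm_fit, contrasts, fit0 = run("bspline", _bspline)

        def _cluster():
            out = {}
            out["kmeans_scores"] = clu.kmeans_cluster(
                X, k=2, seed=stage_seed(config.seed, "kmeans-scores"),
                n_start=config.kmeans_restarts, truth=truth,
            )
            som = config.som
            out["som_scores"] = clu.som_cluster(
                X, som, seed=stage_seed(config.seed, "som-scores"), truth=truth
            )
            wf = chemical_wavelet_features(pair_panel, level=config.level, wavelet=config.wavelet)
            wf_truth = (
                pair_panel.obs.drop_duplicates("chemical_id")
                .set_index("chemical_id")["moa_label"]
                .reindex(wf.index)
                .to_numpy()
            )
            out["kmeans_wavelet"] = clu.kmeans_cluster(
                wf.to_numpy(), k=2, seed=stage_seed(config.seed, "kmeans-wavelet"),
                n_start=config.kmeans_restarts, truth=wf_truth,
            )
            u_feats = np.array(
                [
                    np.concatenate([fit0.u[c][lv] for lv in fit0.design.levels_present])
                    for c in fit0.design.chemicals
                ]
            )
            u_truth = np.array([fit0.design.groups[c] for c in fit0.design.chemicals])
            out["kmeans_bspline_u"] = clu.kmeans_cluster(
                u_feats, k=2, seed=stage_seed(config.seed, "kmeans-bspline"),
                n_start=config.kmeans_restarts, truth=u_truth,
            )
            return out

        reports = run("clustering", _cluster)

        # three-group clustering over all chemicals when a remainder group exists
        all_moa = scores["moa_label"].dropna()
        if all_moa.nunique() >= 3:
            top3 = list(all_moa.value_counts().index[:3])
            s3 = scores[scores["moa_label"].isin(top3)]
            reports["kmeans_scores_3group"] = clu.kmeans_cluster(
                s3[vcols].to_numpy(), k=3,
                seed=stage_seed(config.seed, "kmeans-scores-3"),
                n_start=config.kmeans_restarts,
                truth=s3["moa_label"].to_numpy(),
            )

    report = PipelineReport(
        panel=panel,
        binning=binning,
        fpca=fpca,
        scores=scores,
        manova_table=manova_table,
        lmm_fit=lmm_fit,
        contrasts=contrasts,
        cluster_reports=reports,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in report.tables().items():
            write_table(table, outdir / f"{name}.csv")
        stage("write")
    stage("done")
    return report
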