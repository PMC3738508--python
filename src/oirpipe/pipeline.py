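"""End-to-end pipeline: synth → segment → quantify → SMIA → stats.

Each stage writes auditable artefacts (TIFF masks, CSV tables, a JSON
stats report, PNG figures) into the output directory; a run manifest
records the config hash and a SHA-256 checksum of every deterministic
artefact, so two runs with the same config are byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import io as oio
from .config import RunConfig
from .metrics import quantify_wholemount
from .segmentation import segment_vessels_trajectory
from .smia import smia_vector
from .stats import (
    GroupDesign,
    anova_tukey,
    choose_n_components,
    manova_mahalanobis,
    pca_scores,
    tunel_summary,
)
from .synth import generate_cohort, preset_design

log = logging.getLogger("oirpipe")


@dataclass
class RunManifest:
    config_digest: str
    started: float
    finished: float = 0.0
    files: dict[str, str] = field(default_factory=dict)  # relpath -> sha256

    def to_dict(self) -> dict:
        return {
            "config_digest": self.config_digest,
            "files": dict(sorted(self.files.items())),
            "n_files": len(self.files),
        }


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunManifest:
    """Execute the full pipeline into ``outdir`` and return its manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    manifest = RunManifest(config_digest=config.digest(), started=time.time())

    def save(relpath: str, writer, *args) -> None:
        path = outdir / relpath
        path.parent.mkdir(parents=True, exist_ok=True)
        writer(path, *args)
        if path.suffix.lower() not in (".png", ".svg"):
            manifest.files[relpath] = oio.sha256_of(path)

    # ---- stage 1: synthesis ---------------------------------------------
    log.info("stage synth: preset=%s n_per_group=%d", config.preset,
             config.n_per_group)
    design = preset_design(
        config.preset, config.seed, image_size=config.synth["image_size"]
    )
    try:
        cohort = generate_cohort(design, config.n_per_group,
                                 n_sections=config.synth["n_sections"])
    except Exception as e:
        raise RuntimeError(f"[synth] {e}") from e

    sample_rows = []
    for s in cohort:
        sid = s.image.sample_id
        save(f"images/{sid}.tif", oio.write_image, s.image.intensity)
        save(f"images/{sid}_preview.png", oio.write_image, s.image.intensity)
        save(f"masks/{sid}_retina.tif", oio.write_mask, s.image.retina_mask)
        save(f"tunel/{sid}.csv", oio.write_table, s.tunel)
        sample_rows.append({"sample_id": sid, "group": s.image.group})
    design_df = pd.DataFrame(sample_rows)
    save("design.csv", oio.write_table, design_df)

    # ---- stages 2-4: segmentation, quantification, SMIA ------------------
    cv_params = config.chan_vese_params
    metrics_rows, vectors, crit_iters = [], [], {}
    for s in cohort:
        sid = s.image.sample_id
        try:
            traj = segment_vessels_trajectory(
                s.image, cv_params, record_every=config.smia["record_every"]
            )
        except Exception as e:
            raise RuntimeError(f"[segment] {sid}: {e}") from e
        vessel = traj.final_mask
        save(f"masks/{sid}_vessel.tif", oio.write_mask, vessel)

        try:
            m, masks = quantify_wholemount(s.image, vessel, **{
                "closing_radius": config.quantify["closing_radius"],
                "tuft_q": config.quantify["tuft_q"],
                "tuft_min_area": config.quantify["tuft_min_area"],
                "tuft_max_area": config.quantify["tuft_max_area"],
                "haem_dark_q": config.quantify["haem_dark_q"],
                "haem_min_area": config.quantify["haem_min_area"],
            })
        except Exception as e:
            raise RuntimeError(f"[quantify] {sid}: {e}") from e
        save(f"masks/{sid}_avascular.tif", oio.write_mask, masks["avascular"])
        metrics_rows.append(vars(m))

        try:
            vec = smia_vector(
                s.image, cv_params, k=config.smia["k"],
                record_every=config.smia["record_every"],
                peripheral_fraction=config.smia["peripheral_fraction"],
                open_radius=config.smia["open_radius"],
            )
            vectors.append((sid, s.image.group, vec.values))
            crit_iters[sid] = list(map(int, vec.critical_iterations))
        except Exception as e:
            raise RuntimeError(f"[smia] {sid}: {e}") from e

    metrics_df = pd.DataFrame(metrics_rows)
    save("metrics.csv", oio.write_table, metrics_df)
    k = config.smia["k"]
    feat_cols = [f"f{j}_{name}" for j in range(1, k + 1)
                 for name in ("area", "perim", "euler")]
    feat_df = pd.DataFrame(
        [dict(zip(["sample_id", "group"], (sid, grp))) | dict(zip(feat_cols, v))
         for sid, grp, v in vectors]
    )
    save("smia_features.csv", oio.write_table, feat_df)
    save("smia_critical_iterations.json", oio.write_json, crit_iters)

    # ---- stage 5: statistics --------------------------------------------
    try:
        report = compute_stats_report(
            metrics_df, feat_df,
            {s.image.sample_id: s.tunel for s in cohort},
            alpha=config.stats["alpha"],
            pca_var_target=config.stats["pca_var_target"],
            n_pcs=config.stats["n_pcs"],
        )
    except Exception as e:
        raise RuntimeError(f"[stats] {e}") from e
    _figures(outdir, metrics_df, report)  # also strips in-memory-only entries
    save("stats_report.json", oio.write_json, report)

    manifest.finished = time.time()
    save("manifest.json", oio.write_json, manifest.to_dict())
    return manifest


def compute_stats_report(
    metrics_df: pd.DataFrame,
    feat_df: pd.DataFrame,
    tunel_tables: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    pca_var_target: float = 0.90,
    n_pcs: int | None = None,
) -> dict:
    """Statistics report over per-sample metrics, SMIA features and TUNEL."""
    design = GroupDesign.from_lists(metrics_df["sample_id"], metrics_df["group"])
    report: dict = {"alpha": alpha}

    for col in ("vaso_obliteration_pct", "neovascularisation_pct",
                "haemorrhage_count"):
        res = anova_tukey(metrics_df[col].to_numpy(dtype=float), design, alpha)
        entry = {
            "F": res.F, "p": res.p_value, "df": list(res.df),
            "degenerate": res.degenerate,
            "group_means": metrics_df.groupby("group")[col].mean().to_dict(),
        }
        if res.tukey is not None:
            entry["tukey"] = res.tukey.to_dict(orient="records")
        report[col] = entry

    fdesign = GroupDesign.from_lists(feat_df["sample_id"], feat_df["group"])
    X = feat_df.drop(columns=["sample_id", "group"]).to_numpy(dtype=float)
    m = n_pcs or choose_n_components(X, fdesign, var_target=pca_var_target)
    scores, explained = pca_scores(X, m)
    clustering = manova_mahalanobis(scores, fdesign)
    report["smia"] = {
        "n_pcs": int(scores.shape[1]),
        "explained_variance_ratio": explained.tolist(),
        "wilks_lambda": clustering.wilks_lambda,
        "manova_F": clustering.F,
        "manova_p": clustering.p_value,
        "group_order": clustering.group_names,
        "mahalanobis_matrix": clustering.distance_matrix.tolist(),
        "distances_to_control": clustering.distances_to_control,
        "dendrogram_newick": clustering.dendrogram.to_newick(),
        "dendrogram_merges": [
            {"left": list(l), "right": list(r), "height": h}
            for l, r, h in clustering.dendrogram.merges
        ],
        "last_singleton": clustering.dendrogram.last_singleton(),
    }
    report["_clustering"] = clustering  # in-memory only; stripped on save

    ts = tunel_summary(tunel_tables, design, alpha=alpha)
    report["tunel"] = {
        "summary": ts.table.to_dict(orient="records"),
        "anova": {
            layer: {"F": r.F, "p": r.p_value, "degenerate": r.degenerate}
            for layer, r in ts.anova.items()
        },
    }
    return report


def _figures(outdir: Path, metrics_df: pd.DataFrame, report: dict) -> None:
    clustering = report.pop("_clustering", None)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    order = [g for g in ("control", "r670", "oir", "r670_oir")
             if g in set(metrics_df["group"])]
    for ax, col, title in zip(
        axes,
        ("vaso_obliteration_pct", "neovascularisation_pct"),
        ("Vaso-obliteration (%)", "Neovascularisation (%)"),
    ):
        g = metrics_df.groupby("group")[col]
        means = g.mean().reindex(order)
        ses = (g.std(ddof=1) / np.sqrt(g.count())).reindex(order)
        ax.bar(order, means, yerr=ses, color=["k", "0.35", "0.7", "w"],
               edgecolor="k")
        ax.set_title(title)
        ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(outdir / "figures_metrics.png", dpi=120)
    plt.close(fig)

    if clustering is not None:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        _plot_dendrogram(ax, clustering.dendrogram)
        ax.set_ylabel("Mahalanobis distance (single linkage)")
        fig.tight_layout()
        fig.savefig(outdir / "figures_dendrogram.png", dpi=120)
        plt.close(fig)
    # strip non-serialisable entry if still present
    report.pop("_clustering", None)


def _plot_dendrogram(ax, dendro) -> None:
    """Minimal dendrogram rendering from the merge list."""
    x: dict[tuple[str, ...], float] = {}
    h: dict[tuple[str, ...], float] = {}
    # leaf order: traverse merges to get a display ordering
    order: list[str] = []

    def collect(cluster):
        if len(cluster) == 1:
            if cluster[0] not in order:
                order.append(cluster[0])

    for left, right, _ in dendro.merges:
        collect(left)
        collect(right)
    for lab in dendro.labels:
        if lab not in order:
            order.append(lab)
    for i, lab in enumerate(order):
        x[(lab,)] = float(i)
        h[(lab,)] = 0.0
    for left, right, height in dendro.merges:
        xl, xr = x[left], x[right]
        hl, hr = h[left], h[right]
        ax.plot([xl, xl], [hl, height], "k-")
        ax.plot([xr, xr], [hr, height], "k-")
        ax.plot([xl, xr], [height, height], "k-")
        merged = tuple(sorted(left + right))
        x[merged] = (xl + xr) / 2.0
        h[merged] = height
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order, rotation=30)
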