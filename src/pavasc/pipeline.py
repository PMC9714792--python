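"""End-to-end orchestration of the expression and image workflows.

Both entry points take a configuration dictionary (typically loaded from a
single JSON file with per-stage sections) and an output directory; every
stage writes its table with a provenance header (config hash, seed) plus a
machine-readable run log of parameters and in/out counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import commnet, io, sc_qc_stats, syndata, vesselimg

log = logging.getLogger("pavasc")

DEFAULT_EXPR_CONFIG = {
    "seed": 0,
    "simulate": {},  # SimExprParams overrides; omit and set "input_dir" to load data
    "qc": {},  # QCThresholds overrides
    "normalize": {"scale": 1e4},
    "markers": {"min_pct": 0.25, "lfc_min": 0.25, "alpha": 0.05},
    "signature": {"n_bins": 24, "ctrl_per_gene": 100, "top_n": 100},
    "commnet": {"n_perm": 1000, "alpha": 0.05},
}


def _stage_seed(seed: int, stage: str) -> int:
    # stage-name-derived substream of the run seed, kept below 2**31
    h = sum(ord(c) * (i + 1) for i, c in enumerate(stage))
    return (seed * 1000003 + h) % (2**31 - 1)


def _merge(defaults: dict, overrides: dict | None) -> dict:
    out = dict(defaults)
    for k, v in (overrides or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = {**out[k], **v}
        else:
            out[k] = v
    return out


def run_expression_pipeline(config: dict | None = None, outdir="pavasc_run") -> dict:
    """QC -> normalize -> markers -> scores -> proportions -> communication.

    Returns a report dict; all tables land in ``outdir``.
    """
    cfg = _merge(DEFAULT_EXPR_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": io.config_hash(cfg), "seed": cfg["seed"]}
    report: dict = {"stages": {}, "provenance": prov}

    # --- input
    if "input_dir" in cfg:
        adata = io.read_expression_dir(cfg["input_dir"])
        truth = None
    else:
        params = syndata.SimExprParams(
            **{**cfg["simulate"], "seed": _stage_seed(cfg["seed"], "simulate")}
        )
        adata, truth = syndata.simulate_counts(params)
        truth.to_json(outdir / "truth.json")
    report["stages"]["input"] = {"n_cells": adata.n_obs, "n_genes": adata.n_vars}

    # --- qc
    thresholds = sc_qc_stats.QCThresholds(**cfg["qc"])
    kept, qc_report = sc_qc_stats.qc_filter(adata, thresholds, sample_key="sample")
    io.write_table(qc_report.reset_index(), outdir / "qc_report.tsv", prov)
    adata = adata[kept].copy()
    report["stages"]["qc"] = {
        "thresholds": dataclasses.asdict(thresholds),
        "n_removed": int(qc_report["removed"].sum()),
        "n_kept": len(kept),
    }

    # --- normalize
    norm = sc_qc_stats.lognormalize(adata, scale=cfg["normalize"]["scale"])

    # --- markers per population
    mk = cfg["markers"]
    marker_tables = []
    populations = list(pd.unique(norm.obs["population"]))
    for pop in populations:
        try:
            t = sc_qc_stats.find_markers(
                norm, pop, min_pct=mk["min_pct"], lfc_min=mk["lfc_min"],
                alpha=mk["alpha"],
            )
        except ValueError as e:
            log.warning("markers skipped for %s: %s", pop, e)
            continue
        t.insert(0, "population", pop)
        marker_tables.append(t)
    markers = pd.concat(marker_tables, ignore_index=True)
    io.write_table(markers, outdir / "markers.tsv", prov)
    report["stages"]["markers"] = {"n_rows": len(markers)}

    # --- signature scores (top-N markers per population)
    sig_cfg = cfg["signature"]
    sig_seed = _stage_seed(cfg["seed"], "signature")
    scores = pd.DataFrame(index=norm.obs_names.copy())
    for pop in populations:
        sub = markers[(markers["population"] == pop) & (markers["log2fc"] > 0)]
        genes = list(sub.sort_values("p_adj")["gene"].head(sig_cfg["top_n"]))
        if not genes:
            continue
        scores[f"score_{pop}"] = sc_qc_stats.signature_score(
            norm, genes, n_bins=sig_cfg["n_bins"],
            ctrl_per_gene=sig_cfg["ctrl_per_gene"], seed=sig_seed,
        )
    io.write_table(scores.reset_index(), outdir / "signature_scores.tsv", prov)
    report["stages"]["signature"] = {"n_signatures": scores.shape[1]}

    # --- cell-cycle phase if gene lists provided
    if "s_genes" in cfg and "g2m_genes" in cfg:
        cc = sc_qc_stats.cell_cycle_phase(
            norm, cfg["s_genes"], cfg["g2m_genes"],
            seed=_stage_seed(cfg["seed"], "cell_cycle"),
        )
        io.write_table(cc.reset_index(), outdir / "cell_cycle.tsv", prov)
        report["stages"]["cell_cycle"] = cc["phase"].value_counts().to_dict()

    # --- proportion tests
    prop_rows = []
    for pop in populations:
        res = sc_qc_stats.proportion_test(norm.obs, pop)
        prop_rows.append((pop, res.t, res.p))
    props = pd.DataFrame(prop_rows, columns=["population", "t", "p"])
    io.write_table(props, outdir / "proportions.tsv", prov)
    report["stages"]["proportions"] = {"n_populations": len(props)}

    # --- communication
    cn = cfg["commnet"]
    if "lr_database" in cfg:
        db = io.read_lr_database(cfg["lr_database"])
    elif truth is not None and truth.lr_channels:
        db = pd.DataFrame(
            [
                {"ligand": c["ligand"], "receptor": c["receptor"], "weight": 0.9}
                for c in truth.lr_channels
            ]
        )
    else:
        db = None
    if db is not None:
        weights = commnet.expression_weights(
            norm, list(pd.unique(pd.concat([db["ligand"], db["receptor"]])))
        )
        edges, edge_report = commnet.score_interactions(weights, db)
        edges = commnet.permutation_test(
            edges=edges, norm=norm, n_perm=cn["n_perm"],
            seed=_stage_seed(cfg["seed"], "permutation"),
        )
        io.write_table(edges, outdir / "lr_edges.tsv", prov)
        summary = commnet.summarize_network(edges, alpha=cn["alpha"])
        io.write_table(
            pd.DataFrame(
                {
                    "population": list(summary.ligand_scores),
                    "ligand_score": list(summary.ligand_scores.values()),
                    "receptor_score": list(summary.receptor_scores.values()),
                }
            ),
            outdir / "lr_population_scores.tsv",
            prov,
        )
        report["stages"]["commnet"] = {
            "n_edges": len(edges),
            "n_significant": int((edges["p_perm"] < cn["alpha"]).sum())
            if len(edges)
            else 0,
            **edge_report,
        }

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report


DEFAULT_IMAGE_CONFIG = {
    "seed": 0,
    "n_probes": 32,
    "samples_per_probe": 100,
    "dilation_radius": 2,
    "positivity_cutoff": 0.1,
    "nucleus_radius": 4.0,
}


def run_image_pipeline(
    config: dict | None = None,
    images: list | None = None,
    groups: list[str] | None = None,
    outdir="pavasc_image_run",
    plot: bool = False,
) -> dict:
    """Segment, profile and quantify each vessel image; compare groups.

    ``images`` is a list of (array, roles) tuples or TIFF paths (with
    sidecar JSON); ``groups`` optionally assigns each image to a condition
    for the rank-sum comparison of positive-percentage summaries.
    Per-image failures are logged and skipped; the run fails only if every
    image fails.
    """
    cfg = _merge(DEFAULT_IMAGE_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": io.config_hash(cfg), "seed": cfg["seed"]}
    if not images:
        raise ValueError("no images provided")

    summaries, rows, errors = [], [], []
    for i, item in enumerate(images):
        try:
            if isinstance(item, (str, Path)):
                img, roles = io.read_image(item)
            else:
                img, roles = item
            if img.ndim == 4:  # z-stack
                img = vesselimg.max_project(img)
            rois = vesselimg.segment_vessel(img, roles)
            profile = vesselimg.radial_profile(
                img, roles, rois, n_probes=cfg["n_probes"],
                samples_per_probe=cfg["samples_per_probe"],
            )
            prof_df = pd.DataFrame(profile.profiles)
            prof_df.insert(0, "position", profile.positions)
            io.write_table(prof_df, outdir / f"profile_{i:03d}.tsv", prov)
            if plot:
                _plot_profile(profile, outdir / f"profile_{i:03d}.png")
            labels, _ = vesselimg.segment_nuclei(
                img[roles.index("dapi")], nucleus_radius=cfg["nucleus_radius"]
            )
            medial = vesselimg.assign_medial(
                labels, img[roles.index("acta2")], img[roles.index("vwf")],
                dilation_radius=cfg["dilation_radius"],
            )
            records, summary = vesselimg.quantify_marker(
                labels, medial, img[roles.index("marker")],
                positivity_cutoff=cfg["positivity_cutoff"],
            )
            records.insert(0, "image", i)
            rows.append(records)
            summaries.append({"image": i, **summary})
        except Exception as e:  # noqa: BLE001 — per-image isolation
            log.warning("image %d failed: %s", i, e)
            errors.append({"image": i, "error": str(e)})
    if not summaries:
        raise RuntimeError(f"all images failed: {errors}")

    nuclei = pd.concat(rows, ignore_index=True)
    io.write_table(nuclei, outdir / "nuclei.tsv", prov)
    summary_df = pd.DataFrame(summaries)
    if groups is not None:
        summary_df["group"] = [groups[s["image"]] for s in summaries]
    io.write_table(summary_df, outdir / "vessel_summaries.tsv", prov)

    report = {
        "provenance": prov,
        "n_images": len(summaries),
        "errors": errors,
        "summaries": summaries,
    }
    if groups is not None and summary_df["group"].nunique() == 2:
        g1, g2 = sorted(summary_df["group"].unique())
        a = summary_df.loc[summary_df["group"] == g1, "positive_percentage"].dropna()
        b = summary_df.loc[summary_df["group"] == g2, "positive_percentage"].dropna()
        if len(a) >= 2 and len(b) >= 2:
            report["group_comparison"] = {
                "groups": [g1, g2],
                **vesselimg.compare_groups(list(a), list(b)),
            }
        else:
            log.warning("fewer than 2 vessels per group; comparison skipped")
    elif groups is not None:
        log.warning("group comparison needs exactly 2 groups; skipped")

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report


def _plot_profile(profile, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for role, vec in profile.profiles.items():
        ax.plot(profile.positions, vec, label=role)
    ax.set_xlabel("normalized radial position (0 = lumen, 1 = outer boundary)")
    ax.set_ylabel("mean probe intensity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
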