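"""End-to-end orchestration behind the command-line interface.

Each stage reads and writes plain-text artifacts (TSV matrices and tidy
tables) in a working directory; every output embeds the configuration hash
and master seed so identical (config, seed) runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atlas as atlas_mod
from .features import feature_table
from .graph_metrics import default_sparsities, sweep_thresholds
from .group_stats import SubjectFeatureTable, edgewise_comparison
from .kls_network import ConnectivityMatrix, build_network
from .roi_extraction import LabelAtlas, ROISampleSet, VolumeImage, process_volume
from .simulate import SimulationConfig, simulate_connectivity_direct, simulate_roi_samples
from .survival_model import (
    PatientRecord,
    loocv_predict,
    permutation_test,
    permutation_test_loocv,
    summarize_weights,
)

__all__ = [
    "DataError",
    "load_config",
    "config_hash",
    "run_simulate",
    "run_build_networks",
    "run_graph_metrics",
    "run_compare_groups",
    "run_predict_survival",
    "run_all",
]

logger = logging.getLogger(__name__)


class DataError(RuntimeError):
    """Missing or malformed input data (CLI exit code 2)."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "klsnet_out",
    "simulate": {"mode": "direct"},
    "network": {"bandwidth": "silverman", "n_grid": 512, "fwhm_mm": 6.0},
    "graph": {
        "sparsity_min": 0.02,
        "sparsity_max": 0.50,
        "sparsity_step": 0.01,
        "n_random_networks": 100,
    },
    "stats": {"q": 0.05, "welch": False},
    "predict": {
        "c": 1.0,
        "epsilon": 0.1,
        "alpha": 0.05,
        "selection": "per_fold",
        "select_on": "fdr",
        # full re-run of the LOOCV per permutation is properly calibrated but
        # costly, hence the reduced default count; fast mode re-pairs fixed
        # predictions and supports the classic 10,000-permutation scale
        "n_perm": 199,
        "perm_mode": "full",
    },
    "paths": {},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults <- YAML file <- explicit overrides, merged recursively."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise DataError(f"config {path} is not a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    """Fingerprint of the analysis configuration (output location excluded)."""
    canon = json.dumps(
        {k: v for k, v in cfg.items() if k != "output_dir"}, sort_keys=True, default=str
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _meta(cfg: dict) -> dict:
    return {"config_hash": config_hash(cfg), "seed": cfg["seed"]}


def _write_table(df: pd.DataFrame, path: Path, cfg: dict) -> None:
    with open(path, "w") as fh:
        for k, v in _meta(cfg).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _sim_config(cfg: dict) -> SimulationConfig:
    block = dict(cfg.get("simulate", {}))
    block.pop("mode", None)
    planted = [tuple(e) for e in block.pop("planted_edges", [])]
    betas_raw = block.pop("outcome_betas", {})
    betas = {}
    for key, b in betas_raw.items():
        i, j = (int(t) for t in str(key).split("-"))
        betas[(i, j)] = float(b)
    return SimulationConfig(
        planted_edges=planted, outcome_betas=betas, seed=int(cfg["seed"]), **block
    )


def run_simulate(cfg: dict, outdir) -> Path:
    """Generate a synthetic cohort and write it to ``outdir``."""
    out = Path(outdir)
    mode = cfg.get("simulate", {}).get("mode", "direct")
    sim_cfg = _sim_config(cfg)
    if mode == "direct":
        cohort = simulate_connectivity_direct(sim_cfg)
    elif mode == "roi":
        cohort = simulate_roi_samples(sim_cfg)
    else:
        raise DataError(f"unknown simulate mode {mode!r}")
    cohort.write(out)
    logger.info("simulated %d subjects into %s", len(cohort.subject_ids), out)
    return out


def _load_cohort_table(datadir: Path) -> pd.DataFrame:
    path = datadir / "cohort.tsv"
    if not path.exists():
        raise DataError(f"cohort table not found: {path}")
    return _read_table(path)


def _load_atlas(cfg: dict) -> LabelAtlas | None:
    paths = cfg.get("paths", {})
    if "atlas" in paths and "lookup" in paths:
        return LabelAtlas.from_nifti(paths["atlas"], paths["lookup"])
    return None


def run_build_networks(cfg: dict, datadir, outdir) -> list[Path]:
    """Build one KLS network file per subject listed in the cohort table.

    Each subject needs either ``<id>.roisamples.tsv`` in ``datadir`` or a
    NIfTI image (``paths.images_dir/<id>.nii[.gz]`` with a configured
    atlas + lookup, in which case smoothing and global normalization run
    first). Missing inputs abort with a per-subject report.
    """
    datadir, out = Path(datadir), Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = _load_cohort_table(datadir)
    net_cfg = cfg.get("network", {})
    atlas = _load_atlas(cfg)
    images_dir = cfg.get("paths", {}).get("images_dir")
    missing, written = [], []
    for sid in cohort["subject_id"]:
        tsv = datadir / f"{sid}.roisamples.tsv"
        nii = None
        if images_dir is not None:
            for ext in (".nii", ".nii.gz"):
                cand = Path(images_dir) / f"{sid}{ext}"
                if cand.exists():
                    nii = cand
                    break
        if tsv.exists():
            rois = ROISampleSet.from_tsv(tsv)
        elif nii is not None and atlas is not None:
            img = VolumeImage.from_nifti(nii)
            rois = process_volume(
                img, atlas, fwhm_mm=float(net_cfg.get("fwhm_mm", 6.0)), subject_id=str(sid)
            )
        else:
            missing.append(str(sid))
            continue
        net = build_network(
            rois,
            bandwidth=net_cfg.get("bandwidth", "silverman"),
            n_grid=int(net_cfg.get("n_grid", 512)),
        )
        net.meta.update(_meta(cfg))
        path = out / f"{sid}.klsnet.tsv"
        net.to_tsv(path)
        written.append(path)
    if missing:
        raise DataError(
            "no input data for subjects: " + ", ".join(missing)
            + f" ({len(written)} other subjects were built)"
        )
    return written


def _load_networks(netdir: Path, subject_ids) -> list[ConnectivityMatrix]:
    mats = []
    missing = []
    for sid in subject_ids:
        path = netdir / f"{sid}.klsnet.tsv"
        if not path.exists():
            missing.append(str(sid))
            continue
        mats.append(ConnectivityMatrix.from_tsv(path, subject_id=str(sid)))
    if missing:
        raise DataError("network files missing for subjects: " + ", ".join(missing))
    return mats


def _sparsities(cfg: dict) -> np.ndarray:
    g = cfg.get("graph", {})
    return default_sparsities(
        float(g.get("sparsity_min", 0.02)),
        float(g.get("sparsity_max", 0.50)),
        float(g.get("sparsity_step", 0.01)),
    )


def run_graph_metrics(cfg: dict, netdir, outdir, subject_ids=None) -> tuple[Path, Path]:
    """Sparsity-sweep metrics for every subject; tidy value and AUC tables."""
    netdir, out = Path(netdir), Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if subject_ids is None:
        subject_ids = sorted(p.name.removesuffix(".klsnet.tsv") for p in netdir.glob("*.klsnet.tsv"))
    if not subject_ids:
        raise DataError(f"no .klsnet.tsv files in {netdir}")
    sparsities = _sparsities(cfg)
    n_rand = int(cfg.get("graph", {}).get("n_random_networks", 100))
    value_rows, auc_rows = [], []
    for sid in subject_ids:
        net = _load_networks(netdir, [sid])[0]
        curves, nodal = sweep_thresholds(
            net, sparsities=sparsities, n_rand=n_rand, seed=int(cfg["seed"])
        )
        for metric, curve in curves.items():
            for s, v in zip(curve.sparsities, curve.values):
                value_rows.append((sid, metric, s, v))
            auc_rows.append((sid, metric, curve.auc))
        for short in ("Dc", "Bc"):
            for r_idx, rid in enumerate(net.region_ids):
                auc_rows.append((sid, f"{short}_r{rid}", nodal[f"{short}_auc"][r_idx]))
    values = pd.DataFrame(value_rows, columns=["subject_id", "metric", "sparsity", "value"])
    aucs = pd.DataFrame(auc_rows, columns=["subject_id", "metric", "auc"])
    vpath, apath = out / "metric_values.tsv", out / "metric_aucs.tsv"
    _write_table(values, vpath, cfg)
    _write_table(aucs, apath, cfg)
    return vpath, apath


def _split_cohort(cohort: pd.DataFrame, netdir: Path):
    pats = cohort[cohort["group"] == "patient"]
    cons = cohort[cohort["group"] == "control"]
    if len(pats) == 0 or len(cons) == 0:
        raise DataError("cohort must contain both patients and controls")
    pat_mats = _load_networks(netdir, pats["subject_id"])
    con_mats = _load_networks(netdir, cons["subject_id"])
    pat_tab = feature_table(pat_mats, "patient", pats["age"].to_numpy(), pats["sex"].to_numpy())
    con_tab = feature_table(con_mats, "control", cons["age"].to_numpy(), cons["sex"].to_numpy())
    return pats, cons, pat_tab, con_tab


def run_compare_groups(cfg: dict, datadir, netdir, outdir, metric_aucs: Path | None = None) -> dict:
    """Edgewise, global-AUC and nodal-AUC patient-vs-control comparisons.

    Each family (edges; global metric AUCs; nodal Dc AUCs; nodal Bc AUCs)
    is FDR-corrected separately; uncorrected p-values are kept alongside.
    """
    datadir, netdir, out = Path(datadir), Path(netdir), Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = _load_cohort_table(datadir)
    q = float(cfg.get("stats", {}).get("q", 0.05))
    welch = bool(cfg.get("stats", {}).get("welch", False))
    pats, cons, pat_tab, con_tab = _split_cohort(cohort, netdir)
    results = {}
    edge_cmp = edgewise_comparison(pat_tab, con_tab, q=q, welch=welch)
    _write_table(edge_cmp, out / "edge_comparison.tsv", cfg)
    results["edges"] = edge_cmp
    if metric_aucs is not None and Path(metric_aucs).exists():
        aucs = _read_table(Path(metric_aucs))
        wide = aucs.pivot(index="subject_id", columns="metric", values="auc")
        families = {
            "global": [c for c in wide.columns if not c.startswith(("Dc_", "Bc_"))],
            "nodal_dc": [c for c in wide.columns if c.startswith("Dc_")],
            "nodal_bc": [c for c in wide.columns if c.startswith("Bc_")],
        }
        for fam, columns in families.items():
            if not columns:
                continue
            sub_tabs = []
            for grp_df, label in ((pats, "patient"), (cons, "control")):
                feats = wide.loc[grp_df["subject_id"]].loc[:, columns].reset_index(drop=True)
                sub_tabs.append(
                    SubjectFeatureTable(
                        subject_ids=list(grp_df["subject_id"]),
                        group=np.repeat(label, len(grp_df)),
                        age=grp_df["age"].to_numpy(),
                        sex=grp_df["sex"].to_numpy(),
                        features=feats,
                    )
                )
            fam_cmp = edgewise_comparison(sub_tabs[0], sub_tabs[1], q=q, welch=welch)
            _write_table(fam_cmp, out / f"{fam}_comparison.tsv", cfg)
            results[fam] = fam_cmp
    return results


def _lobe_map(cfg: dict, region_ids: list[int]) -> dict[int, str]:
    paths = cfg.get("paths", {})
    if "lookup" in paths:
        tbl = pd.read_csv(paths["lookup"], sep="\t")
        return dict(zip((int(i) for i in tbl["id"]), (str(g) for g in tbl["lobe"])))
    if len(region_ids) == 90:
        _, _, lobes = atlas_mod.aal90_lookup()
        return lobes
    # fallback: single unlabeled group so aggregation still works
    return {rid: "all" for rid in region_ids}


def run_predict_survival(cfg: dict, datadir, netdir, outdir) -> dict:
    """LOOCV survival prediction, permutation p, and weight aggregation."""
    datadir, netdir, out = Path(datadir), Path(netdir), Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = _load_cohort_table(datadir)
    if "overall_survival_months" not in cohort.columns:
        raise DataError("cohort table lacks overall_survival_months")
    pats, cons, pat_tab, con_tab = _split_cohort(cohort, netdir)
    surv = pats["overall_survival_months"].to_numpy(dtype=float)
    if np.any(~np.isfinite(surv)):
        raise DataError("missing overall survival for some patients")
    records = [
        PatientRecord(
            subject_id=str(sid),
            connection_features=pat_tab.features.iloc[k],
            age=float(pat_tab.age[k]),
            sex=float(pat_tab.sex[k]),
            overall_survival=float(surv[k]),
        )
        for k, sid in enumerate(pats["subject_id"])
    ]
    p_cfg = cfg.get("predict", {})
    kwargs = dict(
        C=float(p_cfg.get("c", 1.0)),
        eps=float(p_cfg.get("epsilon", 0.1)),
        alpha=float(p_cfg.get("alpha", 0.05)),
        selection=p_cfg.get("selection", "per_fold"),
        select_on=p_cfg.get("select_on", "fdr"),
    )
    result = loocv_predict(records, con_tab, **kwargs)
    n_perm = int(p_cfg.get("n_perm", 10000))
    if p_cfg.get("perm_mode", "fast") == "full":
        result.permutation_p = permutation_test_loocv(
            records, con_tab, n_perm=n_perm, seed=int(cfg["seed"]), **kwargs
        )
    else:
        result.permutation_p = permutation_test(result, n_perm=n_perm, seed=int(cfg["seed"]))
    region_ids = _load_networks(netdir, [pats["subject_id"].iloc[0]])[0].region_ids
    result.lobe_weights = summarize_weights(result.mean_weights, _lobe_map(cfg, region_ids))

    _write_table(
        pd.DataFrame(
            {
                "subject_id": result.subject_ids,
                "observed_months": result.observed_raw,
                "observed_deconfounded": result.observed,
                "predicted_deconfounded": result.predicted,
            }
        ),
        out / "predictions.tsv",
        cfg,
    )
    _write_table(
        pd.DataFrame(
            {"connection": result.mean_weights.index, "mean_weight": result.mean_weights.values}
        ),
        out / "edge_weights.tsv",
        cfg,
    )
    _write_table(
        pd.DataFrame(
            sorted(result.lobe_weights.items()), columns=["lobe", "weight"]
        ),
        out / "lobe_weights.tsv",
        cfg,
    )
    summary = {
        "pearson_r": result.pearson_r,
        "permutation_p": result.permutation_p,
        "n_patients": len(records),
        "n_permutations": n_perm,
        "mean_n_selected": float(np.mean(result.n_selected_per_fold)),
        **_meta(cfg),
    }
    with open(out / "prediction_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def run_all(cfg: dict, outdir) -> dict:
    """simulate -> build (if needed) -> graph metrics -> compare -> predict."""
    out = Path(outdir)
    datadir = out / "data"
    netdir = out / "networks"
    run_simulate(cfg, datadir)
    if cfg.get("simulate", {}).get("mode", "direct") == "roi":
        run_build_networks(cfg, datadir, netdir)
    else:
        netdir = datadir  # direct mode already wrote .klsnet.tsv files
    _, apath = run_graph_metrics(cfg, netdir, out / "graph")
    run_compare_groups(cfg, datadir, netdir, out / "stats", metric_aucs=apath)
    return run_predict_survival(cfg, datadir, netdir, out / "predict")
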