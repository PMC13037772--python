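"""End-to-end pipeline: features -> end motifs -> qPCR -> TF -> classify -> stats.

Driven by a flat config dict (usually loaded from YAML).  One master seed
fans out to stage-specific seeds by stable hashing of stage names, so each
stage is individually reproducible regardless of stage order.  Outputs are
plain TSV/JSON; rerunning with an identical config and seed reproduces them
byte for byte.  On a stage failure, outputs of completed stages are retained
and MANIFEST.json records how far the run got.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import cohort_stats as cst
from . import end_motifs as em
from . import fragment_metrics as fm
from . import qpcr_quant as qq
from . import tumor_fraction as tfmod
from .core_io import Genome, read_fragment_tsv, read_sample_sheet, write_feature_table

log = logging.getLogger("cffrag")

DEFAULT_CONFIG = {
    "reference": None,          # FASTA path
    "fragments_dir": None,      # directory of <sample_id>.tsv fragment tables
    "sample_sheet": None,       # samples.csv
    "qpcr_csv": None,           # replicate-level Cq table
    "dilutions_csv": None,      # standard-curve series
    "out": None,                # output directory
    "master_seed": 0,
    "end_motif_k": 5,
    "end_motif_background_n": 50_000,
    "bin_size": tfmod.BIN_SIZE,
    "cv_mode": "all_samples",
    "n_trees": clf.N_TREES,
    "target_specificities": [0.90, 0.95],
}

STAGES = ["features", "endmotifs", "qpcr", "tf", "classify", "stats"]


def stage_seed(master_seed: int, stage: str) -> int:
    return zlib.crc32(f"{master_seed}:{stage}".encode()) % (2**31)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        import yaml

        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = {**DEFAULT_CONFIG, **user}
    for key in ("reference", "fragments_dir", "sample_sheet", "qpcr_csv", "out"):
        if cfg[key] is None:
            raise ValueError(f"config key {key!r} is required")
        if key != "out" and not Path(cfg[key]).exists():
            raise FileNotFoundError(f"config {key}: {cfg[key]} does not exist")
    return cfg


def run_pipeline(config) -> dict:
    """Run all stages; returns the aggregated report dict (also written to disk)."""
    cfg = load_config(config)
    out = Path(cfg["out"])
    out.mkdir(parents=True, exist_ok=True)
    for key, value in sorted(cfg.items()):
        log.info("config %s = %r", key, value)

    manifest: dict = {"completed": [], "failed": None}
    report: dict = {"seed": cfg["master_seed"]}
    state: dict = {}
    try:
        for stage in STAGES:
            log.info("stage %s (seed %d)", stage, stage_seed(cfg["master_seed"], stage))
            _RUNNERS[stage](cfg, out, state, report)
            manifest["completed"].append(stage)
    except Exception as exc:
        manifest["failed"] = {"stage": stage, "error": str(exc)}
        _write_json(out / "MANIFEST.json", manifest)
        raise
    _write_json(out / "MANIFEST.json", manifest)
    _write_json(out / "report.json", report)
    return report


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _sample_fragments_path(cfg, sample_id: str) -> Path:
    return Path(cfg["fragments_dir"]) / f"{sample_id}.tsv"


def _stage_features(cfg, out, state, report):
    samples = read_sample_sheet(cfg["sample_sheet"])
    state["samples"] = samples
    rows = []
    hists = {}
    for sample_id in samples["sample_id"]:
        frags = list(read_fragment_tsv(_sample_fragments_path(cfg, sample_id)))
        hist = fm.length_histogram(frags)
        hists[sample_id] = hist
        feats = fm.size_features(hist)
        rows.append({"sample_id": sample_id, "prop_short": feats.prop_short,
                     "prop_long": feats.prop_long, "prop_electro": feats.prop_electro,
                     "modal_size": feats.modal_size, "periodicity": feats.periodicity,
                     "n_fragments": feats.n_total})
    features = pd.DataFrame(rows)
    state["features"] = features
    state["histograms"] = hists
    write_feature_table(features, out / "features.tsv")
    report["n_samples"] = len(features)


def _stage_endmotifs(cfg, out, state, report):
    genome = Genome.from_fasta(cfg["reference"])
    state["genome"] = genome
    seed = stage_seed(cfg["master_seed"], "endmotifs")
    samples = state["samples"]
    per_group: dict[str, list] = {}
    rows = []
    for sample_id, group in zip(samples["sample_id"], samples["group"]):
        frags = list(read_fragment_tsv(_sample_fragments_path(cfg, sample_id)))
        mat = em.end_context_frequencies(frags, genome, k=cfg["end_motif_k"])
        bias = em.bias_vs_background(mat, genome, cfg["end_motif_background_n"], seed)
        per_group.setdefault(group, []).append(bias)
        for i, pos in enumerate(mat.positions):
            for b, base in enumerate(em.BASES):
                rows.append({"sample_id": sample_id, "group": group,
                             "position": int(pos), "base": base,
                             "frequency": mat.values[i, b],
                             "bias": bias.values[i, b]})
    pd.DataFrame(rows).to_csv(out / "endmotifs.tsv", sep="\t", index=False)
    summary = {}
    if len(per_group) == 2:
        (ga, ma), (gb, mb) = sorted(per_group.items())
        diff = em.group_difference(ma, mb)
        summary["difference"] = {"a": ga, "b": gb, "matrix": diff.tolist()}
    _write_json(out / "endmotifs.json", summary)


def _stage_qpcr(cfg, out, state, report):
    qpcr = qq.read_qpcr_csv(cfg["qpcr_csv"])
    if cfg["dilutions_csv"]:
        curve = qq.fit_standard_curve(qq.read_dilution_csv(cfg["dilutions_csv"]))
    else:
        from .synthetic_cohort import DEFAULT_CURVE as curve  # noqa: N811
    quant = qq.quantify_samples(qpcr, curve)
    state["quant"] = quant
    quant.to_csv(out / "quant.tsv", sep="\t", index=False)
    report["standard_curve"] = {"slope": curve.slope, "intercept": curve.intercept,
                                "r_squared": curve.r_squared,
                                "efficiency": curve.efficiency}


def _stage_tf(cfg, out, state, report):
    genome = state["genome"]
    samples = state["samples"]
    rows = []
    for sample_id in samples["sample_id"]:
        frags = read_fragment_tsv(_sample_fragments_path(cfg, sample_id))
        bins = tfmod.bin_counts(frags, genome, cfg["bin_size"])
        bins = tfmod.gc_correct(bins)
        bins = tfmod.log2_ratios(bins)
        est = tfmod.estimate_tf(bins)
        rows.append({"sample_id": sample_id, "tf": est.tf,
                     "detected": est.detected, "loglik": est.loglik})
    tf_df = pd.DataFrame(rows)
    state["tf"] = tf_df
    tf_df.to_csv(out / "tf.tsv", sep="\t", index=False)
    report["tf_detected"] = int(tf_df["detected"].sum())


def _stage_classify(cfg, out, state, report):
    table = clf.build_feature_table(
        state["samples"],
        state["quant"].set_index("sample_id")["short_index"],
        state["tf"].set_index("sample_id")["tf"],
        state["features"].set_index("sample_id")["prop_short"],
        state["features"].set_index("sample_id")["prop_long"],
    )
    state["table"] = table
    write_feature_table(table, out / "feature_table.tsv")
    seed = stage_seed(cfg["master_seed"], "classify")
    scores = clf.cv_scores(table, cfg["cv_mode"], seed, cfg["n_trees"])
    scores.to_csv(out / "scores.tsv", sep="\t", index=False)
    labels = (scores["group"] == "cancer").to_numpy()
    metrics: dict = {"mode": cfg["cv_mode"],
                     "auc": {"random_forest": clf.roc_auc(scores["score"], labels)}}
    eligible = table[table["sample_id"].isin(scores["sample_id"])]
    y = (eligible["group"] == "cancer").to_numpy()
    for feat in clf.FEATURES:
        vals = eligible[feat].to_numpy()
        metrics["auc"][feat] = clf.roc_auc(vals if feat != "prop_long_wgs" else -vals, y)
    roc = clf.roc_curve_points(scores["score"], labels)
    roc.to_csv(out / "roc.tsv", sep="\t", index=False)
    metrics["operating_points"] = {}
    for target in cfg["target_specificities"]:
        r = clf.sensitivity_at_specificity(scores["score"], labels, target)
        metrics["operating_points"][f"spec_{target:.2f}"] = {
            "sensitivity": r.sensitivity, "specificity": r.specificity,
            "threshold": r.threshold,
            "confusion": {"tp": r.tp, "fp": r.fp, "tn": r.tn, "fn": r.fn},
        }
    _write_json(out / "metrics.json", metrics)
    report["classification"] = metrics


def _stage_stats(cfg, out, state, report):
    table = state["table"]
    rows = []
    healthy = table[table["group"] == "healthy"]
    cancer = table[table["group"] == "cancer"]
    for feat in clf.FEATURES:
        cmp = cst.mann_whitney(cancer[feat], healthy[feat], "cancer", "healthy")
        rows.append({"comparison": feat, "n_cancer": cmp.n_a, "n_healthy": cmp.n_b,
                     "median_cancer": cmp.median_a, "median_healthy": cmp.median_b,
                     "iqr_cancer": cmp.iqr_a, "iqr_healthy": cmp.iqr_b,
                     "U": cmp.u, "p_value": cmp.p_value, "method": cmp.method})
    stats_df = pd.DataFrame(rows)
    stats_df.to_csv(out / "stats.tsv", sep="\t", index=False)
    report["stats"] = {
        r["comparison"]: {"median_cancer": r["median_cancer"],
                          "median_healthy": r["median_healthy"],
                          "p_value": r["p_value"]}
        for r in rows
    }
    rho_short = cst.spearman(table["tf_ichor"], table["prop_short_wgs"])
    rho_long = cst.spearman(table["tf_ichor"], table["prop_long_wgs"])
    report["spearman_tf"] = {"prop_short": rho_short, "prop_long": rho_long}


_RUNNERS = {
    "features": _stage_features,
    "endmotifs": _stage_endmotifs,
    "qpcr": _stage_qpcr,
    "tf": _stage_tf,
    "classify": _stage_classify,
    "stats": _stage_stats,
}
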