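"""Pipeline stages over a cohort directory.

Each stage reads the previous stage's outputs from the shared work
directory, writes its own outputs to a stage-specific subdirectory, logs the
counts at every filter, and records a manifest entry with input/output
checksums. Stages never mutate their inputs; identical config + seed
reproduce identical output checksums.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, diffacc, model, occupancy, score
from .config import PipelineConfig
from .intervals import read_bed, read_bedpe, write_bed
from .manifest import record_stage
from .simulate import simulate_cohort

log = logging.getLogger("kre")

FMT = dict(sep="\t", index=False, float_format="%.6g")


class MissingUpstreamError(FileNotFoundError):
    pass


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingUpstreamError(
            f"missing {path}; run the '{producer}' stage first"
        )
    return path


def _sample_cols(cfg: PipelineConfig, genotype: str, condition: str) -> list[str]:
    return [f"{genotype}_{condition}_{r}" for r in range(1, cfg.cohort.replicates + 1)]


def _stage_dir(cfg: PipelineConfig, stage: str) -> Path:
    d = Path(cfg.workdir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig) -> dict:
    out = _stage_dir(cfg, "cohort")
    cohort_cfg = cfg.cohort
    cohort_cfg.seed = cfg.seed
    truth = simulate_cohort(cohort_cfg, out)
    outputs = [p for p in out.rglob("*") if p.is_file()]
    record_stage(cfg.workdir, "simulate", [], outputs, cfg.config_hash())
    log.info("simulated cohort: %d elements, %d genes, %d features",
             cohort_cfg.n_elements, cohort_cfg.n_genes, cohort_cfg.n_features)
    return {"n_elements": cohort_cfg.n_elements, "truth": truth}


def stage_diffacc(cfg: PipelineConfig) -> dict:
    cohort = Path(cfg.workdir) / "cohort"
    signals_path = _require(cohort / "signals.tsv", "simulate")
    out = _stage_dir(cfg, "diffacc")
    signals = pd.read_csv(signals_path, sep="\t")
    th = cfg.thresholds

    results = {}
    norm_tables = {}
    for genotype in ("ctrl", "egr1kd"):
        stim = _sample_cols(cfg, genotype, "scf")
        ctrl = _sample_cols(cfg, genotype, "pbs")
        common = diffacc.first_pass_common(
            signals, stim, ctrl,
            max_abs_log2fc=np.log2(th.common_max_fc), pseudocount=th.pseudocount,
        )
        norm = diffacc.ma_normalize(
            signals[["element_id"] + stim + ctrl], stim, ctrl, common,
            pseudocount=th.pseudocount,
        )
        norm_tables[genotype] = norm
        norm.to_csv(out / f"normalized_{genotype}.tsv", **FMT)
    stim_c, ctrl_c = _sample_cols(cfg, "ctrl", "scf"), _sample_cols(cfg, "ctrl", "pbs")
    stim_p, ctrl_p = _sample_cols(cfg, "egr1kd", "scf"), _sample_cols(cfg, "egr1kd", "pbs")
    calls = diffacc.call_kres(
        norm_tables["ctrl"], stim_c, ctrl_c,
        fc_threshold=th.fc_threshold, alpha=th.alpha, pseudocount=th.pseudocount,
    )
    calls.to_csv(out / "kre_calls.tsv", **FMT)
    egr1 = diffacc.call_egr1_sensitivity(
        norm_tables["ctrl"], norm_tables["egr1kd"], calls,
        stim_c, ctrl_c, stim_p, ctrl_p,
        fc_threshold=th.fc_threshold, alpha=th.alpha, pseudocount=th.pseudocount,
    )
    egr1.to_csv(out / "egr1_calls.tsv", **FMT)
    counts = calls["label"].value_counts().to_dict()
    log.info("KRE calls: %s; EGR1-sensitive %d / %d responsive",
             counts, int((egr1["label"] == "egr1_sensitive").sum()), len(egr1))
    record_stage(
        cfg.workdir, "diffacc", [signals_path],
        sorted(out.glob("*.tsv")), cfg.config_hash(),
    )
    results.update({"kre_counts": counts, "n_egr1_tested": len(egr1)})
    return results


def stage_annotate(cfg: PipelineConfig) -> dict:
    cohort = Path(cfg.workdir) / "cohort"
    inputs = [
        _require(cohort / name, "simulate")
        for name in ("elements.bed", "de_ctrl.tsv", "de_egr1kd.tsv",
                     "tss.tsv", "contacts.bedpe")
    ]
    out = _stage_dir(cfg, "annotate")
    th = cfg.thresholds
    elements = read_bed(cohort / "elements.bed")
    de_ctrl = pd.read_csv(cohort / "de_ctrl.tsv", sep="\t")
    de_pert = pd.read_csv(cohort / "de_egr1kd.tsv", sep="\t")
    promoters = annotate.read_tss_table(cohort / "tss.tsv")
    contacts = read_bedpe(cohort / "contacts.bedpe")

    classes = annotate.classify_transcripts_egr1(
        de_ctrl, de_pert, fc_threshold=th.fc_threshold, alpha=th.alpha
    )
    classes.to_csv(out / "transcript_classes.tsv", **FMT)
    links = annotate.link_elements(
        elements, promoters, contacts, max_distance=th.link_distance
    )
    links.to_csv(out / "links.tsv", **FMT)
    labels, summary = annotate.label_elements(links, classes)
    labels.to_csv(out / "element_labels.tsv", **FMT)
    summary["unlinked_elements"] = len(elements) - labels.shape[0]
    log.info("annotation: %s", summary)
    record_stage(cfg.workdir, "annotate", inputs,
                 sorted(out.glob("*.tsv")), cfg.config_hash())
    return summary


def stage_features(cfg: PipelineConfig) -> dict:
    cohort = Path(cfg.workdir) / "cohort"
    manifest_path = _require(cohort / "chip_manifest.tsv", "simulate")
    elements_path = _require(cohort / "elements.bed", "simulate")
    out = _stage_dir(cfg, "features")
    elements = read_bed(elements_path)
    catalog = occupancy.read_catalog(
        manifest_path, merge_contexts=cfg.switches.merge_contexts
    )
    merged = occupancy.merge_replicates(catalog)
    kept, summary = occupancy.qc_filter(
        merged, elements, min_peaks=cfg.thresholds.min_peaks
    )
    matrix = occupancy.build_matrix(elements, kept)
    matrix.to_csv(out / "occupancy.tsv", sep="\t")
    meta = occupancy.occupancy_fractions(matrix).reset_index()
    meta.columns = ["feature", "occupancy_fraction"]
    feats = pd.read_csv(cohort / "features.tsv", sep="\t")
    meta = meta.merge(feats, on="feature", how="left")
    meta["footprint_scf"] = meta["footprint_scf"].fillna(False)
    meta.to_csv(out / "feature_meta.tsv", **FMT)
    log.info("occupancy: %d datasets -> %d merged -> %d retained factors",
             len(catalog), len(merged), len(kept))
    record_stage(cfg.workdir, "features", [manifest_path, elements_path],
                 sorted(out.glob("*.tsv")), cfg.config_hash())
    summary["matrix_shape"] = list(matrix.shape)
    return summary


def _training_sets(cfg: PipelineConfig) -> dict[str, model.TrainingSet]:
    """Kit-responsiveness and EGR1-sensitivity training sets from labels."""
    labels_path = _require(
        Path(cfg.workdir) / "annotate" / "element_labels.tsv", "annotate"
    )
    occ_path = _require(
        Path(cfg.workdir) / "features" / "occupancy.tsv", "features"
    )
    labels = pd.read_csv(labels_path, sep="\t")
    occ = pd.read_csv(occ_path, sep="\t", index_col="element_id")
    labels = labels[labels["element_id"].isin(occ.index)]
    sets = {}
    y_kit = labels.set_index("element_id")["responsive"].astype(int)
    sets["kit"] = model.TrainingSet(occ.loc[y_kit.index], y_kit.to_numpy())
    if "egr1_class" in labels.columns:
        resp = labels[labels["egr1_class"].isin(["sensitive", "insensitive"])]
        if resp["egr1_class"].nunique() == 2:
            y = (resp.set_index("element_id")["egr1_class"] == "sensitive").astype(int)
            sets["egr1"] = model.TrainingSet(occ.loc[y.index], y.to_numpy())
    return sets


def stage_train(cfg: PipelineConfig) -> dict:
    out = _stage_dir(cfg, "train")
    meta_path = _require(
        Path(cfg.workdir) / "features" / "feature_meta.tsv", "features"
    )
    meta = pd.read_csv(meta_path, sep="\t")
    footprints = meta.set_index("feature")["footprint_scf"]
    sets = _training_sets(cfg)
    report = {}
    for name, ts in sets.items():
        metrics = model.kfold_evaluate(
            ts, k=cfg.k_folds, seed=cfg.seed, hyperparams=cfg.hyperparams,
            k_neighbors=cfg.smote_k_neighbors,
        )
        pd.DataFrame(
            {"fold": range(1, metrics.k + 1), "accuracy": metrics.accuracy,
             "auroc": metrics.auroc, "aupr": metrics.aupr}
        ).to_csv(out / f"{name}_metrics.tsv", **FMT)
        balanced = model.smote_balance(
            ts, k_neighbors=cfg.smote_k_neighbors, seed=cfg.seed
        )
        fitted = model.train_classifier(balanced, cfg.hyperparams, seed=cfg.seed)
        model.save_model(fitted, out / f"{name}_model.json")
        attr = model.attribute_features(fitted, ts.features)
        model.attribution_scores(attr).reset_index().rename(
            columns={"index": "feature"}
        ).to_csv(out / f"{name}_attributions.tsv", **FMT)
        pos = set(ts.features.index[ts.labels == 1])
        neg = set(ts.features.index[ts.labels == 0])
        fw = model.log_odds_features(ts.features, pos, neg)
        fw = model.select_predictors(
            fw, footprints, min_fraction=cfg.thresholds.min_occupancy_fraction
        )
        fw.to_csv(out / f"{name}_feature_weights.tsv", **FMT)
        report[name] = metrics.summary()
        report[name]["n_selected"] = int(fw["selected"].sum())
        log.info("%s model: %s", name, report[name])
    record_stage(
        cfg.workdir, "train",
        [meta_path], sorted(list(out.glob("*.tsv")) + list(out.glob("*.json"))),
        cfg.config_hash(),
    )
    return report


def stage_score(cfg: PipelineConfig) -> dict:
    cohort = Path(cfg.workdir) / "cohort"
    ann_path = _require(cohort / "annotations.tsv", "simulate")
    occ_path = _require(Path(cfg.workdir) / "features" / "occupancy.tsv", "features")
    fw_path = _require(
        Path(cfg.workdir) / "train" / "kit_feature_weights.tsv", "train"
    )
    calls_path = _require(
        Path(cfg.workdir) / "diffacc" / "kre_calls.tsv", "diffacc"
    )
    out = _stage_dir(cfg, "score")
    annotations = pd.read_csv(ann_path, sep="\t")
    occ = pd.read_csv(occ_path, sep="\t", index_col="element_id")
    weights = pd.read_csv(fw_path, sep="\t")
    calls = pd.read_csv(calls_path, sep="\t")
    kre_ids = list(calls.loc[calls["label"] != "insensitive", "element_id"])
    table, summary = score.score_all(
        annotations, occ, weights,
        element_ids=kre_ids,
        high_threshold=cfg.thresholds.high_score,
        kit_context_penalty=cfg.switches.kit_context_penalty,
        conservation_bonus=cfg.switches.conservation_bonus,
    )
    table.to_csv(out / "kre_scores.tsv", **FMT)
    log.info("scoring: %s", summary)
    record_stage(cfg.workdir, "score",
                 [ann_path, occ_path, fw_path, calls_path],
                 [out / "kre_scores.tsv"], cfg.config_hash())
    return summary


def stage_transfer(cfg: PipelineConfig) -> dict:
    cohort = Path(cfg.workdir) / "cohort"
    calls_path = _require(Path(cfg.workdir) / "diffacc" / "kre_calls.tsv", "diffacc")
    acc_path = _require(cohort / "mep_accessible.bed", "simulate")
    enh_path = _require(cohort / "mep_enhancers.bed", "simulate")
    out = _stage_dir(cfg, "transfer")
    elements = read_bed(cohort / "elements.bed")
    calls = pd.read_csv(calls_path, sep="\t")
    kre_ids = set(calls.loc[calls["label"] != "insensitive", "element_id"])
    from .intervals import IntervalSet

    kres = IntervalSet([iv for iv in elements if iv.id in kre_ids]).sort()
    part = score.transfer_partition(kres, read_bed(acc_path), read_bed(enh_path))
    write_bed(part["shared"], out / "shared.bed")
    write_bed(part["unique"], out / "unique_control_group.bed")
    write_bed(part["enhancer_overlap"], out / "enhancer_overlap.bed")
    frac = pd.DataFrame(
        [
            {"set": "shared", "count": part["n_shared"], "total": part["n"],
             "fraction": part["shared_fraction"]},
            {"set": "unique", "count": part["n_unique"], "total": part["n"],
             "fraction": part["n_unique"] / part["n"] if part["n"] else 0.0},
            {"set": "enhancer_overlap", "count": part["n_enhancer"],
             "total": part["n"], "fraction": part["enhancer_fraction"]},
        ]
    )
    frac.to_csv(out / "fractions.tsv", **FMT)
    log.info("transfer: shared %.1f%%, enhancer %.1f%%",
             100 * part["shared_fraction"], 100 * part["enhancer_fraction"])
    record_stage(cfg.workdir, "transfer",
                 [calls_path, acc_path, enh_path],
                 sorted(list(out.glob("*.bed")) + [out / "fractions.tsv"]),
                 cfg.config_hash())
    return {k: part[k] for k in
            ("n", "n_shared", "n_unique", "n_enhancer",
             "shared_fraction", "enhancer_fraction")}


STAGES = {
    "simulate": stage_simulate,
    "diffacc": stage_diffacc,
    "annotate": stage_annotate,
    "features": stage_features,
    "train": stage_train,
    "score": stage_score,
    "transfer": stage_transfer,
}


def run_demo(cfg: PipelineConfig) -> dict:
    """End-to-end synthetic run; returns and writes a summary report."""
    report: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    stage_simulate(cfg)
    report["diffacc"] = stage_diffacc(cfg)
    report["annotate"] = stage_annotate(cfg)
    report["features"] = {
        k: v for k, v in stage_features(cfg).items() if k != "dropped"
    }
    report["train"] = stage_train(cfg)
    report["score"] = stage_score(cfg)
    report["transfer"] = stage_transfer(cfg)
    # planted-truth comparison: selected features vs planted columns
    truth_feats = pd.read_csv(
        Path(cfg.workdir) / "cohort" / "truth" / "features.tsv", sep="\t"
    )
    fw = pd.read_csv(
        Path(cfg.workdir) / "train" / "kit_feature_weights.tsv", sep="\t"
    )
    planted = set(truth_feats.loc[truth_feats["planted"] == "kit", "feature"])
    selected = set(fw.loc[fw["selected"], "feature"])
    report["planted_recovery"] = {
        "n_planted": len(planted),
        "n_selected": len(selected),
        "planted_selected": len(planted & selected),
    }
    path = Path(cfg.workdir) / "demo_report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    return report
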