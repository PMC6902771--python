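"""End-to-end orchestration replicating the study design on synthetic cohorts.

The replica runs, from one master seed:

1. simulate the case-control cohort (157 diffuse glioma, 157 + 157 controls)
   and preprocess it (positive call -> background subtraction ->
   internal-control normalization -> 64-unit robustness filter);
2. split every annotation group 100:57 into training set 1 / validation set 1;
3. beam-search miRNA panels by LOOCV accuracy on training set 1, stop panel
   growth at the last significant DeLong AUC improvement, recentre the cutoff
   at the Youden optimum, and evaluate on validation set 1;
4. simulate the 3-tumor cohort (85 GBM / 42 PCNSL / 28 metastatic), hold out a
   stratified fifth as validation set 2, build the paired-LASSO 3-class index
   on training set 2 (50 repeated 4:1 splits) and cross-tabulate both sets.

Every number in the report is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, lda_index, performance, preprocess, simulate, three_tumor


@dataclass
class StudyConfig:
    seed: int = 0
    train_fraction_two_group: float = 100.0 / 157.0
    max_panel_size: int = 5
    beam_width: int = 50
    alpha: float = 0.05
    threshold: float = preprocess.DEFAULT_THRESHOLD
    prevalence: float = preprocess.DEFAULT_PREVALENCE
    controls: tuple = preprocess.DEFAULT_CONTROLS
    n_repeats: int = 50
    three_tumor_train_fraction: float = 0.8
    two_group_overrides: dict = field(default_factory=dict)
    three_tumor_overrides: dict = field(default_factory=dict)


def version_info(config: StudyConfig | None = None) -> dict:
    info = {"package": "mirindex", "version": __version__}
    if config is not None:
        info["config"] = asdict(config)
    return info


def split_counts(labels, mask) -> dict:
    labels = np.asarray(labels, dtype=object)
    return {
        str(g): [int((labels[mask] == g).sum()), int((labels[~mask] == g).sum())]
        for g in sorted(set(labels))
    }


def _perf_dict(perf: performance.DiagnosticPerformance) -> dict:
    out = {}
    for name in ("sensitivity", "specificity", "accuracy", "auc"):
        value = getattr(perf, name)
        if value is None:
            continue
        lo, hi = perf.ci[name]
        out[name] = round(float(value), 6)
        out[f"{name}_ci"] = [round(float(lo), 6), round(float(hi), 6)]
    out["n_positive"] = perf.n_positive
    out["n_negative"] = perf.n_negative
    return out


def run_two_group_arm(config: StudyConfig, seed_seq: np.random.SeedSequence) -> dict:
    sim_seed, split_seed = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(2)]
    sim_cfg = simulate.two_group_config(seed=sim_seed, **config.two_group_overrides)
    raw, ann, truth = simulate.generate_cohort(sim_cfg)
    norm, report = preprocess.preprocess_pipeline(
        raw, ann, controls=config.controls,
        threshold=config.threshold, prevalence=config.prevalence,
    )
    candidates = [m for m in report.kept_mirnas if m not in set(config.controls)]
    groups = ann.groups_for(norm.sample_ids)
    rng = np.random.default_rng(split_seed)
    train_mask = three_tumor.stratified_split(
        groups, config.train_fraction_two_group, rng
    )
    y = groups == "diffuse_glioma"
    X = norm.log2_for(candidates)

    table = lda_index.search_best_combinations(
        X[train_mask], y[train_mask], candidates,
        max_size=config.max_panel_size, beam_width=config.beam_width,
        positive_label="diffuse_glioma", negative_label="noncancer",
    )
    k_star = lda_index.select_final_size(table, alpha=config.alpha)
    chosen = table.row(k_star)
    idx = [candidates.index(m) for m in chosen.mirna_ids]
    model = lda_index.calibrate_cutoff_youden(
        chosen.model, X[train_mask][:, idx], y[train_mask]
    )

    val_scores, val_calls = lda_index.score_samples(model, X[~train_mask][:, idx])
    perf = performance.confusion_metrics(val_calls, y[~train_mask])
    auc, lo, hi = performance.roc_auc(val_scores, y[~train_mask])
    perf.auc = auc
    perf.ci["auc"] = (lo, hi)

    train_scores, train_calls = lda_index.score_samples(model, X[train_mask][:, idx])
    train_perf = performance.confusion_metrics(train_calls, y[train_mask])
    t_auc, t_lo, t_hi = performance.roc_auc(train_scores, y[train_mask])
    train_perf.auc = t_auc
    train_perf.ci["auc"] = (t_lo, t_hi)

    return {
        "seeds": {"simulate": sim_seed, "split": split_seed},
        "n_filtered_mirnas": len(report.kept_mirnas),
        "split_counts_train_validation": split_counts(groups, train_mask),
        "candidate_table": [
            {
                "size": r.size,
                "mirnas": list(r.mirna_ids),
                "loocv_accuracy": round(r.loocv_accuracy, 6),
                "apparent_auc": round(r.apparent_auc, 6),
                "p_vs_previous": None
                if r.p_vs_previous is None
                else round(r.p_vs_previous, 6),
            }
            for r in table.rows
        ],
        "chosen_size": k_star,
        "chosen_panel": list(chosen.mirna_ids),
        "planted_markers": {
            g: list(ids) for g, ids in truth.markers.items()
        },
        "index_model": model.to_document().payload,
        "training_performance": _perf_dict(train_perf),
        "validation_performance": _perf_dict(perf),
    }


def run_three_tumor_arm(config: StudyConfig, seed_seq: np.random.SeedSequence) -> dict:
    sim_seed, split_seed, fit_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(3)
    ]
    sim_cfg = simulate.three_tumor_config(seed=sim_seed, **config.three_tumor_overrides)
    raw, ann, truth = simulate.generate_cohort(sim_cfg)
    norm, report = preprocess.preprocess_pipeline(
        raw, ann, controls=config.controls,
        threshold=config.threshold, prevalence=config.prevalence,
    )
    candidates = [m for m in report.kept_mirnas if m not in set(config.controls)]
    groups = ann.groups_for(norm.sample_ids)
    rng = np.random.default_rng(split_seed)
    train_mask = three_tumor.stratified_split(
        groups, config.three_tumor_train_fraction, rng
    )
    X = norm.log2_for(candidates)
    classes = tuple(sim_cfg.group_sizes)
    result = three_tumor.build_three_tumor_index(
        X[train_mask], groups[train_mask], candidates,
        classes=classes, n_repeats=config.n_repeats, seed=fit_seed,
    )
    rep = result.representative
    train_preds = three_tumor.classify_matrix(rep, X[train_mask], candidates)
    val_preds = three_tumor.classify_matrix(rep, X[~train_mask], candidates)
    tab_train = three_tumor.cross_tabulate(train_preds, groups[train_mask], classes)
    tab_val = three_tumor.cross_tabulate(val_preds, groups[~train_mask], classes)
    contrast_stats = {}
    for c, summary in result.contrast_summaries.items():
        auc_m, auc_lo, auc_hi = summary.mean_ci(summary.aucs)
        n_m, n_lo, n_hi = summary.mean_ci(summary.feature_counts)
        contrast_stats[c] = {
            "mean_heldout_auc": round(auc_m, 6),
            "heldout_auc_ci": [round(auc_lo, 6), round(auc_hi, 6)],
            "mean_n_mirnas": round(n_m, 6),
            "n_mirnas_ci": [round(n_lo, 6), round(n_hi, 6)],
        }
    return {
        "seeds": {"simulate": sim_seed, "split": split_seed, "fit": fit_seed},
        "split_counts_train_validation": split_counts(groups, train_mask),
        "contrasts": contrast_stats,
        "pairing_mean_accuracy": {
            f"{a}+{b}": round(float(np.mean(accs)), 6)
            for (a, b), accs in result.pairing_accuracies.items()
        },
        "representative": {
            "classes": list(rep.classes),
            "n_mirnas": len(rep.mirna_union),
            "training_accuracy": round(result.training_accuracy, 6),
        },
        "validation_accuracy": round(
            three_tumor.three_class_accuracy(val_preds, groups[~train_mask]), 6
        ),
        "cross_tab_training": tab_train.counts.to_dict(),
        "cross_tab_validation": tab_val.counts.to_dict(),
    }


def run_study_replica(config: StudyConfig | None = None, out_dir=None) -> dict:
    """Execute both arms and return (optionally write) the structured report."""
    config = config or StudyConfig()
    root = np.random.SeedSequence(config.seed)
    two_group_seq, three_tumor_seq = root.spawn(2)
    report = {
        "version_info": version_info(config),
        "glioma_index_arm": run_two_group_arm(config, two_group_seq),
        "three_tumor_arm": run_three_tumor_arm(config, three_tumor_seq),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        target = out_dir / "study_replica_report.json"
        if target.exists():
            raise FileExistsError(f"{target} exists; refusing to overwrite")
        target.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
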