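"""Simulation studies that measure whether the pipeline recovers planted truth.

These are the package's own operating-characteristic checks, run on cohorts
from :mod:`mirindex.simulate`:

* ``single_marker_recovery`` — one strong marker (log2 FC 2, biological SD
  0.5) among 49 null miRNAs at n = 40 + 40; how often is it the size-1
  combination-search winner?
* ``panel_recovery`` — three planted markers (|log2 FC| 1.5) among 200 nulls
  at n = 100 + 200; how often does the final selected panel contain at least
  two of them?
* ``null_loocv_accuracy`` — permuted-label null data (n = 50, 3 features);
  LOOCV accuracy should sit at chance.
"""

from __future__ import annotations

import numpy as np

from . import lda_index, preprocess, simulate


def _child_seeds(seed: int, n: int) -> list:
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n)]


def _searchable_cohort(cfg):
    raw, ann, truth = simulate.generate_cohort(cfg)
    norm, report = preprocess.preprocess_pipeline(raw, ann)
    candidates = [
        m for m in report.kept_mirnas if m not in set(preprocess.DEFAULT_CONTROLS)
    ]
    groups = ann.groups_for(norm.sample_ids)
    y = groups == "diffuse_glioma"
    X = norm.log2_for(candidates)
    return X, y, candidates, truth


def single_marker_recovery(n_reps: int = 100, seed: int = 0) -> float:
    """Fraction of replicates in which the planted marker wins the size-1 search."""
    wins = 0
    for rep_seed in _child_seeds(seed, n_reps):
        cfg = simulate.SimulationConfig(
            n_mirnas=53,  # 49 nulls + 1 marker + 3 controls
            group_sizes={"diffuse_glioma": 40, "noncancer_1": 40},
            marker_effects={"diffuse_glioma": [2.0]},
            biological_sd=0.5,
            baseline_log2_mean_range=(8.0, 13.0),
            group_cohorts={
                "diffuse_glioma": "biobank_minus20",
                "noncancer_1": "biobank_minus20",
            },
            seed=rep_seed,
        )
        X, y, candidates, truth = _searchable_cohort(cfg)
        table = lda_index.search_best_combinations(X, y, candidates, max_size=1)
        marker = next(iter(truth.markers["diffuse_glioma"]))
        wins += table.rows[0].mirna_ids[0] == marker
    return wins / n_reps


def panel_recovery(n_reps: int = 50, seed: int = 0, min_recovered: int = 2) -> float:
    """Fraction of replicates whose final panel holds >= 2 of 3 planted markers."""
    hits = 0
    for rep_seed in _child_seeds(seed, n_reps):
        cfg = simulate.SimulationConfig(
            n_mirnas=206,  # 200 nulls + 3 markers + 3 controls
            group_sizes={
                "diffuse_glioma": 100,
                "noncancer_1": 100,
                "noncancer_2": 100,
            },
            marker_effects={"diffuse_glioma": [1.5, 1.5, -1.5]},
            baseline_log2_mean_range=(8.0, 13.0),
            seed=rep_seed,
        )
        X, y, candidates, truth = _searchable_cohort(cfg)
        table = lda_index.search_best_combinations(
            X, y, candidates, max_size=5, beam_width=50
        )
        k = lda_index.select_final_size(table)
        panel = set(table.row(k).mirna_ids)
        markers = set(truth.markers["diffuse_glioma"])
        hits += len(panel & markers) >= min_recovered
    return hits / n_reps


def null_loocv_accuracy(n_reps: int = 200, seed: int = 0, n: int = 50) -> float:
    """Mean LOOCV accuracy of a 3-feature Fisher LDA on permuted-label null data."""
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_reps):
        X = rng.normal(size=(n, 3))
        y = np.zeros(n, dtype=bool)
        y[rng.permutation(n)[: n // 2]] = True
        acc, _, _, _ = lda_index.loocv_subset_stats(X, y, range(3))
        accs.append(acc)
    return float(np.mean(accs))
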