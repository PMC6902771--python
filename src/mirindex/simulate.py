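"""Synthetic serum-miRNA cohort generator with planted ground truth.

Measurement model, per miRNA i and sample j:

    log2 true signal = b_i + effect_i(group_j) + s_j + o_c(j) + eps_ij

with per-miRNA baseline b_i ~ Uniform(baseline range), per-sample log2 scale
factor s_j ~ Normal(0, sample_scale_sd) (multiplicative on the raw scale, the
quantity internal-control normalization must remove), per-cohort additive
batch offset o_c (mimicking biobank -20C vs clinic -80C storage arms), and
log2 biological noise eps.  Internal-control miRNAs get zero group effect and
a smaller noise SD (they are stable by construction).  On the linear scale the
recorded signal is 2^(log2 signal) plus additive truncated-Gaussian background
noise; the background estimate is an independent draw from the same background
distribution, so detection censoring (signal <= background) arises naturally
for dim probes.

miRNAs are mutually independent; real serum co-expression structure is not
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import RawExpressionMatrix, SampleAnnotationTable
from .preprocess import DEFAULT_CONTROLS

#: baselines below this (log2) may be censored by background; controls and
#: planted markers are drawn above it so they stay detectable and pass the
#: 64-intensity-unit robustness filter.
STABLE_BASELINE_MIN = 8.0


@dataclass
class SimulationConfig:
    n_mirnas: int = 359
    group_sizes: dict = field(
        default_factory=lambda: {
            "diffuse_glioma": 157,
            "noncancer_1": 157,
            "noncancer_2": 157,
        }
    )
    # group label -> list of per-marker log2 fold changes (vs all other groups)
    marker_effects: dict = field(
        default_factory=lambda: {"diffuse_glioma": [1.5, 1.2, -1.0]}
    )
    baseline_log2_mean_range: tuple = (4.0, 13.0)
    biological_sd: float = 0.6
    sample_scale_sd: float = 0.5
    control_ids: tuple = DEFAULT_CONTROLS
    control_sd: float = 0.1
    background_mean: float = 32.0
    background_sd: float = 8.0
    # cohort label -> additive log2 batch offset
    cohort_offsets: dict = field(
        default_factory=lambda: {"biobank_minus20": 0.0, "clinic_minus80": 0.3}
    )
    # group label -> cohort label
    group_cohorts: dict = field(
        default_factory=lambda: {
            "diffuse_glioma": "biobank_minus20",
            "noncancer_1": "biobank_minus20",
            "noncancer_2": "clinic_minus80",
        }
    )
    seed: int = 0

    def __post_init__(self):
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("all group sizes must be >= 1")
        if self.control_sd > self.biological_sd:
            raise ValueError("control_sd must not exceed biological_sd")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        n_markers = sum(len(v) for v in self.marker_effects.values())
        if self.n_mirnas < len(self.control_ids) + n_markers:
            raise ValueError("n_mirnas too small for controls + markers")


@dataclass
class GroundTruth:
    markers: dict  # group label -> {mirna_id: log2 effect}
    scale_factors: pd.Series  # per-sample linear scale 2**s_j
    cohorts: pd.Series  # per-sample cohort label


def _truncated_normal(rng, mean, sd, size):
    draws = rng.normal(mean, sd, size)
    return np.maximum(draws, 0.0)


def generate_cohort(config: SimulationConfig):
    """Returns (RawExpressionMatrix, SampleAnnotationTable, GroundTruth)."""
    n_controls = len(config.control_ids)
    n_other = config.n_mirnas - n_controls
    mirna_ids = [f"miR-sim-{i + 1:04d}" for i in range(n_other)] + list(config.control_ids)

    groups = []
    for g, n in config.group_sizes.items():
        groups.extend([g] * n)
    groups = np.array(groups, dtype=object)
    n_samples = len(groups)
    sample_ids = [f"S{j + 1:04d}" for j in range(n_samples)]

    ss = np.random.SeedSequence(config.seed)
    rng_feat, rng_sample, rng_noise, rng_meta = [
        np.random.default_rng(c) for c in ss.spawn(4)
    ]

    # markers: first len(effects) simulated (non-control) miRNAs per group block
    markers: dict = {}
    cursor = 0
    effect_matrix = np.zeros((config.n_mirnas, n_samples))
    for g, effects in config.marker_effects.items():
        if g not in config.group_sizes:
            raise ValueError(f"marker group {g!r} not in group_sizes")
        ids = {}
        for e in effects:
            mid = mirna_ids[cursor]
            if mid in config.control_ids:
                raise ValueError(f"control id {mid!r} collides with a marker")
            ids[mid] = float(e)
            effect_matrix[cursor, groups == g] = e
            cursor += 1
        markers[g] = ids

    lo, hi = config.baseline_log2_mean_range
    baselines = rng_feat.uniform(lo, hi, config.n_mirnas)
    stable_lo = max(lo, STABLE_BASELINE_MIN)
    # markers (leading rows) and controls (trailing rows) stay bright
    n_marker_rows = cursor
    baselines[:n_marker_rows] = rng_feat.uniform(stable_lo, hi, n_marker_rows)
    baselines[n_other:] = rng_feat.uniform(stable_lo, hi, n_controls)

    s_j = rng_sample.normal(0.0, config.sample_scale_sd, n_samples)
    cohorts = np.array([config.group_cohorts[g] for g in groups], dtype=object)
    offsets = np.array([config.cohort_offsets[c] for c in cohorts])

    sd = np.full(config.n_mirnas, config.biological_sd)
    sd[n_other:] = config.control_sd
    eps = rng_noise.normal(0.0, 1.0, (config.n_mirnas, n_samples)) * sd[:, None]

    log2_signal = (
        baselines[:, None] + effect_matrix + (s_j + offsets)[None, :] + eps
    )
    true_linear = np.exp2(log2_signal)
    bg_noise = _truncated_normal(
        rng_noise, config.background_mean, config.background_sd,
        (config.n_mirnas, n_samples),
    )
    background = _truncated_normal(
        rng_noise, config.background_mean, config.background_sd,
        (config.n_mirnas, n_samples),
    )
    signal = true_linear + bg_noise

    ages = rng_meta.integers(20, 81, n_samples)
    sexes = rng_meta.choice(["M", "F"], n_samples)
    ann = SampleAnnotationTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": groups,
                "age": ages,
                "sex": sexes,
                "cohort": cohorts,
            }
        )
    )
    raw = RawExpressionMatrix(
        mirna_ids=mirna_ids,
        sample_ids=sample_ids,
        signal=signal,
        background=background,
    )
    truth = GroundTruth(
        markers=markers,
        scale_factors=pd.Series(np.exp2(s_j), index=sample_ids),
        cohorts=pd.Series(cohorts, index=sample_ids),
    )
    return raw, ann, truth


def two_group_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The diffuse-glioma vs noncancer study conditions (157 cases, 157+157 controls)."""
    return SimulationConfig(seed=seed, **overrides)


def three_tumor_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The 3-tumor cohort conditions: 85 GBM, 42 PCNSL, 28 metastatic, with
    20 planted markers per one-vs-rest contrast at |log2 FC| 1."""

    def alternating(n, magnitude=1.0):
        return [magnitude if i % 2 == 0 else -magnitude for i in range(n)]

    defaults = dict(
        group_sizes={"GBM": 85, "PCNSL": 42, "metastatic": 28},
        marker_effects={
            "GBM": alternating(20),
            "PCNSL": alternating(20),
            "metastatic": alternating(20),
        },
        group_cohorts={
            "GBM": "biobank_minus20",
            "PCNSL": "biobank_minus20",
            "metastatic": "biobank_minus20",
        },
    )
    defaults.update(overrides)
    return SimulationConfig(seed=seed, **defaults)


def generate_three_tumor_cohort(config: SimulationConfig | None = None, seed: int = 0):
    if config is None:
        config = three_tumor_config(seed=seed)
    return generate_cohort(config)


def truth_to_frame(truth: GroundTruth) -> pd.DataFrame:
    rows = []
    for group, ids in truth.markers.items():
        for mid, eff in ids.items():
            rows.append({"group": group, "mirna_id": mid, "log2_fc": eff})
    return pd.DataFrame(rows)
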