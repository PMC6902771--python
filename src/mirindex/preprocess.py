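"""Microarray signal preprocessing.

The fixed pipeline order is: positive call -> background subtraction ->
internal-control normalization -> robust prevalence filter.  Positive call is
a strict exceedance of the background estimate; only positive-call signals
carry information downstream (non-detected cells are zeroed).  Normalization
divides each sample by the mean background-subtracted signal of designated
internal-control miRNAs and rescales by the cohort mean of those factors, so
the result stays in intensity units and the 64-intensity-unit robustness
filter remains meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import RawExpressionMatrix, SampleAnnotationTable

logger = logging.getLogger(__name__)

DEFAULT_CONTROLS = ("miR-149-3p", "miR-2861", "miR-4463")
DEFAULT_THRESHOLD = 64.0
DEFAULT_PREVALENCE = 0.5
LOG2_FLOOR = 1.0


@dataclass
class NormalizedMatrix:
    """Control-normalized signals, in intensity units, plus their log2 transform."""

    mirna_ids: list
    sample_ids: list
    norm_signal: np.ndarray
    log2_signal: np.ndarray
    controls_used: list
    reference_level: float

    def to_frame(self, log2: bool = False) -> pd.DataFrame:
        values = self.log2_signal if log2 else self.norm_signal
        return pd.DataFrame(values, index=self.mirna_ids, columns=self.sample_ids)

    def log2_for(self, mirna_ids) -> np.ndarray:
        """Samples x features array of log2 signals for the named miRNAs."""
        idx = [self.mirna_ids.index(m) for m in mirna_ids]
        return self.log2_signal[idx, :].T.copy()


@dataclass
class FilterReport:
    kept_mirnas: list
    dropped_mirnas: list  # (mirna_id, reason)
    prevalence_by_group: pd.DataFrame  # miRNA x group fractions
    threshold: float
    prevalence_cutoff: float

    def to_frame(self) -> pd.DataFrame:
        dropped_reason = dict(self.dropped_mirnas)
        rows = []
        for m in self.prevalence_by_group.index:
            rows.append(
                {
                    "mirna_id": m,
                    "kept": m in set(self.kept_mirnas),
                    "reason": dropped_reason.get(m, ""),
                    **{
                        f"prevalence_{g}": self.prevalence_by_group.loc[m, g]
                        for g in self.prevalence_by_group.columns
                    },
                }
            )
        return pd.DataFrame(rows)


def positive_call(raw: RawExpressionMatrix) -> RawExpressionMatrix:
    """Fill detection flags: a spot is detected iff signal strictly exceeds background."""
    if np.any(raw.background < 0):
        raise ValueError("negative background estimate")
    detected = raw.signal > raw.background
    return RawExpressionMatrix(
        mirna_ids=raw.mirna_ids,
        sample_ids=raw.sample_ids,
        signal=raw.signal,
        background=raw.background,
        detected=detected,
    )


def subtract_background(raw: RawExpressionMatrix) -> RawExpressionMatrix:
    """Background-subtract detected cells; zero out non-detected cells.

    By the strict positive call the subtracted values are > 0 wherever detected.
    """
    if raw.detected is None:
        raise ValueError("detection flags missing; run positive_call first")
    signal = np.where(raw.detected, raw.signal - raw.background, 0.0)
    return RawExpressionMatrix(
        mirna_ids=raw.mirna_ids,
        sample_ids=raw.sample_ids,
        signal=signal,
        background=np.zeros_like(signal),
        detected=raw.detected,
    )


def normalize_internal_controls(
    raw: RawExpressionMatrix,
    controls=DEFAULT_CONTROLS,
    log2_floor: float = LOG2_FLOOR,
) -> NormalizedMatrix:
    """Divide each sample by its mean internal-control signal, rescaled to stay in intensity units.

    With per-sample control mean ``m_j`` and cohort constant ``M = mean_j(m_j)``,
    the normalized signal is ``signal * M / m_j``; a single-sample matrix is left
    unchanged (M = m_j).
    """
    controls = list(controls)
    if raw.detected is None:
        raise ValueError("detection flags missing; run positive_call first")
    rows = []
    for c in controls:
        i = raw.mirna_index(c)
        not_det = ~raw.detected[i, :]
        nonpos = raw.signal[i, :] <= 0
        bad = not_det | nonpos
        if bad.any():
            j = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"internal control {c!r} undetected or non-positive in sample "
                f"{raw.sample_ids[j]!r}"
            )
        rows.append(i)
    m_j = raw.signal[rows, :].mean(axis=0)
    M = float(m_j.mean())
    norm = raw.signal * (M / m_j)[np.newaxis, :]
    log2sig = np.log2(np.maximum(norm, log2_floor))
    logger.info(
        "normalized %d samples with controls %s (reference level %.3f)",
        len(raw.sample_ids), controls, M,
    )
    return NormalizedMatrix(
        mirna_ids=raw.mirna_ids,
        sample_ids=raw.sample_ids,
        norm_signal=norm,
        log2_signal=log2sig,
        controls_used=controls,
        reference_level=M,
    )


def robust_filter(
    norm: NormalizedMatrix,
    annotations: SampleAnnotationTable,
    threshold: float = DEFAULT_THRESHOLD,
    prevalence: float = DEFAULT_PREVALENCE,
) -> FilterReport:
    """Keep miRNAs whose normalized signal exceeds `threshold` in more than
    `prevalence` of samples in *every* group (both comparisons strict)."""
    groups = annotations.groups_for(norm.sample_ids)
    labels = sorted(set(groups))
    masks = {}
    for g in labels:
        mask = groups == g
        if not mask.any():
            raise ValueError(f"empty group {g!r}")
        masks[g] = mask
    prev = {}
    for g, mask in masks.items():
        prev[g] = (norm.norm_signal[:, mask] > threshold).mean(axis=1)
    prev_df = pd.DataFrame(prev, index=norm.mirna_ids)
    kept, dropped = [], []
    for i, m in enumerate(norm.mirna_ids):
        failing = [g for g in labels if not (prev_df.iloc[i][g] > prevalence)]
        if failing:
            dropped.append(
                (m, f"prevalence <= {prevalence:g} in group(s) {','.join(failing)}")
            )
        else:
            kept.append(m)
    logger.info(
        "robust filter kept %d / %d miRNAs (>%g units in >%g of each group)",
        len(kept), len(norm.mirna_ids), threshold, prevalence,
    )
    return FilterReport(
        kept_mirnas=kept,
        dropped_mirnas=dropped,
        prevalence_by_group=prev_df,
        threshold=threshold,
        prevalence_cutoff=prevalence,
    )


def preprocess_pipeline(
    raw: RawExpressionMatrix,
    annotations: SampleAnnotationTable,
    controls=DEFAULT_CONTROLS,
    threshold: float = DEFAULT_THRESHOLD,
    prevalence: float = DEFAULT_PREVALENCE,
):
    """positive_call -> subtract_background -> normalize -> robust_filter."""
    flagged = positive_call(raw)
    sub = subtract_background(flagged)
    norm = normalize_internal_controls(sub, controls=controls)
    report = robust_filter(norm, annotations, threshold=threshold, prevalence=prevalence)
    return norm, report
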