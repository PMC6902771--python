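"""Text-format I/O: expression matrices, sample annotations, model documents.

Expression matrices are tab-separated, miRNAs as rows and samples as columns,
with ``miRNA_id`` in the first header cell.  Per-spot background lives in a
sidecar file with the same basename and suffix ``.bg.tsv``; detection flags
(0/1) in an optional ``.detected.tsv`` sidecar.  Model documents are YAML with
a ``format_version`` field; writing then reading reproduces every coefficient
bit-exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

FORMAT_VERSION = 1
MODEL_KINDS = ("linear_index", "binary_lasso", "three_class")


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class RawExpressionMatrix:
    """miRNA x sample raw signals with background estimates and positive-call flags.

    ``background`` is always stored as a full matrix; per-sample scalar
    backgrounds are broadcast on construction.  ``detected`` may be None until
    :func:`mirindex.preprocess.positive_call` fills it.
    """

    mirna_ids: list
    sample_ids: list
    signal: np.ndarray
    background: np.ndarray
    detected: np.ndarray | None = None

    def __post_init__(self):
        self.mirna_ids = list(self.mirna_ids)
        self.sample_ids = list(self.sample_ids)
        _check_unique(self.mirna_ids, "miRNA")
        _check_unique(self.sample_ids, "sample")
        self.signal = np.asarray(self.signal, dtype=float)
        shape = (len(self.mirna_ids), len(self.sample_ids))
        if self.signal.shape != shape:
            raise ValueError(f"signal shape {self.signal.shape} != {shape}")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signals must be finite")
        if np.any(self.signal < 0):
            raise ValueError("signals must be >= 0")
        bg = np.asarray(self.background, dtype=float)
        if bg.ndim == 0:
            bg = np.full(shape, float(bg))
        elif bg.ndim == 1:
            if bg.shape[0] != shape[1]:
                raise ValueError("per-sample background length mismatch")
            bg = np.broadcast_to(bg, shape).copy()
        elif bg.shape != shape:
            raise ValueError(f"background shape {bg.shape} != {shape}")
        if not np.all(np.isfinite(bg)):
            raise ValueError("background must be finite")
        self.background = bg
        if self.detected is not None:
            det = np.asarray(self.detected, dtype=bool)
            if det.shape != shape:
                raise ValueError(f"detected shape {det.shape} != {shape}")
            self.detected = det

    @property
    def shape(self):
        return self.signal.shape

    def mirna_index(self, mirna_id: str) -> int:
        try:
            return self.mirna_ids.index(mirna_id)
        except ValueError:
            raise KeyError(f"miRNA {mirna_id!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.signal, index=self.mirna_ids, columns=self.sample_ids)


@dataclass
class SampleAnnotationTable:
    """Per-sample annotations: group label plus free extra columns (age, sex, cohort...)."""

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame
        if "sample_id" not in df.columns:
            raise ValueError("annotation table must contain a 'sample_id' column")
        if "group" not in df.columns:
            raise ValueError("annotation table must contain a 'group' column")
        if df["sample_id"].duplicated().any():
            dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        bad = df["group"].isna() | (df["group"].astype(str).str.strip() == "")
        if bad.any():
            sid = df.loc[bad, "sample_id"].iloc[0]
            raise ValueError(f"empty group label for sample {sid!r}")
        if "age" in df.columns:
            ages = pd.to_numeric(df["age"], errors="coerce")
            if (ages.dropna() < 0).any():
                raise ValueError("age must be >= 0")
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return list(self.frame["sample_id"])

    def groups_for(self, sample_ids) -> np.ndarray:
        lookup = dict(zip(self.frame["sample_id"], self.frame["group"]))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples without annotation: {missing[:5]}")
        return np.array([lookup[s] for s in sample_ids], dtype=object)

    def group_labels(self) -> list:
        return sorted(set(self.frame["group"]))


@dataclass
class ModelDocument:
    """Serialized model container with provenance metadata."""

    model_kind: str
    payload: dict
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(
                f"unknown model_kind {self.model_kind!r}; expected one of {MODEL_KINDS}"
            )


def _bg_path(path: Path) -> Path:
    return path.with_suffix(".bg.tsv")


def _detected_path(path: Path) -> Path:
    return path.with_suffix(".detected.tsv")


def _read_numeric_tsv(path: Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate miRNA id in {what}: {dup!r}")
    if pd.Index(df.columns).duplicated().any():
        dup = pd.Index(df.columns)[pd.Index(df.columns).duplicated()][0]
        raise ValueError(f"duplicate sample id in {what}: {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            # str.astype(float) is correctly rounded, so %.17g output
            # round-trips bit-exactly (pd.to_numeric is not)
            values[:, j] = df[col].values.astype(float)
        except (ValueError, TypeError):
            for i, cell in enumerate(df[col]):
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise ValueError(
                        f"non-numeric cell in {what} at miRNA {df.index[i]!r}, "
                        f"sample {col!r}"
                    ) from None
            raise
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"missing cell in {what} at miRNA {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    return out


def read_expression_matrix(path) -> RawExpressionMatrix:
    """Read a TSV expression matrix plus optional ``.bg.tsv`` / ``.detected.tsv`` sidecars.

    A missing background sidecar defaults to per-sample background 0 with a warning.
    """
    path = Path(path)
    sig = _read_numeric_tsv(path, "signal matrix")
    bgp = _bg_path(path)
    if bgp.exists():
        bg = _read_numeric_tsv(bgp, "background matrix")
        if list(bg.index) != list(sig.index) or list(bg.columns) != list(sig.columns):
            raise ValueError("background sidecar ids do not match signal matrix")
        background = bg.values
    else:
        warnings.warn(
            f"no background sidecar {bgp.name}; defaulting to background 0",
            stacklevel=2,
        )
        background = np.zeros(sig.shape)
    detected = None
    dtp = _detected_path(path)
    if dtp.exists():
        det = _read_numeric_tsv(dtp, "detected matrix")
        detected = det.values > 0.5
    return RawExpressionMatrix(
        mirna_ids=list(sig.index),
        sample_ids=list(sig.columns),
        signal=sig.values,
        background=background,
        detected=detected,
    )


def write_expression_matrix(matrix: RawExpressionMatrix, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _dump(values, p):
        df = pd.DataFrame(values, index=matrix.mirna_ids, columns=matrix.sample_ids)
        df.index.name = "miRNA_id"
        df.to_csv(p, sep="\t", lineterminator="\n", float_format="%.17g")

    _dump(matrix.signal, path)
    _dump(matrix.background, _bg_path(path))
    if matrix.detected is not None:
        _dump(matrix.detected.astype(int), _detected_path(path))


def read_annotations(path) -> SampleAnnotationTable:
    df = pd.read_csv(Path(path), sep="\t", dtype={"sample_id": str, "group": str})
    return SampleAnnotationTable(df)


def write_annotations(table: SampleAnnotationTable, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_model(doc: ModelDocument, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    body = {
        "format_version": FORMAT_VERSION,
        "model_kind": doc.model_kind,
        "metadata": doc.metadata,
        "payload": doc.payload,
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(body, fh, sort_keys=False, allow_unicode=True)


def read_model(path) -> ModelDocument:
    with open(Path(path), encoding="utf-8") as fh:
        body = yaml.safe_load(fh)
    if not isinstance(body, dict) or "model_kind" not in body:
        raise ValueError(f"{path}: not a model document")
    kind = body["model_kind"]
    if kind not in MODEL_KINDS:
        raise ValueError(f"{path}: unknown model_kind {kind!r}")
    version = body.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported format_version {version!r}")
    return ModelDocument(
        model_kind=kind,
        payload=body.get("payload", {}),
        metadata=body.get("metadata", {}),
    )
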