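"""Three-class brain-tumor discrimination from paired one-vs-rest L1-logistic models.

Two binary models with distinct positive classes (say A-vs-rest and B-vs-rest)
compose into a 3-class rule over classes (A, B, C):

    (positive, negative) -> A       (negative, positive) -> B
    (negative, negative) -> C       (positive, positive) -> not_determined

Candidate pairs come from repeated stratified 4:1 splits of the training
cohort (50 by default); for each split three one-vs-rest contrasts are fitted
with 10-fold cross-validated penalty selection and evaluated on the held-out
fifth.  All three pairings of the per-split binary models are combined, and a
representative model is the candidate with the best training-set 3-class
accuracy ("not determined" counts as an error), ties going to the sparser
panel then to candidate order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io_formats, performance
from .lasso_logistic import BinaryLassoModel, predict_matrix, train_binary

NOT_DETERMINED = "not_determined"


@dataclass
class ThreeClassModel:
    model_a: BinaryLassoModel  # positive class = classes[0]
    model_b: BinaryLassoModel  # positive class = classes[1]
    classes: tuple  # (A, B, C); C is the residual class

    def __post_init__(self):
        a, b, c = self.classes
        if len({a, b, c}) != 3:
            raise ValueError("classes must be three distinct labels")
        if self.model_a.positive_label != a or self.model_b.positive_label != b:
            raise ValueError("binary model positive labels must match classes (A, B)")

    @property
    def decision_table(self) -> dict:
        a, b, c = self.classes
        return {
            (True, False): a,
            (False, True): b,
            (False, False): c,
            (True, True): NOT_DETERMINED,
        }

    @property
    def mirna_union(self) -> list:
        return sorted(set(self.model_a.active_mirnas) | set(self.model_b.active_mirnas))

    def to_document(self, metadata: dict | None = None) -> io_formats.ModelDocument:
        payload = {
            "classes": list(self.classes),
            "model_a": self.model_a.to_document().payload,
            "model_b": self.model_b.to_document().payload,
        }
        return io_formats.ModelDocument("three_class", payload, metadata or {})

    @classmethod
    def from_document(cls, doc: io_formats.ModelDocument) -> "ThreeClassModel":
        if doc.model_kind != "three_class":
            raise ValueError(f"expected three_class document, got {doc.model_kind!r}")
        p = doc.payload
        return cls(
            model_a=BinaryLassoModel.from_document(
                io_formats.ModelDocument("binary_lasso", p["model_a"])
            ),
            model_b=BinaryLassoModel.from_document(
                io_formats.ModelDocument("binary_lasso", p["model_b"])
            ),
            classes=tuple(p["classes"]),
        )


def combine_binary(model_a: BinaryLassoModel, model_b: BinaryLassoModel, classes) -> ThreeClassModel:
    """Pair two one-vs-rest models into a 3-class rule with a not-determined outcome."""
    if model_a.positive_label == model_b.positive_label:
        raise ValueError("the two binary models must target distinct positive classes")
    return ThreeClassModel(model_a=model_a, model_b=model_b, classes=tuple(classes))


def classify_three(model: ThreeClassModel, sample) -> str:
    """4-way call for one sample (mapping miRNA id -> log2 signal)."""
    from .lasso_logistic import predict_probability

    call_a = predict_probability(model.model_a, sample) >= 0.5
    call_b = predict_probability(model.model_b, sample) >= 0.5
    return model.decision_table[(call_a, call_b)]


def classify_matrix(model: ThreeClassModel, X, mirna_ids) -> np.ndarray:
    calls_a = predict_matrix(model.model_a, X, mirna_ids) >= 0.5
    calls_b = predict_matrix(model.model_b, X, mirna_ids) >= 0.5
    table = model.decision_table
    return np.array(
        [table[(bool(a), bool(b))] for a, b in zip(calls_a, calls_b)], dtype=object
    )


@dataclass
class CrossTab:
    """Predicted {A, B, C, not_determined} x true {A, B, C} counts and column fractions."""

    counts: pd.DataFrame
    fractions: pd.DataFrame

    def render(self) -> str:
        lines = ["Test result\t" + "\t".join(self.counts.columns)]
        for pred in self.counts.index:
            cells = []
            for true in self.counts.columns:
                c = self.counts.loc[pred, true]
                total = self.counts[true].sum()
                cells.append(f"{c}/{total} ({100 * self.fractions.loc[pred, true]:.1f})")
            lines.append(f"{pred}\t" + "\t".join(cells))
        return "\n".join(lines)


def cross_tabulate(predictions, truths, classes) -> CrossTab:
    predictions = np.asarray(predictions, dtype=object)
    truths = np.asarray(truths, dtype=object)
    classes = list(classes)
    unknown = set(truths) - set(classes)
    if unknown:
        raise ValueError(f"unknown true label(s): {sorted(unknown)}")
    unknown_pred = set(predictions) - set(classes) - {NOT_DETERMINED}
    if unknown_pred:
        raise ValueError(f"unknown predicted label(s): {sorted(unknown_pred)}")
    pred_levels = classes + [NOT_DETERMINED]
    counts = pd.DataFrame(0, index=pred_levels, columns=classes, dtype=int)
    for p, t in zip(predictions, truths):
        counts.loc[p, t] += 1
    fractions = counts / counts.sum(axis=0)
    return CrossTab(counts=counts, fractions=fractions)


def three_class_accuracy(predictions, truths) -> float:
    """Exact-match accuracy; a not_determined call is always an error."""
    predictions = np.asarray(predictions, dtype=object)
    truths = np.asarray(truths, dtype=object)
    return float((predictions == truths).mean())


def stratified_split(labels, train_fraction: float, rng) -> np.ndarray:
    """Boolean mask (True = training) from a per-class seeded split."""
    labels = np.asarray(labels, dtype=object)
    mask = np.zeros(len(labels), dtype=bool)
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} too small to stratify")
        idx = rng.permutation(idx)
        # ceiling allocation: a 4:1 split of (85, 42, 28) gives (68, 34, 23)
        n_train = int(np.ceil(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        mask[idx[:n_train]] = True
    return mask


@dataclass
class RepeatRecord:
    model: BinaryLassoModel
    heldout_auc: float
    n_active: int


@dataclass
class RepeatSummary:
    contrast: str
    records: list

    @property
    def aucs(self) -> np.ndarray:
        return np.array([r.heldout_auc for r in self.records])

    @property
    def feature_counts(self) -> np.ndarray:
        return np.array([r.n_active for r in self.records], dtype=float)

    def mean_ci(self, values) -> tuple:
        values = np.asarray(values, dtype=float)
        m = float(values.mean())
        if len(values) < 2:
            return m, m, m
        half = 1.96 * values.std(ddof=1) / np.sqrt(len(values))
        return m, float(m - half), float(m + half)


def repeated_binary_models(
    X,
    labels,
    positive_class: str,
    mirna_ids=None,
    n_repeats: int = 50,
    train_fraction: float = 0.8,
    seed: int = 0,
    n_folds: int = 10,
) -> RepeatSummary:
    """One-vs-rest LASSO models over repeated stratified 4:1 splits.

    Each repeat fits on the training 4/5 with 10-fold CV penalty selection and
    records the AUC on the held-out 1/5 plus the active-feature count.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if positive_class not in set(labels):
        raise ValueError(f"positive class {positive_class!r} absent from labels")
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_repeats)
    records = []
    for r in range(n_repeats):
        rng = np.random.default_rng(int(seeds[2 * r]))
        train = stratified_split(labels, train_fraction, rng)
        y = labels == positive_class
        model = train_binary(
            X[train],
            y[train],
            mirna_ids=mirna_ids,
            positive_label=positive_class,
            negative_label="others",
            n_folds=n_folds,
            seed=int(seeds[2 * r + 1] % (2**31)),
        )
        prob = predict_matrix(model, X[~train], mirna_ids or model.mirna_ids)
        auc, _, _ = performance.roc_auc(prob, y[~train])
        records.append(RepeatRecord(model=model, heldout_auc=auc, n_active=model.n_active))
    return RepeatSummary(contrast=f"{positive_class}_vs_others", records=records)


def select_representative(candidates, X_train, mirna_ids, truths) -> tuple:
    """Rank combined models by training 3-class accuracy; ties to fewer miRNAs,
    then candidate order.  Returns (winner, training_accuracy)."""
    if not candidates:
        raise ValueError("need at least one candidate model")
    best = None
    for pos, cand in enumerate(candidates):
        preds = classify_matrix(cand, X_train, mirna_ids)
        acc = three_class_accuracy(preds, truths)
        key = (-acc, len(cand.mirna_union), pos)
        if best is None or key < best[0]:
            best = (key, cand, acc)
    return best[1], best[2]


@dataclass
class ThreeTumorResult:
    representative: ThreeClassModel
    training_accuracy: float
    contrast_summaries: dict  # positive class -> RepeatSummary
    pairing_accuracies: dict  # (A_label, B_label) -> list of training accuracies
    candidates: list = field(repr=False, default_factory=list)


def build_three_tumor_index(
    X_train,
    labels_train,
    mirna_ids,
    classes=("GBM", "PCNSL", "metastatic"),
    n_repeats: int = 50,
    seed: int = 0,
    n_folds: int = 10,
) -> ThreeTumorResult:
    """Full 3-Tumor procedure on a training cohort.

    Per repeat: one stratified 4:1 split; three one-vs-rest LASSO fits on the
    4/5 part; the three pairings of those fits become combined candidates.
    The representative model maximizes training-cohort 3-class accuracy.
    """
    X_train = np.asarray(X_train, dtype=float)
    labels_train = np.asarray(labels_train, dtype=object)
    classes = tuple(classes)
    summaries = {
        c: repeated_binary_models(
            X_train,
            labels_train,
            positive_class=c,
            mirna_ids=mirna_ids,
            n_repeats=n_repeats,
            seed=int(np.random.SeedSequence([seed, ci]).generate_state(1)[0] % (2**31)),
            n_folds=n_folds,
        )
        for ci, c in enumerate(classes)
    }
    pairings = [
        (classes[0], classes[1], classes[2]),
        (classes[1], classes[2], classes[0]),
        (classes[0], classes[2], classes[1]),
    ]
    candidates = []
    pairing_accuracies = {}
    for a, b, c in pairings:
        accs = []
        for r in range(n_repeats):
            cand = combine_binary(
                summaries[a].records[r].model,
                summaries[b].records[r].model,
                classes=(a, b, c),
            )
            candidates.append(cand)
            preds = classify_matrix(cand, X_train, mirna_ids)
            accs.append(three_class_accuracy(preds, labels_train))
        pairing_accuracies[(a, b)] = accs
    representative, acc = select_representative(
        candidates, X_train, mirna_ids, labels_train
    )
    return ThreeTumorResult(
        representative=representative,
        training_accuracy=acc,
        contrast_summaries=summaries,
        pairing_accuracies=pairing_accuracies,
        candidates=candidates,
    )
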