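"""Two-group linear discriminant index models.

A diagnostic index is a Fisher linear discriminant over log2 normalized
signals of a small miRNA panel: coefficients proportional to
(pooled within-class covariance)^-1 (mean_pos - mean_neg), intercept set so
the score is zero at the midpoint of the projected class means, and finally
recentred so the Youden-optimal cutoff sits exactly at 0.  Panels are chosen
by a beam search over miRNA subsets ranked by leave-one-out cross-validated
accuracy, and panel growth stops when the AUC gain is no longer significant
(paired DeLong test).

The subset search is the hot loop; leave-one-out refits are computed exactly
via rank-one Sherman-Morrison downdates of the pooled scatter matrix inside a
numba kernel, which is verified against the explicit refit loop in the tests.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from . import io_formats, performance


@dataclass
class LinearIndexModel:
    """Named miRNA coefficients + intercept defining a discriminant score with cutoff 0."""

    mirna_ids: list
    coefficients: np.ndarray
    intercept: float
    positive_label: str = "positive"
    negative_label: str = "negative"
    cutoff: float = 0.0
    scale: str = "log2"

    def __post_init__(self):
        self.mirna_ids = list(self.mirna_ids)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.mirna_ids),):
            raise ValueError("one coefficient per miRNA required")

    def to_document(self, metadata: dict | None = None) -> io_formats.ModelDocument:
        payload = {
            "mirna_ids": list(self.mirna_ids),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "cutoff": float(self.cutoff),
            "positive_label": self.positive_label,
            "negative_label": self.negative_label,
            "scale": self.scale,
        }
        return io_formats.ModelDocument("linear_index", payload, metadata or {})

    @classmethod
    def from_document(cls, doc: io_formats.ModelDocument) -> "LinearIndexModel":
        if doc.model_kind != "linear_index":
            raise ValueError(f"expected linear_index document, got {doc.model_kind!r}")
        p = doc.payload
        return cls(
            mirna_ids=p["mirna_ids"],
            coefficients=np.array(p["coefficients"], dtype=float),
            intercept=p["intercept"],
            cutoff=p.get("cutoff", 0.0),
            positive_label=p.get("positive_label", "positive"),
            negative_label=p.get("negative_label", "negative"),
            scale=p.get("scale", "log2"),
        )


def published_glioma_index() -> LinearIndexModel:
    """The frozen 3-miRNA serum index for diffuse glioma, shipped as package data."""
    ref = importlib.resources.files("mirindex").joinpath("data/glioma_index.model")
    with importlib.resources.as_file(ref) as path:
        return LinearIndexModel.from_document(io_formats.read_model(path))


def fit_fisher_lda(
    X,
    labels,
    mirna_ids=None,
    positive_label: str = "positive",
    negative_label: str = "negative",
    ridge: str | None = "auto",
) -> LinearIndexModel:
    """Fisher LDA: w = pooled_cov^-1 (mu_pos - mu_neg), intercept at the midpoint.

    ``labels`` is boolean (True = positive class).  A singular pooled covariance
    gets a ridge of 1e-6 * trace/p on the diagonal when ridge='auto', else a
    hard error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n, k = X.shape
    if mirna_ids is None:
        mirna_ids = [f"feature_{i}" for i in range(k)]
    n1 = int(y.sum())
    n0 = n - n1
    if n1 < 2 or n0 < 2:
        raise ValueError(f"each class needs >= 2 samples (got {n0} / {n1})")
    mu1 = X[y].mean(axis=0)
    mu0 = X[~y].mean(axis=0)
    c1 = X[y] - mu1
    c0 = X[~y] - mu0
    cov = (c1.T @ c1 + c0.T @ c0) / (n - 2)
    tr = np.trace(cov)
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        if ridge != "auto":
            raise np.linalg.LinAlgError("singular pooled within-class covariance")
        cov = cov + np.eye(k) * (1e-6 * tr / k + 1e-12)
    w = np.linalg.solve(cov, mu1 - mu0)
    intercept = -float(w @ (mu0 + mu1)) / 2.0
    return LinearIndexModel(
        mirna_ids=mirna_ids,
        coefficients=w,
        intercept=intercept,
        positive_label=positive_label,
        negative_label=negative_label,
    )


def score_samples(model: LinearIndexModel, X, mirna_ids=None):
    """Score a samples x features array; returns (scores, calls) with call = score >= cutoff."""
    X = np.asarray(X, dtype=float)
    if mirna_ids is not None and list(mirna_ids) != list(model.mirna_ids):
        idx = []
        ids = list(mirna_ids)
        for m in model.mirna_ids:
            if m not in ids:
                raise KeyError(f"model miRNA {m!r} missing from input features")
            idx.append(ids.index(m))
        X = X[:, idx]
    scores = X @ model.coefficients + model.intercept
    return scores, scores >= model.cutoff


def score_index(model: LinearIndexModel, sample):
    """Score one sample given as a mapping miRNA id -> log2 normalized signal."""
    values = []
    for m in model.mirna_ids:
        try:
            values.append(float(sample[m]))
        except (KeyError, IndexError):
            raise KeyError(f"model miRNA {m!r} missing from sample") from None
    score = float(np.dot(values, model.coefficients) + model.intercept)
    return score, score >= model.cutoff


@dataclass
class LoocvResult:
    scores: np.ndarray
    predictions: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float


def loocv_classify(X, labels, ridge: str | None = "auto") -> LoocvResult:
    """Leave-one-out: refit Fisher LDA without each sample, score it held out.

    Prediction rule: held-out score >= 0 -> positive.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n = X.shape[0]
    if n < 4:
        raise ValueError("LOOCV needs at least 4 samples")
    scores = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for j in range(n):
        keep[j] = False
        if y[keep].sum() == 0 or (~y[keep]).sum() == 0:
            raise ValueError("removing a sample empties a class")
        m = fit_fisher_lda(X[keep], y[keep], ridge=ridge)
        scores[j] = float(X[j] @ m.coefficients + m.intercept)
        keep[j] = True
    preds = scores >= 0.0
    sens = float((preds & y).sum() / y.sum())
    spec = float((~preds & ~y).sum() / (~y).sum())
    return LoocvResult(
        scores=scores,
        predictions=preds,
        accuracy=float((preds == y).mean()),
        sensitivity=sens,
        specificity=spec,
    )


# ---------------------------------------------------------------------------
# numba kernels for the subset search
# ---------------------------------------------------------------------------


@njit(cache=False)
def _auc_midrank(scores, yb):
    n = scores.shape[0]
    order = np.argsort(scores)
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and scores[order[j + 1]] == scores[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    n1 = 0
    rsum = 0.0
    for t in range(n):
        if yb[t] == 1:
            n1 += 1
            rsum += ranks[t]
    n0 = n - n1
    return (rsum - n1 * (n1 + 1) / 2.0) / (n1 * n0)


@njit(cache=False)
def _eval_one(Xs, yb):
    """LOOCV accuracy/sensitivity/specificity and apparent AUC of one feature subset."""
    n, k = Xs.shape
    n1 = 0
    for i in range(n):
        n1 += yb[i]
    n0 = n - n1
    mu0 = np.zeros(k)
    mu1 = np.zeros(k)
    for i in range(n):
        if yb[i] == 1:
            for j in range(k):
                mu1[j] += Xs[i, j]
        else:
            for j in range(k):
                mu0[j] += Xs[i, j]
    for j in range(k):
        mu0[j] /= n0
        mu1[j] /= n1
    S = np.zeros((k, k))
    for i in range(n):
        if yb[i] == 1:
            for a in range(k):
                va = Xs[i, a] - mu1[a]
                for b in range(a, k):
                    S[a, b] += va * (Xs[i, b] - mu1[b])
        else:
            for a in range(k):
                va = Xs[i, a] - mu0[a]
                for b in range(a, k):
                    S[a, b] += va * (Xs[i, b] - mu0[b])
    for a in range(k):
        for b in range(a + 1, k):
            S[b, a] = S[a, b]
    tr = 0.0
    for a in range(k):
        tr += S[a, a]
    det = np.linalg.det(S)
    scale = (tr / k) ** k if tr > 0 else 1.0
    if not (det > 1e-10 * scale):
        eps = 1e-6 * tr / k + 1e-300
        for a in range(k):
            S[a, a] += eps
    Sinv = np.linalg.inv(S)
    dmu = mu1 - mu0
    w_full = Sinv @ dmu
    sc_full = Xs @ w_full
    auc = _auc_midrank(sc_full, yb)

    correct = 0
    tp = 0
    tn = 0
    v = np.empty(k)
    dmup = np.empty(k)
    for i in range(n):
        if yb[i] == 1:
            nc = n1
            for j in range(k):
                v[j] = Xs[i, j] - mu1[j]
                dmup[j] = dmu[j] - v[j] / (nc - 1.0)
        else:
            nc = n0
            for j in range(k):
                v[j] = Xs[i, j] - mu0[j]
                dmup[j] = dmu[j] + v[j] / (nc - 1.0)
        alpha = nc / (nc - 1.0)
        Sv = Sinv @ v
        denom = 1.0 - alpha * np.dot(v, Sv)
        if abs(denom) < 1e-12:
            Sp = S - alpha * np.outer(v, v)
            trp = 0.0
            for a in range(k):
                trp += Sp[a, a]
            for a in range(k):
                Sp[a, a] += 1e-6 * trp / k + 1e-300
            wl = np.linalg.solve(Sp, dmup)
        else:
            coef = alpha * np.dot(Sv, dmup) / denom
            wl = Sinv @ dmup + coef * Sv
        sc_i = 0.0
        for j in range(k):
            musum_j = mu0[j] + mu1[j] - v[j] / (nc - 1.0)
            sc_i += wl[j] * (Xs[i, j] - 0.5 * musum_j)
        pred = 1 if sc_i >= 0.0 else 0
        if pred == yb[i]:
            correct += 1
            if yb[i] == 1:
                tp += 1
            else:
                tn += 1
    return correct / n, tp / n1, tn / n0, auc


@njit(cache=False)
def _eval_subsets(X, yb, subsets):
    n = X.shape[0]
    N, k = subsets.shape
    accs = np.empty(N)
    sens = np.empty(N)
    specs = np.empty(N)
    aucs = np.empty(N)
    Xs = np.empty((n, k))
    for s in range(N):
        for jj in range(k):
            c = subsets[s, jj]
            for i in range(n):
                Xs[i, jj] = X[i, c]
        a, se, sp, au = _eval_one(Xs, yb)
        accs[s] = a
        sens[s] = se
        specs[s] = sp
        aucs[s] = au
    return accs, sens, specs, aucs


def loocv_subset_stats(X, labels, subset_indices):
    """Fast exact LOOCV stats (accuracy, sensitivity, specificity, apparent AUC)
    for one subset of feature columns; used by the beam search."""
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    yb = np.asarray(labels, dtype=np.int8)
    Xs = np.ascontiguousarray(X[:, list(subset_indices)])
    return _eval_one(Xs, yb)


# ---------------------------------------------------------------------------
# combination search
# ---------------------------------------------------------------------------


@dataclass
class CandidateRow:
    size: int
    mirna_ids: tuple
    model: LinearIndexModel
    loocv_accuracy: float
    loocv_sensitivity: float
    loocv_specificity: float
    apparent_auc: float
    p_vs_previous: float | None


@dataclass
class CandidateTable:
    rows: list

    def row(self, size: int) -> CandidateRow:
        for r in self.rows:
            if r.size == size:
                return r
        raise KeyError(f"no candidate of size {size}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "size": r.size,
                    "mirnas": ",".join(r.mirna_ids),
                    "loocv_accuracy": r.loocv_accuracy,
                    "loocv_sensitivity": r.loocv_sensitivity,
                    "loocv_specificity": r.loocv_specificity,
                    "apparent_auc": r.apparent_auc,
                    "p_vs_previous": r.p_vs_previous,
                }
                for r in self.rows
            ]
        )


def search_best_combinations(
    X,
    labels,
    candidate_mirnas,
    max_size: int = 5,
    beam_width: int | float = 50,
    positive_label: str = "positive",
    negative_label: str = "negative",
) -> CandidateTable:
    """Per-size best miRNA panels by LOOCV accuracy under a deterministic beam search.

    Ties are broken by higher apparent AUC, then lexicographically by the sorted
    id tuple.  ``beam_width=np.inf`` makes the search exhaustive.  The table
    records, for each size, the winner's LOOCV metrics, apparent AUC and the
    DeLong P value of its apparent-score AUC against the previous size's winner.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    y = np.asarray(labels, dtype=bool)
    yb = y.astype(np.int8)
    ids = list(candidate_mirnas)
    if not ids:
        raise ValueError("candidate list is empty")
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    if max_size > len(ids):
        warnings.warn(
            f"max_size {max_size} exceeds {len(ids)} candidates; truncating",
            stacklevel=2,
        )
        max_size = len(ids)
    col = {m: i for i, m in enumerate(ids)}

    def rank_key(entry):
        acc, auc, subset = entry
        return (-acc, -auc, subset)

    rows = []
    prev_scores = None
    beam = [()]  # subsets of ids (sorted tuples)
    for size in range(1, max_size + 1):
        seen = set()
        ext = []
        for base in beam:
            used = set(base)
            for m in ids:
                if m in used:
                    continue
                subset = tuple(sorted(base + (m,)))
                if subset not in seen:
                    seen.add(subset)
                    ext.append(subset)
        sub_idx = np.array([[col[m] for m in s] for s in ext], dtype=np.int64)
        accs, sens, specs, aucs = _eval_subsets(X, yb, sub_idx)
        ranked = sorted(
            zip(accs, aucs, ext, sens, specs),
            key=lambda e: (-e[0], -e[1], e[2]),
        )
        best_acc, best_auc, best_subset, best_sens, best_spec = ranked[0]
        model = fit_fisher_lda(
            X[:, [col[m] for m in best_subset]],
            y,
            mirna_ids=list(best_subset),
            positive_label=positive_label,
            negative_label=negative_label,
        )
        scores = X[:, [col[m] for m in best_subset]] @ model.coefficients + model.intercept
        p_prev = None
        if prev_scores is not None:
            p_prev = performance.delong_test(scores, prev_scores, y)
        rows.append(
            CandidateRow(
                size=size,
                mirna_ids=best_subset,
                model=model,
                loocv_accuracy=float(best_acc),
                loocv_sensitivity=float(best_sens),
                loocv_specificity=float(best_spec),
                apparent_auc=float(best_auc),
                p_vs_previous=p_prev,
            )
        )
        prev_scores = scores
        n_beam = len(ext) if np.isinf(beam_width) else int(beam_width)
        beam = [e[2] for e in ranked[:n_beam]]
    return CandidateTable(rows)


def select_final_size(table: CandidateTable, alpha: float = 0.05) -> int:
    """Smallest size k whose successor brings no significant AUC improvement.

    If every increment is significant the largest size wins.  This is the
    operational form of "maximum accuracy using the minimum number of miRNAs".
    """
    sizes = sorted(r.size for r in table.rows)
    for k in sizes:
        nxt = [r for r in table.rows if r.size == k + 1]
        if not nxt:
            return k
        p = nxt[0].p_vs_previous
        if p is None or p >= alpha:
            return k
    return sizes[-1]


def calibrate_cutoff_youden(model: LinearIndexModel, X, labels) -> LinearIndexModel:
    """Shift the intercept so the Youden-optimal threshold becomes exactly 0."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=bool)
    scores = X @ model.coefficients + model.intercept
    if np.ptp(scores) == 0:
        warnings.warn("degenerate constant scores; cutoff left unchanged", stacklevel=2)
        return replace(model, cutoff=0.0)
    t_star, _ = performance.best_youden_threshold(scores, y)
    return replace(model, intercept=model.intercept - t_star, cutoff=0.0)
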