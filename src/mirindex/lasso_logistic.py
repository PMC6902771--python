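"""L1-penalized binary logistic regression.

Solver: outer iteratively reweighted least squares (quadratic approximation to
the logistic deviance) with inner cyclic coordinate descent on the weighted,
penalized least-squares problem, glmnet-style.  Features are standardized to
zero mean / unit variance internally; the penalty applies on that scale and
the intercept is unpenalized.  The objective is

    (1/n) * sum_i log(1 + exp(-y~_i eta_i)) + lambda * sum_j |beta_j|

so ``lambda_max = max_j |<x_j, y - ybar>| / n`` kills every coefficient.
Convergence: max coefficient change < 1e-7 on the standardized scale.

Penalty selection is stratified 10-fold cross-validation over a descending
log-spaced grid from lambda_max, minimizing mean held-out binomial deviance
(the 1-SE alternative is exposed as a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import io_formats

TOL = 1e-7
MAX_OUTER = 100
MAX_INNER = 1000
MIN_WEIGHT = 1e-5


@dataclass
class BinaryLassoModel:
    """Sparse logistic discriminator on log2 signals, with stored standardization."""

    mirna_ids: list
    coefficients: np.ndarray  # original scale
    intercept: float  # original scale
    lambda_: float
    positive_label: str
    negative_label: str
    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        k = len(self.mirna_ids)
        for name in ("coefficients", "center", "scale"):
            if getattr(self, name).shape != (k,):
                raise ValueError(f"{name} must have one entry per miRNA")

    @property
    def active_mirnas(self) -> list:
        return [m for m, c in zip(self.mirna_ids, self.coefficients) if c != 0.0]

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    def to_document(self, metadata: dict | None = None) -> io_formats.ModelDocument:
        payload = {
            "mirna_ids": list(self.mirna_ids),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "lambda": float(self.lambda_),
            "positive_label": self.positive_label,
            "negative_label": self.negative_label,
            "center": [float(c) for c in self.center],
            "scale": [float(s) for s in self.scale],
        }
        return io_formats.ModelDocument("binary_lasso", payload, metadata or {})

    @classmethod
    def from_document(cls, doc: io_formats.ModelDocument) -> "BinaryLassoModel":
        if doc.model_kind != "binary_lasso":
            raise ValueError(f"expected binary_lasso document, got {doc.model_kind!r}")
        p = doc.payload
        return cls(
            mirna_ids=p["mirna_ids"],
            coefficients=np.array(p["coefficients"], dtype=float),
            intercept=p["intercept"],
            lambda_=p["lambda"],
            positive_label=p["positive_label"],
            negative_label=p["negative_label"],
            center=np.array(p["center"], dtype=float),
            scale=np.array(p["scale"], dtype=float),
        )


def standardize(X):
    """Column center/scale (population SD); constant columns get scale 1."""
    X = np.asarray(X, dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    return (X - center) / scale, center, scale


def lambda_max(X, y) -> float:
    """Smallest penalty at which the LASSO solution is all-zero (KKT at the null model)."""
    Xs, _, _ = standardize(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    return float(np.max(np.abs(Xs.T @ (y - y.mean()))) / n)


@njit(cache=False)
def _lasso_path_std(Xs, y, lambdas, tol, max_outer, max_inner, min_weight):
    """Warm-started coordinate-descent path on standardized features.

    Returns (betas, intercepts, status) with status 0 on convergence at every
    lambda, else the 1-based index of the first failing lambda.
    """
    n, p = Xs.shape
    nlam = lambdas.shape[0]
    betas = np.zeros((nlam, p))
    b0s = np.zeros(nlam)
    beta = np.zeros(p)
    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, b0)
    w = np.empty(n)
    r = np.empty(n)
    wx2 = np.empty(p)
    status = 0
    for li in range(nlam):
        lam = lambdas[li]
        converged_outer = False
        for _outer in range(max_outer):
            # quadratic approximation at current eta
            wsum = 0.0
            for i in range(n):
                mu = 1.0 / (1.0 + np.exp(-eta[i]))
                wi = mu * (1.0 - mu)
                if wi < min_weight:
                    wi = min_weight
                w[i] = wi
                wsum += wi
                # working residual: z_i - eta_i with z = eta + (y - mu)/w
                r[i] = (y[i] - mu) / wi
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * Xs[i, j] * Xs[i, j]
                wx2[j] = s / n
            max_change = 0.0
            # coordinate descent to convergence on this approximation:
            # full sweeps alternate with cheap sweeps over the active set
            inner_budget = max_inner
            while inner_budget > 0:
                inner_budget -= 1
                maxd = 0.0
                for j in range(p):
                    g = beta[j] * wx2[j]
                    for i in range(n):
                        g += w[i] * Xs[i, j] * r[i] / n
                    if g > lam:
                        nb = (g - lam) / wx2[j]
                    elif g < -lam:
                        nb = (g + lam) / wx2[j]
                    else:
                        nb = 0.0
                    d = nb - beta[j]
                    if d != 0.0:
                        for i in range(n):
                            r[i] -= d * Xs[i, j]
                        beta[j] = nb
                        ad = abs(d)
                        if ad > maxd:
                            maxd = ad
                # unpenalized intercept
                db_num = 0.0
                for i in range(n):
                    db_num += w[i] * r[i]
                db = db_num / wsum
                if db != 0.0:
                    b0 += db
                    for i in range(n):
                        r[i] -= db
                    if abs(db) > maxd:
                        maxd = abs(db)
                if maxd > max_change:
                    max_change = maxd
                if maxd < tol:
                    break
                # iterate on the current active set until it stabilizes
                while inner_budget > 0:
                    inner_budget -= 1
                    maxd_a = 0.0
                    for j in range(p):
                        if beta[j] == 0.0:
                            continue
                        g = beta[j] * wx2[j]
                        for i in range(n):
                            g += w[i] * Xs[i, j] * r[i] / n
                        if g > lam:
                            nb = (g - lam) / wx2[j]
                        elif g < -lam:
                            nb = (g + lam) / wx2[j]
                        else:
                            nb = 0.0
                        d = nb - beta[j]
                        if d != 0.0:
                            for i in range(n):
                                r[i] -= d * Xs[i, j]
                            beta[j] = nb
                            ad = abs(d)
                            if ad > maxd_a:
                                maxd_a = ad
                    db_num = 0.0
                    for i in range(n):
                        db_num += w[i] * r[i]
                    db = db_num / wsum
                    if db != 0.0:
                        b0 += db
                        for i in range(n):
                            r[i] -= db
                        if abs(db) > maxd_a:
                            maxd_a = abs(db)
                    if maxd_a > max_change:
                        max_change = maxd_a
                    if maxd_a < tol:
                        break
            # refresh eta from scratch to avoid drift
            for i in range(n):
                s = b0
                for j in range(p):
                    if beta[j] != 0.0:
                        s += Xs[i, j] * beta[j]
                eta[i] = s
            if max_change < tol:
                converged_outer = True
                break
        if not converged_outer:
            status = li + 1
            break
        for j in range(p):
            betas[li, j] = beta[j]
        b0s[li] = b0
    return betas, b0s, status


def _fit_path(X, y, lambdas):
    Xs, center, scale = standardize(X)
    Xs = np.ascontiguousarray(Xs)
    yf = np.asarray(y, dtype=float)
    lam = np.asarray(lambdas, dtype=float)
    betas, b0s, status = _lasso_path_std(
        Xs, yf, lam, TOL, MAX_OUTER, MAX_INNER, MIN_WEIGHT
    )
    if status != 0:
        raise RuntimeError(
            f"coordinate descent failed to converge at lambda index {status - 1} "
            f"(lambda={lam[status - 1]:.4g}) within {MAX_OUTER} outer iterations"
        )
    return betas, b0s, center, scale


def fit_lasso_logistic(
    X,
    y,
    lambda_: float,
    mirna_ids=None,
    positive_label: str = "positive",
    negative_label: str = "negative",
) -> BinaryLassoModel:
    """Fit at a single penalty; coefficients are reported on the original scale."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    n, k = X.shape
    if mirna_ids is None:
        mirna_ids = [f"feature_{i}" for i in range(k)]
    betas, b0s, center, scale = _fit_path(X, y, [float(lambda_)])
    beta_std = betas[0]
    coef = beta_std / scale
    intercept = float(b0s[0] - np.sum(beta_std * center / scale))
    return BinaryLassoModel(
        mirna_ids=list(mirna_ids),
        coefficients=coef,
        intercept=intercept,
        lambda_=float(lambda_),
        positive_label=positive_label,
        negative_label=negative_label,
        center=center,
        scale=scale,
    )


def predict_probability(model: BinaryLassoModel, sample) -> float:
    """Logistic probability for one sample (mapping miRNA id -> log2 signal)."""
    values = []
    for m in model.mirna_ids:
        try:
            values.append(float(sample[m]))
        except (KeyError, IndexError):
            raise KeyError(f"model miRNA {m!r} missing from sample") from None
    eta = float(np.dot(values, model.coefficients) + model.intercept)
    return 1.0 / (1.0 + np.exp(-eta))


def predict_matrix(model: BinaryLassoModel, X, mirna_ids):
    """Vectorized probabilities for a samples x features array."""
    ids = list(mirna_ids)
    idx = []
    for m in model.mirna_ids:
        if m not in ids:
            raise KeyError(f"model miRNA {m!r} missing from input features")
        idx.append(ids.index(m))
    eta = np.asarray(X, dtype=float)[:, idx] @ model.coefficients + model.intercept
    return 1.0 / (1.0 + np.exp(-eta))


def binomial_deviance(y, prob) -> float:
    y = np.asarray(y, dtype=float)
    prob = np.clip(np.asarray(prob, dtype=float), 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


def stratified_folds(y, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (round-robin after a seeded shuffle)."""
    y = np.asarray(y, dtype=bool)
    n = len(y)
    if n < n_folds:
        raise ValueError("need at least n_folds samples")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=np.int64)
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


@dataclass
class CvResult:
    lambda_star: float
    lambda_1se: float
    lambdas: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    folds: np.ndarray


def default_lambda_grid(X, y, n_lambda: int = 50, ratio: float = 0.01) -> np.ndarray:
    lmax = lambda_max(X, y)
    return np.geomspace(lmax, lmax * ratio, n_lambda)


def cv_select_lambda(
    X,
    y,
    n_folds: int = 10,
    lambda_grid=None,
    seed: int = 0,
    one_se: bool = False,
) -> CvResult:
    """Pick the penalty minimizing mean held-out binomial deviance over stratified folds."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X, y)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    folds = stratified_folds(y, n_folds, seed)
    dev = np.empty((n_folds, len(lambda_grid)))
    for f in range(n_folds):
        train = folds != f
        test = ~train
        if y[train].all() or not y[train].any():
            raise ValueError(f"fold {f}: training part lost a class")
        betas, b0s, center, scale = _fit_path(X[train], y[train], lambda_grid)
        Xt = (X[test] - center) / scale
        for li in range(len(lambda_grid)):
            eta = Xt @ betas[li] + b0s[li]
            prob = 1.0 / (1.0 + np.exp(-eta))
            dev[f, li] = binomial_deviance(y[test], prob)
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    best = int(np.argmin(mean_dev))
    lambda_star = float(lambda_grid[best])
    # largest lambda within one SE of the minimum (grid is descending)
    within = np.flatnonzero(mean_dev <= mean_dev[best] + se_dev[best])
    lambda_1se = float(lambda_grid[within[0]])
    return CvResult(
        lambda_star=lambda_1se if one_se else lambda_star,
        lambda_1se=lambda_1se,
        lambdas=lambda_grid,
        mean_deviance=mean_dev,
        se_deviance=se_dev,
        folds=folds,
    )


def train_binary(
    X,
    y,
    mirna_ids=None,
    positive_label: str = "positive",
    negative_label: str = "negative",
    n_folds: int = 10,
    seed: int = 0,
    one_se: bool = False,
) -> BinaryLassoModel:
    """cv_select_lambda followed by a final fit on all data at the selected penalty."""
    cv = cv_select_lambda(X, y, n_folds=n_folds, seed=seed, one_se=one_se)
    return fit_lasso_logistic(
        X, y, cv.lambda_star,
        mirna_ids=mirna_ids,
        positive_label=positive_label,
        negative_label=negative_label,
    )


def kkt_residuals(model: BinaryLassoModel, X, y):
    """(max inactive violation, max active stationarity residual) on the standardized scale.

    At an exact solution: |g_j| <= lambda for inactive features and
    g_j = -lambda * sign(beta_j) for active ones, with g the deviance gradient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xs = (X - model.center) / model.scale
    beta_std = model.coefficients * model.scale
    eta = Xs @ beta_std + (model.intercept + np.sum(model.coefficients * model.center))
    prob = 1.0 / (1.0 + np.exp(-eta))
    g = Xs.T @ (prob - y) / len(y)
    active = beta_std != 0
    inactive_violation = 0.0
    if (~active).any():
        inactive_violation = float(np.max(np.abs(g[~active])) - model.lambda_)
    active_residual = 0.0
    if active.any():
        active_residual = float(
            np.max(np.abs(g[active] + model.lambda_ * np.sign(beta_std[active])))
        )
    return max(inactive_violation, 0.0), active_residual
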