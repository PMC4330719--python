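"""Least-squares probabilistic classification (LSPC) and evaluation.

LSPC models the class-posterior as a linear combination of Gaussian kernels
centered on the training points, fitted by regularized least squares — a
closed-form solve, no iteration.  Model selection uses randomized stratified
ten-fold cross-validation on the training set; generalization is measured on
a chronologically held-out test set, repeated to capture the randomness of
training, and calibrated against label-shuffled null models by permutation
testing.  Paired condition comparisons use the Wilcoxon signed-rank test
with an exact small-sample null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "LspcModel",
    "Metrics",
    "RepeatedMetrics",
    "PermutationResult",
    "WilcoxonResult",
    "lspc_fit",
    "lspc_predict",
    "inner_cv_select",
    "evaluate_repeated",
    "compute_metrics",
    "permutation_test",
    "compare_conditions",
]

POSITIVE = "chirp"
NEGATIVE = "silent"

DEFAULT_SIGMA_FACTORS = (0.1, 0.3, 1.0, 3.0, 10.0)
DEFAULT_LAMBDAS = (1e-3, 1e-2, 1e-1, 1.0)


# --------------------------------------------------------------------------
# LSPC core
# --------------------------------------------------------------------------

@dataclass
class LspcModel:
    centers: np.ndarray   # training feature vectors, n x d
    sigma: float
    lam: float
    theta: np.ndarray     # n x n_classes coefficients
    classes: np.ndarray   # ordered labels; ties break toward the last class

    @property
    def tie_label(self):
        return self.classes[-1]


def _gauss_kernel(X: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(centers**2, axis=1)[None, :]
        - 2.0 * X @ centers.T
    )
    return np.exp(-np.maximum(d2, 0.0) / (2.0 * sigma**2))


def lspc_fit(features: np.ndarray, labels: np.ndarray,
             sigma: float, lam: float) -> LspcModel:
    """Closed-form LSPC fit: per class y, theta_y solves
    ``(G'G/n + lam*I) theta = G' b_y / n`` with the full training Gram G."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if sigma <= 0 or lam < 0:
        raise ValueError("sigma must be positive and lambda non-negative")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit a classifier")
    n = len(X)
    G = _gauss_kernel(X, X, sigma)
    Bmat = (y[:, None] == classes[None, :]).astype(float)
    A = G.T @ G / n + lam * np.eye(n)
    rhs = G.T @ Bmat / n
    try:
        theta = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular LSPC system (duplicated points with lambda=0?); "
            "use lambda > 0"
        ) from err
    return LspcModel(centers=X, sigma=sigma, lam=lam, theta=theta,
                     classes=classes)


def lspc_predict(model: LspcModel, features: np.ndarray):
    """Predicted labels and clipped-normalized posteriors.

    Raw scores are rectified at zero and normalized per trial; all-negative
    score vectors fall back to a uniform posterior.  Ties are broken toward
    the last class in ``model.classes`` (the silent/negative class for the
    chirp-vs-silent problem, which avoids false alarms).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.centers.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape} does not match centers "
            f"{model.centers.shape}"
        )
    k = _gauss_kernel(X, model.centers, model.sigma)
    scores = k @ model.theta
    clipped = np.maximum(scores, 0.0)
    tot = clipped.sum(axis=1, keepdims=True)
    uniform = np.full_like(clipped, 1.0 / clipped.shape[1])
    posteriors = np.where(tot > 0, clipped / np.where(tot > 0, tot, 1.0), uniform)
    # argmax with ties toward the LAST class: scan classes in order and keep
    # later classes on equal posterior
    best = np.zeros(len(X), dtype=int)
    for j in range(1, posteriors.shape[1]):
        best = np.where(posteriors[:, j] >= posteriors[np.arange(len(X)), best],
                        j, best)
    return model.classes[best], posteriors


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass
class Metrics:
    """Binary detection metrics (chirp = positive, silent = negative)."""

    accuracy: float
    false_positive_rate: float
    false_negative_rate: float
    dprime: float
    n_pos: int
    n_neg: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "false_positive_rate": self.false_positive_rate,
            "false_negative_rate": self.false_negative_rate,
            "dprime": self.dprime,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def compute_metrics(predictions, truth,
                    positive: str = POSITIVE, negative: str = NEGATIVE) -> Metrics:
    """Accuracy, FPR, FNR, and d-prime from predicted and true labels.

    d' = z(hit rate) - z(false-alarm rate), with rates clipped to
    [1/(2N), 1 - 1/(2N)] so the quantiles stay finite.
    """
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError("predictions and truth must have equal length")
    pos = true == positive
    neg = true == negative
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in the truth labels")
    fnr = float(np.mean(pred[pos] != positive))
    fpr = float(np.mean(pred[neg] == positive))
    accuracy = float(np.mean(pred == true))
    hit = np.clip(1.0 - fnr, 1.0 / (2 * n_pos), 1.0 - 1.0 / (2 * n_pos))
    fa = np.clip(fpr, 1.0 / (2 * n_neg), 1.0 - 1.0 / (2 * n_neg))
    dprime = float(norm.ppf(hit) - norm.ppf(fa))
    return Metrics(accuracy=accuracy, false_positive_rate=fpr,
                   false_negative_rate=fnr, dprime=dprime,
                   n_pos=n_pos, n_neg=n_neg)


# --------------------------------------------------------------------------
# model selection and repeated evaluation
# --------------------------------------------------------------------------

def _median_pairwise_distance(X: np.ndarray, rng=None, max_points: int = 500) -> float:
    if len(X) > max_points:
        rng = rng or np.random.default_rng(0)
        X = X[rng.choice(len(X), max_points, replace=False)]
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(X**2, axis=1)[None, :]
        - 2.0 * X @ X.T
    )
    iu = np.triu_indices(len(X), k=1)
    med = float(np.sqrt(np.maximum(np.median(d2[iu]), 0.0)))
    return med if med > 0 else 1.0


def _stratified_folds(y: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Randomized stratified fold assignment; every fold sees every class."""
    for _attempt in range(10):
        fold = np.empty(len(y), dtype=int)
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            idx = rng.permutation(idx)
            fold[idx] = np.arange(len(idx)) % n_folds
        ok = all(
            len(np.unique(y[fold == f])) == len(np.unique(y))
            for f in range(n_folds)
        )
        if ok:
            return fold
    raise ValueError(
        f"could not build {n_folds} stratified folds with every class present"
    )


def inner_cv_select(
    features: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 10,
    sigma_grid: np.ndarray | None = None,
    lambda_grid: np.ndarray | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Randomized stratified K-fold selection of (sigma, lambda).

    The grid point with the best mean validation accuracy is refit on the
    full training data.  Ties break toward the smaller sigma, then the
    larger lambda (the smoother, more regularized model).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if rng is None:
        rng = np.random.default_rng(seed)
    if sigma_grid is None:
        med = _median_pairwise_distance(X, rng=np.random.default_rng(0))
        sigma_grid = med * np.asarray(DEFAULT_SIGMA_FACTORS)
    else:
        sigma_grid = np.asarray(sigma_grid, dtype=float)
    if lambda_grid is None:
        lambda_grid = np.asarray(DEFAULT_LAMBDAS)
    else:
        lambda_grid = np.asarray(lambda_grid, dtype=float)

    fold = _stratified_folds(y, n_folds, rng)
    classes = np.unique(y)
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(X**2, axis=1)[None, :]
        - 2.0 * X @ X.T
    )
    d2 = np.maximum(d2, 0.0)

    acc = np.zeros((len(sigma_grid), len(lambda_grid)))
    for f in range(n_folds):
        va = fold == f
        tr = ~va
        n_tr = int(tr.sum())
        Bmat = (y[tr, None] == classes[None, :]).astype(float)
        y_va = y[va]
        for si, sigma in enumerate(sigma_grid):
            G = np.exp(-d2[np.ix_(tr, tr)] / (2 * sigma**2))
            Kva = np.exp(-d2[np.ix_(va, tr)] / (2 * sigma**2))
            GtG = G.T @ G / n_tr
            rhs = G.T @ Bmat / n_tr
            for li, lam in enumerate(lambda_grid):
                theta = np.linalg.solve(GtG + lam * np.eye(n_tr), rhs)
                scores = Kva @ theta
                best = np.zeros(len(y_va), dtype=int)
                for j in range(1, len(classes)):
                    best = np.where(
                        scores[:, j] >= scores[np.arange(len(y_va)), best],
                        j, best)
                acc[si, li] += np.mean(classes[best] == y_va)
    acc /= n_folds

    best_val = acc.max()
    cands = np.argwhere(acc >= best_val - 1e-12)
    # smaller sigma first, then larger lambda
    cands = sorted(cands.tolist(), key=lambda sl: (sl[0], -sl[1]))
    si, li = cands[0]
    sigma, lam = float(sigma_grid[si]), float(lambda_grid[li])
    model = lspc_fit(X, y, sigma, lam)
    return sigma, lam, model


@dataclass
class RepeatedMetrics:
    """Distribution of test metrics over repeated model selections."""

    metrics: list
    selected: list  # (sigma, lambda) per repeat

    def _values(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.metrics])

    def mean(self, name: str = "accuracy") -> float:
        return float(self._values(name).mean())

    def se(self, name: str = "accuracy") -> float:
        v = self._values(name)
        return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0

    def summary(self) -> dict:
        out = {}
        for name in ("accuracy", "false_positive_rate",
                     "false_negative_rate", "dprime"):
            out[name] = {"mean": self.mean(name), "se": self.se(name)}
        out["n_repeats"] = len(self.metrics)
        return out


def evaluate_repeated(
    train_features, train_labels, test_features, test_labels,
    n_repeats: int = 100, seed: int | None = None,
    n_folds: int = 10,
    sigma_grid=None, lambda_grid=None,
) -> RepeatedMetrics:
    """Repeat inner-CV model selection and fixed-test-set evaluation.

    Each repeat re-randomizes the fold assignment (and hence the selected
    hyperparameters), capturing the training-randomness component of the
    performance distribution.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else \
        np.random.SeedSequence(seed)
    children = ss.spawn(n_repeats)
    metrics, selected = [], []
    for ss in children:
        rng = np.random.default_rng(ss)
        sigma, lam, model = inner_cv_select(
            train_features, train_labels, n_folds=n_folds,
            sigma_grid=sigma_grid, lambda_grid=lambda_grid, rng=rng)
        pred, _ = lspc_predict(model, test_features)
        metrics.append(compute_metrics(pred, test_labels))
        selected.append((sigma, lam))
    return RepeatedMetrics(metrics=metrics, selected=selected)


@dataclass
class PermutationResult:
    p_value: float
    observed_accuracy: float
    null_accuracies: np.ndarray


def permutation_test(
    train_features, train_labels, test_features, test_labels,
    n_perm: int = 100, seed: int | None = None,
    observed_accuracy: float | None = None,
    n_observed_repeats: int = 10,
    n_folds: int = 10,
    sigma_grid=None, lambda_grid=None,
) -> PermutationResult:
    """Label-shuffling null for the classification accuracy.

    Each permutation re-shuffles the *training* labels, reruns model
    selection, and evaluates on the intact test set.  The p-value uses the
    add-one correction: ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else \
        np.random.SeedSequence(seed)
    obs_ss, perm_ss = ss.spawn(2)
    y_tr = np.asarray(train_labels)
    if observed_accuracy is None:
        rep = evaluate_repeated(
            train_features, train_labels, test_features, test_labels,
            n_repeats=n_observed_repeats, seed=obs_ss,
            n_folds=n_folds, sigma_grid=sigma_grid, lambda_grid=lambda_grid)
        observed_accuracy = rep.mean("accuracy")

    null = np.empty(n_perm)
    for i, child in enumerate(perm_ss.spawn(n_perm)):
        rng = np.random.default_rng(child)
        y_shuf = rng.permutation(y_tr)
        _, _, model = inner_cv_select(
            train_features, y_shuf, n_folds=n_folds,
            sigma_grid=sigma_grid, lambda_grid=lambda_grid, rng=rng)
        pred, _ = lspc_predict(model, test_features)
        null[i] = np.mean(pred == np.asarray(test_labels))

    p = (1.0 + np.sum(null >= observed_accuracy)) / (n_perm + 1.0)
    return PermutationResult(p_value=float(p),
                             observed_accuracy=float(observed_accuracy),
                             null_accuracies=null)


# --------------------------------------------------------------------------
# paired comparison: Wilcoxon signed-rank
# --------------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    p_value: float
    statistic: float  # W+ (sum of positive ranks)
    n_used: int
    n_zero: int


def _signed_rank_null_cdf(ranks2: np.ndarray) -> np.ndarray:
    """Exact null pmf of 2*W+ over all sign assignments, by convolution.

    ``ranks2`` are doubled ranks (integers even with midrank ties)."""
    total = int(ranks2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        r = int(r)
        new = pmf.copy()
        new[r:] += pmf[: total + 1 - r]
        pmf = new / 2.0
    return pmf


def compare_conditions(paired_metric_a, paired_metric_b,
                       exact_max_n: int = 25) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (count reported).  For n <= ``exact_max_n``
    the null distribution of the rank sum is exact (all 2^n sign
    assignments, computed by convolution); above that a normal approximation
    with continuity and tie correction is used.
    """
    a = np.asarray(paired_metric_a, dtype=float)
    b = np.asarray(paired_metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D and of equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    nonzero = d != 0
    n_zero = int((~nonzero).sum())
    d = d[nonzero]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1.0", stacklevel=2)
        return WilcoxonResult(p_value=1.0, statistic=0.0, n_used=0,
                              n_zero=n_zero)

    order = np.argsort(np.abs(d), kind="stable")
    ranks = np.empty(n)
    absd = np.abs(d)[order]
    i = 0
    pos = 1
    while i < n:
        j = i
        while j + 1 < n and absd[j + 1] == absd[i]:
            j += 1
        ranks[order[i:j + 1]] = (pos + (pos + (j - i))) / 2.0  # midranks
        pos += j - i + 1
        i = j + 1
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        ranks2 = np.round(2 * ranks).astype(int)
        pmf = _signed_rank_null_cdf(ranks2)
        w2 = int(round(2 * w_plus))
        cdf = pmf[: w2 + 1].sum()
        sf = pmf[w2:].sum()
        p = min(1.0, 2.0 * min(cdf, sf))
    else:
        mu = n * (n + 1) / 4.0
        tie_groups = np.unique(absd, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - \
            np.sum(tie_groups**3 - tie_groups) / 48.0
        if var <= 0:
            p = 1.0
        else:
            z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
            p = float(2.0 * norm.sf(abs(z)))
            p = min(1.0, p)
    return WilcoxonResult(p_value=float(p), statistic=w_plus,
                          n_used=n, n_zero=n_zero)
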