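"""Leave-one-subject-out linear-SVM classification with nested F-score feature
selection over a percentage grid, max-statistic permutation inference, and
selected-edge aggregation.

Procedure per cross-validation fold: rank all features by their two-group
one-way ANOVA F score *computed on the training subjects only*, keep the top
N% for each N on the grid, train a soft-margin linear SVM, and score the
held-out subject.  The grid accuracy profile is summarized by its maximum;
family-wise-error control over the grid uses a permutation null of the
per-permutation *maximum* accuracy, so every grid point's p-value is corrected
for the selection of N.

Label coding: controls (HC) are +1 and patients (OSA) are -1, so a positive
decision value or positive feature weight pushes toward the control class.
Patients are the positive class for sensitivity/specificity and ROC purposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import SVC

try:  # low-overhead binding to the same libsvm solver SVC wraps; the
    # permutation test refits thousands of tiny SVMs and the estimator-API
    # overhead would dominate.  Equivalence with SVC is asserted in the tests.
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover - exercised only on exotic builds
    _libsvm = None

HC_LABEL = 1
OSA_LABEL = -1
DEFAULT_GRID: tuple[int, ...] = tuple(range(10, 101, 10))


def _svm_fit(
    x: np.ndarray, y: np.ndarray, C: float, tol: float = 1e-3
) -> tuple[np.ndarray, float]:
    """(w, b) of a linear soft-margin SVM, oriented like ``SVC`` (d>0 -> +1)."""
    if _libsvm is not None:
        _, sv, _, dual_coef, intercept, *_ = _libsvm.fit(
            np.ascontiguousarray(x, dtype=np.float64),
            np.asarray(y, dtype=np.float64),
            svm_type=0,
            kernel="linear",
            C=C,
            tol=tol,
        )
        return -(dual_coef[0] @ sv), float(-intercept[0])
    clf = SVC(kernel="linear", C=C, tol=tol)  # pragma: no cover
    clf.fit(x, y)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def encode_labels(groups) -> np.ndarray:
    """Map 'HC'/'OSA' strings to the +1/-1 coding used throughout."""
    mapping = {"HC": HC_LABEL, "OSA": OSA_LABEL}
    try:
        return np.array([mapping[g] for g in groups])
    except KeyError as err:
        raise ValueError(f"unknown group label {err.args[0]!r}; expected 'HC' or 'OSA'") from None


def f_score_rank(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-group one-way ANOVA F per feature and a stable descending ranking.

    For two groups F equals the squared pooled t.  Features with zero
    within-group variance but distinct group means are perfectly separating:
    they get F = +inf and rank first.  Ties (including among infinities) break
    by ascending feature index.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("training labels must contain exactly two classes")
    g1, g2 = x[y == classes[0]], x[y == classes[1]]
    n1, n2 = g1.shape[0], g2.shape[0]
    m1, m2 = g1.mean(0), g2.mean(0)
    gm = (n1 * m1 + n2 * m2) / (n1 + n2)
    ssb = n1 * (m1 - gm) ** 2 + n2 * (m2 - gm) ** 2  # df = 1
    ssw = ((g1 - m1) ** 2).sum(0) + ((g2 - m2) ** 2).sum(0)  # df = n - 2
    msw = ssw / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(msw > 0, ssb / np.where(msw > 0, msw, 1.0), np.where(ssb > 0, np.inf, 0.0))
    order = np.argsort(-f, kind="stable")
    return f, order


def n_selected(percent: int, n_features: int) -> int:
    """floor(percent/100 * n_features), the per-grid-point feature count."""
    k = percent * n_features // 100
    if k < 1:
        raise ValueError(f"selecting {percent}% of {n_features} features leaves none")
    return k


def select_top_fraction(ranking: np.ndarray, percent: int, n_features: int) -> np.ndarray:
    """First floor(percent/100 * n_features) entries of a feature ranking."""
    return np.asarray(ranking)[: n_selected(percent, n_features)]


def train_linear_svm(
    x: np.ndarray, y: np.ndarray, C: float = 1.0, tol: float = 1e-3
) -> tuple[np.ndarray, float]:
    """Soft-margin linear SVM; returns (weights, bias) of d(x) = w.x + b.

    With the +1/-1 coding, d(x) > 0 predicts the +1 (control) class.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    if np.unique(y).size != 2:
        raise ValueError("training set must contain both classes")
    return _svm_fit(np.asarray(x, dtype=float), np.asarray(y), C, tol=tol)


@dataclass
class FoldResult:
    """One leave-one-out fold: per-percentage selections, weights, decision."""

    test_index: int
    true_label: int
    selected: dict[int, np.ndarray]
    weights: dict[int, np.ndarray]
    bias: dict[int, float]
    decision: dict[int, float]
    predicted: dict[int, int]


@dataclass
class SelectedEdgeSet:
    """Union of features selected in >= 1 fold at the best grid point."""

    edges: np.ndarray  # feature indices, ascending
    weights: np.ndarray  # mean SVM weight over the folds where selected
    frequency: np.ndarray  # fraction of folds in which selected
    percentage: int
    n_folds: int

    @property
    def positive(self) -> np.ndarray:
        """Features whose mean weight pushes toward the control class."""
        return self.edges[self.weights > 0]

    @property
    def negative(self) -> np.ndarray:
        return self.edges[self.weights < 0]


@dataclass
class MVPAResult:
    percentages: tuple[int, ...]
    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    best_percentage: int
    decision_values: np.ndarray  # n_subjects x n_percentages, held-out values
    folds: list[FoldResult]
    y: np.ndarray
    C: float
    auc: float = np.nan
    roc_points: tuple[np.ndarray, np.ndarray] | None = None
    null_max: np.ndarray | None = None
    fwe_p: np.ndarray | None = None
    n_perm: int = 0
    seed: int | None = None
    selected: SelectedEdgeSet | None = None

    @property
    def final_accuracy(self) -> float:
        return float(self.accuracy[self.percentages.index(self.best_percentage)])


def _accuracy_profile(pred: np.ndarray, y: np.ndarray):
    """(accuracy, sensitivity, specificity) per grid point; patients positive."""
    y = y[:, None]
    is_pat = y == OSA_LABEL
    acc = (pred == y).mean(0)
    sens = (pred[is_pat[:, 0]] == OSA_LABEL).mean(0) if is_pat.any() else np.full(pred.shape[1], np.nan)
    spec = (pred[~is_pat[:, 0]] == HC_LABEL).mean(0) if (~is_pat).any() else np.full(pred.shape[1], np.nan)
    return acc, sens, spec


def _fit_predict_grid(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    percentages,
    C: float,
    collect: bool = False,
):
    """Rank on the training set, then fit/score one SVM per grid point."""
    e = x_train.shape[1]
    _, order = f_score_rank(x_train, y_train)
    decisions = np.empty(len(percentages))
    detail = {} if collect else None
    for pi, pct in enumerate(percentages):
        sel = order[: n_selected(pct, e)]
        w, b = _svm_fit(x_train[:, sel], y_train, C)
        decisions[pi] = float(x_test[sel] @ w + b)
        if collect:
            detail[pct] = (np.sort(sel), w, b, sel)
    return decisions, detail


def loocv_classify(
    x: np.ndarray,
    y: np.ndarray,
    percentages=DEFAULT_GRID,
    C: float = 1.0,
    standardize: bool = False,
) -> MVPAResult:
    """Leave-one-subject-out classification over the feature-selection grid.

    Feature ranking (and optional standardization) is recomputed inside every
    fold from the training subjects only, so the held-out subject never
    influences its own feature selection.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    n, e = x.shape
    if n < 4 or min((y == HC_LABEL).sum(), (y == OSA_LABEL).sum()) < 2:
        raise ValueError("need at least 4 subjects with both classes represented twice")
    percentages = tuple(int(p) for p in percentages)

    decision = np.zeros((n, len(percentages)))
    folds: list[FoldResult] = []
    for k in range(n):
        mask = np.arange(n) != k
        xtr, ytr = x[mask], y[mask]
        xte = x[k]
        if standardize:
            mu, sd = xtr.mean(0), xtr.std(0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)
            xtr = (xtr - mu) / sd
            xte = (xte - mu) / sd
        d, detail = _fit_predict_grid(xtr, ytr, xte, percentages, C, collect=True)
        decision[k] = d
        folds.append(
            FoldResult(
                test_index=k,
                true_label=int(y[k]),
                selected={p: v[0] for p, v in detail.items()},
                weights={p: v[1][np.argsort(v[3])] for p, v in detail.items()},
                bias={p: v[2] for p, v in detail.items()},
                decision={p: float(decision[k, pi]) for pi, p in enumerate(percentages)},
                predicted={
                    p: (HC_LABEL if decision[k, pi] > 0 else OSA_LABEL)
                    for pi, p in enumerate(percentages)
                },
            )
        )

    pred = np.where(decision > 0, HC_LABEL, OSA_LABEL)
    acc, sens, spec = _accuracy_profile(pred, y)
    best = percentages[int(np.argmax(acc))]  # argmax takes the first (smallest) on ties

    return MVPAResult(
        percentages=percentages,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        best_percentage=best,
        decision_values=decision,
        folds=folds,
        y=y.copy(),
        C=C,
    )


def roc_auc(decision_values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and AUC from held-out decision values; patients positive.

    Decision values are oriented toward the control class, so the patient
    score is their negation.  AUC uses rank averaging for ties and equals the
    normalized Mann–Whitney U statistic.
    """
    y = np.asarray(y)
    if np.unique(y).size != 2:
        raise ValueError("both classes required for a ROC curve")
    score = -np.asarray(decision_values, dtype=float)
    y_pos = (y == OSA_LABEL).astype(int)
    fpr, tpr, _ = roc_curve(y_pos, score)
    return fpr, tpr, float(roc_auc_score(y_pos, score))


def aggregate_selected_edges(
    folds: list[FoldResult], percentage: int, n_features: int
) -> SelectedEdgeSet:
    """Union of per-fold selections at one grid point, with mean weights.

    A feature's aggregated weight is the mean of its SVM weight over the folds
    where it was selected; its frequency is the fraction of folds selecting it.
    """
    wsum = np.zeros(n_features)
    count = np.zeros(n_features, dtype=int)
    for fold in folds:
        sel = fold.selected[percentage]
        w = fold.weights[percentage]
        wsum[sel] += w
        count[sel] += 1
    edges = np.flatnonzero(count)
    return SelectedEdgeSet(
        edges=edges,
        weights=wsum[edges] / count[edges],
        frequency=count[edges] / len(folds),
        percentage=percentage,
        n_folds=len(folds),
    )


def permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    percentages=DEFAULT_GRID,
    C: float = 1.0,
    n_perm: int = 10000,
    seed: int | None = None,
    mode: str = "within-fold",
    true_accuracies: np.ndarray | None = None,
    return_full: bool = False,
):
    """Max-statistic permutation null for the LOOCV accuracy grid.

    Each permutation reruns the entire nested procedure with exchanged labels
    and records the *maximum* accuracy over the grid; comparing every true
    accuracy against this null of maxima yields family-wise-error corrected
    p-values for the grid search.

    ``mode`` selects how labels are exchanged:

    * ``"within-fold"`` (default): inside every cross-validation fold the
      training labels are shuffled independently; held-out predictions are
      scored against the true labels.
    * ``"global"``: one label permutation per permutation step, applied before
      the cross-validation loop.

    Returns (null_max, fwe_p) or (null_max, fwe_p, null_grid) with
    ``return_full``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if mode not in ("within-fold", "global"):
        raise ValueError("mode must be 'within-fold' or 'global'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    n, e = x.shape
    percentages = tuple(int(p) for p in percentages)
    rng = np.random.default_rng(seed)

    if true_accuracies is None:
        true_accuracies = loocv_classify(x, y, percentages, C).accuracy
    true_accuracies = np.asarray(true_accuracies, dtype=float)

    mask_all = ~np.eye(n, dtype=bool)
    null_grid = np.empty((n_perm, len(percentages)))
    for b in range(n_perm):
        y_ref = y if mode == "within-fold" else rng.permutation(y)
        correct = np.zeros(len(percentages))
        for k in range(n):
            mask = mask_all[k]
            ytr = y_ref[mask]
            if mode == "within-fold":
                ytr = rng.permutation(ytr)
            if np.unique(ytr).size < 2:  # pragma: no cover - cannot happen with >=2 per class
                continue
            d, _ = _fit_predict_grid(x[mask], ytr, x[k], percentages, C)
            pred = np.where(d > 0, HC_LABEL, OSA_LABEL)
            correct += pred == y_ref[k]
        null_grid[b] = correct / n
    null_max = null_grid.max(axis=1)

    fwe_p = np.array(
        [max(int((null_max >= a).sum()), 1) / n_perm for a in true_accuracies]
    )
    if return_full:
        return null_max, fwe_p, null_grid
    return null_max, fwe_p


def run_mvpa(
    x: np.ndarray,
    y: np.ndarray,
    percentages=DEFAULT_GRID,
    C: float = 1.0,
    n_perm: int = 0,
    seed: int | None = None,
    perm_mode: str = "within-fold",
    standardize: bool = False,
) -> MVPAResult:
    """Full MVPA: LOOCV grid, ROC/AUC at the best grid point, selected-edge
    aggregation, and (when ``n_perm`` > 0) the FWE permutation test."""
    result = loocv_classify(x, y, percentages, C, standardize=standardize)
    best_idx = result.percentages.index(result.best_percentage)
    fpr, tpr, auc = roc_auc(result.decision_values[:, best_idx], y)
    result.roc_points = (fpr, tpr)
    result.auc = auc
    result.selected = aggregate_selected_edges(
        result.folds, result.best_percentage, np.asarray(x).shape[1]
    )
    result.seed = seed
    if n_perm:
        null_max, fwe_p = permutation_test(
            x, y, percentages, C, n_perm=n_perm, seed=seed, mode=perm_mode,
            true_accuracies=result.accuracy,
        )
        result.null_max = null_max
        result.fwe_p = fwe_p
        result.n_perm = n_perm
    return result
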