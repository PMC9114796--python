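"""Binary group discrimination with a soft-margin kernel SVM.

Ten-fold stratified cross-validation over participants, with per-fold
standardization fitted on the training split only.  Reported accuracy is
the unweighted mean of fold accuracies; confusion matrices are
row-normalized per true class.  ROC curves come from a threshold sweep of
the pooled cross-validated decision scores (AUC equals the normalized
Mann-Whitney U statistic).

The default kernel is RBF with ``kernel_scale="auto"`` (median pairwise
distance heuristic) and box constraint 1; all of it is configurable.  The
unit of classification is one vector per participant (participant-mean
features), which avoids subject overlap between training and test folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.svm import SVC

from .gait_features import FEATURES
from .group_stats import pca as run_pca

#: the four group pairs examined by the pair suite
DEFAULT_PAIRS = (
    ("mild_pd", "healthy_older"),
    ("mild_pd", "healthy_young"),
    ("healthy_older", "healthy_young"),
    ("mild_pd", "advanced_pd"),
)

#: feature sets examined per pair: all six variables, the first two
#: principal components of the pooled pair, and each vertical variable alone
DEFAULT_FEATURE_SETS = ("all", "pc2", "V1", "V2", "V3")


@dataclass(frozen=True)
class ClassifierSpec:
    kernel: str = "rbf"  # "rbf" | "linear" | "polynomial"
    box_constraint: float = 1.0
    kernel_scale: float | str = "auto"  # positive scalar or "auto"
    degree: int = 3
    standardize: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.box_constraint <= 0:
            raise ValueError("box_constraint must be > 0")
        if isinstance(self.kernel_scale, (int, float)) and self.kernel_scale <= 0:
            raise ValueError("kernel_scale must be > 0")
        if self.kernel not in ("rbf", "linear", "polynomial"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


@dataclass
class CvResult:
    folds: np.ndarray  # fold index per subject
    fold_accuracy: np.ndarray  # per-fold accuracy, percent
    accuracy: float  # unweighted mean of fold accuracies, percent
    classes: tuple[str, str]
    confusion: np.ndarray  # 2x2, row-normalized percent per true class
    recall: dict[str, float]  # percent per class
    scores: np.ndarray  # cross-validated decision score per subject
    labels: np.ndarray  # true labels per subject


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

def make_folds(labels: Sequence, k: int = 10, seed: int = 0) -> np.ndarray:
    """Deterministic stratified k-fold assignment.

    Shuffles each class with the seeded RNG and deals it round-robin across
    folds, so per-fold class counts differ by at most one from exact
    proportionality.  Warns (but proceeds) when a class has < k members.
    """
    y = np.asarray(labels)
    n = len(y)
    if n < k:
        raise ValueError(f"need >= k={k} subjects, got {n}")
    rng = np.random.default_rng(seed)
    folds = np.full(n, -1, dtype=int)
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            warnings.warn(
                f"class {cls!r} has {len(idx)} < k={k} members; folds as balanced "
                "as possible",
                stacklevel=2,
            )
        idx = idx[rng.permutation(len(idx))]
        for j, i in enumerate(idx):
            folds[i] = (j + offset) % k
        offset += len(idx) % k  # stagger so small classes spread across folds
    return folds


# ---------------------------------------------------------------------------
# SVM cross-validation
# ---------------------------------------------------------------------------

def _gamma(spec: ClassifierSpec, x: np.ndarray) -> float | str:
    if spec.kernel == "linear":
        return "scale"
    if spec.kernel_scale == "auto":
        d = pdist(x)
        med = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
        return 1.0 / (2.0 * med**2)
    return 1.0 / (2.0 * float(spec.kernel_scale) ** 2)


def _fit_svm(x: np.ndarray, y: np.ndarray, spec: ClassifierSpec) -> SVC:
    kernel = {"rbf": "rbf", "linear": "linear", "polynomial": "poly"}[spec.kernel]
    clf = SVC(
        C=spec.box_constraint,
        kernel=kernel,
        gamma=_gamma(spec, x),
        degree=spec.degree,
        random_state=spec.seed,
    )
    clf.fit(x, y)
    return clf


def svm_cross_validate(
    x: np.ndarray,
    y: Sequence,
    spec: ClassifierSpec | None = None,
    k: int = 10,
) -> CvResult:
    """Stratified k-fold CV of the soft-margin kernel SVM on two classes."""
    spec = spec or ClassifierSpec()
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y)
    classes = tuple(sorted(np.unique(y).tolist()))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    folds = make_folds(y, k=k, seed=spec.seed)
    pred = np.empty(len(y), dtype=object)
    scores = np.full(len(y), np.nan)
    fold_acc = []
    for f in range(k):
        test = folds == f
        train = ~test
        if not np.any(test):
            continue
        xt, xs = x[train], x[test]
        if spec.standardize:
            mu = xt.mean(axis=0)
            sd = xt.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            xt = (xt - mu) / sd
            xs = (xs - mu) / sd
        clf = _fit_svm(xt, y[train], spec)
        p = clf.predict(xs)
        pred[test] = p
        # decision_function sign refers to classes_[1]; orient to classes[1]
        s = clf.decision_function(xs)
        if tuple(clf.classes_) != classes:
            s = -s
        scores[test] = s
        fold_acc.append(100.0 * float(np.mean(p == y[test])))

    confusion = np.zeros((2, 2))
    recall = {}
    for i, cls in enumerate(classes):
        m = y == cls
        for j, other in enumerate(classes):
            confusion[i, j] = 100.0 * float(np.mean(pred[m] == other))
        recall[cls] = confusion[i, i]
    return CvResult(
        folds=folds,
        fold_accuracy=np.asarray(fold_acc),
        accuracy=float(np.mean(fold_acc)),
        classes=classes,
        confusion=confusion,
        recall=recall,
        scores=scores,
        labels=y,
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_curve(scores: Sequence[float], labels: Sequence, positive=None) -> RocResult:
    """ROC by threshold sweep over the unique scores; AUC by trapezoid.

    The AUC equals the Mann-Whitney U statistic normalized by ``n1 * n2``
    (ties counted half).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("ROC needs exactly two classes")
    if positive is None:
        positive = sorted(classes.tolist())[1]
    pos = y == positive
    n_pos = int(pos.sum())
    n_neg = len(y) - n_pos
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    pos_sorted = pos[order]
    # merge tied scores into single thresholds
    distinct = np.r_[True, np.diff(s_sorted) != 0]
    tp = np.cumsum(pos_sorted)[np.flatnonzero(np.r_[distinct[1:], True])]
    fp = np.cumsum(~pos_sorted)[np.flatnonzero(np.r_[distinct[1:], True])]
    thresholds = s_sorted[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def decision_boundary_grid(
    clf: SVC,
    x_range: tuple[float, float],
    y_range: tuple[float, float],
    resolution: int = 200,
    standardizer: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Dense label predictions over a 2-D grid (for boundary plots).

    The classifier must have been fitted on exactly two features.
    Returns ``(xx, yy, labels)`` meshgrid-shaped arrays.
    """
    if clf.n_features_in_ != 2:
        raise ValueError("decision_boundary_grid needs a 2-feature model")
    xx, yy = np.meshgrid(
        np.linspace(*x_range, resolution), np.linspace(*y_range, resolution)
    )
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    if standardizer is not None:
        mu, sd = standardizer
        pts = (pts - mu) / sd
    labels = clf.predict(pts).reshape(xx.shape)
    return xx, yy, labels


# ---------------------------------------------------------------------------
# Pair suite
# ---------------------------------------------------------------------------

@dataclass
class PairResult:
    pair: tuple[str, str]
    feature_set: str
    cv: CvResult
    roc: RocResult
    pca_loadings: np.ndarray | None = None  # for the pc2 feature set


def _design_matrix(table: pd.DataFrame, feature_set: str, pc_scores=None, pc_loadings=None):
    """Feature matrix for one feature set; returns (x, loadings or None)."""
    if feature_set == "all":
        return table[list(FEATURES)].to_numpy(dtype=float), None
    if feature_set == "pc2":
        if pc_scores is not None:
            return pc_scores, pc_loadings
        res = run_pca(table, standardize=True)
        return res.scores[:, :2], res.loadings[:, :2]
    if feature_set in FEATURES:
        return table[[feature_set]].to_numpy(dtype=float), None
    raise ValueError(f"unknown feature set {feature_set!r}")


def run_pair_suite(
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    feature_sets: Sequence[str] = DEFAULT_FEATURE_SETS,
    spec: ClassifierSpec | None = None,
    k: int = 10,
    pc_scope: str = "cohort",
) -> list[PairResult]:
    """Run every (group pair) x (feature set) discrimination.

    For the ``pc2`` set the principal components are, by default, computed
    once on the whole input table (``pc_scope="cohort"``), so that every
    pair is examined in the same forward/vertical component plane; with
    ``pc_scope="pair"`` they are recomputed on the pooled data of the two
    groups being compared.  In both scopes the components are fitted before
    the folds are split — a deliberate, documented leakage caveat mirroring
    the one-value-per-subject scatter usage.  Pairs with a missing group
    are skipped.
    """
    spec = spec or ClassifierSpec()
    if pc_scope not in ("cohort", "pair"):
        raise ValueError(f"unknown pc_scope {pc_scope!r}")
    present = set(table["group"].unique())
    cohort_pca = None
    if pc_scope == "cohort" and "pc2" in feature_sets:
        cohort_pca = run_pca(table, standardize=True)
    results = []
    for pair in pairs:
        if not set(pair) <= present:
            warnings.warn(f"pair {pair} skipped: group(s) missing", stacklevel=2)
            continue
        mask = table["group"].isin(pair).to_numpy()
        sub = table[mask].reset_index(drop=True)
        for fs in feature_sets:
            if fs == "pc2" and cohort_pca is not None:
                x, loadings = _design_matrix(
                    sub, fs,
                    pc_scores=cohort_pca.scores[mask, :2],
                    pc_loadings=cohort_pca.loadings[:, :2],
                )
            else:
                x, loadings = _design_matrix(sub, fs)
            cv = svm_cross_validate(x, sub["group"].to_numpy(), spec, k=k)
            roc = roc_curve(cv.scores, cv.labels, positive=pair[0])
            results.append(PairResult(pair=pair, feature_set=fs, cv=cv, roc=roc,
                                      pca_loadings=loadings))
    return results


def accuracy_table(results: Sequence[PairResult]) -> pd.DataFrame:
    """Pairs x feature-sets accuracy table (percent)."""
    rows = {}
    for r in results:
        key = " vs ".join(r.pair)
        rows.setdefault(key, {})[r.feature_set] = round(r.cv.accuracy, 1)
    return pd.DataFrame(rows).T


def confusion_tables(results: Sequence[PairResult]) -> dict[str, pd.DataFrame]:
    """Row-normalized confusion matrices (percent), one per pair/feature set."""
    out = {}
    for r in results:
        key = f"{' vs '.join(r.pair)} [{r.feature_set}]"
        out[key] = pd.DataFrame(
            np.round(r.cv.confusion, 1),
            index=[f"true {c}" for c in r.cv.classes],
            columns=[f"pred {c}" for c in r.cv.classes],
        )
    return out
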