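"""Group-level statistics: one-way ANOVA, Shaffer sequentially rejective
pairwise post hocs, PCA on the feature table, and Horn-style parallel
analysis for component retention.

The Shaffer procedure tests the sorted pairwise p-values sequentially at
``alpha / t_j``, where ``t_j`` is the largest number of pairwise null
hypotheses that can simultaneously be true given that ``j - 1`` have been
rejected.  For group comparisons the achievable truth counts are the sums
of within-block pair counts over partitions of the group set (for four
groups: {0, 1, 2, 3, 6}, giving the sequence 6, 3, 3, 3, 2, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gait_features import FEATURES


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ss_between: float
    ss_within: float


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    t_j: int
    alpha_adjusted: float
    p_adjusted: float
    reject: bool


@dataclass
class PosthocResult:
    comparisons: list[PairwiseComparison]  # sorted by ascending raw p
    alpha: float
    method: str = "shaffer"

    def rejected_pairs(self) -> list[tuple[str, str]]:
        return [c.pair for c in self.comparisons if c.reject]


@dataclass
class PcaResult:
    variables: list[str]
    loadings: np.ndarray  # variables x components (component-variable correlations)
    sdev: np.ndarray
    variance_proportion: np.ndarray
    cumulative_proportion: np.ndarray
    scores: np.ndarray  # observations x components
    components: np.ndarray  # variables x components, unit eigenvectors
    standardized: bool
    mean: np.ndarray
    scale: np.ndarray


@dataclass
class ParallelAnalysisResult:
    n_components: int
    observed_eigenvalues: np.ndarray
    thresholds: np.ndarray
    reps: int
    percentile: float
    seed: int


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def one_way_anova(groups: Sequence[np.ndarray] | Mapping[str, np.ndarray]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA from the sums-of-squares
    decomposition."""
    if isinstance(groups, Mapping):
        groups = list(groups.values())
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_between = float(sum(len(a) * (a.mean() - grand) ** 2 for a in arrays))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_b = len(arrays) - 1
    df_w = len(all_values) - len(arrays)
    if ss_within == 0.0:
        f_stat = 0.0 if ss_between == 0 else np.inf
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f_stat, df_b, df_w))
    return AnovaResult(float(f_stat), df_b, df_w, p, ss_between, ss_within)


# ---------------------------------------------------------------------------
# Shaffer post hoc
# ---------------------------------------------------------------------------

def achievable_truth_counts(k: int) -> set[int]:
    """Numbers of pairwise equalities achievable among k group means.

    A configuration of equalities partitions the groups into blocks; the
    number of true pairwise null hypotheses is the sum of C(b, 2) over
    block sizes b.  Enumerates integer partitions of k.
    """
    def partitions(n: int, cap: int):
        if n == 0:
            yield []
            return
        for first in range(min(n, cap), 0, -1):
            for rest in partitions(n - first, first):
                yield [first] + rest

    return {sum(comb(b, 2) for b in p) for p in partitions(k, k)}


def shaffer_t_sequence(k: int) -> list[int]:
    """The per-step maxima t_1 >= t_2 >= ... for k groups (m = C(k,2) steps)."""
    m = comb(k, 2)
    achievable = achievable_truth_counts(k)
    seq = []
    for j in range(1, m + 1):
        cap = m - (j - 1)
        seq.append(max(s for s in achievable if s <= cap))
    return seq


def shaffer_posthoc(
    groups: Mapping[str, np.ndarray],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> PosthocResult:
    """All pairwise two-sample t tests with Shaffer sequential rejection.

    Pooled-variance t tests by default (``equal_var=False`` for Welch).
    Adjusted p-values are the running maxima of ``p_j * t_j`` capped at 1,
    so that ``p_adjusted <= alpha`` reproduces the sequential decisions.
    """
    labels = list(groups)
    if len(labels) < 3:
        raise ValueError("Shaffer post hoc needs >= 3 groups (else use a plain t test)")
    data = {k: np.asarray(v, dtype=float).ravel() for k, v in groups.items()}
    raw = []
    for a, b in combinations(labels, 2):
        t_stat, p = stats.ttest_ind(data[a], data[b], equal_var=equal_var)
        raw.append(((a, b), float(t_stat), float(p)))
    raw.sort(key=lambda r: r[2])
    t_seq = shaffer_t_sequence(len(labels))

    comparisons = []
    running_adj = 0.0
    still_rejecting = True
    for ((pair, t_stat, p), t_j) in zip(raw, t_seq):
        level = alpha / t_j
        running_adj = min(1.0, max(running_adj, p * t_j))
        reject = still_rejecting and p <= level
        if not reject:
            still_rejecting = False
        comparisons.append(
            PairwiseComparison(
                pair=pair,
                statistic=t_stat,
                p_raw=p,
                t_j=t_j,
                alpha_adjusted=level,
                p_adjusted=running_adj,
                reject=reject,
            )
        )
    return PosthocResult(comparisons=comparisons, alpha=alpha)


# ---------------------------------------------------------------------------
# PCA and parallel analysis
# ---------------------------------------------------------------------------

def _feature_matrix(table: pd.DataFrame | np.ndarray, variables: Sequence[str] | None):
    if isinstance(table, pd.DataFrame):
        variables = list(variables) if variables is not None else [
            c for c in FEATURES if c in table.columns
        ] or [c for c in table.columns if np.issubdtype(table[c].dtype, np.number)]
        x = table[variables].to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
        variables = list(variables) if variables is not None else [
            f"x{i}" for i in range(x.shape[1])
        ]
    return x, variables


def pca(
    table: pd.DataFrame | np.ndarray,
    standardize: bool = True,
    variables: Sequence[str] | None = None,
) -> PcaResult:
    """PCA via eigen-decomposition of the covariance/correlation matrix.

    With ``standardize=True`` (default) variables are scaled to unit
    variance, so loadings equal component-variable correlations.  Sign
    convention: each component's largest-magnitude loading is positive.
    """
    x, variables = _feature_matrix(table, variables)
    n, p = x.shape
    if n < 2 or p < 2:
        raise ValueError("need >= 2 observations and >= 2 variables")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing/non-finite values in the feature matrix")
    mean = x.mean(axis=0)
    xc = x - mean
    sd = xc.std(axis=0, ddof=1)
    if standardize:
        zero = np.flatnonzero(sd == 0)
        if len(zero):
            raise ValueError(f"zero-variance column {variables[zero[0]]!r} cannot be standardized")
        scale = sd
    else:
        scale = np.ones(p)
    xs = xc / scale
    cov = (xs.T @ xs) / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    sdev = np.sqrt(eigval)
    # loadings as component-variable correlations: eigvec * sdev / var_sd
    var_sd = xs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        loadings = eigvec * sdev[None, :]
        loadings = loadings / np.where(var_sd == 0, 1.0, var_sd)[:, None]
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(p):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            eigvec[:, j] *= -1
    scores = xs @ eigvec
    total = eigval.sum()
    prop = eigval / total if total > 0 else np.zeros(p)
    return PcaResult(
        variables=variables,
        loadings=loadings,
        sdev=sdev,
        variance_proportion=prop,
        cumulative_proportion=np.cumsum(prop),
        scores=scores,
        components=eigvec,
        standardized=standardize,
        mean=mean,
        scale=scale,
    )


def parallel_analysis(
    table: pd.DataFrame | np.ndarray,
    reps: int = 1000,
    percentile: float = 95.0,
    seed: int = 0,
    variables: Sequence[str] | None = None,
) -> ParallelAnalysisResult:
    """Horn-style parallel analysis on the correlation matrix.

    Observed eigenvalues are compared rank-wise against the requested
    percentile of eigenvalues from ``reps`` standard-normal datasets of the
    same shape; retention stops at the first rank that fails.
    """
    x, _ = _feature_matrix(table, variables)
    n, p = x.shape
    if n < 3 or p < 2:
        raise ValueError("need >= 3 observations and >= 2 variables")
    if reps < 100:
        warnings.warn(f"parallel analysis with reps={reps} < 100 is unstable", stacklevel=2)
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    sims = np.empty((reps, p))
    for r in range(reps):
        sim = rng.standard_normal((n, p))
        sims[r] = np.sort(np.linalg.eigvalsh(np.corrcoef(sim, rowvar=False)))[::-1]
    thresholds = np.percentile(sims, percentile, axis=0)
    n_keep = 0
    for lam, thr in zip(obs, thresholds):
        if lam > thr:
            n_keep += 1
        else:
            break
    return ParallelAnalysisResult(
        n_components=n_keep,
        observed_eigenvalues=obs,
        thresholds=thresholds,
        reps=reps,
        percentile=percentile,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Feature-table front end
# ---------------------------------------------------------------------------

def feature_anova_report(
    table: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> dict[str, dict]:
    """Per-feature one-way ANOVA + Shaffer post hoc across the groups.

    Features are analyzed independently (no cross-variable multiplicity
    adjustment).
    """
    out: dict[str, dict] = {}
    for feat in FEATURES:
        groups = {g: sub[feat].to_numpy() for g, sub in table.groupby("group")}
        anova = one_way_anova(groups)
        entry: dict = {"anova": anova}
        if len(groups) >= 3:
            entry["posthoc"] = shaffer_posthoc(groups, alpha=alpha, equal_var=equal_var)
        out[feat] = entry
    return out
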