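"""Two-group statistics for methylation readouts.

Conventions used throughout the package:

* ``labels`` is a boolean array, ``True`` for disease (case) samples.
* ``direction`` states which side of a measurement is disease-positive.
  qMSP ``delta_cp`` uses ``"lower_is_positive"`` (hypermethylated cases carry
  more methylated template, hence fewer cycles to threshold); probabilities
  and beta-values use ``"higher_is_positive"``.  The convention is explicit
  in every call so a ROC can never be silently inverted.
* AUC is the probability that a random case outranks a random control, ties
  counting one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LOWER_IS_POSITIVE = "lower_is_positive"
HIGHER_IS_POSITIVE = "higher_is_positive"

__all__ = [
    "LOWER_IS_POSITIVE",
    "HIGHER_IS_POSITIVE",
    "RocResult",
    "LogisticFit",
    "GroupComparison",
    "mann_whitney_two_tailed",
    "roc_auc",
    "closest_topleft_cutoff",
    "bootstrap_ci",
    "roc_analysis",
    "fit_logistic_ridge",
    "combine_genes_logistic",
    "group_comparison",
]


def _as_groups(values, labels):
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape:
        raise ValueError("values and labels must have the same length")
    if not y.any() or y.all():
        raise ValueError("both classes must be present")
    return v, y


def _oriented(values, direction):
    v = np.asarray(values, dtype=float)
    if direction == LOWER_IS_POSITIVE:
        return -v
    if direction == HIGHER_IS_POSITIVE:
        return v
    raise ValueError(f"unknown direction {direction!r}")


def mann_whitney_two_tailed(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    The exact null distribution (full enumeration) is used when both groups
    have at most ``exact_max_n`` observations and the data carry no ties;
    otherwise the normal approximation with continuity and tie correction.
    Returns ``(U, p)`` with U counted for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        # degenerate constant data: no evidence either way
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact"
        if (not has_ties and max(x.size, y.size) <= exact_max_n)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def roc_auc(values, labels, direction: str = HIGHER_IS_POSITIVE) -> float:
    """Rank-based AUC: fraction of (case, control) pairs correctly ordered."""
    v, y = _as_groups(values, labels)
    v = _oriented(v, direction)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    ranks = stats.rankdata(v)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _confusion_curves(v, y, direction):
    """Sensitivity/specificity over all candidate cutoffs.

    Candidates are midpoints between adjacent sorted unique values plus
    +/- infinity.  A sample sitting exactly at a cutoff is called positive
    (<= for lower_is_positive, >= otherwise).
    """
    uniq = np.unique(v)
    mid = (uniq[:-1] + uniq[1:]) / 2.0
    cand = np.concatenate([[-np.inf], mid, [np.inf]])
    if direction == LOWER_IS_POSITIVE:
        pos = v[:, None] <= cand[None, :]
    else:
        pos = v[:, None] >= cand[None, :]
    n1 = y.sum()
    n0 = (~y).sum()
    sens = pos[y].sum(axis=0) / n1
    spec = (~pos[~y]).sum(axis=0) / n0
    return cand, sens, spec


def closest_topleft_cutoff(
    values, labels, direction: str = LOWER_IS_POSITIVE
) -> tuple[float, float, float]:
    """Cutoff minimizing ``(1-sens)**2 + (1-spec)**2`` (closest to top-left).

    Ties are broken toward higher sensitivity, then toward the lower cutoff.
    Returns ``(cutoff, sensitivity, specificity)`` on the original scale.
    """
    v, y = _as_groups(values, labels)
    cand, sens, spec = _confusion_curves(v, y, direction)
    obj = (1.0 - sens) ** 2 + (1.0 - spec) ** 2
    order = np.lexsort((cand, 1.0 - sens, obj))
    best = order[0]
    return float(cand[best]), float(sens[best]), float(spec[best])


def bootstrap_ci(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    values,
    labels,
    n_boot: int = 200,
    level: float = 0.95,
    seed: int | None = None,
    max_retry: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap CI, resampling stratified within each class."""
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap iterations")
    v, y = _as_groups(values, labels)
    rng = np.random.default_rng(seed)
    idx_case = np.flatnonzero(y)
    idx_ctrl = np.flatnonzero(~y)
    out = np.empty(n_boot)
    for b in range(n_boot):
        est = np.nan
        for _ in range(max_retry):
            take = np.concatenate(
                [
                    rng.choice(idx_case, idx_case.size, replace=True),
                    rng.choice(idx_ctrl, idx_ctrl.size, replace=True),
                ]
            )
            est = metric_fn(v[take], y[take])
            if np.isfinite(est):
                break
        out[b] = est
    alpha = (1.0 - level) / 2.0
    lo, hi = np.nanquantile(out, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class RocResult:
    """ROC summary for one marker or composite score."""

    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    direction: str
    n_case: int
    n_control: int


def roc_analysis(
    values,
    labels,
    direction: str = LOWER_IS_POSITIVE,
    n_boot: int = 200,
    level: float = 0.95,
    seed: int | None = None,
) -> RocResult:
    """AUC, closest-topleft cutoff and bootstrap CIs in one pass.

    Sensitivity/specificity CIs are bootstrapped at the cutoff fixed on the
    full sample, matching how a frozen cutoff would be used prospectively.
    """
    v, y = _as_groups(values, labels)
    auc = roc_auc(v, y, direction)
    cutoff, sens, spec = closest_topleft_cutoff(v, y, direction)

    def _sens_at(vv, yy):
        pos = vv <= cutoff if direction == LOWER_IS_POSITIVE else vv >= cutoff
        return pos[yy].mean()

    def _spec_at(vv, yy):
        pos = vv <= cutoff if direction == LOWER_IS_POSITIVE else vv >= cutoff
        return (~pos[~yy]).mean()

    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)
    auc_ci = bootstrap_ci(
        lambda vv, yy: roc_auc(vv, yy, direction), v, y, n_boot, level, int(seeds[0])
    )
    sens_ci = bootstrap_ci(_sens_at, v, y, n_boot, level, int(seeds[1]))
    spec_ci = bootstrap_ci(_spec_at, v, y, n_boot, level, int(seeds[2]))
    return RocResult(
        auc=auc,
        auc_ci=auc_ci,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        sensitivity_ci=sens_ci,
        specificity_ci=spec_ci,
        direction=direction,
        n_case=int(y.sum()),
        n_control=int((~y).sum()),
    )


@dataclass
class LogisticFit:
    """Ridge-stabilized maximum-likelihood logistic fit."""

    coef: np.ndarray
    intercept: float
    se: np.ndarray  # standard errors for [intercept, coef...]
    converged: bool
    separation_flag: bool
    ridge: float

    def predict_proba(self, X) -> np.ndarray:
        eta = self.intercept + np.asarray(X, dtype=float) @ self.coef
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic_ridge(
    X,
    y,
    ridge: float = 1e-6,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    A tiny ridge penalty (on slopes only, default 1e-6) keeps the Newton step
    solvable under complete separation in small cross-validation folds; fits
    that run into separation are flagged rather than silently truncated.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on sample count")
    n, p = X.shape
    Xa = np.column_stack([np.ones(n), X])
    pen = np.diag(np.r_[0.0, np.full(p, ridge)])
    beta = np.zeros(p + 1)
    converged = False
    for _ in range(max_iter):
        eta = Xa @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = Xa.T @ (y - mu) - pen @ beta
        hess = (Xa * w[:, None]).T @ Xa + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = Xa @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (Xa * w[:, None]).T @ Xa + pen
    cov = np.linalg.inv(info)
    separation = (not converged) or bool(np.max(np.abs(beta)) > 50.0)
    return LogisticFit(
        coef=beta[1:],
        intercept=float(beta[0]),
        se=np.sqrt(np.diag(cov)),
        converged=converged,
        separation_flag=separation,
        ridge=ridge,
    )


def combine_genes_logistic(
    delta_cp: pd.DataFrame,
    labels,
    ridge: float = 1e-6,
) -> tuple[pd.Series, LogisticFit]:
    """Composite score for a gene subset: fitted probability of disease.

    ``delta_cp`` is samples x genes (complete cases only); the returned score
    feeds the usual ROC machinery with direction ``higher_is_positive``.
    """
    if delta_cp.isna().any().any():
        raise ValueError("delta_cp contains missing values; restrict to complete cases")
    y = np.asarray(labels, dtype=bool)
    fit = fit_logistic_ridge(delta_cp.to_numpy(dtype=float), y.astype(float), ridge=ridge)
    scores = pd.Series(
        fit.predict_proba(delta_cp.to_numpy(dtype=float)),
        index=delta_cp.index,
        name="score",
    )
    return scores, fit


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)


def _dunn_posthoc(values: np.ndarray, groups: np.ndarray, alpha: float) -> pd.DataFrame:
    """Dunn's z tests on mean ranks with Holm adjustment."""
    n = values.size
    ranks = stats.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    levels = np.unique(groups)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            gi = ranks[groups == levels[i]]
            gj = ranks[groups == levels[j]]
            se = np.sqrt(var_base * (1.0 / gi.size + 1.0 / gj.size))
            z = (gi.mean() - gj.mean()) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append((levels[i], levels[j], z, p))
    out = pd.DataFrame(rows, columns=["group1", "group2", "z", "p_raw"])
    if len(out):
        rej, p_adj, _, _ = multipletests(out["p_raw"], alpha=alpha, method="holm")
        out["p_adj"] = p_adj
        out["significant"] = rej
    return out


def group_comparison(values, groups, alpha: float = 0.05) -> GroupComparison:
    """Kruskal-Wallis across >=2 groups; Dunn-Holm posthoc when significant."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = np.unique(g)
    if levels.size < 2:
        raise ValueError("need at least two groups")
    samples = [v[g == lev] for lev in levels]
    if any(s.size == 0 for s in samples):
        raise ValueError("every group must be nonempty")
    if np.unique(v).size == 1:
        return GroupComparison(statistic=0.0, p_value=1.0)
    h, p = stats.kruskal(*samples)
    posthoc = _dunn_posthoc(v, g, alpha) if p < alpha else pd.DataFrame()
    return GroupComparison(statistic=float(h), p_value=float(p), posthoc=posthoc)
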