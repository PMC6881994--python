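"""The ovarian-cancer risk score: a logistic combination of gene delta_cp.

The score is ``epsilon + sum_i beta_i * delta_cp_i`` over the marker panel;
samples scoring at or above the cutoff are classified as disease.  Because
hypermethylation lowers delta_cp, the panel coefficients are negative.  The
module ships the published three-gene equation (AMPD3/NRN1/TBX15 with
coefficients -0.47/-0.41/-0.57, intercept 6.38, cutoff 0.73) and a
repeated, stratified 10-fold cross-validated fitting procedure whose
coefficients are aggregated (mean by default, median stored alongside) over
all folds of all replications.  A Hanley-McNeil AUC-based sample-size
planner sizes validation cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from .rocstats import (
    HIGHER_IS_POSITIVE,
    RocResult,
    closest_topleft_cutoff,
    fit_logistic_ridge,
    roc_analysis,
)

__all__ = [
    "RiskModel",
    "SampleSizePlan",
    "published_model",
    "score",
    "classify",
    "fit_cv_model",
    "evaluate",
    "auc_sample_size",
    "plan_study",
]

PUBLISHED_GENES = ("AMPD3", "NRN1", "TBX15")
PUBLISHED_COEFFICIENTS = (-0.47, -0.41, -0.57)
PUBLISHED_INTERCEPT = 6.38
PUBLISHED_CUTOFF = 0.73


@dataclass
class RiskModel:
    """A frozen risk-score: genes, per-gene coefficients, intercept, cutoff."""

    genes: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    cutoff: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.genes):
            raise ValueError("one coefficient per gene required")

    def to_json(self, path) -> None:
        payload = {
            "genes": list(self.genes),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "cutoff": self.cutoff,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            genes=tuple(d["genes"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            cutoff=float(d["cutoff"]),
            provenance=d.get("provenance", {}),
        )


def published_model() -> RiskModel:
    """The published three-gene risk equation with its cutoff of 0.73."""
    return RiskModel(
        genes=PUBLISHED_GENES,
        coefficients=np.asarray(PUBLISHED_COEFFICIENTS),
        intercept=PUBLISHED_INTERCEPT,
        cutoff=PUBLISHED_CUTOFF,
        provenance={"source": "published"},
    )


def _dcp_matrix(model: RiskModel, delta_cp) -> np.ndarray:
    """Extract the model's genes, in model order, as an (n, p) array."""
    if isinstance(delta_cp, Mapping):
        delta_cp = pd.DataFrame([delta_cp])
    missing = [g for g in model.genes if g not in delta_cp.columns]
    if missing:
        raise KeyError(f"delta_cp missing model gene(s): {', '.join(missing)}")
    x = delta_cp.loc[:, list(model.genes)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("delta_cp contains missing values for model genes")
    return x


def score(model: RiskModel, delta_cp) -> np.ndarray | float:
    """Risk score ``epsilon + sum beta_i * delta_cp_i`` per sample.

    ``delta_cp`` may be a single mapping ``{gene: value}`` (returns a float)
    or a samples x genes DataFrame (returns an array).
    """
    single = isinstance(delta_cp, Mapping)
    x = _dcp_matrix(model, delta_cp)
    s = model.intercept + x @ model.coefficients
    return float(s[0]) if single else s


def classify(model: RiskModel, scores) -> np.ndarray | bool:
    """Disease call: score >= cutoff (boundary counts as positive)."""
    s = np.asarray(scores, dtype=float)
    calls = s >= model.cutoff
    return bool(calls) if calls.ndim == 0 else calls


def fit_cv_model(
    delta_cp: pd.DataFrame,
    labels,
    folds: int = 10,
    replications: int = 200,
    seed: int = 0,
    aggregation: str = "mean",
    ridge: float = 1e-6,
) -> RiskModel:
    """Repeated stratified k-fold cross-validated logistic risk model.

    Each replication shuffles a stratified ``folds``-fold split; every
    training fold contributes one logistic fit.  The final coefficients and
    intercept are the ``aggregation`` (mean or median) over all
    folds x replications; both aggregates are stored in provenance.  The
    cutoff is chosen closest-topleft on the aggregated model's in-sample
    scores.
    """
    if aggregation not in ("mean", "median"):
        raise ValueError("aggregation must be 'mean' or 'median'")
    y = np.asarray(labels, dtype=bool)
    x = delta_cp.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("delta_cp contains missing values; restrict to complete cases")
    n_case, n_ctrl = int(y.sum()), int((~y).sum())
    if min(n_case, n_ctrl) < folds:
        raise ValueError(f"need >= {folds} samples per class for {folds}-fold stratified CV")
    rng = np.random.default_rng(seed)
    coefs = []
    any_separation = False
    for _ in range(replications):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(0, 2**31 - 1))
        )
        for train_idx, _test_idx in skf.split(x, y):
            fit = fit_logistic_ridge(x[train_idx], y[train_idx].astype(float), ridge=ridge)
            any_separation |= fit.separation_flag
            coefs.append(np.r_[fit.intercept, fit.coef])
    coefs = np.asarray(coefs)
    mean_c = coefs.mean(axis=0)
    median_c = np.median(coefs, axis=0)
    chosen = mean_c if aggregation == "mean" else median_c
    model = RiskModel(
        genes=tuple(delta_cp.columns),
        coefficients=chosen[1:],
        intercept=float(chosen[0]),
        cutoff=np.nan,
        provenance={
            "folds": folds,
            "replications": replications,
            "seed": seed,
            "aggregation": aggregation,
            "ridge": ridge,
            "separation_encountered": bool(any_separation),
            "mean_coefficients": mean_c[1:].tolist(),
            "median_coefficients": median_c[1:].tolist(),
            "mean_intercept": float(mean_c[0]),
            "median_intercept": float(median_c[0]),
            "n_fits": int(coefs.shape[0]),
        },
    )
    in_sample = score(model, delta_cp)
    cutoff, _, _ = closest_topleft_cutoff(in_sample, y, HIGHER_IS_POSITIVE)
    model.cutoff = float(cutoff)
    return model


def evaluate(
    model: RiskModel,
    delta_cp: pd.DataFrame,
    labels,
    n_boot: int = 200,
    seed: int | None = None,
) -> dict:
    """Apply a frozen model to a cohort and report sens/spec/AUC (+CIs).

    Samples with missing delta_cp for any model gene are excluded (and
    counted).  Sensitivity (specificity) at the frozen cutoff is NaN-flagged
    when the cohort has no cases (controls) instead of raising.
    """
    y = pd.Series(np.asarray(labels, dtype=bool), index=delta_cp.index)
    sub = delta_cp.loc[:, list(model.genes)]
    keep = sub.notna().all(axis=1)
    n_excluded = int((~keep).sum())
    sub, y = sub[keep], y[keep]
    if len(sub) == 0:
        raise ValueError("no valid samples to evaluate")
    s = score(model, sub)
    calls = classify(model, s)
    yv = y.to_numpy()
    sens = float(calls[yv].mean()) if yv.any() else np.nan
    spec = float((~calls[~yv]).mean()) if (~yv).any() else np.nan
    out = {
        "n": int(len(sub)),
        "n_case": int(yv.sum()),
        "n_control": int((~yv).sum()),
        "n_excluded": n_excluded,
        "sensitivity": sens,
        "specificity": spec,
        "auc": np.nan,
        "roc": None,
    }
    if yv.any() and (~yv).any():
        roc: RocResult = roc_analysis(
            s, yv, HIGHER_IS_POSITIVE, n_boot=n_boot, seed=seed
        )
        out["auc"] = roc.auc
        out["roc"] = roc
    return out


@dataclass
class SampleSizePlan:
    auc_alt: float
    auc_null: float
    alpha: float
    power: float
    ratio: float
    n_per_group: int
    train_to_test_ratio: float
    pad_per_group: int
    test_per_group: int
    train_per_group: int

    @property
    def test_total(self) -> int:
        return 2 * self.test_per_group

    @property
    def train_total(self) -> int:
        return 2 * self.train_per_group


def _hanley_mcneil_var(theta: float, n: int, ratio: float) -> float:
    """Variance of an AUC estimate for n cases and n*ratio controls."""
    q1 = theta / (2.0 - theta)
    q2 = 2.0 * theta**2 / (1.0 + theta)
    return (
        theta * (1.0 - theta)
        + (n - 1) * (q1 - theta**2)
        + (n * ratio - 1) * (q2 - theta**2)
    ) / (n**2 * ratio)


def auc_sample_size(
    theta_alt: float,
    theta_null: float = 0.5,
    alpha: float = 0.05,
    power: float = 0.8,
    ratio: float = 1.0,
    max_n: int = 100_000,
) -> int:
    """Smallest per-group n to detect AUC ``theta_alt`` against ``theta_null``.

    Two-sided test at level ``alpha`` with the requested power, using the
    Hanley-McNeil AUC variance under the null and the alternative.
    """
    if not (0.5 <= theta_null < theta_alt < 1.0):
        raise ValueError("need 0.5 <= theta_null < theta_alt < 1")
    z_a = sps.norm.ppf(1.0 - alpha / 2.0)
    z_b = sps.norm.ppf(power)
    gap = theta_alt - theta_null
    for n in range(2, max_n + 1):
        lhs = z_a * np.sqrt(_hanley_mcneil_var(theta_null, n, ratio)) + z_b * np.sqrt(
            _hanley_mcneil_var(theta_alt, n, ratio)
        )
        if lhs <= gap:
            return n
    raise RuntimeError(f"no solution below n={max_n}")


def plan_study(
    n_test_per_group: int,
    train_to_test_ratio: float = 1.5,
    pad_per_group: int = 2,
    theta_alt: float = 0.75,
    theta_null: float = 0.5,
    alpha: float = 0.05,
    power: float = 0.8,
    ratio: float = 1.0,
) -> SampleSizePlan:
    """Derive training/testing cohort sizes from a per-group base n.

    Testing gets ``n + pad`` per group; training gets
    ``round(train_to_test_ratio * n) + pad`` (half-up rounding, so 28.5
    becomes 29).  The pad guards against failed assays.
    """
    if n_test_per_group < 1:
        raise ValueError("n_test_per_group must be positive")
    test = n_test_per_group + pad_per_group
    train = int(np.floor(train_to_test_ratio * n_test_per_group + 0.5)) + pad_per_group
    return SampleSizePlan(
        auc_alt=theta_alt,
        auc_null=theta_null,
        alpha=alpha,
        power=power,
        ratio=ratio,
        n_per_group=n_test_per_group,
        train_to_test_ratio=train_to_test_ratio,
        pad_per_group=pad_per_group,
        test_per_group=test,
        train_per_group=train,
    )
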