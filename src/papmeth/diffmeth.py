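"""Shared highly-differentially-methylated (HDM) feature calling.

One routine serves both the tissue read-count stage and the array stages:
per feature it computes the group-median difference (the HDM level), a
two-sided Mann-Whitney p value and the AUC, then applies the stage's
thresholds.  A feature only passes if it is hypermethylated in cases
(positive HDM level); hypomethylation never passes regardless of p.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .rocstats import HIGHER_IS_POSITIVE, mann_whitney_two_tailed, roc_auc

__all__ = ["differential_table"]


def differential_table(
    values: pd.DataFrame,
    labels,
    delta_min: float,
    p_max: float,
    auc_min: float,
    level_stat: str = "median",
) -> pd.DataFrame:
    """Per-feature differential methylation for a features x samples matrix.

    Parameters
    ----------
    values
        Features (genes or probes) in rows, samples in columns.  Missing
        entries are handled feature-wise complete-case; features with an
        empty group after dropping NaNs are excluded with a warning.
    labels
        Boolean per sample, True = case.
    delta_min, p_max, auc_min
        Stage thresholds; ``pass`` requires hdm_level > max(0, delta_min),
        p < p_max and auc > auc_min.
    level_stat
        ``"median"`` (default, matches nonparametric testing) or ``"mean"``.

    Returns a DataFrame indexed by feature with columns
    ``hdm_level, p_value, auc, passed``.
    """
    y = np.asarray(labels, dtype=bool)
    if y.size != values.shape[1]:
        raise ValueError("labels length must match sample count")
    if not y.any() or y.all():
        raise ValueError("both groups must be nonempty")
    if level_stat not in ("median", "mean"):
        raise ValueError("level_stat must be 'median' or 'mean'")
    agg = np.nanmedian if level_stat == "median" else np.nanmean

    rows = {}
    dropped = []
    mat = values.to_numpy(dtype=float)
    for i, feature in enumerate(values.index):
        row = mat[i]
        ok = np.isfinite(row)
        yy = y[ok]
        if not yy.any() or yy.all():
            dropped.append(feature)
            continue
        case = row[ok][yy]
        ctrl = row[ok][~yy]
        level = float(agg(case) - agg(ctrl))
        _, p = mann_whitney_two_tailed(case, ctrl)
        auc = roc_auc(row[ok], yy, HIGHER_IS_POSITIVE)
        passed = (level > 0) and (level > delta_min) and (p < p_max) and (auc > auc_min)
        rows[feature] = (level, p, auc, passed)
    if dropped:
        warnings.warn(
            f"{len(dropped)} feature(s) dropped: one group entirely missing",
            stacklevel=2,
        )
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["hdm_level", "p_value", "auc", "passed"]
    )
    out.index.name = values.index.name or "feature"
    out["passed"] = out["passed"].astype(bool)
    return out
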