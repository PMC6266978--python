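"""Xenograft response phenotyping.

Each tumor model (cell-line or PDX xenograft) is grown in control and
retinoid-treated arms; the decision variable is final tumor weight.  The
fold change treated/control together with a two-sample t-test partitions
models into three response phenotypes:

* ``sensitive`` -- treatment significantly reduced tumor weight (FC < 1),
* ``promoted``  -- treatment significantly increased tumor weight (FC > 1),
* ``resistant`` -- no significant effect.

The binary supervision contrast used by all downstream biomarker discovery
is sensitive vs everything else (``other`` = resistant + promoted).
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_fold_change",
    "categorize_response",
    "label_models",
    "association_test",
]

CATEGORIES = ("sensitive", "resistant", "promoted")


def compute_fold_change(treated_weights, control_weights, equal_var: bool = False):
    """Fold change of mean tumor weight (treated/control) and t-test p-value.

    Welch's unequal-variance t is the default; ``equal_var=True`` gives the
    pooled-variance Student t.  Two degenerate cases are resolved explicitly:
    if both arms are constant and equal the p-value is reported as 1.0, and
    as 0.0 if constant but different.
    """
    t_arr = np.asarray(treated_weights, dtype=float)
    c_arr = np.asarray(control_weights, dtype=float)
    if t_arr.size < 2 or c_arr.size < 2:
        raise ValueError("need >= 2 weights per arm")
    if np.any(t_arr <= 0) or np.any(c_arr <= 0):
        raise ValueError("tumor weights must be strictly positive")
    fc = float(t_arr.mean() / c_arr.mean())
    with warnings.catch_warnings():
        # near-identical arms trip scipy's precision-loss warning; the
        # degenerate outcome is resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(t_arr, c_arr, equal_var=equal_var)
    p = float(res.pvalue)
    if np.isnan(p):  # zero variance in both arms
        p = 1.0 if np.isclose(t_arr.mean(), c_arr.mean()) else 0.0
    return fc, p


def categorize_response(fold_change: float, p_value: float, alpha: float = 0.05) -> str:
    """Map (fold change, p) to a response phenotype.

    sensitive if p < alpha and FC < 1; promoted if p < alpha and FC > 1;
    resistant otherwise.
    """
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    if p_value < alpha:
        if fold_change < 1:
            return "sensitive"
        if fold_change > 1:
            return "promoted"
    return "resistant"


def label_models(growth: pd.DataFrame, alpha: float = 0.05, equal_var: bool = False) -> pd.DataFrame:
    """Phenotype every model in a growth table.

    ``growth`` needs columns ``model_id``, ``arm`` (control/treated) and
    ``final_weight``.  Returns one row per model with fold change, p-value,
    category and the binary supervision class.
    """
    required = {"model_id", "arm", "final_weight"}
    missing = required - set(growth.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    rows = []
    for model_id, sub in growth.groupby("model_id", sort=True):
        treated = sub.loc[sub["arm"] == "treated", "final_weight"].to_numpy()
        control = sub.loc[sub["arm"] == "control", "final_weight"].to_numpy()
        fc, p = compute_fold_change(treated, control, equal_var=equal_var)
        cat = categorize_response(fc, p, alpha=alpha)
        rows.append(
            {
                "model_id": model_id,
                "fold_change": fc,
                "p_value": p,
                "category": cat,
                "supervision_class": "sensitive" if cat == "sensitive" else "other",
            }
        )
    return pd.DataFrame(rows)


def association_test(labels: Mapping[str, str], covariate: Mapping[str, bool]):
    """Fisher's exact test of supervision class vs a binary model covariate.

    ``labels`` maps model id -> {'sensitive', 'other'}; ``covariate`` maps
    the same ids -> bool.  Returns the 2x2 table (rows: sensitive/other,
    columns: covariate True/False) and the two-sided exact p-value from
    hypergeometric tail summation.
    """
    if set(labels) != set(covariate):
        raise ValueError("labels and covariate must cover the same model ids")
    table = np.zeros((2, 2), dtype=int)
    for model_id, lab in labels.items():
        if lab not in ("sensitive", "other"):
            raise ValueError(f"invalid supervision class {lab!r} for {model_id}")
        i = 0 if lab == "sensitive" else 1
        j = 0 if covariate[model_id] else 1
        table[i, j] += 1
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)
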