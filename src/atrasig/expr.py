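"""Differential expression between supervision classes and qPCR quantification.

Two contrasts are supported on log2 expression matrices:

* ``baseline`` -- untreated arrays, sensitive models vs all others;
* ``induced``  -- each model is first reduced to its per-feature induction
  value (treated log2 minus control log2), and the classes are compared on
  those inductions.

Both use the shared moderated two-group machinery (`atrasig._moderated`);
cutoff flags follow |log2 FC| > 0.7 and p < 0.01 by default, with BH
q-values always reported alongside the raw p-values.

qPCR relative expression is efficiency-corrected and normalized to the
geometric mean of two reference genes:

    rel(g, s) = E_g^(-Cq_gs) / geomean_r( E_r^(-Cq_rs) )
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._moderated import two_group_test

__all__ = ["differential_expression", "induction_table", "qpcr_relative_expression"]


def _class_mask(columns, classes: pd.Series) -> np.ndarray:
    classes = pd.Series(classes)
    missing = [c for c in columns if c not in classes.index]
    if missing:
        raise ValueError(f"samples without class label: {missing}")
    vals = classes.loc[list(columns)]
    bad = sorted(set(vals) - {"sensitive", "other"})
    if bad:
        raise ValueError(f"invalid class labels: {bad}")
    return (vals == "sensitive").to_numpy()


def induction_table(expr_treated: pd.DataFrame, expr_control: pd.DataFrame) -> pd.DataFrame:
    """Per-(feature, model) log2 induction: treated minus control."""
    if set(expr_treated.columns) != set(expr_control.columns):
        unpaired = set(expr_treated.columns) ^ set(expr_control.columns)
        raise ValueError(f"unpaired models between arms: {sorted(unpaired)}")
    if not expr_treated.index.equals(expr_control.index):
        raise ValueError("feature indices differ between arms")
    return expr_treated - expr_control[expr_treated.columns]


def differential_expression(
    expr: pd.DataFrame,
    classes: pd.Series,
    contrast: str = "baseline",
    expr_treated: pd.DataFrame | None = None,
    fc_cutoff: float = 0.7,
    p_cutoff: float = 0.01,
    moderated: bool = True,
) -> pd.DataFrame:
    """Two-group differential expression for one contrast.

    For ``contrast='baseline'`` ``expr`` holds untreated log2 values.  For
    ``contrast='induced'`` ``expr`` holds the control arm and
    ``expr_treated`` the paired treated arm; the test runs on per-model
    inductions.  Returns a DataFrame sorted by p with columns ``feature``,
    ``log2_fc``, ``t``, ``p_value``, ``q_value``, ``passes_cutoff``,
    ``contrast``.
    """
    if contrast not in ("baseline", "induced"):
        raise ValueError("contrast must be 'baseline' or 'induced'")
    if contrast == "induced":
        if expr_treated is None:
            raise ValueError("contrast='induced' requires expr_treated")
        values = induction_table(expr_treated, expr)
    else:
        values = expr
    if not values.index.is_unique or not values.columns.is_unique:
        raise ValueError("feature and sample ids must be unique")
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError("expression values must be finite")
    mask = _class_mask(values.columns, classes)
    res = two_group_test(values.to_numpy(), mask, moderated=moderated)
    q = multipletests(res["p"], method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "feature": values.index,
            "log2_fc": res["diff"],
            "t": res["t"],
            "p_value": res["p"],
            "q_value": q,
            "contrast": contrast,
        }
    )
    out["passes_cutoff"] = (out["log2_fc"].abs() > fc_cutoff) & (out["p_value"] < p_cutoff)
    out = out.sort_values(["p_value", "feature"], kind="mergesort").reset_index(drop=True)
    return out


def qpcr_relative_expression(
    cq: pd.DataFrame,
    efficiencies: Mapping[str, float],
    reference_genes: Sequence[str] = ("GAPDH", "B2M"),
) -> pd.DataFrame:
    """Efficiency-corrected relative expression from Cq values.

    ``cq`` is genes x samples (cycles); ``efficiencies`` maps each gene,
    including the references, to its amplification efficiency E in (1, 2].
    Output is target genes x samples; ratios of two outputs (e.g. the
    FABP5/CRABP2 ratio) are plain element-wise quotients.
    """
    ref = list(reference_genes)
    for r in ref:
        if r not in cq.index:
            raise ValueError(f"reference gene {r!r} missing from Cq table")
    for g in cq.index:
        if g not in efficiencies:
            raise ValueError(f"no primer efficiency for gene {g!r}")
        e = efficiencies[g]
        if not (1.0 < e <= 2.0):
            raise ValueError(f"efficiency for {g!r} must be in (1, 2], got {e}")
    for g in cq.index:
        for s in cq.columns:
            v = cq.at[g, s]
            if pd.isna(v):
                raise ValueError(f"missing Cq for gene {g!r}, sample {s!r}")
            if v <= 0:
                raise ValueError(f"non-positive Cq for gene {g!r}, sample {s!r}")
    eff = np.array([float(efficiencies[g]) for g in cq.index])
    # quantity proportional to starting template: E^(-Cq)
    log_quant = -np.log(eff)[:, None] * cq.to_numpy()
    ref_pos = [cq.index.get_loc(r) for r in ref]
    log_norm = log_quant[ref_pos].mean(axis=0)  # log of geometric mean
    targets = [g for g in cq.index if g not in ref]
    rows = [cq.index.get_loc(g) for g in targets]
    rel = np.exp(log_quant[rows] - log_norm[None, :])
    return pd.DataFrame(rel, index=pd.Index(targets, name=cq.index.name), columns=cq.columns)
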