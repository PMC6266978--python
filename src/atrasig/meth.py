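"""Differential methylation, probe annotation and gene-set intersection.

Beta-values (methylation fractions in [0,1]) are tested on the M scale
M = log2(beta/(1-beta)), which is variance-stabilized for linear modelling,
while effect sizes are always reported as delta-beta on the original scale.
Probes flagged as cross-reactive or SNP-associated in the manifest are
removed before testing.  CpG island context uses fixed Illumina-style
flanks: shore = within 2 kb of an island edge, shelf = 2-4 kb, otherwise
open sea, with half-open boundaries (a probe exactly 2,000 bp from an edge
is shelf).
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._moderated import two_group_test
from .expr import _class_mask

__all__ = [
    "BETA_EPS",
    "beta_to_m",
    "m_to_beta",
    "filter_probes",
    "differential_methylation",
    "island_relations",
    "annotate_island_context",
    "probes_to_genes",
    "intersect_gene_sets",
    "spearman",
    "methylation_expression_correlation",
]

logger = logging.getLogger(__name__)

BETA_EPS = 1e-6
SHORE_BP = 2000
SHELF_BP = 4000
ISLAND_RELATIONS = ("island", "n_shore", "s_shore", "n_shelf", "s_shelf", "open_sea")


def beta_to_m(beta, eps: float = BETA_EPS):
    """M = log2(beta/(1-beta)) with beta clipped to [eps, 1-eps]."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))


def m_to_beta(m):
    """Inverse logit2: beta = 2^M / (2^M + 1)."""
    m = np.asarray(m, dtype=float)
    return 1.0 / (1.0 + np.exp2(-m))


def filter_probes(beta: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Drop blacklisted (cross-reactive / SNP-associated) probes.

    Every probe in ``beta`` must appear in the manifest; the number of
    dropped probes is logged.
    """
    manifest = manifest.set_index("probe_id") if "probe_id" in manifest.columns else manifest
    missing = beta.index.difference(manifest.index)
    if len(missing) > 0:
        raise ValueError(f"probes absent from manifest: {sorted(missing)[:10]}")
    black = manifest.loc[beta.index, "blacklist"].astype(bool)
    kept = beta.loc[~black.to_numpy()]
    logger.info("filter_probes: dropped %d of %d probes", int(black.sum()), len(beta))
    return kept


def differential_methylation(
    beta: pd.DataFrame,
    classes: pd.Series,
    scale: str = "M",
    p_cutoff: float = 0.01,
    moderated: bool = True,
) -> pd.DataFrame:
    """Supervised two-group differential methylation per probe.

    ``beta`` is probes x samples in [0,1]; ``classes`` maps sample ids to
    'sensitive'/'other'.  The test runs on the chosen scale ('M' default,
    'beta' optional); ``delta_beta`` is always mean beta(sensitive) minus
    mean beta(other).  ``significant`` flags p < p_cutoff; BH q-values are
    reported alongside.
    """
    if scale not in ("M", "beta"):
        raise ValueError("scale must be 'M' or 'beta'")
    vals = beta.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("beta values must lie in [0, 1]")
    if not beta.index.is_unique:
        raise ValueError("probe ids must be unique")
    mask = _class_mask(beta.columns, classes)
    X = beta_to_m(vals) if scale == "M" else vals
    res = two_group_test(X, mask, moderated=moderated)
    delta_beta = vals[:, mask].mean(axis=1) - vals[:, ~mask].mean(axis=1)
    q = multipletests(res["p"], method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "probe_id": beta.index,
            "delta_beta": delta_beta,
            "t": res["t"],
            "p_value": res["p"],
            "q_value": q,
        }
    )
    out["significant"] = out["p_value"] < p_cutoff
    out = out.sort_values(["p_value", "probe_id"], kind="mergesort").reset_index(drop=True)
    return out


def _merged_islands(islands: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Sort and merge island intervals (0-based half-open) per chromosome."""
    out = {}
    for chrom, sub in islands.groupby("chrom"):
        ivs = sub[["start", "end"]].sort_values("start").to_numpy()
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def island_relations(chroms: Sequence[str], positions: Sequence[int], islands: pd.DataFrame) -> np.ndarray:
    """CpG island relation for 1-based probe positions by interval arithmetic.

    Distance d to the nearest island edge classifies a probe outside all
    islands: shore for 1 <= d < 2000, shelf for 2000 <= d < 4000, open sea
    beyond.  North (n_) means the probe lies 5' of (before) its nearest
    island; equidistant ties resolve north.
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    if np.any(pd.isna(positions)) or np.any(positions < 1):
        raise ValueError("every probe needs a valid 1-based position")
    by_chrom = _merged_islands(islands)
    rel = np.empty(len(positions), dtype=object)
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        p0 = positions[sel] - 1  # 0-based point
        if chrom not in by_chrom:
            rel[sel] = "open_sea"
            continue
        starts, ends = by_chrom[chrom]
        idx = np.searchsorted(starts, p0, side="right") - 1
        inside = (idx >= 0) & (p0 < ends[np.clip(idx, 0, None)])
        d_left = np.where(idx >= 0, p0 - ends[np.clip(idx, 0, None)] + 1, np.iinfo(np.int64).max)
        right = idx + 1
        has_right = right < len(starts)
        d_right = np.where(has_right, starts[np.clip(right, None, len(starts) - 1)] - p0, np.iinfo(np.int64).max)
        north = d_right <= d_left  # probe before the nearest island
        d = np.minimum(d_left, d_right)
        r = np.where(
            d < SHORE_BP,
            np.where(north, "n_shore", "s_shore"),
            np.where(d < SHELF_BP, np.where(north, "n_shelf", "s_shelf"), "open_sea"),
        )
        r = np.where(inside, "island", r)
        rel[sel] = r
    return rel


def annotate_island_context(
    dmp_probe_ids: Iterable[str], manifest: pd.DataFrame, islands: pd.DataFrame
):
    """Island relation of each DMP plus frequency table vs all-probe background.

    Returns ``(relations, table)`` where ``relations`` is a Series over the
    DMP probes and ``table`` has one row per relation with columns ``dmp``
    and ``background``, each summing to 1.
    """
    man = manifest.set_index("probe_id") if "probe_id" in manifest.columns else manifest
    dmp_ids = list(dmp_probe_ids)
    missing = [p for p in dmp_ids if p not in man.index]
    if missing:
        raise ValueError(f"probes absent from manifest: {missing[:10]}")
    all_rel = pd.Series(
        island_relations(man["chrom"].to_numpy(), man["pos"].to_numpy(), islands),
        index=man.index,
    )
    dmp_rel = all_rel.loc[dmp_ids]
    table = pd.DataFrame(
        {
            "dmp": dmp_rel.value_counts(normalize=True),
            "background": all_rel.value_counts(normalize=True),
        }
    ).reindex(ISLAND_RELATIONS).fillna(0.0)
    return dmp_rel, table


def probes_to_genes(probe_ids: Iterable[str], manifest: pd.DataFrame) -> set[str]:
    """Union of gene associations for a probe set.

    Manifest ``gene`` entries are semicolon-separated ``GENE:REGION`` tags
    (empty for unannotated probes); a probe mapping to several genes
    contributes to all of them.
    """
    man = manifest.set_index("probe_id") if "probe_id" in manifest.columns else manifest
    genes: set[str] = set()
    for pid in probe_ids:
        if pid not in man.index:
            continue
        entry = man.at[pid, "gene"]
        if pd.isna(entry) or entry == "":
            continue
        for tag in str(entry).split(";"):
            genes.add(tag.split(":")[0])
    return genes


def intersect_gene_sets(dm_genes, de_baseline_genes, de_induced_genes) -> dict:
    """All seven Venn regions of the three gene lists.

    The triple intersection is the predicted methylation-regulated gene set.
    Region keys name the lists each region belongs to exclusively.
    """
    A, B, C = set(dm_genes), set(de_baseline_genes), set(de_induced_genes)
    regions = {
        "dm_only": A - B - C,
        "de_baseline_only": B - A - C,
        "de_induced_only": C - A - B,
        "dm_de_baseline": (A & B) - C,
        "dm_de_induced": (A & C) - B,
        "de_baseline_de_induced": (B & C) - A,
        "triple": A & B & C,
    }
    regions["counts"] = {k: len(v) for k, v in regions.items()}
    return regions


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n."""
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum(axis=1))
    rhos = (ryc @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x, y, exact_max_n: int = 9):
    """Spearman rank correlation with average-rank ties.

    p-values come from the t-approximation for n > ``exact_max_n`` and from
    full permutation enumeration for small n.  Degenerate (constant) input
    yields (nan, nan, note).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), "degenerate: constant input"
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p, ""


def methylation_expression_correlation(
    beta: pd.DataFrame, expr: pd.DataFrame, pairs: Iterable[tuple[str, str]]
) -> pd.DataFrame:
    """Per-(probe, gene) Spearman correlation across shared samples."""
    shared = [s for s in beta.columns if s in expr.columns]
    rows = []
    for probe, gene in pairs:
        if len(shared) < 4:
            raise ValueError(f"pair ({probe}, {gene}): fewer than 4 shared samples")
        rho, p, note = spearman(beta.loc[probe, shared], expr.loc[gene, shared])
        rows.append({"probe_id": probe, "gene": gene, "rho": rho, "p_value": p, "n": len(shared), "note": note})
    return pd.DataFrame(rows)
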