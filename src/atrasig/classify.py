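"""Signature refinement and per-sample reference-panel classification.

The deployable classifier is a small ordered set of CpG probes together
with the reference panel's beta-values and labels.  A query sample is
classified by appending it to the reference matrix, hierarchically
clustering, and reading off the label composition of the smallest
dendrogram cluster that contains the query and at least one reference
(clade-purity rule): all-sensitive -> predicted-sensitive, all-other ->
resistant, mixed -> ambiguous.  Queries are always clustered one at a time
so a call never depends on the rest of the cohort.

The agglomerative clusterer is implemented here with an explicit
deterministic tie-break (smallest pair of cluster indices) and emits a
scipy-compatible merge matrix, so downstream utilities such as
``scipy.cluster.hierarchy.cophenet`` apply directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meth import differential_methylation

__all__ = [
    "SignatureModel",
    "ClassificationResult",
    "harmonize_probes",
    "refine_signature",
    "pairwise_distances",
    "cluster",
    "classify_sample",
    "classify_cohort",
    "cohort_summary",
]

CATEGORIES = ("predicted-sensitive", "ambiguous", "resistant")


@dataclass
class SignatureModel:
    """Ordered probe list + reference panel; everything needed to classify."""

    probes: list[str]
    reference: pd.DataFrame  # samples x probes
    labels: pd.Series  # sample -> 'sensitive' | 'other'
    sublabels: pd.Series | None = None  # sample -> 'cell_line' | 'pdx'
    metric: str = "euclidean"
    linkage: str = "complete"
    p_threshold: float = 0.01
    k: int = 6
    warning: bool = False
    ranking: str = "p, then |delta_beta| desc, then probe id"

    def __post_init__(self):
        if len(self.probes) < 1:
            raise ValueError("signature needs at least one probe")
        missing = [p for p in self.probes if p not in self.reference.columns]
        if missing:
            raise ValueError(f"probes absent from reference matrix: {missing}")
        labs = set(self.labels.loc[self.reference.index])
        if not labs or not labs <= {"sensitive", "other"}:
            raise ValueError("reference labels must be 'sensitive' or 'other'")

    def to_json(self) -> str:
        payload = {
            "probes": self.probes,
            "samples": list(self.reference.index),
            "beta": self.reference[self.probes].to_numpy().tolist(),
            "labels": self.labels.loc[self.reference.index].to_dict(),
            "sublabels": None if self.sublabels is None else self.sublabels.to_dict(),
            "metric": self.metric,
            "linkage": self.linkage,
            "p_threshold": self.p_threshold,
            "k": self.k,
            "warning": self.warning,
            "ranking": self.ranking,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        d = json.loads(text)
        ref = pd.DataFrame(d["beta"], index=d["samples"], columns=d["probes"])
        return cls(
            probes=d["probes"],
            reference=ref,
            labels=pd.Series(d["labels"]),
            sublabels=None if d["sublabels"] is None else pd.Series(d["sublabels"]),
            metric=d["metric"],
            linkage=d["linkage"],
            p_threshold=d["p_threshold"],
            k=d["k"],
            warning=d["warning"],
            ranking=d.get("ranking", ""),
        )


@dataclass
class ClassificationResult:
    query_id: str
    category: str
    cluster_members: list[tuple[str, str]]  # (reference sample, label)
    cophenetic_height: float


def harmonize_probes(probes_a, probes_b, candidate_probes) -> list[str]:
    """Candidate probes present on both platforms, original order preserved."""
    a, b = set(probes_a), set(probes_b)
    kept = [p for p in candidate_probes if p in a and p in b]
    if not kept:
        raise ValueError("no candidate probe is shared by both platforms; signature impossible")
    return kept


def refine_signature(
    beta_panel: pd.DataFrame,
    labels: pd.Series,
    p_threshold: float = 0.01,
    k: int = 6,
    scale: str = "M",
    metric: str = "euclidean",
    linkage: str = "complete",
    sublabels: pd.Series | None = None,
) -> SignatureModel:
    """Re-test the harmonized candidates with PDXs in the sensitive class.

    Probes with p < ``p_threshold`` are ranked by ascending p, ties broken
    by descending |delta beta| then probe id, and the top ``k`` become the
    signature.  If fewer than ``k`` pass, all passing probes are returned
    with ``warning=True``; zero passing is an error.
    """
    dm = differential_methylation(beta_panel, labels, scale=scale, p_cutoff=p_threshold)
    passing = dm[dm["significant"]].copy()
    if len(passing) == 0:
        raise ValueError(f"no probe passes p < {p_threshold}; cannot build signature")
    passing["abs_db"] = passing["delta_beta"].abs()
    passing = passing.sort_values(
        ["p_value", "abs_db", "probe_id"], ascending=[True, False, True], kind="mergesort"
    )
    warning = len(passing) < k
    top = passing["probe_id"].head(k).tolist()
    return SignatureModel(
        probes=top,
        reference=beta_panel.loc[top].T.copy(),
        labels=labels.loc[beta_panel.columns].copy(),
        sublabels=None if sublabels is None else sublabels.loc[beta_panel.columns].copy(),
        metric=metric,
        linkage=linkage,
        p_threshold=p_threshold,
        k=k,
        warning=warning,
    )


def pairwise_distances(X: np.ndarray, metric: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if metric == "euclidean":
        diff = X[:, None, :] - X[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    if metric == "manhattan":
        diff = X[:, None, :] - X[None, :, :]
        return np.abs(diff).sum(axis=2)
    if metric == "correlation":
        sd = X.std(axis=1)
        if np.any(sd == 0):
            raise ValueError("correlation metric undefined for constant rows")
        return 1.0 - np.corrcoef(X)
    raise ValueError(f"unknown metric {metric!r}")


def cluster(matrix, metric: str = "euclidean", linkage: str = "complete") -> np.ndarray:
    """Agglomerative dendrogram over the rows of ``matrix``.

    Returns a scipy-style merge matrix Z of shape (n-1, 4): each row is
    (cluster_a, cluster_b, height, size) with new clusters numbered n,
    n+1, ...  Ties in the minimum inter-cluster distance are broken by the
    smallest pair of cluster indices, so the dendrogram is deterministic.
    Ward linkage requires euclidean input and reports scipy-compatible
    heights (sqrt of the Lance-Williams-updated squared distance).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains missing or non-finite values")
    if linkage not in ("complete", "average", "ward"):
        raise ValueError(f"unknown linkage {linkage!r}")
    if linkage == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the euclidean metric")
    n = X.shape[0]
    D = pairwise_distances(X, metric)
    if linkage == "ward":
        D = D**2
    np.fill_diagonal(D, np.inf)

    ids = list(range(n))  # ascending cluster ids, stays sorted as merges append
    sizes = {i: 1 for i in range(n)}
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        k = len(ids)
        # row-major scan over i<j finds the lexicographically smallest tied pair
        iu = np.triu_indices(k, 1)
        flat = D[iu]
        best = int(np.argmin(flat))
        i, j = int(iu[0][best]), int(iu[1][best])
        a, b = ids[i], ids[j]
        dist = D[i, j]
        height = float(np.sqrt(dist)) if linkage == "ward" else float(dist)
        new_id = n + step
        new_size = sizes[a] + sizes[b]
        Z[step] = (a, b, height, new_size)

        # Lance-Williams update of distances to the merged cluster
        keep = [x for x in range(k) if x not in (i, j)]
        d_ia = D[i, keep]
        d_jb = D[j, keep]
        if linkage == "complete":
            d_new = np.maximum(d_ia, d_jb)
        elif linkage == "average":
            d_new = (sizes[a] * d_ia + sizes[b] * d_jb) / new_size
        else:  # ward, on squared distances
            nk = np.array([sizes[ids[x]] for x in keep], dtype=float)
            d_new = ((sizes[a] + nk) * d_ia + (sizes[b] + nk) * d_jb - nk * D[i, j]) / (new_size + nk)
        D = D[np.ix_(keep, keep)]
        D = np.pad(D, ((0, 1), (0, 1)), constant_values=0.0)
        D[-1, :-1] = d_new
        D[:-1, -1] = d_new
        D[-1, -1] = np.inf
        ids = [ids[x] for x in keep] + [new_id]
        sizes[new_id] = new_size
    return Z


def _leaf_sets(Z: np.ndarray, n: int) -> list[set[int]]:
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    out = []
    for step, (a, b, _h, _s) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        out.append(merged)
    return out


def classify_sample(query: pd.Series, model: SignatureModel, rule: str = "clade", margin: float = 0.2) -> ClassificationResult:
    """Classify one query sample against the reference panel.

    ``rule='clade'`` (default) applies the smallest-enclosing-cluster
    purity rule.  ``rule='centroid'`` is a nearest-centroid alternative:
    the query is ambiguous when the two class-centroid distances differ by
    less than ``margin`` (relative to the larger), otherwise it takes the
    nearer class.
    """
    missing = [p for p in model.probes if p not in query.index or pd.isna(query[p])]
    if missing:
        raise ValueError(f"query missing signature probes: {missing}")
    q = query[model.probes].to_numpy(dtype=float)
    ref = model.reference[model.probes].to_numpy(dtype=float)
    ref_labels = model.labels.loc[model.reference.index].to_numpy()
    qid = str(query.name) if query.name is not None else "query"

    if rule == "centroid":
        c_sens = ref[ref_labels == "sensitive"].mean(axis=0)
        c_other = ref[ref_labels == "other"].mean(axis=0)
        d_s = float(np.linalg.norm(q - c_sens))
        d_o = float(np.linalg.norm(q - c_other))
        scale = max(d_s, d_o, 1e-12)
        if abs(d_s - d_o) / scale < margin:
            cat = "ambiguous"
        else:
            cat = "predicted-sensitive" if d_s < d_o else "resistant"
        members = list(zip(model.reference.index, ref_labels))
        return ClassificationResult(qid, cat, members, float("nan"))
    if rule != "clade":
        raise ValueError(f"unknown rule {rule!r}")

    # a panel with no separation carries no signal: every query is ambiguous
    if np.all(ref == ref[0]):
        members = list(zip(model.reference.index, ref_labels))
        return ClassificationResult(qid, "ambiguous", members, float("nan"))

    X = np.vstack([ref, q])
    n = X.shape[0]
    q_idx = n - 1
    Z = cluster(X, metric=model.metric, linkage=model.linkage)
    # merge heights are monotone, so the first merge containing the query
    # is its smallest enclosing cluster with >= 1 reference
    for step, merged in enumerate(_leaf_sets(Z, n)):
        if q_idx in merged:
            ref_members = sorted(m for m in merged if m != q_idx)
            labs = {ref_labels[m] for m in ref_members}
            if labs == {"sensitive"}:
                cat = "predicted-sensitive"
            elif labs == {"other"}:
                cat = "resistant"
            else:
                cat = "ambiguous"
            members = [(model.reference.index[m], ref_labels[m]) for m in ref_members]
            return ClassificationResult(qid, cat, members, float(Z[step, 2]))
    raise AssertionError("query never merged; dendrogram invalid")


def classify_cohort(queries: pd.DataFrame, model: SignatureModel, rule: str = "clade") -> pd.DataFrame:
    """Classify every column of a probes x samples query matrix, one at a time."""
    rows = []
    for sample in queries.columns:
        res = classify_sample(queries[sample], model, rule=rule)
        rows.append(
            {
                "query_id": sample,
                "category": res.category,
                "cluster_members": ";".join(m for m, _ in res.cluster_members),
                "cophenetic_height": res.cophenetic_height,
            }
        )
    return pd.DataFrame(rows)


def cohort_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of each category; fractions NA for an empty cohort."""
    total = len(calls)
    counts = {c: int((calls["category"] == c).sum()) if total else 0 for c in CATEGORIES}
    fracs = {c: (counts[c] / total if total else float("nan")) for c in CATEGORIES}
    return pd.DataFrame({"count": counts, "fraction": fracs})
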