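"""End-to-end discovery pipeline on a cohort.

Runs the full chain the package implements: blacklist filtering ->
supervised differential methylation on the cell lines -> platform
harmonization of the candidate probes -> PDX-augmented refinement to the
top-k signature -> one-at-a-time classification of every query ->
cohort summary.  Intermediate tables are returned so each stage can be
inspected or re-used.
"""

from __future__ import annotations

import pandas as pd

from .classify import classify_cohort, cohort_summary, harmonize_probes, refine_signature
from .meth import differential_methylation, filter_probes
from .synth import Cohort

__all__ = ["run_discovery"]


def run_discovery(
    cohort: Cohort,
    p_dmp: float = 0.01,
    p_refine: float = 0.01,
    k: int = 6,
    metric: str = "euclidean",
    linkage: str = "complete",
) -> dict:
    """Discover the signature on a cohort and classify its queries.

    Stage 1 tests cell lines only (sensitive vs other); stage 2 re-tests
    the harmonized candidates with PDXs added to the sensitive class and
    keeps the top ``k`` probes; stage 3 classifies each query individually.
    """
    beta = filter_probes(cohort.panel_beta, cohort.manifest)
    lines = cohort.line_labels
    dm = differential_methylation(beta[lines.index], lines, p_cutoff=p_dmp)
    candidates = dm.loc[dm["significant"], "probe_id"].tolist()

    man = cohort.manifest.set_index("probe_id")
    plat = man["platform"]
    hm450 = set(plat.index[(plat == "HM450") | (plat == "both")])
    epic = set(plat.index[(plat == "EPIC") | (plat == "both")])
    harmonized = harmonize_probes(hm450, epic, candidates)

    panel_labels = cohort.panel_labels
    sublabels = pd.Series(
        cohort.samples.set_index("sample_id").loc[panel_labels.index, "sample_type"]
    )
    model = refine_signature(
        beta.loc[harmonized, panel_labels.index],
        panel_labels,
        p_threshold=p_refine,
        k=k,
        metric=metric,
        linkage=linkage,
        sublabels=sublabels,
    )
    calls = classify_cohort(cohort.query_beta.loc[model.probes], model)
    summary = cohort_summary(calls)
    return {
        "dmp": dm,
        "candidates": candidates,
        "harmonized": harmonized,
        "signature": model,
        "calls": calls,
        "summary": summary,
    }
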