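"""Direct-repeat response-element scanning (RARE / PPRE).

Retinoic-acid response elements are direct repeats of the nuclear-receptor
half-site RGKTCA separated by 1, 2 or 5 bp spacers (DR1/DR2/DR5); PPREs are
DR1 repeats of the same half-site.  Matching is exact IUPAC matching on
both strands -- no mismatches, no position-weight scoring.  An 'N' in the
genome matches only an 'N' pattern code; spacer positions match anything.
Hit coordinates are always reported on the forward strand, 0-based
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MotifSpec",
    "rare_spec",
    "ppre_spec",
    "reverse_complement",
    "scan_motifs",
    "genes_near_motifs",
    "annotate_de_lists",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}
IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "S": "S", "W": "W", "N": "N",
}


@dataclass(frozen=True)
class MotifSpec:
    """A direct-repeat motif: half-site, allowed spacer lengths, both strands."""

    name: str = "custom"
    half_site: str = "RGKTCA"
    spacers: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.half_site:
            raise ValueError("half_site must be non-empty")
        bad = sorted(set(self.half_site.upper()) - set(IUPAC))
        if bad:
            raise ValueError(f"invalid IUPAC codes in half_site: {bad}")
        if any(s < 0 for s in self.spacers):
            raise ValueError("spacers must be >= 0")

    def pattern(self, spacer: int) -> str:
        h = self.half_site.upper()
        return h + "N" * spacer + h


def rare_spec() -> MotifSpec:
    """Canonical RARE: DR1/DR2/DR5 repeats of RGKTCA."""
    return MotifSpec(name="RARE", half_site="RGKTCA", spacers=(1, 2, 5))


def ppre_spec() -> MotifSpec:
    """Canonical PPRE: DR1 repeat of RGKTCA."""
    return MotifSpec(name="PPRE", half_site="RGKTCA", spacers=(1,))


def reverse_complement(seq: str) -> str:
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r}") from None


def _match_positions(arr: np.ndarray, pattern: str) -> np.ndarray:
    """Start positions where ``pattern`` (IUPAC) matches the uint8 sequence."""
    n = arr.size
    plen = len(pattern)
    if n < plen:
        return np.empty(0, dtype=int)
    width = n - plen + 1
    valid = np.ones(width, dtype=bool)
    for j, code in enumerate(pattern):
        table = np.zeros(256, dtype=bool)
        table[np.frombuffer(IUPAC[code].encode(), dtype=np.uint8)] = True
        valid &= table[arr[j : j + width]]
        if not valid.any():
            break
    return np.nonzero(valid)[0]


def scan_motifs(sequences: Mapping[str, str], spec: MotifSpec) -> pd.DataFrame:
    """All direct-repeat hits on both strands of a sequence set.

    Overlapping hits and hits from different spacers at the same position
    are all reported.  Columns: chrom, start, end (0-based half-open),
    strand, spacer, sequence (forward-strand slice).
    """
    records = []
    for chrom in sorted(sequences):
        seq = sequences[chrom].upper()
        bad = sorted(set(seq) - set("ACGTN"))
        if bad:
            raise ValueError(f"sequence {chrom!r} has invalid characters: {bad}")
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for spacer in sorted(set(spec.spacers)):
            fwd = spec.pattern(spacer)
            plen = len(fwd)
            for strand, pattern in (("+", fwd), ("-", reverse_complement(fwd))):
                for start in _match_positions(arr, pattern):
                    records.append(
                        {
                            "chrom": chrom,
                            "start": int(start),
                            "end": int(start) + plen,
                            "strand": strand,
                            "spacer": spacer,
                            "sequence": seq[start : start + plen],
                        }
                    )
    hits = pd.DataFrame(records, columns=["chrom", "start", "end", "strand", "spacer", "sequence"])
    return hits.sort_values(["chrom", "start", "spacer", "strand"], kind="mergesort").reset_index(drop=True)


def genes_near_motifs(genes: pd.DataFrame, hits: pd.DataFrame, window_bp: int = 10000):
    """Genes with a motif hit within ``window_bp`` of the gene span.

    ``genes`` has BED-style columns chrom, start, end, name (0-based
    half-open).  Distance is the gap between the gene interval and the hit
    interval (0 when overlapping); a gene is included iff its minimum
    distance over hits is <= window_bp.  Returns ``(gene_set, table)``
    where ``table`` has one row per gene with the nearest-hit distance
    (NaN when no hit shares the chromosome).
    """
    rows = []
    near: set[str] = set()
    for _, g in genes.iterrows():
        sub = hits[hits["chrom"] == g["chrom"]]
        if len(sub) == 0:
            rows.append({"gene": g["name"], "nearest_distance": np.nan, "within_window": False})
            continue
        hs = sub["start"].to_numpy()
        he = sub["end"].to_numpy()
        gap = np.maximum(np.maximum(hs - g["end"], g["start"] - he), 0)
        d = int(gap.min())
        within = d <= window_bp
        if within:
            near.add(g["name"])
        rows.append({"gene": g["name"], "nearest_distance": d, "within_window": within})
    return near, pd.DataFrame(rows)


def annotate_de_lists(
    de_features: Iterable[str],
    feature_to_gene: Mapping[str, str],
    rare_genes: set[str],
    ppre_genes: set[str],
) -> dict:
    """Partition DE features by response-element proximity of their gene.

    Returns disjoint counts ``rare_only``, ``ppre_only``, ``both``,
    ``neither`` (unmapped features count as neither and are tallied in
    ``unmapped``); the four partition counts sum to the number of features.
    """
    counts = {"rare_only": 0, "ppre_only": 0, "both": 0, "neither": 0, "unmapped": 0}
    for f in de_features:
        gene = feature_to_gene.get(f)
        if gene is None:
            counts["neither"] += 1
            counts["unmapped"] += 1
            continue
        r = gene in rare_genes
        p = gene in ppre_genes
        if r and p:
            counts["both"] += 1
        elif r:
            counts["rare_only"] += 1
        elif p:
            counts["ppre_only"] += 1
        else:
            counts["neither"] += 1
    return counts
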