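"""Synthetic methylation cohorts with known ground truth.

Emulates the statistical structure of the study design that the rest of
the package analyses: a labeled reference panel of 13 cell-line
methylation arrays (5 sensitive / 4 resistant / 4 treatment-promoted)
plus 4 PDXs, a 70-sample query cohort, paired control/treated expression
arrays for the cell lines, xenograft growth tables with multiplicative
treatment effects, an Illumina-manifest-like probe annotation, and a toy
genome carrying planted direct-repeat response elements.

Generative model
----------------
* Per-probe baseline M-values come from a two-component (hypo/hyper)
  Gaussian mixture, giving the bimodal beta distribution typical of
  450K/EPIC arrays.
* Per-probe residual variances are drawn from a scaled inverse-chi-square
  prior with (d0, s0_sq) -- the same hierarchical form the moderated test
  assumes.
* Planted DMPs separate the sensitive class (sensitive lines + PDXs +
  true-sensitive queries) from everyone else by ``delta_beta`` on the beta
  scale; the shift is planted on the M scale via the logit2 transform of
  the two class baselines, with random sign per probe.
* Coupled (probe, gene) pairs make the gene's log2 expression a
  decreasing function of the probe's beta, enforcing the negative
  methylation-expression relation; coupled genes are also planted in both
  differential-expression truth sets.
* Tumor weights are lognormal around a control mean of 1 g with ~20% CV;
  the treated-arm mean is multiplied by the group's growth factor.
* The toy genome background is scrubbed of chance nuclear-receptor
  half-sites before direct-repeat motifs are planted near a known
  fraction of gene starts, so per-gene motif truth flags are exact.

Same config + same seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import meth
from .motif import IUPAC, rare_spec

__all__ = [
    "ConfigError",
    "SyntheticConfig",
    "SyntheticTruth",
    "Cohort",
    "generate_cohort",
    "generate_growth",
    "write_cohort",
]

# fixed aspects of the simulated assays (not part of the tunable design)
HYPO_MODE_M = -2.5
HYPER_MODE_M = 2.5
MODE_SD_M = 0.8
EXPR_BASE_MEAN = 7.0
EXPR_BASE_SD = 1.5
EXPR_D0 = 10.0
EXPR_S0_SQ = 0.09
COUPLING_SLOPE = 4.0  # log2 units per beta unit, negative relation
COUPLING_NOISE_SD = 0.15
WEIGHT_SDLOG = 0.2
CONTROL_WEIGHT_G = 1.0
GENE_LENGTH = 2000
MOTIF_MAX_OFFSET = 9000
BLACKLIST_FRACTION = 0.02
N_BLACKLISTED_PLANTED = 3


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration; names the offending field."""


@dataclass(frozen=True)
class SyntheticConfig:
    n_probes: int = 10000
    n_genes: int = 300
    n_sensitive_lines: int = 5
    n_resistant_lines: int = 4
    n_promoted_lines: int = 4
    n_pdx: int = 4
    n_queries: int = 70
    true_sensitive_fraction: float = 0.17
    n_planted_dmp: int = 100
    delta_beta: float = 0.3
    n_planted_de: int = 50
    de_log2fc: float = 1.5
    n_coupled: int = 17
    d0: float = 4.0
    s0_sq: float = 0.04
    platform_both_fraction: float = 0.85
    sensitive_fc: float = 0.4
    resistant_fc: float = 1.0
    promoted_fc: float = 1.8
    mice_per_arm: int = 8
    motif_gene_fraction: float = 0.3
    genome_length: int = 7_500_000
    seed: int = 0

    def validate(self) -> None:
        counts = [
            "n_probes", "n_genes", "n_sensitive_lines", "n_resistant_lines",
            "n_promoted_lines", "n_pdx", "n_queries", "n_planted_dmp",
            "n_planted_de", "n_coupled", "mice_per_arm",
        ]
        for name in counts:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("true_sensitive_fraction", "platform_both_fraction", "motif_gene_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        if not (0.0 < self.delta_beta < 1.0):
            raise ConfigError("delta_beta must be in (0, 1)")
        if self.n_planted_dmp > self.n_probes:
            raise ConfigError("n_planted_dmp must be <= n_probes")
        if self.n_planted_de > self.n_genes:
            raise ConfigError("n_planted_de must be <= n_genes")
        if self.n_coupled > min(self.n_planted_dmp, self.n_planted_de):
            raise ConfigError("n_coupled must be <= min(n_planted_dmp, n_planted_de)")
        if self.d0 <= 0:
            raise ConfigError("d0 must be > 0")
        if self.s0_sq <= 0:
            raise ConfigError("s0_sq must be > 0")
        for name in ("sensitive_fc", "resistant_fc", "promoted_fc"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.mice_per_arm < 2:
            raise ConfigError("mice_per_arm must be >= 2")
        if self.n_sensitive_lines < 2 or self.n_resistant_lines + self.n_promoted_lines < 2:
            raise ConfigError("n_sensitive_lines and other-class lines must each be >= 2")
        if self.n_genes > 0 and self.genome_length < 23_000 * self.n_genes:
            raise ConfigError(
                "genome_length too small: need >= 23,000 bp per gene so that motif "
                "windows of neighboring genes cannot overlap"
            )
        if self.seed < 0:
            raise ConfigError("seed must be >= 0")


@dataclass
class SyntheticTruth:
    planted_dmp_ids: list[str]
    planted_de_baseline: list[str]
    planted_de_induced: list[str]
    coupled_pairs: list[tuple[str, str]]
    query_labels: dict[str, str]  # query id -> 'sensitive' | 'resistant'
    rare_genes: list[str]
    ppre_genes: list[str]
    blacklisted_planted: list[str]

    def to_json(self) -> str:
        d = asdict(self)
        d["coupled_pairs"] = [list(p) for p in self.coupled_pairs]
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class Cohort:
    config: SyntheticConfig
    panel_beta: pd.DataFrame  # probes x (cell lines + PDXs)
    query_beta: pd.DataFrame  # probes x queries
    expr_control: pd.DataFrame  # genes x cell lines
    expr_treated: pd.DataFrame
    growth: pd.DataFrame
    manifest: pd.DataFrame
    genes: pd.DataFrame  # BED-like: chrom, start, end, name
    islands: pd.DataFrame  # chrom, start, end (0-based half-open)
    genome: dict[str, str]
    samples: pd.DataFrame
    truth: SyntheticTruth

    @property
    def panel_labels(self) -> pd.Series:
        """Supervision class of every panel sample."""
        sub = self.samples[self.samples["sample_type"] != "query"]
        return pd.Series(sub["supervision_class"].to_numpy(), index=sub["sample_id"].to_numpy())

    @property
    def line_labels(self) -> pd.Series:
        """Supervision class of the cell lines only (no PDXs)."""
        sub = self.samples[self.samples["sample_type"] == "cell_line"]
        return pd.Series(sub["supervision_class"].to_numpy(), index=sub["sample_id"].to_numpy())


def generate_growth(models, mice_per_arm: int, effects: Mapping[str, float], seed: int) -> pd.DataFrame:
    """Per-mouse final tumor weights and a four-point volume series.

    Weights are lognormal with mean ``CONTROL_WEIGHT_G`` grams in the
    control arm and mean multiplied by ``effects[model]`` in the treated
    arm.  Volumes follow the caliper convention length x width x depth / 2
    (recorded in ``DataFrame.attrs['volume_convention']``).
    """
    if mice_per_arm < 2:
        raise ValueError("mice_per_arm must be >= 2")
    for m in models:
        if effects[m] <= 0:
            raise ValueError(f"growth effect for {m!r} must be > 0")
    rng = np.random.default_rng(seed)
    day_fracs = {"volume_day7": 0.1, "volume_day14": 0.3, "volume_day21": 0.6, "volume_day28": 1.0}
    rows = []
    for model in models:
        for arm in ("control", "treated"):
            mean_w = CONTROL_WEIGHT_G * (effects[model] if arm == "treated" else 1.0)
            mu = np.log(mean_w) - WEIGHT_SDLOG**2 / 2.0
            weights = np.exp(rng.normal(mu, WEIGHT_SDLOG, mice_per_arm))
            for i, w in enumerate(weights):
                row = {"model_id": model, "arm": arm, "mouse_id": f"{model}_{arm}_{i + 1}", "final_weight": float(w)}
                for col, frac in day_fracs.items():
                    row[col] = float(w * 800.0 * frac * np.exp(rng.normal(0.0, 0.15)))
                rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["volume_convention"] = "length x width x depth / 2"
    return out


def _scrub_half_sites(arr: np.ndarray) -> None:
    """Destroy all chance occurrences of the RGKTCA half-site (both strands)."""
    from .motif import _match_positions, reverse_complement

    half = "RGKTCA"
    half_rc = reverse_complement(half)  # TGAMCY
    for _ in range(20):
        fwd = _match_positions(arr, half)
        rev = _match_positions(arr, half_rc)
        if fwd.size == 0 and rev.size == 0:
            return
        arr[fwd + 3] = ord("C")  # RGKTCA requires T at offset 3
        arr[rev] = ord("C")  # TGAMCY requires T at offset 0
    raise AssertionError("half-site scrubbing did not converge")


def _realize_iupac(pattern: str, rng: np.random.Generator) -> str:
    """One concrete ACGT realization of an IUPAC pattern (N -> random base)."""
    out = []
    for c in pattern:
        choices = "ACGT" if c == "N" else IUPAC[c]
        out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a fully self-consistent synthetic cohort with ground truth."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # --- sample ids and class structure ------------------------------------
    sens = [f"sens{i + 1}" for i in range(cfg.n_sensitive_lines)]
    res = [f"res{i + 1}" for i in range(cfg.n_resistant_lines)]
    prom = [f"prom{i + 1}" for i in range(cfg.n_promoted_lines)]
    pdx = [f"pdx{i + 1}" for i in range(cfg.n_pdx)]
    lines = sens + res + prom
    panel = lines + pdx
    queries = [f"q{i + 1:03d}" for i in range(cfg.n_queries)]

    n_true = int(round(cfg.true_sensitive_fraction * cfg.n_queries))
    true_idx = set(rng.choice(cfg.n_queries, size=n_true, replace=False).tolist()) if n_true else set()
    query_labels = {q: ("sensitive" if i in true_idx else "resistant") for i, q in enumerate(queries)}

    all_samples = panel + queries
    sens_mask = np.array(
        [s in sens or s in pdx for s in panel] + [query_labels[q] == "sensitive" for q in queries]
    )

    # --- probe baselines, planted effects, variances -----------------------
    probes = [f"cg{i + 1:08d}" for i in range(cfg.n_probes)]
    planted_idx = np.sort(rng.choice(cfg.n_probes, size=cfg.n_planted_dmp, replace=False))
    hyper = rng.random(cfg.n_probes) < 0.5
    mu = rng.normal(0.0, MODE_SD_M, cfg.n_probes) + np.where(hyper, HYPER_MODE_M, HYPO_MODE_M)
    mu_sens = mu.copy()
    mu_other = mu.copy()
    if cfg.n_planted_dmp:
        b_low = rng.uniform(0.1, 0.9 - cfg.delta_beta, cfg.n_planted_dmp)
        sens_high = rng.random(cfg.n_planted_dmp) < 0.5
        beta_s = np.where(sens_high, b_low + cfg.delta_beta, b_low)
        beta_o = np.where(sens_high, b_low, b_low + cfg.delta_beta)
        mu_sens[planted_idx] = meth.beta_to_m(beta_s)
        mu_other[planted_idx] = meth.beta_to_m(beta_o)
    sigma2 = cfg.d0 * cfg.s0_sq / rng.chisquare(cfg.d0, cfg.n_probes)
    sigma = np.sqrt(sigma2)

    M = (
        mu_other[:, None]
        + (mu_sens - mu_other)[:, None] * sens_mask[None, :]
        + rng.normal(0.0, 1.0, (cfg.n_probes, len(all_samples))) * sigma[:, None]
    )
    beta = meth.m_to_beta(M)
    beta_df = pd.DataFrame(beta, index=pd.Index(probes, name="probe_id"), columns=all_samples)
    panel_beta = beta_df[panel].copy()
    query_beta = beta_df[queries].copy()

    # --- manifest ----------------------------------------------------------
    chrom_names = ["chr1", "chr2"]
    chrom_len = cfg.genome_length // 2
    probe_chrom_idx = rng.integers(0, 2, cfg.n_probes)
    probe_pos = rng.integers(1, chrom_len + 1, cfg.n_probes)
    n_islands = max(1, cfg.genome_length // 25_000)
    isl_chrom = rng.integers(0, 2, n_islands)
    isl_start = rng.integers(0, max(1, chrom_len - 2000), n_islands)
    isl_len = rng.integers(400, 1501, n_islands)
    islands = pd.DataFrame(
        {
            "chrom": [chrom_names[i] for i in isl_chrom],
            "start": isl_start,
            "end": isl_start + isl_len,
        }
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    probe_chroms = np.array([chrom_names[i] for i in probe_chrom_idx])
    relations = meth.island_relations(probe_chroms, probe_pos, islands)

    genes = [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)]
    regions = np.array(["TSS1500", "TSS200", "Body"])
    assoc_draw = rng.random(cfg.n_probes)
    gene_pick = rng.integers(0, max(cfg.n_genes, 1), (cfg.n_probes, 2))
    region_pick = rng.integers(0, 3, (cfg.n_probes, 2))
    gene_col = []
    for i in range(cfg.n_probes):
        if cfg.n_genes == 0 or assoc_draw[i] < 0.2:
            gene_col.append("")
        elif assoc_draw[i] < 0.9:
            gene_col.append(f"{genes[gene_pick[i, 0]]}:{regions[region_pick[i, 0]]}")
        else:
            g1, g2 = gene_pick[i]
            if g1 == g2:
                g2 = (g2 + 1) % cfg.n_genes
            gene_col.append(
                f"{genes[g1]}:{regions[region_pick[i, 0]]};{genes[g2]}:{regions[region_pick[i, 1]]}"
            )

    plat_draw = rng.random(cfg.n_probes)
    half_rest = (1.0 - cfg.platform_both_fraction) / 2.0
    platform = np.where(
        plat_draw < cfg.platform_both_fraction,
        "both",
        np.where(plat_draw < cfg.platform_both_fraction + half_rest, "HM450", "EPIC"),
    )
    blacklist = rng.random(cfg.n_probes) < BLACKLIST_FRACTION

    # --- coupled pairs and planted DE sets ---------------------------------
    coupled_pairs: list[tuple[str, str]] = []
    coupled_probe_idx = np.array([], dtype=int)
    coupled_gene_idx = np.array([], dtype=int)
    if cfg.n_coupled:
        coupled_probe_idx = rng.choice(planted_idx, size=cfg.n_coupled, replace=False)
        coupled_gene_idx = rng.choice(cfg.n_genes, size=cfg.n_coupled, replace=False)
        blacklist[coupled_probe_idx] = False  # coupling must survive filtering
        for pi, gi in zip(coupled_probe_idx, coupled_gene_idx):
            gene_col[pi] = f"{genes[gi]}:TSS200"
            coupled_pairs.append((probes[pi], genes[gi]))

    # blacklist deliberately hits a few planted (non-coupled) DMPs so the
    # cross-reactive/SNP filter is consequential
    free_planted = np.setdiff1d(planted_idx, coupled_probe_idx)
    n_bl = min(N_BLACKLISTED_PLANTED, free_planted.size)
    bl_planted = rng.choice(free_planted, size=n_bl, replace=False) if n_bl else np.array([], dtype=int)
    blacklist[bl_planted] = True

    manifest = pd.DataFrame(
        {
            "probe_id": probes,
            "chrom": probe_chroms,
            "pos": probe_pos,
            "island_relation": relations,
            "gene": gene_col,
            "platform": platform,
            "blacklist": blacklist,
        }
    )

    remaining = np.setdiff1d(np.arange(cfg.n_genes), coupled_gene_idx)
    n_extra = cfg.n_planted_de - cfg.n_coupled
    extra_base = rng.choice(remaining, size=min(n_extra, remaining.size), replace=False)
    extra_ind = rng.choice(remaining, size=min(n_extra, remaining.size), replace=False)
    base_idx = np.concatenate([coupled_gene_idx, extra_base]).astype(int)
    ind_idx = np.concatenate([coupled_gene_idx, extra_ind]).astype(int)

    # --- expression --------------------------------------------------------
    a_g = rng.normal(EXPR_BASE_MEAN, EXPR_BASE_SD, cfg.n_genes)
    sig_e = np.sqrt(EXPR_D0 * EXPR_S0_SQ / rng.chisquare(EXPR_D0, max(cfg.n_genes, 1)))
    b_g = np.zeros(cfg.n_genes)
    b_g[extra_base] = rng.choice([-1.0, 1.0], size=extra_base.size) * cfg.de_log2fc
    i_g = np.zeros(cfg.n_genes)
    i_g[ind_idx] = rng.choice([-1.0, 1.0], size=ind_idx.size) * cfg.de_log2fc

    line_sens = np.array([s in sens for s in lines])
    noise_c = rng.normal(0.0, 1.0, (cfg.n_genes, len(lines))) * sig_e[:, None]
    noise_t = rng.normal(0.0, 1.0, (cfg.n_genes, len(lines))) * sig_e[:, None]
    expr_control = a_g[:, None] + b_g[:, None] * line_sens[None, :] + noise_c
    expr_treated = a_g[:, None] + b_g[:, None] * line_sens[None, :] + i_g[:, None] * line_sens[None, :] + noise_t
    # coupled genes: expression is a decreasing function of the probe's beta
    for pi, gi in zip(coupled_probe_idx, coupled_gene_idx):
        bvals = panel_beta.iloc[pi][lines].to_numpy()
        base = a_g[gi] + COUPLING_SLOPE * 0.5 - COUPLING_SLOPE * bvals
        expr_control[gi] = base + rng.normal(0.0, COUPLING_NOISE_SD, len(lines))
        expr_treated[gi] = base + i_g[gi] * line_sens + rng.normal(0.0, COUPLING_NOISE_SD, len(lines))
    gene_index = pd.Index(genes, name="gene")
    expr_control = pd.DataFrame(expr_control, index=gene_index, columns=lines)
    expr_treated = pd.DataFrame(expr_treated, index=gene_index, columns=lines)

    # --- growth ------------------------------------------------------------
    effects = {}
    for s in sens:
        effects[s] = cfg.sensitive_fc
    for r in res:
        effects[r] = cfg.resistant_fc
    for p in prom:
        effects[p] = cfg.promoted_fc
    growth = generate_growth(lines, cfg.mice_per_arm, effects, seed=int(rng.integers(2**31)))

    # --- toy genome with planted response elements -------------------------
    spacing = cfg.genome_length // max(cfg.n_genes, 1)
    gene_rows = []
    for i in range(cfg.n_genes):
        flat = i * spacing + spacing // 2
        ci = 0 if flat < chrom_len else 1
        start = flat - ci * chrom_len
        gene_rows.append({"chrom": chrom_names[ci], "start": start, "end": start + GENE_LENGTH, "name": genes[i]})
    genes_bed = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "name"])

    base_map = np.frombuffer(b"ACGT", dtype=np.uint8)
    chrom_arrays = {}
    for name in chrom_names:
        arr = base_map[rng.integers(0, 4, chrom_len)].copy()
        _scrub_half_sites(arr)
        chrom_arrays[name] = arr

    spec = rare_spec()
    n_motif = int(round(cfg.motif_gene_fraction * cfg.n_genes))
    motif_gene_idx = np.sort(rng.choice(cfg.n_genes, size=n_motif, replace=False)) if n_motif else np.array([], dtype=int)
    rare_genes, ppre_genes = [], []
    for gi in motif_gene_idx:
        row = genes_bed.iloc[gi]
        spacer = int(rng.choice(spec.spacers))
        site = _realize_iupac(spec.pattern(spacer), rng)
        arr = chrom_arrays[row["chrom"]]
        offset = int(rng.integers(-MOTIF_MAX_OFFSET, MOTIF_MAX_OFFSET + 1))
        pos = int(np.clip(row["start"] + offset, 0, arr.size - len(site)))
        arr[pos : pos + len(site)] = np.frombuffer(site.encode(), dtype=np.uint8)
        rare_genes.append(genes[gi])
        if spacer == 1:
            ppre_genes.append(genes[gi])
    genome = {name: arr.tobytes().decode() for name, arr in chrom_arrays.items()}

    # --- sample sheet and truth --------------------------------------------
    sample_rows = []
    for s in panel:
        if s in sens:
            cat, typ, sup = "sensitive", "cell_line", "sensitive"
        elif s in res:
            cat, typ, sup = "resistant", "cell_line", "other"
        elif s in prom:
            cat, typ, sup = "promoted", "cell_line", "other"
        else:
            cat, typ, sup = "pdx", "pdx", "sensitive"
        sample_rows.append({"sample_id": s, "sample_type": typ, "category": cat, "supervision_class": sup})
    for q in queries:
        sample_rows.append({"sample_id": q, "sample_type": "query", "category": "query", "supervision_class": ""})
    samples = pd.DataFrame(sample_rows)

    truth = SyntheticTruth(
        planted_dmp_ids=[probes[i] for i in planted_idx],
        planted_de_baseline=sorted(genes[i] for i in set(base_idx.tolist())),
        planted_de_induced=sorted(genes[i] for i in set(ind_idx.tolist())),
        coupled_pairs=coupled_pairs,
        query_labels=query_labels,
        rare_genes=rare_genes,
        ppre_genes=ppre_genes,
        blacklisted_planted=[probes[i] for i in np.sort(bl_planted)],
    )
    assert set(truth.planted_dmp_ids) <= set(probes)
    assert set(g for _, g in truth.coupled_pairs) <= set(truth.planted_de_baseline)
    assert set(p for p, _ in truth.coupled_pairs) <= set(truth.planted_dmp_ids)

    return Cohort(
        config=cfg,
        panel_beta=panel_beta,
        query_beta=query_beta,
        expr_control=expr_control,
        expr_treated=expr_treated,
        growth=growth,
        manifest=manifest,
        genes=genes_bed,
        islands=islands,
        genome=genome,
        samples=samples,
        truth=truth,
    )


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write every cohort artifact as plain text under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.panel_beta.to_csv(out / "beta_panel.tsv", sep="\t", float_format="%.6g")
    cohort.query_beta.to_csv(out / "beta_queries.tsv", sep="\t", float_format="%.6g")
    cohort.expr_control.to_csv(out / "expr_control.tsv", sep="\t", float_format="%.6g")
    cohort.expr_treated.to_csv(out / "expr_treated.tsv", sep="\t", float_format="%.6g")
    cohort.manifest.to_csv(out / "manifest.csv", index=False)
    cohort.samples.to_csv(out / "samples.csv", index=False)
    cohort.growth.to_csv(out / "growth.csv", index=False, float_format="%.6g")
    cohort.genes.to_csv(out / "genes.bed", sep="\t", header=False, index=False)
    cohort.islands.to_csv(out / "islands.bed", sep="\t", header=False, index=False)
    with open(out / "genome.fa", "w") as fh:
        for name in sorted(cohort.genome):
            fh.write(f">{name}\n")
            seq = cohort.genome[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    (out / "truth.json").write_text(cohort.truth.to_json())
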