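"""Differential methylation, island annotation, gene mapping, correlation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from atrasig import (
    annotate_island_context,
    differential_methylation,
    filter_probes,
    intersect_gene_sets,
    island_relations,
    methylation_expression_correlation,
    probes_to_genes,
    spearman,
)


def toy_beta(seed, n_probes=20, n_samples=10):
    rng = np.random.default_rng(seed)
    beta = pd.DataFrame(
        rng.uniform(0.05, 0.95, (n_probes, n_samples)),
        index=[f"cg{i:03d}" for i in range(n_probes)],
        columns=[f"s{i}" for i in range(n_samples)],
    )
    classes = pd.Series(["sensitive"] * 5 + ["other"] * 5, index=beta.columns)
    return beta, classes


def bh_reference(p):
    """Plain step-up Benjamini-Hochberg, ten lines, no vectorized tricks."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


class TestFilterProbes:
    def test_empty_blacklist_is_identity(self):
        beta, _ = toy_beta(0)
        manifest = pd.DataFrame({"probe_id": beta.index, "blacklist": False})
        assert filter_probes(beta, manifest).equals(beta)

    def test_exact_count_removed(self):
        beta, _ = toy_beta(1)
        black = beta.index[:4]
        manifest = pd.DataFrame({"probe_id": beta.index, "blacklist": beta.index.isin(black)})
        out = filter_probes(beta, manifest)
        assert len(out) == len(beta) - 4
        assert not set(black) & set(out.index)

    def test_unknown_probe_rejected(self):
        beta, _ = toy_beta(2)
        manifest = pd.DataFrame({"probe_id": beta.index[:-1], "blacklist": False})
        with pytest.raises(ValueError, match="absent"):
            filter_probes(beta, manifest)

    def test_blacklisted_planted_probes_never_called(self, default_cohort, default_discovery):
        black = set(default_cohort.truth.blacklisted_planted)
        assert black  # the generator plants some deliberately
        assert not black & set(default_discovery["dmp"]["probe_id"])
        assert not black & set(default_discovery["candidates"])


class TestDifferentialMethylation:
    def test_unmoderated_matches_t_oracle(self):
        beta, classes = toy_beta(3)
        res = differential_methylation(beta, classes, moderated=False).set_index("probe_id")
        M = np.log2(beta / (1 - beta))
        for probe in beta.index:
            a = M.loc[probe, classes == "sensitive"]
            b = M.loc[probe, classes == "other"]
            assert res.at[probe, "p_value"] == pytest.approx(
                stats.ttest_ind(a, b, equal_var=True).pvalue, abs=1e-10
            )

    def test_delta_beta_reported_on_beta_scale(self):
        beta, classes = toy_beta(4)
        res = differential_methylation(beta, classes).set_index("probe_id")
        mask = classes == "sensitive"
        for probe in beta.index[:5]:
            expected = beta.loc[probe, mask].mean() - beta.loc[probe, ~mask].mean()
            assert res.at[probe, "delta_beta"] == pytest.approx(expected, abs=1e-12)

    def test_label_swap_flips_delta_sign(self):
        beta, classes = toy_beta(5)
        swapped = classes.map({"sensitive": "other", "other": "sensitive"})
        r1 = differential_methylation(beta, classes).set_index("probe_id")
        r2 = differential_methylation(beta, swapped).set_index("probe_id")
        assert np.allclose(r1["delta_beta"], -r2.loc[r1.index, "delta_beta"])
        assert np.allclose(r1["p_value"], r2.loc[r1.index, "p_value"])

    def test_invariant_to_column_permutation(self):
        beta, classes = toy_beta(6)
        perm = list(reversed(beta.columns))
        r1 = differential_methylation(beta, classes).set_index("probe_id")
        r2 = differential_methylation(beta[perm], classes).set_index("probe_id")
        assert np.allclose(r1["p_value"], r2.loc[r1.index, "p_value"])

    def test_bh_q_values_match_step_up_reference(self):
        beta, classes = toy_beta(7, n_probes=50)
        res = differential_methylation(beta, classes)
        q_ref = bh_reference(res["p_value"].tolist())
        assert np.allclose(res["q_value"], q_ref, atol=1e-12)
        # monotone in p-rank
        assert (np.diff(res.sort_values("p_value")["q_value"]) >= -1e-12).all()

    def test_out_of_range_beta_rejected(self):
        beta, classes = toy_beta(8)
        beta.iloc[0, 0] = 1.4
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            differential_methylation(beta, classes)


class TestIslandAnnotation:
    ISLANDS = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [11_000]})

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (10_500, "island"),  # inside
            (10_001, "island"),  # first base (1-based pos of 0-based start)
            (11_000, "island"),  # last base of half-open interval
            (11_001, "s_shore"),  # 1 bp past the edge
            (9_500, "n_shore"),
            (13_000, "s_shelf"),  # exactly 2000 bp from the edge -> shelf
            (8_001, "n_shelf"),
            (16_000, "open_sea"),
        ],
    )
    def test_boundary_rules(self, pos, expected):
        rel = island_relations(["chr1"], [pos], self.ISLANDS)
        assert rel[0] == expected

    def test_matches_brute_force_interval_scan(self):
        rng = np.random.default_rng(9)
        n_isl = 30
        starts = np.sort(rng.choice(np.arange(0, 900_000, 6000), n_isl, replace=False))
        islands = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + rng.integers(300, 1500, n_isl)})
        pos = rng.integers(1, 1_000_000, 1000)
        fast = island_relations(["chr1"] * 1000, pos, islands)

        def brute(p1):
            p0 = p1 - 1
            best_d, north = None, None
            for s, e in islands[["start", "end"]].to_numpy():
                if s <= p0 < e:
                    return "island"
                d = s - p0 if p0 < s else p0 - e + 1
                if best_d is None or d < best_d or (d == best_d and p0 < s):
                    best_d, north = d, p0 < s
            if best_d < 2000:
                return "n_shore" if north else "s_shore"
            if best_d < 4000:
                return "n_shelf" if north else "s_shelf"
            return "open_sea"

        expected = np.array([brute(p) for p in pos])
        assert (fast == expected).all()

    def test_missing_coordinate_rejected(self):
        manifest = pd.DataFrame(
            {"probe_id": ["cg1"], "chrom": ["chr1"], "pos": [np.nan], "island_relation": ["island"]}
        )
        with pytest.raises(ValueError):
            annotate_island_context(["cg1"], manifest, self.ISLANDS)

    def test_frequency_tables_sum_to_one(self, small_cohort):
        dmp_ids = small_cohort.truth.planted_dmp_ids
        _, table = annotate_island_context(dmp_ids, small_cohort.manifest, small_cohort.islands)
        assert table["dmp"].sum() == pytest.approx(1.0, abs=1e-12)
        assert table["background"].sum() == pytest.approx(1.0, abs=1e-12)


class TestGeneMapping:
    MANIFEST = pd.DataFrame(
        {
            "probe_id": ["cg1", "cg2", "cg3", "cg4"],
            "gene": ["GENEA:TSS200", "GENEA:Body;GENEB:TSS1500", "", "GENEC:Body"],
        }
    )

    def test_unannotated_probes_contribute_nothing(self):
        assert probes_to_genes(["cg3"], self.MANIFEST) == set()

    def test_shared_gene_deduplicated(self):
        assert probes_to_genes(["cg1", "cg2"], self.MANIFEST) == {"GENEA", "GENEB"}

    def test_matches_flatten_unique_oracle(self, small_cohort):
        man = small_cohort.manifest
        probes = man["probe_id"].sample(200, random_state=0).tolist()
        oracle = set()
        lookup = man.set_index("probe_id")["gene"]
        for p in probes:
            entry = lookup[p]
            if entry:
                for tag in entry.split(";"):
                    oracle.add(tag.split(":")[0])
        assert probes_to_genes(probes, man) == oracle


class TestVenn:
    def test_disjoint_sets_empty_triple(self):
        r = intersect_gene_sets({"a"}, {"b"}, {"c"})
        assert r["triple"] == set()

    def test_hand_enumerated_regions(self):
        r = intersect_gene_sets({"g1", "g2", "g3"}, {"g2", "g3"}, {"g3"})
        assert r["triple"] == {"g3"}
        assert r["counts"] == {
            "dm_only": 1,
            "de_baseline_only": 0,
            "de_induced_only": 0,
            "dm_de_baseline": 1,
            "dm_de_induced": 0,
            "de_baseline_de_induced": 0,
            "triple": 1,
        }

    def test_regions_partition_the_union(self):
        rng = np.random.default_rng(10)
        universe = [f"g{i}" for i in range(50)]
        A, B, C = (set(rng.choice(universe, 20, replace=False)) for _ in range(3))
        r = intersect_gene_sets(A, B, C)
        regions = [v for k, v in r.items() if k != "counts"]
        assert set().union(*regions) == A | B | C
        assert sum(len(v) for v in regions) == len(A | B | C)


class TestSpearman:
    def test_perfect_negative_monotone(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        rho, _, note = spearman(x, -x)
        assert rho == pytest.approx(-1.0)
        assert note == ""

    def test_constant_input_degenerate(self):
        rho, p, note = spearman([0.5] * 5, [1, 2, 3, 4, 5])
        assert np.isnan(rho) and np.isnan(p)
        assert "degenerate" in note

    def test_exact_permutation_p_at_n6(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=6), rng.normal(size=6)
        rho, p, _ = spearman(x, y)
        # independent full enumeration using the Sum-d^2 formula (no ties)
        rx = stats.rankdata(x)
        n = 6
        rho_obs = 1 - 6 * np.sum((rx - stats.rankdata(y)) ** 2) / (n * (n**2 - 1))
        assert rho == pytest.approx(rho_obs, abs=1e-12)
        count = 0
        for perm in itertools.permutations(stats.rankdata(y)):
            r = 1 - 6 * np.sum((rx - np.array(perm)) ** 2) / (n * (n**2 - 1))
            if abs(r) >= abs(rho_obs) - 1e-12:
                count += 1
        assert p == pytest.approx(count / math.factorial(n), abs=1e-12)

    def test_large_n_matches_t_approximation(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p, _ = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_coupled_pairs_strongly_anticorrelated(self, default_cohort):
        c = default_cohort
        corr = methylation_expression_correlation(c.panel_beta, c.expr_control, c.truth.coupled_pairs)
        assert (corr["rho"] < -0.5).all()
        assert (corr["n"] == 13).all()

    def test_too_few_shared_samples_rejected(self):
        beta = pd.DataFrame([[0.1, 0.2, 0.3]], index=["cg1"], columns=["a", "b", "c"])
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g1"], columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="fewer than 4"):
            methylation_expression_correlation(beta, expr, [("cg1", "g1")])
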