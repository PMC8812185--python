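"""Synteny chaining, reciprocal-best pairing, expression classifications and
HG-HG network divergence."""

from itertools import combinations, product

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from polytopo import homoeology as H
from polytopo.genome_io import STAGES, GenomicIntervalSet
from polytopo.synthetic import SimulationConfig, simulate_expression, simulate_genome

TWO_CHROMS = (("A01", 6_000_000, "At"), ("D01", 4_000_000, "Dt"))


def _genome(at_ids, dt_ids):
    rows = []
    for i, g in enumerate(at_ids):
        rows.append(("cA", i * 10_000, i * 10_000 + 2_000, g))
    for i, g in enumerate(dt_ids):
        rows.append(("cD", i * 10_000, i * 10_000 + 2_000, g))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])

    class _G:
        pass

    g = _G()
    g.frame = frame
    return GenomicIntervalSet(frame)


def _sim(pairs, score=500.0):
    rows = []
    for a, d in pairs:
        rows.append((a, d, score, 1e-50))
        rows.append((d, a, score, 1e-50))
    return pd.DataFrame(rows, columns=["query", "subject", "score", "evalue"])


def brute_force_chains(qranks, sranks, min_genes=5, max_gap=10):
    """Exhaustive best monotone chain cover over <= 12 hits."""
    n = len(qranks)
    best_blocks = []
    remaining = set(range(n))
    while True:
        best = []
        idx = sorted(remaining)
        for r in range(len(idx), 0, -1):
            for sub in combinations(idx, r):
                q = [qranks[i] for i in sub]
                s = [sranks[i] for i in sub]
                if all(q[i + 1] > q[i] and q[i + 1] - q[i] <= max_gap for i in range(len(q) - 1)):
                    inc = all(
                        s[i + 1] > s[i] and s[i + 1] - s[i] <= max_gap
                        for i in range(len(s) - 1)
                    )
                    dec = all(
                        s[i + 1] < s[i] and s[i] - s[i + 1] <= max_gap
                        for i in range(len(s) - 1)
                    )
                    if inc or dec:
                        best = list(sub)
                        break
            if best:
                break
        if len(best) < min_genes:
            break
        best_blocks.append(best)
        remaining -= set(best)
    return best_blocks


class TestSynteny:
    def test_perfectly_collinear_ten_genes_form_one_block(self):
        at = [f"a{i}" for i in range(10)]
        dt = [f"d{i}" for i in range(10)]
        genes = _genome(at, dt)
        blocks = H.find_syntenic_blocks(genes, _sim(zip(at, dt)))
        assert blocks["block_id"].nunique() == 1
        assert len(blocks) == 10

    def test_collinear_run_of_four_is_below_block_minimum(self):
        at = [f"a{i}" for i in range(4)]
        dt = [f"d{i}" for i in range(4)]
        blocks = H.find_syntenic_blocks(_genome(at, dt), _sim(zip(at, dt)))
        assert len(blocks) == 0

    def test_inversion_toy_matches_brute_force_oracle(self):
        # 12 collinear hits with the middle 6 inverted
        at = [f"a{i}" for i in range(12)]
        perm = list(range(3)) + list(range(8, 2, -1)) + list(range(9, 12))
        dt = [f"d{i}" for i in range(12)]
        pairs = [(at[i], dt[perm[i]]) for i in range(12)]
        genes = _genome(at, dt)
        blocks = H.find_syntenic_blocks(genes, _sim(pairs))
        got = sorted(
            tuple(sorted(g["query"]))
            for _, g in blocks.groupby("block_id")
        )
        oracle = brute_force_chains(list(range(12)), perm)
        expected = sorted(tuple(sorted(at[i] for i in b)) for b in oracle)
        assert got == expected

    def test_antiparallel_block_found(self):
        at = [f"a{i}" for i in range(6)]
        dt = [f"d{i}" for i in range(6)]
        pairs = [(at[i], dt[5 - i]) for i in range(6)]  # fully inverted
        blocks = H.find_syntenic_blocks(_genome(at, dt), _sim(pairs))
        assert blocks["block_id"].nunique() == 1


class TestReciprocalBest:
    def test_mutual_best_inside_block_paired(self):
        at = [f"a{i}" for i in range(6)]
        dt = [f"d{i}" for i in range(6)]
        sim = _sim(zip(at, dt))
        blocks = H.find_syntenic_blocks(_genome(at, dt), sim)
        pairs = H.reciprocal_best_pairs(sim, blocks)
        assert len(pairs) == 6
        assert pairs["at_gene"].is_unique and pairs["dt_gene"].is_unique

    def test_mutual_best_outside_block_rejected(self):
        sim = _sim([("a0", "d0")])  # one isolated hit: no block possible
        blocks = H.find_syntenic_blocks(_genome(["a0"], ["d0"]), sim)
        assert len(H.reciprocal_best_pairs(sim, blocks)) == 0

    def test_one_directional_best_rejected(self):
        at = [f"a{i}" for i in range(6)]
        dt = [f"d{i}" for i in range(6)]
        sim = _sim(zip(at, dt))
        # a0's best becomes d1, but d1's best remains a1: no reciprocity
        sim.loc[(sim["query"] == "a0"), "subject"] = "d1"
        sim.loc[(sim["query"] == "a0"), "score"] = 999.0
        blocks = H.find_syntenic_blocks(_genome(at, dt), sim)
        pairs = H.reciprocal_best_pairs(sim, blocks)
        assert "a0" not in set(pairs["at_gene"])

    def test_planted_pairs_recovered_without_false_positives(self):
        for seed in (21, 22):
            cfg = SimulationConfig(seed=seed, chromosomes=TWO_CHROMS)
            genome, truth = simulate_genome(cfg)
            blocks = H.find_syntenic_blocks(genome.genes, truth.similarity)
            pairs = H.reciprocal_best_pairs(truth.similarity, blocks)
            tp = set(zip(truth.homoeolog_pairs["at_gene"], truth.homoeolog_pairs["dt_gene"]))
            cp = set(zip(pairs["at_gene"], pairs["dt_gene"]))
            assert len(tp & cp) / len(tp) >= 0.98
            assert len(cp - tp) == 0


def _expr(table):
    """table: {gene: {stage: [fpkm...]}} -> tidy frame."""
    rows = []
    for gene, stages in table.items():
        for stage, reps in stages.items():
            for k, v in enumerate(reps):
                rows.append((gene, stage, k + 1, v))
    return pd.DataFrame(rows, columns=["gene_id", "stage", "replicate", "fpkm"])


class TestExpressionFlags:
    def test_expressed_requires_all_three_replicates_above_one(self):
        e = _expr(
            {
                "g1": {"0DPA": [1.5, 1.2, 3.0]},
                "g2": {"0DPA": [1.5, 0.9, 3.0]},
            }
        )
        flags = H.expressed_flags(e)
        assert bool(flags.loc["g1", "0DPA"]) is True
        assert bool(flags.loc["g2", "0DPA"]) is False


class TestDeStandin:
    def test_planted_eightfold_change_recovered_at_low_dispersion(self):
        rng = np.random.default_rng(0)
        hits = tries = 0
        for seed in range(10):
            # low-noise regime: tight replicates and well-measured genes
            cfg = SimulationConfig(
                seed=300 + seed,
                chromosomes=TWO_CHROMS,
                nb_dispersion=0.002,
                base_fpkm_b=20.0,
            )
            genome, truth = simulate_genome(cfg)
            expr = simulate_expression(genome, truth, cfg)
            plan = truth.expression_plan.set_index("gene_id")
            ratio = plan["fpkm_5DPA"] / plan["fpkm_0DPA"]
            planted = ratio[(ratio >= 8) | (ratio <= 1 / 8)].index
            if not len(planted):
                continue
            de = H.de_standin(expr, "0DPA", "5DPA").set_index("gene_id")
            hits += int(de.loc[planted, "de"].sum())
            tries += len(planted)
        assert tries > 20
        assert hits / tries >= 0.95

    def test_null_genes_stay_below_one_percent_plus_noise(self):
        rates = []
        for seed in range(10):
            cfg = SimulationConfig(
                seed=400 + seed,
                chromosomes=TWO_CHROMS,
                de_fraction=0.0,
                bias_fraction=0.0,
            )
            genome, truth = simulate_genome(cfg)
            expr = simulate_expression(genome, truth, cfg)
            de = H.de_standin(expr, "0DPA", "5DPA")
            rates.append(de["de"].mean())
        # 1% + 3 sigma of a binomial at the observed scale
        n = 150
        assert np.mean(rates) <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / n)

    def test_zero_variance_degenerate_shortcut(self):
        e = _expr(
            {
                "g1": {"0DPA": [2.0, 2.0, 2.0], "5DPA": [2.0, 2.0, 2.0]},
                "g2": {"0DPA": [2.0, 2.0, 2.0], "5DPA": [64.0, 64.0, 64.0]},
            }
        )
        de = H.de_standin(e, "0DPA", "5DPA").set_index("gene_id")
        assert de.loc["g1", "degenerate"] and not de.loc["g1", "de"]
        assert de.loc["g2", "de"]

    def test_external_de_table_ingested_verbatim(self):
        table = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "log2fc": [2.5, 0.5], "fdr": [0.001, 0.001]}
        )
        out = H.ingest_de_table(table).set_index("gene_id")
        assert bool(out.loc["g1", "de"]) and not bool(out.loc["g2", "de"])


class TestBias:
    def _pairs(self):
        return pd.DataFrame(
            {"pair_id": ["p1"], "at_gene": ["a1"], "dt_gene": ["d1"]}
        )

    def test_fourfold_ratio_with_clear_significance_called(self):
        e = _expr(
            {"a1": {"0DPA": [40.0, 41.0, 39.0]}, "d1": {"0DPA": [10.0, 10.5, 9.5]}}
        )
        out = H.bias_calls(e, self._pairs(), "0DPA")
        assert out.iloc[0]["bias"] == "At"

    def test_inclusive_thresholds_at_exact_boundary(self):
        # ratio exactly 2 with near-zero variance: fc >= 2 and fdr <= 0.05
        e = _expr(
            {
                "a1": {"0DPA": [20.0, 20.000001, 19.999999]},
                "d1": {"0DPA": [10.0, 10.0000005, 9.9999995]},
            }
        )
        pairs = self._pairs()
        out = H.bias_calls(e, pairs, "0DPA", eps=0.0)
        assert out.iloc[0]["fc_at_over_dt"] == pytest.approx(2.0, rel=1e-6)
        assert out.iloc[0]["bias"] == "At"

    def test_both_members_silent_flagged_none(self):
        e = _expr(
            {"a1": {"0DPA": [0.1, 0.2, 0.1]}, "d1": {"0DPA": [0.01, 0.02, 0.01]}}
        )
        out = H.bias_calls(e, self._pairs(), "0DPA")
        assert out.iloc[0]["bias"] == "none"
        assert bool(out.iloc[0]["both_silent"])

    def test_trajectories(self):
        def calls(bias_by_stage):
            return {
                s: pd.DataFrame({"pair_id": ["p1"], "bias": [bias_by_stage[i]]})
                for i, s in enumerate(STAGES)
            }

        assert (
            H.bias_trajectory(calls(["At"] * 4)).iloc[0]["trajectory"] == "conserved_At"
        )
        assert (
            H.bias_trajectory(calls(["At", "At", "none", "none"])).iloc[0]["trajectory"]
            == "dynamic"
        )
        assert H.bias_trajectory(calls(["none"] * 4)).iloc[0]["trajectory"] == "none"


class TestPairChange:
    def test_single_common_opposite(self):
        assert H.pair_change_category("up", "none") == "single"
        assert H.pair_change_category("up", "up") == "common"
        assert H.pair_change_category("up", "down") == "opposite"
        assert H.pair_change_category("none", "none") == "none"

    def test_exhaustive_truth_table_counts(self):
        cats = [
            H.pair_change_category(a, d)
            for a, d in product(("up", "down", "none"), repeat=2)
        ]
        counts = pd.Series(cats).value_counts().to_dict()
        assert counts == {"single": 4, "common": 2, "opposite": 2, "none": 1}

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError):
            H.pair_change_category("sideways", "up")


class TestNetworks:
    def _net(self, edges, pairs):
        g = nx.Graph()
        g.add_nodes_from(pairs)
        g.add_edges_from(edges)
        return g

    def test_identical_edge_sets_give_zero_divergence(self):
        pairs = ["p1", "p2", "p3"]
        a = self._net([("p1", "p2")], pairs)
        assert H.network_divergence(a, a.copy()) == 0.0

    def test_disjoint_edge_sets_give_full_divergence(self):
        pairs = ["p1", "p2", "p3", "p4"]
        a = self._net([("p1", "p2")], pairs)
        b = self._net([("p3", "p4")], pairs)
        assert H.network_divergence(a, b) == 1.0

    def test_hand_counted_toy_two_thirds(self):
        pairs = ["p1", "p2", "p3", "p4"]
        at = self._net([("p1", "p2")], pairs)
        dt = self._net([("p1", "p2"), ("p2", "p3"), ("p3", "p4")], pairs)
        assert H.network_divergence(at, dt) == pytest.approx(2 / 3)
        assert H.shared_homoeologous_edges(at, dt) == {frozenset(("p1", "p2"))}

    def test_build_network_from_classified_loops(self):
        pairs = pd.DataFrame(
            {
                "pair_id": ["p1", "p2"],
                "at_gene": ["a1", "a2"],
                "dt_gene": ["d1", "d2"],
            }
        )
        frame = pd.DataFrame(
            {
                "chrom": ["cA"],
                "anchor1": [0],
                "anchor2": [50_000],
                "homoeolog_class": ["HG-HG"],
                "hg_genes1": ["a1"],
                "hg_genes2": ["a2"],
            }
        )
        net = H.build_hg_network(frame, pairs, None, "At")
        assert net.has_edge("p1", "p2")
        assert net.degree("p1") == 1
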