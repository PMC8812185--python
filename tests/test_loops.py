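"""Loop filtering semantics, the stand-in caller's recovery and calibration,
anchor taxonomies, densities and mark dynamics."""

import numpy as np
import pandas as pd
import pytest

from polytopo import loops as lp
from polytopo.domains import tadset_from_frame
from polytopo.genome_io import GenomicIntervalSet, LoopSet
from polytopo.synthetic import SimulationConfig, simulate_genome, simulate_hic

TWO_CHROMS = (("A01", 6_000_000, "At"), ("D01", 4_000_000, "Dt"))


def _loops(records, extra=None):
    frame = pd.DataFrame(
        records, columns=["chrom", "anchor1", "anchor2", "contact_count", "fdr"]
    )
    frame["p_value"] = frame["fdr"] / 2
    frame["stage"] = "0DPA"
    if extra:
        for k, v in extra.items():
            frame[k] = v
    return LoopSet(frame, 5_000)


def _genes(positions, chrom="c", prefix="g"):
    return GenomicIntervalSet(
        pd.DataFrame(
            {
                "chrom": chrom,
                "start": positions,
                "end": [p + 2_000 for p in positions],
                "gene_id": [f"{prefix}{i}" for i in range(len(positions))],
            }
        )
    )


class TestFilter:
    def test_count_11_fdr_0004_kept(self):
        assert len(lp.filter_loops(_loops([("c", 0, 50_000, 11, 0.004)]))) == 1

    def test_count_10_dropped_despite_tiny_fdr(self):
        assert len(lp.filter_loops(_loops([("c", 0, 50_000, 10, 0.0001)]))) == 0

    def test_fdr_0005_dropped_strict(self):
        assert len(lp.filter_loops(_loops([("c", 0, 50_000, 50, 0.005)]))) == 0

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(0)
        records = [
            ("c", int(a) * 5_000, int(a + g) * 5_000, int(c), float(f))
            for a, g, c, f in zip(
                rng.integers(0, 100, 50),
                rng.integers(2, 50, 50),
                rng.integers(0, 30, 50),
                rng.uniform(0, 0.05, 50),
            )
        ]
        ls = _loops(records)
        kept = lp.filter_loops(ls)
        assert kept.anchor_keys() <= ls.anchor_keys()


class TestCaller:
    def test_uniform_matrix_yields_no_calls(self, toy_matrix_factory):
        m = toy_matrix_factory(np.full((100, 100), 4.0), resolution=5_000)
        calls = lp.call_loops_standin(m, max_gap=50)
        assert (calls.frame["fdr"] >= 0.005).all()

    def test_empty_matrix_rejected(self, toy_matrix_factory):
        m = toy_matrix_factory(np.zeros((10, 10)), resolution=5_000)
        with pytest.raises(ValueError, match="empty"):
            lp.call_loops_standin(m)

    def test_planted_loops_recovered_with_few_false_anchors(self):
        recov, false_frac = [], []
        for seed in (11, 12):
            cfg = SimulationConfig(seed=seed, chromosomes=TWO_CHROMS)
            genome, truth = simulate_genome(cfg)
            m = simulate_hic(genome, truth, "0DPA", cfg)
            calls = lp.call_loops_standin(m)
            sig = calls.subset((calls.frame["fdr"] < 0.005).to_numpy())
            tl = truth.loops["0DPA"]
            loop_level = tl[tl["kind"] != "clique"]
            truth_keys = set(
                zip(loop_level["chrom"], loop_level["anchor1"], loop_level["anchor2"])
            )
            all_planted = set(zip(tl["chrom"], tl["anchor1"], tl["anchor2"]))
            called = sig.anchor_keys()
            recov.append(len(truth_keys & called) / len(truth_keys))
            # false calls = calls not explained by any planted signal; the
            # clique TAD-pair rectangles carry genuine planted enrichment
            rects = []
            tads = truth.tads["0DPA"].set_index("tad_id")
            for cl in truth.cliques["0DPA"]:
                spans = [
                    (cl["chrom"], tads.loc[t, "start"], tads.loc[t, "end"])
                    for t in cl["tad_ids"]
                ]
                for x in spans:
                    for y in spans:
                        rects.append((x, y))

            def in_rect(key):
                chrom, a1, a2 = key
                return any(
                    c1 == chrom and s1 <= a1 < e1 and s2 <= a2 < e2
                    for (c1, s1, e1), (_, s2, e2) in rects
                )

            false = [
                k for k in called - all_planted if not in_rect(k)
            ]
            false_frac.append(len(false) / max(len(called), 1))
        assert min(recov) >= 0.80
        assert max(false_frac) <= 0.05

    def test_null_calibration_on_decay_only_matrices(self):
        total_calls = 0
        n_chrom = 0
        for seed in range(5):
            cfg = SimulationConfig(seed=100 + seed, chromosomes=TWO_CHROMS).decay_only()
            genome, truth = simulate_genome(cfg)
            m = simulate_hic(genome, truth, "0DPA", cfg)
            calls = lp.call_loops_standin(m)
            total_calls += int((calls.frame["fdr"] < 0.005).sum())
            n_chrom += len(genome.chrom_names)
        assert total_calls / n_chrom <= 1.0


class TestAnchorTaxonomy:
    @pytest.mark.parametrize(
        "gene_bins,expected",
        [
            ((True, True), "G-G"),
            ((True, False), "G-N"),
            ((False, True), "G-N"),
            ((False, False), "N-N"),
        ],
    )
    def test_exhaustive_gene_presence_truth_table(self, gene_bins, expected):
        positions = []
        if gene_bins[0]:
            positions.append(10_000)  # inside anchor1 bin [10000, 15000)
        if gene_bins[1]:
            positions.append(50_000)
        genes = _genes(positions)
        ls = _loops([("c", 10_000, 50_000, 20, 0.001)])
        out = lp.classify_anchor_loops(ls, genes)
        assert out.frame.iloc[0]["anchor_class"] == expected

    def test_classification_commutes_with_filtering(self):
        rng = np.random.default_rng(1)
        records = [
            ("c", int(a) * 5_000, int(a + g) * 5_000, int(c), float(f))
            for a, g, c, f in zip(
                rng.integers(0, 200, 80),
                rng.integers(2, 80, 80),
                rng.integers(0, 40, 80),
                rng.uniform(0, 0.02, 80),
            )
        ]
        genes = _genes(list(rng.integers(0, 1_000_000, 30)))
        ls = _loops(records)
        a = lp.filter_loops(lp.classify_anchor_loops(ls, genes))
        b = lp.classify_anchor_loops(lp.filter_loops(ls), genes)
        assert a.frame[["chrom", "anchor1", "anchor2", "anchor_class"]].equals(
            b.frame[["chrom", "anchor1", "anchor2", "anchor_class"]]
        )

    def test_gene_loop_degree_counts(self):
        genes = _genes([10_000, 50_000, 100_000])
        ls = _loops(
            [
                ("c", 10_000, 50_000, 20, 0.001),  # G-G: g0, g1
                ("c", 10_000, 200_000, 20, 0.001),  # G-N: g0
            ]
        )
        out = lp.gene_loop_degree(lp.classify_anchor_loops(ls, genes))
        row = out.set_index("gene_id").loc["g0"]
        assert (row["G-G"], row["G-N"]) == (1, 1)


class TestHomoeologClasses:
    def _peaks(self, spec):
        """spec: {(chrom, pos): [marks]} -> {mark: interval set}"""
        rows = {m: [] for m in ("H3K27ac", "H3K4me3", "H3K9me2")}
        for (chrom, pos), marks in spec.items():
            for m in marks:
                rows[m].append((chrom, pos + 2_000, pos + 3_000, m))
        return {
            m: GenomicIntervalSet(
                pd.DataFrame(r, columns=["chrom", "start", "end", "name"])
            )
            for m, r in rows.items()
            if r
        }

    def _classified(self, peaks_spec, mapped=True):
        genes = _genes([10_000], prefix="a")  # homoeolog gene in anchor1
        pairs = pd.DataFrame(
            {"pair_id": ["p1"], "at_gene": ["a0"], "dt_gene": ["zz"]}
        )
        ls = _loops([("c", 10_000, 50_000, 20, 0.001)])
        tax = lp.classify_anchor_loops(ls, genes)
        homology = (
            pd.DataFrame(
                {
                    "chrom_a": ["c"],
                    "start_a": [50_000],
                    "end_a": [55_000],
                    "chrom_b": ["d"],
                    "start_b": [30_000],
                    "end_b": [35_000],
                }
            )
            if mapped
            else pd.DataFrame(
                columns=["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b"]
            )
        )
        return lp.classify_homoeolog_loops(
            tax, pairs, genes, homology, self._peaks(peaks_spec)
        )

    def test_same_marks_on_homologous_counterpart_is_homo_same(self):
        out = self._classified(
            {("c", 50_000): ["H3K27ac"], ("d", 30_000): ["H3K27ac"]}
        )
        assert out.frame.iloc[0]["homoeolog_class"] == "HG-HN"
        assert out.frame.iloc[0]["hn_subtype"] == "homo_same"

    def test_differing_marks_is_homo_different(self):
        out = self._classified(
            {("c", 50_000): ["H3K27ac"], ("d", 30_000): ["H3K9me2"]}
        )
        assert out.frame.iloc[0]["hn_subtype"] == "homo_different"

    def test_unmapped_non_gene_anchor_is_non_homo(self):
        genes = _genes([10_000], prefix="a")
        pairs = pd.DataFrame({"pair_id": ["p1"], "at_gene": ["a0"], "dt_gene": ["zz"]})
        ls = _loops([("c", 10_000, 200_000, 20, 0.001)])
        tax = lp.classify_anchor_loops(ls, genes)
        homology = pd.DataFrame(
            {
                "chrom_a": ["c"],
                "start_a": [50_000],
                "end_a": [55_000],
                "chrom_b": ["d"],
                "start_b": [30_000],
                "end_b": [35_000],
            }
        )
        out = lp.classify_homoeolog_loops(tax, pairs, genes, homology, {})
        assert out.frame.iloc[0]["hn_subtype"] == "non_homo"

    def test_missing_map_warns_and_sets_na(self):
        with pytest.warns(UserWarning, match="homology map"):
            out = self._classified({}, mapped=False)
        assert out.frame.iloc[0]["hn_subtype"] == "n/a"

    def test_both_homoeolog_anchors_is_hg_hg(self):
        genes = _genes([10_000, 50_000], prefix="a")
        pairs = pd.DataFrame(
            {
                "pair_id": ["p1", "p2"],
                "at_gene": ["a0", "a1"],
                "dt_gene": ["z1", "z2"],
            }
        )
        ls = _loops([("c", 10_000, 50_000, 20, 0.001)])
        tax = lp.classify_anchor_loops(ls, genes)
        out = lp.classify_homoeolog_loops(tax, pairs, genes, None, None)
        assert out.frame.iloc[0]["homoeolog_class"] == "HG-HG"


class TestDensities:
    def test_window_with_exactly_20_genes_is_gene_poor(self):
        genes = _genes(list(np.linspace(0, 490_000, 20).astype(int)))
        classes = lp.gene_density_classes(genes, {"c": 1_000_000})
        assert classes.iloc[0]["class"] == "gene-poor"
        genes21 = _genes(list(np.linspace(0, 490_000, 21).astype(int)))
        classes21 = lp.gene_density_classes(genes21, {"c": 1_000_000})
        assert classes21.iloc[0]["class"] == "gene-rich"

    def test_doubling_loop_count_leaves_normalized_density_unchanged(self):
        genes = _genes(list(np.linspace(0, 900_000, 30).astype(int)))
        base = [("c", 10_000, 100_000, 20, 0.001), ("c", 600_000, 800_000, 20, 0.001)]
        one = _loops(base)
        two = _loops(base + base)  # identical pattern, twice the loops
        d1 = lp.loop_density_normalizations(one, genes, {"c": 1_000_000})
        d2 = lp.loop_density_normalizations(two, genes, {"c": 1_000_000})
        assert np.allclose(
            d1["positional_density"]["density"], d2["positional_density"]["density"]
        )

    def test_all_anchors_in_gene_rich_regions(self):
        genes = _genes(list(np.linspace(0, 490_000, 30).astype(int)))
        ls = _loops([("c", 10_000, 100_000, 20, 0.001)])
        out = lp.loop_density_normalizations(ls, genes, {"c": 1_000_000})
        assert out["anchor_proportion_normalized"]["gene-rich"] == pytest.approx(1.0)
        assert out["anchor_proportion_normalized"]["gene-poor"] == 0.0


class TestBoundaryProfile:
    def _tads(self):
        return tadset_from_frame(
            pd.DataFrame({"chrom": ["c"], "start": [0], "end": [400_000]})
        )

    def test_single_central_anchor_sits_at_half(self):
        ls = _loops([("c", 195_000, 200_000, 20, 0.001)])
        out = lp.boundary_relative_profile(ls, self._tads(), n_meta_bins=10)
        assert out["profile"][4] + out["profile"][5] == pytest.approx(1.0)

    def test_boundary_planted_anchors_give_bimodal_profile(self):
        ls = _loops(
            [("c", 0, 390_000, 20, 0.001) for _ in range(1)]
            + [("c", 5_000, 395_000, 20, 0.001)]
        )
        out = lp.boundary_relative_profile(ls, self._tads(), n_meta_bins=10)
        edge_mass = out["profile"][0] + out["profile"][-1]
        assert edge_mass >= 0.5

    def test_anchors_outside_tads_counted_separately(self):
        ls = _loops([("c", 500_000, 600_000, 20, 0.001)])
        out = lp.boundary_relative_profile(ls, self._tads())
        assert out["n_outside"] == 2
        assert out["n_anchors"] == 0


class TestMarkDynamics:
    def test_active_to_inactive_transition_counted(self):
        genes = _genes([])
        ls = _loops([("c", 10_000, 50_000, 20, 0.001)])
        tax = lp.classify_anchor_loops(ls, genes)
        mk = lambda spec: {
            m: GenomicIntervalSet(
                pd.DataFrame(
                    [(c, p + 2_000, p + 3_000, m) for (c, p), marks in spec.items() if m in marks],
                    columns=["chrom", "start", "end", "name"],
                )
            )
            for m in ("H3K27ac", "H3K4me3", "H3K9me2")
        }
        peaks = {
            "s1": mk({("c", 10_000): ["H3K27ac"], ("c", 50_000): ["H3K27ac"]}),
            "s2": mk({("c", 10_000): ["H3K9me2"], ("c", 50_000): ["H3K27ac"]}),
        }
        out = lp.mark_context_dynamics({"s1": tax, "s2": tax}, peaks, ("s1", "s2"))
        row = out.iloc[0]
        assert (row["active_to_inactive"], row["inactive_to_active"]) == (1, 0)

    def test_unchanged_marks_give_zero_transitions(self):
        genes = _genes([])
        ls = _loops([("c", 10_000, 50_000, 20, 0.001)])
        tax = lp.classify_anchor_loops(ls, genes)
        peaks_one = {
            m: GenomicIntervalSet(
                pd.DataFrame(
                    [("c", 12_000, 13_000, m)], columns=["chrom", "start", "end", "name"]
                )
            )
            for m in ("H3K27ac",)
        }
        peaks = {"s1": peaks_one, "s2": peaks_one}
        out = lp.mark_context_dynamics({"s1": tax, "s2": tax}, peaks, ("s1", "s2"))
        assert out.iloc[0]["active_to_inactive"] == 0
        assert out.iloc[0]["inactive_to_active"] == 0


class TestConservedLoops:
    def test_exact_anchor_match_required(self):
        a = _loops([("c", 10_000, 50_000, 20, 0.001)])
        b = _loops([("c", 10_000, 50_000, 25, 0.002)])
        c = _loops([("c", 15_000, 50_000, 25, 0.002)])  # shifted anchor
        out = lp.conserved_loop_fraction({"s1": a, "s2": b, "s3": c})
        assert out["n_conserved"] == 1
        assert out["n_union"] == 2
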