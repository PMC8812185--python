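"""Insulation scores, TAD calling, conservation rules and homology classes."""

import numpy as np
import pandas as pd
import pytest

from polytopo import contacts, domains
from polytopo.domains import (
    InsulationTrack,
    boundary_interior_assignment,
    classify_tad_homology,
    conserved_boundaries,
    insulation_score,
    positional_shift_bias,
    tad_conserved_between,
    tadset_from_frame,
)
from polytopo.genome_io import GenomicIntervalSet


def brute_force_insulation(dense, w):
    n = dense.shape[0]
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        total = 0.0
        for r in range(i - w, i):
            for c in range(i + 1, i + 1 + w):
                total += dense[r, c]
        raw[i] = total / (w * w)
    mean = np.nanmean(raw)
    return np.log2(raw / mean)


def balanced_toy(toy_matrix_factory, dense, resolution=20_000):
    m = toy_matrix_factory(dense, resolution=resolution)
    return contacts.ice_balance(m, filter_low=0.0)


class TestInsulation:
    def test_uniform_matrix_scores_zero_where_defined(self, toy_matrix_factory):
        m = balanced_toy(toy_matrix_factory, np.full((40, 40), 4.0))
        track = insulation_score(m, window=5)
        defined = ~np.isnan(track.score)
        assert defined.sum() == 40 - 10
        assert np.allclose(track.score[defined], 0.0, atol=1e-9)

    def test_two_perfect_blocks_have_unique_minimum_at_junction(self, toy_matrix_factory):
        n = 40
        dense = np.full((n, n), 0.5)
        dense[:20, :20] = 6.0
        dense[20:, 20:] = 6.0
        m = balanced_toy(toy_matrix_factory, dense)
        track = insulation_score(m, window=5)
        # the squares at the two junction-adjacent bins (19 and 20) are both
        # entirely cross-block, so the minimum is attained exactly there
        lowest = np.nanmin(track.score)
        at_min = set(np.where(track.score == lowest)[0])
        assert at_min <= {19, 20} and 20 in at_min or 19 in at_min
        assert lowest < np.nanmin(np.delete(track.score, [19, 20]))

    def test_matches_brute_force_on_random_matrices(self, toy_matrix_factory):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 60
            dense = rng.poisson(6.0, (n, n)).astype(float) + 1.0
            dense = np.triu(dense) + np.triu(dense, 1).T
            m = balanced_toy(toy_matrix_factory, dense)
            w = m.chrom_weights("chr1")
            bal = dense * np.outer(w, w)
            track = insulation_score(m, window=5)
            expected = brute_force_insulation(bal, 5)
            ok = ~np.isnan(expected)
            assert np.allclose(track.score[ok], expected[ok], atol=1e-9)

    def test_window_beyond_half_chromosome_rejected(self, toy_matrix_factory):
        m = balanced_toy(toy_matrix_factory, np.ones((10, 10)))
        with pytest.raises(ValueError, match="window"):
            insulation_score(m, window=6)


def _ins_track(score, resolution=20_000):
    bins = pd.DataFrame({"chrom": "c", "start": np.arange(len(score)) * resolution})
    return InsulationTrack(
        bins=bins, score=np.asarray(score, float), window=5, resolution=resolution
    )


class TestCallTads:
    def test_uniform_track_gives_single_structure(self):
        track = _ins_track(np.zeros(30))
        with pytest.warns(UserWarning, match="no boundary"):
            tads = domains.call_tads(track)
        assert len(tads) == 1

    def test_deeper_minimum_wins_within_delta_window(self):
        score = np.zeros(30)
        score[10] = -0.5
        score[12] = -0.9  # deeper, 2 bins away
        tads = domains.call_tads(_ins_track(score), delta_window=3)
        assert list(tads.boundaries()["pos"] // 20_000) == [12]

    def test_planted_boundaries_recovered(self):
        from polytopo.synthetic import SimulationConfig, simulate_genome, simulate_hic

        hits = []
        for seed in range(201, 207):  # pooled recovery over independent seeds
            cfg = SimulationConfig(
                seed=seed,
                chromosomes=(("A01", 8_000_000, "At"), ("D01", 5_000_000, "Dt")),
            )
            genome, truth = simulate_genome(cfg)
            m = simulate_hic(genome, truth, "0DPA", cfg)
            b20 = contacts.ice_balance(m.aggregate(20_000))
            called = domains.call_tads(insulation_score(b20)).boundaries()
            tt = truth.tads["0DPA"]
            for chrom in genome.chrom_names:
                tb = tt[tt["chrom"] == chrom]["start"].to_numpy()[1:] // 20_000
                cb = called[called["chrom"] == chrom]["pos"].to_numpy() // 20_000
                hits += [bool(len(cb) and (np.abs(cb - b) <= 1).any()) for b in tb]
        assert np.mean(hits) >= 0.90

    def test_output_tiles_each_chromosome(self, small_matrix):
        b20 = contacts.ice_balance(small_matrix.aggregate(20_000))
        tset = domains.call_tads(insulation_score(b20))
        for chrom, grp in tset.frame.groupby("chrom"):
            s = grp.sort_values("start")
            assert s["start"].iloc[0] == 0
            assert (s["end"].to_numpy()[:-1] == s["start"].to_numpy()[1:]).all()


def _tads(chrom_bounds, n_bins=50, res=20_000):
    return tadset_from_frame(
        pd.DataFrame(
            {
                "chrom": "c",
                "start": [0] + [b * res for b in chrom_bounds],
                "end": [b * res for b in chrom_bounds] + [n_bins * res],
            }
        ),
        res,
    )


class TestConservation:
    def test_identical_sets_are_thoroughly_conserved(self):
        sets = {s: _tads([10, 20, 35]) for s in ("0DPA", "5DPA", "10DPA", "20DPA")}
        out = domains.tad_conservation(sets)
        assert (out["class"] == "thoroughly_conserved").all()

    def test_boundary_shifted_exactly_40kb_still_conserved(self):
        t1 = _tads([10, 20])
        t2 = _tads([10, 22])  # 2 bins = 40 kb, inclusive tolerance
        flags = conserved_boundaries(t1, t2)
        assert flags["conserved"].all()
        assert tad_conserved_between(t1, t2).all()

    def test_boundary_shifted_60kb_not_conserved(self):
        t1 = _tads([10, 20])
        t2 = _tads([10, 23])
        flags = conserved_boundaries(t1, t2).set_index("pos")
        assert bool(flags.loc[10 * 20_000, "conserved"])
        assert not bool(flags.loc[20 * 20_000, "conserved"])

    def test_conservation_is_symmetric(self):
        rng = np.random.default_rng(1)
        b1 = sorted(rng.choice(np.arange(5, 45, 4), 5, replace=False))
        b2 = sorted(rng.choice(np.arange(5, 45, 4), 5, replace=False))
        t1, t2 = _tads(b1), _tads(b2)
        f12 = conserved_boundaries(t1, t2)
        f21 = conserved_boundaries(t2, t1)
        # a boundary of t1 conserved in t2 implies its witness in t2 is
        # conserved in t1 (the relation on positions is symmetric)
        for _, r in f12[f12["conserved"]].iterrows():
            near = f21[np.abs(f21["pos"] - r["pos"]) <= 40_000]
            assert near["conserved"].any()


class TestBoundaryInterior:
    def _genes(self, positions):
        return GenomicIntervalSet(
            pd.DataFrame(
                {
                    "chrom": "c",
                    "start": positions,
                    "end": [p + 2_000 for p in positions],
                    "gene_id": [f"g{i}" for i in range(len(positions))],
                }
            )
        )

    def test_gene_at_junction_is_boundary_and_center_is_interior(self):
        tads = _tads([10, 20])
        genes = self._genes([10 * 20_000 + 1_000, 15 * 20_000 + 1_000])
        out = boundary_interior_assignment(tads, genes)
        assert list(out.sort_values("start")["position"]) == ["boundary", "interior"]

    def test_planted_boundary_expression_boost_recovered(self, small_data, small_expression):
        genome, truth = small_data
        tads = tadset_from_frame(truth.tads["0DPA"])
        assigned = boundary_interior_assignment(tads, genome.genes)
        mean_fpkm = (
            small_expression[small_expression["stage"] == "0DPA"]
            .groupby("gene_id")["fpkm"]
            .mean()
        )
        vals = assigned.set_index("gene_id")["position"]
        b = mean_fpkm[vals.reindex(mean_fpkm.index) == "boundary"]
        i = mean_fpkm[vals.reindex(mean_fpkm.index) == "interior"]
        res = domains.boundary_interior_test(b.dropna(), i.dropna())
        assert res["p_value"] < 0.05


class TestHomology:
    def _setup(self, dt_bounds):
        # At: one TAD [0, 10) bins with genes g1, g2; Dt: configurable
        at = tadset_from_frame(
            pd.DataFrame({"chrom": ["cA"], "start": [0], "end": [10 * 20_000]})
        )
        dt = tadset_from_frame(
            pd.DataFrame(
                {
                    "chrom": "cD",
                    "start": [0] + [b * 20_000 for b in dt_bounds],
                    "end": [b * 20_000 for b in dt_bounds] + [10 * 20_000],
                }
            )
        )
        genes = GenomicIntervalSet(
            pd.DataFrame(
                {
                    "chrom": ["cA", "cA", "cD", "cD"],
                    "start": [40_000, 120_000, 40_000, 120_000],
                    "end": [42_000, 122_000, 42_000, 122_000],
                    "gene_id": ["a1", "a2", "d1", "d2"],
                }
            )
        )
        pairs = pd.DataFrame(
            {"pair_id": ["p1", "p2"], "at_gene": ["a1", "a2"], "dt_gene": ["d1", "d2"]}
        )
        return at, dt, genes, pairs

    def test_identical_pair_content_is_homoeologous(self):
        at, dt, genes, pairs = self._setup(dt_bounds=[])
        out = classify_tad_homology(at, dt, pairs, genes)
        assert len(out) == 1
        assert out[0].classification == "homoeologous"
        assert out[0].pair_ids == ("p1", "p2")

    def test_partners_split_across_dt_tads_is_partitioned(self):
        at, dt, genes, pairs = self._setup(dt_bounds=[4])  # boundary between d1, d2
        out = classify_tad_homology(at, dt, pairs, genes)
        assert out[0].classification == "partitioned"
        assert len(out[0].dt_tads) == 2

    def test_tads_without_homoeologous_genes_unclassified(self):
        at, dt, genes, _ = self._setup(dt_bounds=[])
        empty_pairs = pd.DataFrame(columns=["pair_id", "at_gene", "dt_gene"])
        assert classify_tad_homology(at, dt, empty_pairs, genes) == []

    def test_swapping_subgenomes_transposes_the_pairing(self):
        at, dt, genes, pairs = self._setup(dt_bounds=[])
        fwd = classify_tad_homology(at, dt, pairs, genes)
        rev = classify_tad_homology(
            dt, at, pairs.rename(columns={"at_gene": "dt_gene", "dt_gene": "at_gene"}), genes
        )
        assert fwd[0].classification == rev[0].classification == "homoeologous"
        assert fwd[0].at_tad in rev[0].dt_tads

    def test_planted_labels_recovered_from_planted_tads(self, small_data):
        genome, truth = small_data
        stage = "0DPA"
        at = tadset_from_frame(
            truth.tads[stage][truth.tads[stage]["chrom"] == "A01"]
        )
        dt = tadset_from_frame(
            truth.tads[stage][truth.tads[stage]["chrom"] == "D01"]
        )
        out = classify_tad_homology(at, dt, truth.homoeolog_pairs, genome.genes)
        called = {h.at_tad: h.classification for h in out}
        planted = truth.tad_homology[stage].set_index("at_tad")["class"]
        agree = [called.get(t) == c for t, c in planted.items() if t in called]
        assert len(agree) > 10
        assert np.mean(agree) == 1.0


class TestPositionalShiftBias:
    def _homology(self, n, shifted_mask, rng):
        out = []
        for i in range(n):
            pid = f"p{i}"
            pos_at = "boundary" if rng.random() < 0.5 else "interior"
            pos_dt = (
                ("interior" if pos_at == "boundary" else "boundary")
                if shifted_mask[i]
                else pos_at
            )
            out.append(
                domains.TadHomologyPair(
                    at_tad=f"a{i}",
                    dt_tads=(f"d{i}",),
                    classification="homoeologous",
                    pair_ids=(pid,),
                    positions_at={pid: pos_at},
                    positions_dt={pid: pos_dt},
                )
            )
        return out

    def test_degenerate_table_reports_infinite_odds(self):
        rng = np.random.default_rng(0)
        shifted = np.array([True] * 10 + [False] * 10)
        hom = self._homology(20, shifted, rng)
        bias = pd.DataFrame(
            {"pair_id": [f"p{i}" for i in range(20)], "bias": ["At"] * 10 + ["none"] * 10}
        )
        out = positional_shift_bias(hom, bias)
        assert out["odds_ratio"] == np.inf
        assert out["continuity_corrected"]

    def test_planted_coupling_gives_enrichment(self):
        rng = np.random.default_rng(1)
        n = 200
        shifted = rng.random(n) < 0.4
        hom = self._homology(n, shifted, rng)
        # bias placed preferentially on shifted pairs
        bias_flags = np.where(
            shifted, rng.random(n) < 0.7, rng.random(n) < 0.15
        )
        bias = pd.DataFrame(
            {
                "pair_id": [f"p{i}" for i in range(n)],
                "bias": np.where(bias_flags, "At", "none"),
            }
        )
        out = positional_shift_bias(hom, bias)
        assert out["odds_ratio"] > 1.0
        assert out["p_permutation"] < 0.05

    def test_independent_planting_covers_odds_of_one(self):
        rng = np.random.default_rng(2)
        covered = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 300
            shifted = r.random(n) < 0.4
            hom = self._homology(n, shifted, rng)
            bias = pd.DataFrame(
                {
                    "pair_id": [f"p{i}" for i in range(n)],
                    "bias": np.where(r.random(n) < 0.3, "At", "none"),
                }
            )
            out = positional_shift_bias(hom, bias, seed=seed)
            if out["p_permutation"] > 0.05:
                covered += 1
        assert covered >= 8
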