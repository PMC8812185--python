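"""Synthetic two-subgenome, four-stage dataset with planted ground truth.

The generator emulates the study design of staged cotton-fiber development in
an allotetraploid: two At chromosomes (larger, TE-richer) and two Dt
chromosomes, four developmental stages (0/5/10/20 days post anthesis), with
planted structure at every level the analysis modules recover:

* A/B compartments at 40 kb as alternating blocks, with contiguous runs of
  >= 2 bins flipping between adjacent stages;
* TAD-like structures at 20 kb tiling each chromosome, with a fraction of
  boundaries moving, appearing or disappearing per stage;
* homoeologous gene pairs in collinear order between subgenomes, with local
  whole-block inversions and Dt-specific insertions; inter-subgenome TAD
  correspondence planted as homoeologous (identical pair content) or
  partitioned (split content);
* chromatin loops at 5 kb as additive Poisson intensity dots, including dense
  loop bundles between the members of planted TAD cliques;
* histone-mark peaks (H3K27ac/H3K4me3 on A-compartment bins, H3K9me2 on B),
  and a non-gene region correspondence map between subgenomes with planted
  mark-presence vectors;
* negative-binomial expression over three replicates with planted subgenome
  bias, stage-wise differential expression, boundary-gene boosts and a
  negative clique-size/expression coupling.

Hi-C counts are Poisson draws from a multiplicative intensity surface
``lambda(i, j) = decay * compartment * tad * clique`` plus additive loop dots;
matrices at coarser resolutions are exact aggregations of the 5-kb matrix.
All randomness flows from ``SimulationConfig.seed`` through
``numpy.random.default_rng``; the same seed reproduces the dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome_io import (
    STAGES,
    BinnedMatrix,
    GenomeModel,
    GenomicIntervalSet,
    LoopSet,
    bin_table,
)

TAD_RES = 20_000
COMP_RES = 40_000
LOOP_RES = 5_000


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults describe the emulated conditions: a desk-scale two-subgenome
    genome (2 x 20 Mb At, 2 x 12 Mb Dt), power-law contact decay with
    exponent 1, moderate compartment/TAD enrichment, and effect sizes at or
    above the calling thresholds of the analysis modules.
    """

    seed: int
    chromosomes: tuple = (
        ("A01", 20_000_000, "At"),
        ("A02", 20_000_000, "At"),
        ("D01", 12_000_000, "Dt"),
        ("D02", 12_000_000, "Dt"),
    )
    # --- genome content ---
    tad_size_bins: tuple = (8, 20)  # TAD length range, 20-kb bins
    genes_per_a_tad: float = 4.0  # Poisson mean (plus 1) in A-compartment TADs
    genes_per_b_tad: float = 1.0
    boundary_gene_prob: float = 0.35
    homoeolog_fraction: float = 0.85
    dt_specific_prob: float = 0.10
    n_inversions_per_chrom: int = 1
    te_density_ratio: float = 2.0  # At : Dt TE density
    te_per_mb_dt: float = 20.0
    n_nongene_regions: int = 30  # homologous non-gene regions per chrom pair
    same_mark_fraction: float = 0.5
    mark_flip_fraction: float = 0.3  # non-gene regions losing active marks late
    # --- compartments (40 kb) ---
    comp_block_bins: tuple = (10, 30)
    comp_switch_fraction: float = 0.025  # bin fraction flipped per stage pair
    # --- TAD stage dynamics (20 kb) ---
    tad_boundary_move_prob: float = 0.08
    tad_boundary_drop_prob: float = 0.04
    tad_boundary_add_prob: float = 0.04
    partition_fraction: float = 0.30  # At TADs whose Dt counterpart is split
    # --- Hi-C intensity model (5 kb) ---
    alpha: float = 1.0  # distance-decay exponent
    hic_depth: float = 10.0  # expected counts at a one-bin gap
    diag_factor: float = 2.0
    compartment_contrast: float = 1.6
    tad_enrichment: float = 2.0
    clique_background: float = 1.5
    loop_intensity: float = 25.0  # additive dot, expected extra counts
    clique_loop_intensity: float = 12.0
    dt_compaction: float = 1.3  # Dt chromosomes more compact
    trans_contacts: int = 20_000
    # --- loops / cliques ---
    loops_per_chrom: int = 60
    loop_conserved_prob: float = 0.25
    hg_mirror_prob: float = 0.2  # At HG-HG loops mirrored onto Dt partners
    loop_gap_bins: tuple = (10, 160)  # 50 kb - 800 kb at 5 kb
    cliques_per_chrom: int = 2
    clique_size_range: tuple = (3, 7)
    clique_loop_density: float = 0.15  # planted loops per TAD bin-pair
    # --- expression ---
    nb_dispersion: float = 0.02  # NB dispersion; 0 = deterministic limit
    bias_fraction: float = 0.30
    bias_effect: float = 4.0
    de_fraction: float = 0.10
    de_effect: float = 8.0
    silent_fraction: float = 0.05
    boundary_expression_boost: float = 3.0
    clique_expression_damp: tuple = (1.0, 0.5, 0.25)  # non-clique, 3<=k<=5, k>5
    base_fpkm_a: float = 30.0
    base_fpkm_b: float = 5.0
    n_replicates: int = 3

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, frac in [
            ("homoeolog_fraction", self.homoeolog_fraction),
            ("comp_switch_fraction", self.comp_switch_fraction),
            ("bias_fraction", self.bias_fraction),
            ("de_fraction", self.de_fraction),
            ("silent_fraction", self.silent_fraction),
            ("loop_conserved_prob", self.loop_conserved_prob),
            ("partition_fraction", self.partition_fraction),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.alpha <= 0 or self.hic_depth <= 0:
            raise ValueError("alpha and hic_depth must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    def decay_only(self) -> "SimulationConfig":
        """Variant with every enrichment switched off: pure power-law decay."""
        return replace(
            self,
            compartment_contrast=1.0,
            tad_enrichment=1.0,
            clique_background=1.0,
            dt_compaction=1.0,
            loops_per_chrom=0,
            cliques_per_chrom=0,
        )


@dataclass
class TruthSet:
    """Planted ground truth at every level of the synthetic dataset."""

    compartments: dict  # stage -> DataFrame(chrom, start, label) at 40 kb
    tads: dict  # stage -> DataFrame(chrom, start, end, tad_id)
    loops: dict  # stage -> DataFrame(chrom, anchor1, anchor2, intensity, kind)
    cliques: dict  # stage -> list of {"chrom", "tad_ids": tuple}
    homoeolog_pairs: pd.DataFrame  # pair_id, at_gene, dt_gene, bias_<stage>...
    tad_homology: dict  # stage -> DataFrame(at_tad, dt_tads, class)
    nongene_homology: pd.DataFrame
    similarity: pd.DataFrame  # directed gene-pair scores
    expression_plan: pd.DataFrame  # gene_id x planted per-stage FPKM + flags
    boundary_gene_ids: set = field(default_factory=set)

    def stage_tads(self, stage: str) -> pd.DataFrame:
        return self.tads[stage]


# ---------------------------------------------------------------------------
# Genome + truth construction
# ---------------------------------------------------------------------------


def _plant_compartments(rng, n_bins: int, cfg: SimulationConfig) -> dict:
    """Alternating A/B blocks at stage 0; >= 2-bin runs flip per stage pair."""
    lo, hi = cfg.comp_block_bins
    labels = np.empty(n_bins, dtype="U1")
    pos, label = 0, rng.choice(["A", "B"])
    while pos < n_bins:
        size = int(rng.integers(lo, hi + 1))
        labels[pos : pos + size] = label
        label = "A" if label == "B" else "B"
        pos += size
    out = {STAGES[0]: labels}
    for s_prev, s in zip(STAGES, STAGES[1:]):
        cur = out[s_prev].copy()
        target = cfg.comp_switch_fraction * n_bins
        flipped = 0
        guard = 0
        while flipped < target and guard < 200:
            guard += 1
            run = int(rng.integers(2, 7))
            start = int(rng.integers(0, max(1, n_bins - run)))
            seg = cur[start : start + run]
            if len(set(seg)) != 1:  # flip homogeneous runs only
                continue
            cur[start : start + run] = "A" if seg[0] == "B" else "B"
            flipped += run
        out[s] = cur
    return out


def _tile_tads(rng, n_bins: int, cfg: SimulationConfig) -> np.ndarray:
    """Internal boundary bin indices tiling a chromosome of n_bins 20-kb bins."""
    lo, hi = cfg.tad_size_bins
    bounds = []
    pos = int(rng.integers(lo, hi + 1))
    while pos < n_bins - lo:
        bounds.append(pos)
        pos += int(rng.integers(lo, hi + 1))
    return np.array(bounds, dtype=int)


def _perturb_boundaries(
    rng, bounds: np.ndarray, n_bins: int, cfg: SimulationConfig, protected: set
) -> np.ndarray:
    """Stage-wise boundary dynamics: move (+-3 bins), drop, add."""
    out = []
    for b in bounds:
        if b in protected:
            out.append(b)
            continue
        u = rng.random()
        if u < cfg.tad_boundary_drop_prob:
            continue
        if u < cfg.tad_boundary_drop_prob + cfg.tad_boundary_move_prob:
            out.append(b + int(rng.choice([-3, 3])))
        else:
            out.append(b)
    # occasional new boundaries inside large gaps
    arr = sorted(set(out))
    extended = []
    prev = 0
    for b in arr + [n_bins]:
        if b - prev >= 2 * cfg.tad_size_bins[0] and rng.random() < cfg.tad_boundary_add_prob * 4:
            mid = prev + (b - prev) // 2
            extended.append(mid)
        if b < n_bins:
            extended.append(b)
        prev = b
    arr = sorted(set(extended))
    # enforce min TAD size of 3 bins
    final = []
    prev = 0
    for b in arr:
        if b - prev >= 3 and n_bins - b >= 3:
            final.append(b)
            prev = b
    return np.array(final, dtype=int)


def _tads_frame(chrom: str, bounds: np.ndarray, n_bins: int) -> pd.DataFrame:
    edges = np.concatenate([[0], bounds, [n_bins]])
    rows = [
        {
            "chrom": chrom,
            "start": int(edges[k]) * TAD_RES,
            "end": int(edges[k + 1]) * TAD_RES,
            "tad_id": f"{chrom}.{k}",
        }
        for k in range(len(edges) - 1)
    ]
    return pd.DataFrame(rows)


def simulate_genome(config: SimulationConfig):
    """Build the genome model and the full planted truth set.

    Returns (GenomeModel, TruthSet). Deterministic under ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed % (2**31), 11])
    chrom_info = {name: (length, sub) for name, length, sub in cfg.chromosomes}
    at_chroms = [c for c, (_, s) in chrom_info.items() if s == "At"]
    dt_chroms = [c for c, (_, s) in chrom_info.items() if s == "Dt"]
    if len(at_chroms) != len(dt_chroms):
        raise ValueError("need equal numbers of At and Dt chromosomes")
    pairs_of_chroms = list(zip(at_chroms, dt_chroms))

    # --- compartments per chromosome per stage (40 kb) ---
    # At chromosomes get fresh block layouts; each Dt chromosome inherits its
    # At partner's labels by coordinate scaling (homoeologous regions share
    # compartment status), which also couples Dt gene density to Dt labels.
    comp_per_chrom = {}
    for chrom in at_chroms:
        n40 = -(-chrom_info[chrom][0] // COMP_RES)
        comp_per_chrom[chrom] = _plant_compartments(rng, n40, cfg)
    for chrom_a, chrom_d in pairs_of_chroms:
        n40_d = -(-chrom_info[chrom_d][0] // COMP_RES)
        n40_a = -(-chrom_info[chrom_a][0] // COMP_RES)
        ratio = chrom_info[chrom_a][0] / chrom_info[chrom_d][0]
        src_idx = np.minimum((np.arange(n40_d) * ratio).astype(int), n40_a - 1)
        comp_per_chrom[chrom_d] = {
            stage: comp_per_chrom[chrom_a][stage][src_idx] for stage in STAGES
        }
    compartments = {}
    for stage in STAGES:
        frames = []
        for chrom, (length, _) in chrom_info.items():
            n40 = -(-length // COMP_RES)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": np.arange(n40) * COMP_RES,
                        "label": comp_per_chrom[chrom][stage],
                    }
                )
            )
        compartments[stage] = pd.concat(frames, ignore_index=True)

    # --- At TADs: stage-0 tiling, then per-stage perturbation ---
    base_bounds = {}
    n20 = {c: -(-chrom_info[c][0] // TAD_RES) for c in chrom_info}
    for chrom in chrom_info:
        base_bounds[chrom] = _tile_tads(rng, n20[chrom], cfg)

    # --- genes on At chromosomes, placed inside stage-0 TADs ---
    gene_rows = []
    boundary_gene_ids = set()
    gene_counter = {}
    at_gene_order = {c: [] for c in at_chroms}
    for chrom in at_chroms:
        length = chrom_info[chrom][0]
        edges = np.concatenate([[0], base_bounds[chrom], [n20[chrom]]])
        comp0 = comp_per_chrom[chrom][STAGES[0]]
        gene_counter[chrom] = 0
        for k in range(len(edges) - 1):
            lo_bp, hi_bp = int(edges[k]) * TAD_RES, int(edges[k + 1]) * TAD_RES
            mid40 = min(((lo_bp + hi_bp) // 2) // COMP_RES, len(comp0) - 1)
            lam = cfg.genes_per_a_tad if comp0[mid40] == "A" else cfg.genes_per_b_tad
            n_genes = 1 + int(rng.poisson(lam)) if comp0[mid40] == "A" else int(
                rng.poisson(lam)
            )
            inner_lo = lo_bp + TAD_RES
            inner_hi = hi_bp - TAD_RES
            if inner_hi - inner_lo < 10_000:
                n_genes = 0
            starts = np.sort(
                rng.integers(inner_lo, max(inner_lo + 1, inner_hi - 5_000), n_genes)
            )
            for s in starts:
                gene_counter[chrom] += 1
                gid = f"G{chrom}G{gene_counter[chrom]:04d}"
                glen = int(rng.integers(1_000, 4_000))
                gene_rows.append(
                    (chrom, int(s), min(int(s) + glen, length), gid, "+")
                )
                at_gene_order[chrom].append(gid)
            # boundary gene in the first bin of the next TAD
            if k < len(edges) - 2 and rng.random() < cfg.boundary_gene_prob:
                b_bp = int(edges[k + 1]) * TAD_RES
                gene_counter[chrom] += 1
                gid = f"G{chrom}G{gene_counter[chrom]:04d}"
                s = b_bp + int(rng.integers(2_000, 10_000))
                gene_rows.append((chrom, s, min(s + 3_000, length), gid, "+"))
                at_gene_order[chrom].append(gid)
                boundary_gene_ids.add(gid)

    # keep At gene order sorted by position (boundary genes interleave)
    at_frame = pd.DataFrame(
        gene_rows, columns=["chrom", "start", "end", "gene_id", "strand"]
    ).sort_values(["chrom", "start"])
    at_gene_order = {
        c: list(at_frame[at_frame["chrom"] == c]["gene_id"]) for c in at_chroms
    }

    # --- homoeolog assignment and Dt gene positions (collinear + inversions) ---
    pair_rows = []
    dt_rows = []
    pair_counter = 0
    inversion_pairs = set()  # pair ids inside inverted blocks
    for chrom_a, chrom_d in pairs_of_chroms:
        sub = at_frame[at_frame["chrom"] == chrom_a]
        ratio = chrom_info[chrom_d][0] / chrom_info[chrom_a][0]
        # boundary-boosted genes stay subgenome-specific so positional
        # expression effects never masquerade as homoeolog bias
        eligible = ~sub["gene_id"].isin(boundary_gene_ids)
        partnered = sub[eligible & (rng.random(len(sub)) < cfg.homoeolog_fraction)]
        dt_pos = (partnered["start"].to_numpy() * ratio).astype(int)
        dt_pos = np.sort(dt_pos + rng.integers(-4_000, 4_000, len(dt_pos)))
        order = list(range(len(partnered)))
        # whole-block inversions spanning ~2 TAD gene groups (order reversed,
        # positions kept sorted, so pair-content per TAD is unchanged)
        for _ in range(cfg.n_inversions_per_chrom):
            if len(order) < 12:
                break
            start = int(rng.integers(0, len(order) - 10))
            width = int(rng.integers(8, 11))
            order[start : start + width] = order[start : start + width][::-1]
            for idx in order[start : start + width]:
                inversion_pairs.add((chrom_a, idx))
        at_ids = partnered["gene_id"].to_list()
        for slot, idx in enumerate(order):
            pair_counter += 1
            pid = f"p{pair_counter:05d}"
            at_gid = at_ids[idx]
            dt_gid = f"G{chrom_d}G{slot + 1:04d}"
            s = int(dt_pos[slot])
            glen = int(rng.integers(1_000, 4_000))
            dt_rows.append(
                (chrom_d, s, min(s + glen, chrom_info[chrom_d][0]), dt_gid, "+")
            )
            pair_rows.append((pid, at_gid, dt_gid, chrom_a, chrom_d))
    pairs = pd.DataFrame(
        pair_rows, columns=["pair_id", "at_gene", "dt_gene", "at_chrom", "dt_chrom"]
    )

    # Dt-specific insertions
    extra = 0
    for chrom_d in dt_chroms:
        n_extra = int(
            cfg.dt_specific_prob * len(pairs[pairs["dt_chrom"] == chrom_d])
        )
        for _ in range(n_extra):
            extra += 1
            s = int(rng.integers(50_000, chrom_info[chrom_d][0] - 50_000))
            dt_rows.append((chrom_d, s, s + 2_000, f"G{chrom_d}X{extra:04d}", "+"))
    dt_frame = pd.DataFrame(
        dt_rows, columns=["chrom", "start", "end", "gene_id", "strand"]
    )
    genes = pd.concat([at_frame, dt_frame], ignore_index=True)
    genes = genes.sort_values(["chrom", "start"]).reset_index(drop=True)

    # --- TAD sets per stage; clique TAD boundaries protected ---
    tads = {}
    stage_bounds = {}
    for si, stage in enumerate(STAGES):
        stage_bounds[stage] = {}
        frames = []
        for chrom in at_chroms:
            if si == 0:
                b = base_bounds[chrom]
            else:
                srng = np.random.default_rng([cfg.seed % (2**31), 23, si, _ci(chrom)])
                b = _perturb_boundaries(
                    srng, base_bounds[chrom], n20[chrom], cfg, protected=set()
                )
            stage_bounds[stage][chrom] = b
            frames.append(_tads_frame(chrom, b, n20[chrom]))
        tads[stage] = frames  # Dt appended below

    # --- Dt TADs per stage from that stage's At gene groups + homology truth ---
    gene_pos = genes.set_index("gene_id")
    tad_homology = {}
    for si, stage in enumerate(STAGES):
        hom_rows = []
        for chrom_a, chrom_d in pairs_of_chroms:
            ratio = chrom_info[chrom_d][0] / chrom_info[chrom_a][0]
            at_tads = _tads_frame(
                chrom_a, stage_bounds[stage][chrom_a], n20[chrom_a]
            )
            cpairs = pairs[pairs["at_chrom"] == chrom_a]
            at_mid = (
                gene_pos.loc[cpairs["at_gene"], ["start", "end"]].sum(axis=1) // 2
            ).to_numpy()
            dt_mid = (
                gene_pos.loc[cpairs["dt_gene"], ["start", "end"]].sum(axis=1) // 2
            ).to_numpy()
            pids = cpairs["pair_id"].to_numpy()
            # group pairs by At TAD
            groups = []
            for _, t in at_tads.iterrows():
                in_tad = (at_mid >= t["start"]) & (at_mid < t["end"])
                groups.append(
                    {
                        "at_tad": t["tad_id"],
                        "pids": pids[in_tad],
                        "dt_mid": np.sort(dt_mid[in_tad]),
                        "scaled_end": t["end"] * ratio,
                    }
                )
            prng = np.random.default_rng(
                [cfg.seed % (2**31), 31, si, _ci(chrom_a)]
            )
            bounds_d = []  # (bp position, kind)
            split_tads = set()
            for gi in range(len(groups) - 1):
                g, g_next = groups[gi], groups[gi + 1]
                if len(g["dt_mid"]) and len(g_next["dt_mid"]):
                    b = (g["dt_mid"][-1] + g_next["dt_mid"][0]) // 2
                else:
                    b = g["scaled_end"]
                bounds_d.append(int(b) // TAD_RES)
                # partition: split this Dt group between two of its genes
                if (
                    len(g["pids"]) >= 2
                    and prng.random() < cfg.partition_fraction
                ):
                    cut = int(prng.integers(1, len(g["pids"])))
                    sb = (g["dt_mid"][cut - 1] + g["dt_mid"][cut]) // 2
                    bounds_d.append(int(sb) // TAD_RES)
                    split_tads.add(g["at_tad"])
            if len(groups) and len(groups[-1]["pids"]) >= 2 and prng.random() < cfg.partition_fraction:
                g = groups[-1]
                cut = int(prng.integers(1, len(g["pids"])))
                sb = (g["dt_mid"][cut - 1] + g["dt_mid"][cut]) // 2
                bounds_d.append(int(sb) // TAD_RES)
                split_tads.add(g["at_tad"])
            # enforce min TAD size; dropped boundaries may fuse content
            arr = sorted(set(bounds_d))
            final = []
            prev = 0
            for b in arr:
                if b - prev >= 3 and n20[chrom_d] - b >= 3:
                    final.append(b)
                    prev = b
            dt_tads = _tads_frame(chrom_d, np.array(final, dtype=int), n20[chrom_d])
            tads[stage].append(dt_tads)
            # honest homology labels from the realized geometry
            dt_sets = {}
            for _, t in dt_tads.iterrows():
                in_tad = (dt_mid >= t["start"]) & (dt_mid < t["end"])
                dt_sets[t["tad_id"]] = frozenset(pids[in_tad])
            for g in groups:
                pset = frozenset(g["pids"])
                if not pset:
                    continue
                partners = [
                    tid for tid, s in dt_sets.items() if s & pset
                ]
                exact = [tid for tid in partners if dt_sets[tid] == pset]
                cls = "homoeologous" if len(exact) == 1 and partners == exact else "partitioned"
                hom_rows.append(
                    {
                        "at_tad": g["at_tad"],
                        "dt_tads": ",".join(partners),
                        "class": cls,
                    }
                )
        tad_homology[stage] = pd.DataFrame(hom_rows)
        tads[stage] = pd.concat(tads[stage], ignore_index=True)

    # --- cliques per stage on protected (stable) TAD windows ---
    cliques, clique_loop_rows = _plant_cliques(rng, tads, n20, chrom_info, cfg)

    # --- loops per stage ---
    loops = _plant_loops(rng, genes, pairs, chrom_info, cfg)
    for stage in STAGES:
        loops[stage] = pd.concat(
            [loops[stage], clique_loop_rows[stage]], ignore_index=True
        )

    # --- TEs ---
    te_rows = []
    te_counter = 0
    for chrom, (length, sub) in chrom_info.items():
        dens = cfg.te_per_mb_dt * (cfg.te_density_ratio if sub == "At" else 1.0)
        n_te = int(dens * length / 1e6)
        starts = np.sort(rng.integers(0, length - 10_000, n_te))
        bounds0 = base_bounds[chrom]
        boundary_bp = set((bounds0 * TAD_RES).tolist())
        for s in starts:
            te_counter += 1
            tlen = int(rng.integers(2_000, 8_000))
            near_boundary = any(abs(int(s) - b) < TAD_RES for b in boundary_bp)
            expr = {
                stage: float(
                    rng.gamma(2.0, (3.0 if near_boundary else 1.0))
                )
                for stage in STAGES
            }
            te_rows.append(
                {
                    "chrom": chrom,
                    "start": int(s),
                    "end": min(int(s) + tlen, length),
                    "te_id": f"TE{te_counter:05d}",
                    "family": rng.choice(["Gypsy", "Copia", "LINE"]),
                    **{f"expr_{stage}": expr[stage] for stage in STAGES},
                }
            )
    tes = pd.DataFrame(te_rows)

    # --- non-gene homology map with planted mark vectors ---
    nongene = _plant_nongene_homology(rng, genes, pairs_of_chroms, chrom_info, cfg)

    # --- peaks coupled to compartments + non-gene region vectors ---
    peaks = _plant_peaks(rng, compartments, nongene, chrom_info, cfg)

    # --- similarity table ---
    similarity = _plant_similarity(rng, genes, pairs)

    # --- expression plan ---
    pairs = _plant_bias(rng, pairs, cfg)
    expression_plan = _plant_expression(
        rng, genes, pairs, compartments, boundary_gene_ids, cliques, tads, cfg
    )

    genome = GenomeModel(
        chromosomes=chrom_info,
        genes=GenomicIntervalSet(genes),
        transposable_elements=GenomicIntervalSet(tes) if len(tes) else None,
        peaks=peaks,
    )
    truth = TruthSet(
        compartments=compartments,
        tads=tads,
        loops=loops,
        cliques=cliques,
        homoeolog_pairs=pairs,
        tad_homology=tad_homology,
        nongene_homology=nongene,
        similarity=similarity,
        expression_plan=expression_plan,
        boundary_gene_ids=boundary_gene_ids,
    )
    return genome, truth


def _ci(chrom: str) -> int:
    return int.from_bytes(chrom.encode(), "little") % (2**31)


def _plant_cliques(rng, tads, n20, chrom_info, cfg):
    """Choose clique TAD sets per stage and plant dense loop bundles."""
    cliques = {stage: [] for stage in STAGES}
    loop_rows = {stage: [] for stage in STAGES}
    for chrom in chrom_info:
        tf0 = tads[STAGES[0]]
        tf0 = tf0[tf0["chrom"] == chrom].reset_index(drop=True)
        for ci in range(cfg.cliques_per_chrom):
            size = int(rng.integers(cfg.clique_size_range[0], cfg.clique_size_range[1] + 1))
            if len(tf0) < size + 2:
                continue
            start_k = int(rng.integers(0, len(tf0) - size))
            member_spans0 = [
                (tf0.loc[start_k + m, "start"], tf0.loc[start_k + m, "end"])
                for m in range(size)
            ]
            # stage dynamics: full clique early, dissolving later (the paper's
            # dominant trend); every other clique instead forms late
            if ci % 2 == 0:
                sizes_by_stage = [size, size, max(3, size - 1), 0]
            else:
                sizes_by_stage = [0, 3, min(size, 4), size]
            for stage, ssize in zip(STAGES, sizes_by_stage):
                if ssize < 3:
                    continue
                spans = member_spans0[:ssize]
                tf = tads[stage]
                tf = tf[tf["chrom"] == chrom]
                member_ids = []
                for lo, hi in spans:
                    mid = (lo + hi) // 2
                    hit = tf[(tf["start"] <= mid) & (tf["end"] > mid)]
                    if len(hit):
                        member_ids.append(hit.iloc[0]["tad_id"])
                member_ids = sorted(set(member_ids))
                if len(member_ids) < 3:
                    continue
                cliques[stage].append({"chrom": chrom, "tad_ids": tuple(member_ids)})
                # plant loop bundles between every member pair
                tfi = tf.set_index("tad_id")
                for a in range(len(member_ids)):
                    for b in range(a + 1, len(member_ids)):
                        ta, tb = tfi.loc[member_ids[a]], tfi.loc[member_ids[b]]
                        b1 = (ta["end"] - ta["start"]) // TAD_RES
                        b2 = (tb["end"] - tb["start"]) // TAD_RES
                        n_loops = max(8, int(round(cfg.clique_loop_density * b1 * b2)))
                        xs = rng.integers(
                            ta["start"] // LOOP_RES, ta["end"] // LOOP_RES, n_loops
                        )
                        ys = rng.integers(
                            tb["start"] // LOOP_RES, tb["end"] // LOOP_RES, n_loops
                        )
                        seen = set()
                        for x, y in zip(xs, ys):
                            if (x, y) in seen:
                                continue
                            seen.add((x, y))
                            loop_rows[stage].append(
                                {
                                    "chrom": chrom,
                                    "anchor1": int(x) * LOOP_RES,
                                    "anchor2": int(y) * LOOP_RES,
                                    "intensity": cfg.clique_loop_intensity,
                                    "kind": "clique",
                                }
                            )
    cols = ["chrom", "anchor1", "anchor2", "intensity", "kind"]
    loop_frames = {
        stage: pd.DataFrame(rows, columns=cols) for stage, rows in loop_rows.items()
    }
    return cliques, loop_frames


def _plant_loops(rng, genes, pairs, chrom_info, cfg):
    """Planted loop dots per stage: G-G, G-N, N-N, HG-HG and HG-HN kinds."""
    loops = {stage: [] for stage in STAGES}
    hg_at = set(pairs["at_gene"])
    hg_dt = set(pairs["dt_gene"])
    # At gene bin -> Dt partner (chrom, bin) for mirrored HG-HG loops
    gpos = genes.set_index("gene_id")
    mirror_of = {}
    for _, p in pairs.iterrows():
        ga, gd = gpos.loc[p["at_gene"]], gpos.loc[p["dt_gene"]]
        key = (ga["chrom"], int((ga["start"] + ga["end"]) // 2) // LOOP_RES)
        mirror_of[key] = (gd["chrom"], int((gd["start"] + gd["end"]) // 2) // LOOP_RES)
    for chrom, (length, _) in chrom_info.items():
        cg = genes[genes["chrom"] == chrom]
        gene_bins = np.unique(((cg["start"] + cg["end"]) // 2) // LOOP_RES)
        hg_mask = cg["gene_id"].isin(hg_at | hg_dt)
        hg_bins = np.unique(
            ((cg[hg_mask]["start"] + cg[hg_mask]["end"]) // 2) // LOOP_RES
        )
        n_bins = length // LOOP_RES
        pool = []
        for _ in range(cfg.loops_per_chrom):
            kind = rng.choice(
                ["G-G", "G-N", "N-N", "HG-HG", "HG-HN"],
                p=[0.3, 0.25, 0.15, 0.15, 0.15],
            )
            gap = int(rng.integers(*cfg.loop_gap_bins))
            if kind in ("G-G", "HG-HG") and len(gene_bins) > 1:
                src = hg_bins if kind == "HG-HG" and len(hg_bins) > 1 else gene_bins
                a = int(rng.choice(src))
                cands = src[(np.abs(src - a) >= cfg.loop_gap_bins[0]) & (np.abs(src - a) <= cfg.loop_gap_bins[1])]
                if not len(cands):
                    continue
                b = int(rng.choice(cands))
            elif kind in ("G-N", "HG-HN") and len(gene_bins):
                src = hg_bins if kind == "HG-HN" and len(hg_bins) else gene_bins
                a = int(rng.choice(src))
                b = a + gap if a + gap < n_bins else a - gap
                if b in set(gene_bins):
                    b = b + 1  # keep the second anchor gene-free
            else:
                a = int(rng.integers(0, n_bins - gap - 1))
                b = a + gap
                kind = "N-N"
            lo, hi = min(a, b), max(a, b)
            if lo == hi or hi >= n_bins:
                continue
            stages_on = (
                list(STAGES)
                if rng.random() < cfg.loop_conserved_prob
                else [s for s in STAGES if rng.random() < 0.5]
            )
            pool.append((lo, hi, kind, stages_on))
        for lo, hi, kind, stages_on in pool:
            for stage in stages_on:
                loops[stage].append(
                    {
                        "chrom": chrom,
                        "anchor1": lo * LOOP_RES,
                        "anchor2": hi * LOOP_RES,
                        "intensity": cfg.loop_intensity,
                        "kind": kind,
                    }
                )
            # a fraction of At HG-HG loops recur between the Dt partners
            if kind == "HG-HG" and rng.random() < cfg.hg_mirror_prob:
                m1 = mirror_of.get((chrom, lo))
                m2 = mirror_of.get((chrom, hi))
                if m1 and m2 and m1[0] == m2[0] and m1[1] != m2[1]:
                    for stage in stages_on:
                        loops[stage].append(
                            {
                                "chrom": m1[0],
                                "anchor1": min(m1[1], m2[1]) * LOOP_RES,
                                "anchor2": max(m1[1], m2[1]) * LOOP_RES,
                                "intensity": cfg.loop_intensity,
                                "kind": "HG-HG",
                            }
                        )
    cols = ["chrom", "anchor1", "anchor2", "intensity", "kind"]
    return {
        stage: pd.DataFrame(rows, columns=cols).drop_duplicates(
            subset=["chrom", "anchor1", "anchor2"]
        )
        for stage, rows in loops.items()
    }


def _plant_nongene_homology(rng, genes, pairs_of_chroms, chrom_info, cfg):
    rows = []
    for chrom_a, chrom_d in pairs_of_chroms:
        ratio = chrom_info[chrom_d][0] / chrom_info[chrom_a][0]
        gene_bins_a = set(
            ((genes[genes["chrom"] == chrom_a]["start"] + genes[genes["chrom"] == chrom_a]["end"]) // 2)
            // LOOP_RES
        )
        n_bins = chrom_info[chrom_a][0] // LOOP_RES
        placed = 0
        guard = 0
        while placed < cfg.n_nongene_regions and guard < cfg.n_nongene_regions * 20:
            guard += 1
            b = int(rng.integers(10, n_bins - 10))
            if b in gene_bins_a:
                continue
            start_a = b * LOOP_RES
            start_d = (int(start_a * ratio) // LOOP_RES) * LOOP_RES
            same = rng.random() < cfg.same_mark_fraction
            vec_a = {m: bool(rng.random() < 0.5) for m in ("H3K27ac", "H3K4me3", "H3K9me2")}
            if not any(vec_a.values()):
                vec_a["H3K27ac"] = True
            if same:
                vec_d = dict(vec_a)
            else:
                vec_d = dict(vec_a)
                flip = rng.choice(list(vec_d))
                vec_d[flip] = not vec_d[flip]
                if not any(vec_d.values()):
                    vec_d["H3K9me2"] = True
            rows.append(
                {
                    "chrom_a": chrom_a,
                    "start_a": start_a,
                    "end_a": start_a + LOOP_RES,
                    "chrom_b": chrom_d,
                    "start_b": start_d,
                    "end_b": start_d + LOOP_RES,
                    "same_marks": same,
                    **{f"a_{m}": vec_a[m] for m in vec_a},
                    **{f"b_{m}": vec_d[m] for m in vec_d},
                }
            )
            placed += 1
    return pd.DataFrame(rows)


def _plant_peaks(rng, compartments, nongene, chrom_info, cfg):
    """Peaks per (stage, mark): actives on A bins, H3K9me2 on B bins, plus the
    planted vectors of homologous non-gene regions."""
    peaks = {}
    for stage in STAGES:
        comp = compartments[stage]
        for mark in ("H3K27ac", "H3K4me3", "H3K9me2"):
            rows = []
            want = "A" if mark in ("H3K27ac", "H3K4me3") else "B"
            sel = comp[comp["label"] == want]
            keep = rng.random(len(sel)) < 0.6
            for _, r in sel[keep].iterrows():
                c = r["start"] + COMP_RES // 2
                rows.append((r["chrom"], c - 1_000, c + 1_000, f"{mark}_{stage}"))
            for _, r in nongene.iterrows():
                if r[f"a_{mark}"]:
                    c = r["start_a"] + LOOP_RES // 2
                    rows.append((r["chrom_a"], c - 500, c + 500, mark))
                if r[f"b_{mark}"]:
                    c = r["start_b"] + LOOP_RES // 2
                    rows.append((r["chrom_b"], c - 500, c + 500, mark))
            peaks[(stage, mark)] = GenomicIntervalSet(
                pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
            )
    return peaks


def _plant_similarity(rng, genes, pairs):
    """Directed similarity hits: reciprocal strong hits for planted pairs plus
    one-way low-score decoys."""
    rows = []
    for _, p in pairs.iterrows():
        score = float(rng.uniform(400, 900))
        rows.append((p["at_gene"], p["dt_gene"], score, 1e-50))
        rows.append((p["dt_gene"], p["at_gene"], score * rng.uniform(0.95, 1.0), 1e-50))
    # decoys: always target genes that already have a stronger true best hit
    targets_at = pairs["at_gene"].to_numpy()
    targets_dt = pairs["dt_gene"].to_numpy()
    all_genes = genes["gene_id"].to_numpy()
    n_decoys = len(pairs) // 3
    for _ in range(n_decoys):
        q = str(rng.choice(all_genes))
        t = str(rng.choice(targets_dt if q.startswith("GA") else targets_at))
        if t == q:
            continue
        rows.append((q, t, float(rng.uniform(50, 150)), 1e-5))
    return pd.DataFrame(rows, columns=["query", "subject", "score", "evalue"])


def _plant_bias(rng, pairs, cfg):
    """Assign per-stage planted bias direction and trajectory per pair."""
    pairs = pairs.copy()
    n = len(pairs)
    traj = np.full(n, "none", dtype=object)
    u = rng.random(n)
    conserved_cut = cfg.bias_fraction / 2
    dynamic_cut = cfg.bias_fraction
    traj[u < conserved_cut / 2] = "conserved_At"
    traj[(u >= conserved_cut / 2) & (u < conserved_cut)] = "conserved_Dt"
    traj[(u >= conserved_cut) & (u < dynamic_cut)] = "dynamic"
    for stage in STAGES:
        pairs[f"bias_{stage}"] = "none"
    for i in range(n):
        if traj[i] == "conserved_At":
            for stage in STAGES:
                pairs.loc[i, f"bias_{stage}"] = "At"
        elif traj[i] == "conserved_Dt":
            for stage in STAGES:
                pairs.loc[i, f"bias_{stage}"] = "Dt"
        elif traj[i] == "dynamic":
            direction = rng.choice(["At", "Dt"])
            k = int(rng.integers(1, 4))
            on = rng.choice(len(STAGES), size=k, replace=False)
            for s in on:
                pairs.loc[i, f"bias_{STAGES[s]}"] = direction
    pairs["trajectory"] = traj
    return pairs


def _plant_expression(rng, genes, pairs, compartments, boundary_ids, cliques, tads, cfg):
    """Planted per-stage FPKM per gene combining compartment base level,
    boundary boost, clique damping, DE events, bias and silent genes."""
    comp0 = {
        (r["chrom"], r["start"]): r["label"]
        for _, r in compartments[STAGES[0]].iterrows()
    }
    # per-TAD clique size class at stage 0
    tf0 = tads[STAGES[0]]
    k_by_tad = {}
    for cl in cliques[STAGES[0]]:
        for tid in cl["tad_ids"]:
            k_by_tad[tid] = max(k_by_tad.get(tid, 0), len(cl["tad_ids"]))
    tad_rows = tf0.to_dict("records")

    rows = []
    dt_partner = dict(zip(pairs["dt_gene"], pairs["pair_id"]))
    at_partner = dict(zip(pairs["at_gene"], pairs["pair_id"]))
    bias_by_pair = pairs.set_index("pair_id")
    for _, g in genes.iterrows():
        gid = g["gene_id"]
        mid = (g["start"] + g["end"]) // 2
        key = (g["chrom"], (mid // COMP_RES) * COMP_RES)
        base = cfg.base_fpkm_a if comp0.get(key) == "A" else cfg.base_fpkm_b
        base *= float(rng.lognormal(0.0, 0.4))
        if gid in boundary_ids:
            base *= cfg.boundary_expression_boost
        ktad = 0
        for t in tad_rows:
            if t["chrom"] == g["chrom"] and t["start"] <= mid < t["end"]:
                ktad = k_by_tad.get(t["tad_id"], 0)
                break
        if ktad > 5:
            base *= cfg.clique_expression_damp[2]
        elif ktad >= 3:
            base *= cfg.clique_expression_damp[1]
        in_pair = gid in at_partner or gid in dt_partner
        silent = rng.random() < cfg.silent_fraction and not in_pair
        de_planted = {}
        profile = np.full(len(STAGES), base)
        if not silent and not in_pair and rng.random() < cfg.de_fraction:
            # one planted step change at a random adjacent-stage transition
            t = int(rng.integers(1, len(STAGES)))
            direction = rng.choice([cfg.de_effect, 1.0 / cfg.de_effect])
            profile[t:] *= direction
            de_planted = {"de_transition": t, "de_direction": float(direction)}
        if silent:
            profile[:] = 0.02
        row = {
            "gene_id": gid,
            "length_kb": (g["end"] - g["start"]) / 1_000,
            "silent": silent,
            "clique_k": ktad,
            **{f"fpkm_{s}": profile[i] for i, s in enumerate(STAGES)},
            **de_planted,
        }
        rows.append(row)
    plan = pd.DataFrame(rows).set_index("gene_id")
    # pair members share one expression profile (a common-change DE event may
    # rescale both); the biased member then gets bias_effect x the partner at
    # exactly the planted stages, so per-stage ratios are 1 or bias_effect
    for _, p in pairs.iterrows():
        ref0 = max(float(plan.loc[p["at_gene"], f"fpkm_{STAGES[0]}"]), 3.0)
        shared = np.full(len(STAGES), ref0)
        if rng.random() < cfg.de_fraction:
            t = int(rng.integers(1, len(STAGES)))
            shared[t:] *= rng.choice([cfg.de_effect, 1.0 / cfg.de_effect])
            shared = np.maximum(shared, 2.0)
        for i, stage in enumerate(STAGES):
            b = p[f"bias_{stage}"]
            lo_val = shared[i]
            plan.loc[p["at_gene"], f"fpkm_{stage}"] = (
                lo_val * cfg.bias_effect if b == "At" else lo_val
            )
            plan.loc[p["dt_gene"], f"fpkm_{stage}"] = (
                lo_val * cfg.bias_effect if b == "Dt" else lo_val
            )
    return plan.reset_index()


# ---------------------------------------------------------------------------
# Hi-C simulation
# ---------------------------------------------------------------------------


def simulate_hic(
    genome: GenomeModel, truth: TruthSet, stage: str, config: SimulationConfig
) -> BinnedMatrix:
    """Draw a 5-kb contact matrix for one stage from the planted intensity.

    lambda(i, j) = depth * |i-j|^-alpha * comp(i, j) * tad(i, j) * clique(i, j)
    plus additive loop dots; counts ~ Poisson(lambda). Coarser matrices are
    obtained with :meth:`BinnedMatrix.aggregate`.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    if stage not in truth.compartments:
        raise ValueError(f"stage {stage!r} absent from truth")
    cfg = config
    bins = bin_table(genome, LOOP_RES)
    n_total = len(bins)
    offsets = {}
    pos = 0
    for chrom, (length, _) in genome.chromosomes.items():
        n = -(-length // LOOP_RES)
        offsets[chrom] = (pos, n)
        pos += n

    rows_all, cols_all, data_all = [], [], []
    comp_stage = truth.compartments[stage]
    tad_stage = truth.tads[stage]
    loops_stage = truth.loops[stage]
    cliques_stage = truth.cliques[stage]
    si = STAGES.index(stage)

    for chrom, (length, sub) in genome.chromosomes.items():
        rng = np.random.default_rng(
            [cfg.seed % (2**31), 47, si, _ci(chrom)]
        )
        off, n = offsets[chrom]
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        lam = cfg.hic_depth * np.maximum(d, 1.0) ** (-cfg.alpha)
        np.fill_diagonal(lam, cfg.hic_depth * cfg.diag_factor)
        if sub == "Dt":
            lam *= cfg.dt_compaction
        # compartment checkerboard (40-kb labels expanded to 5-kb bins)
        if cfg.compartment_contrast != 1.0:
            cl = comp_stage[comp_stage["chrom"] == chrom]["label"].to_numpy()
            lab5 = np.repeat(cl, COMP_RES // LOOP_RES)[:n]
            same = np.equal.outer(lab5, lab5)
            lam *= np.where(same, cfg.compartment_contrast, 1.0)
        # TAD blocks
        if cfg.tad_enrichment != 1.0:
            tid5 = np.full(n, -1)
            tf = tad_stage[tad_stage["chrom"] == chrom]
            for k, (_, t) in enumerate(tf.iterrows()):
                tid5[t["start"] // LOOP_RES : t["end"] // LOOP_RES] = k
            same_tad = np.equal.outer(tid5, tid5) & (tid5 >= 0)[:, None]
            lam *= np.where(same_tad, cfg.tad_enrichment, 1.0)
        # clique rectangles (mild background on member TAD pairs)
        if cfg.clique_background != 1.0 and cliques_stage:
            tf = tad_stage[tad_stage["chrom"] == chrom].set_index("tad_id")
            for cl in cliques_stage:
                if cl["chrom"] != chrom:
                    continue
                spans = [
                    (tf.loc[t, "start"] // LOOP_RES, tf.loc[t, "end"] // LOOP_RES)
                    for t in cl["tad_ids"]
                ]
                for a in range(len(spans)):
                    for b in range(a + 1, len(spans)):
                        (s1, e1), (s2, e2) = spans[a], spans[b]
                        lam[s1:e1, s2:e2] *= cfg.clique_background
                        lam[s2:e2, s1:e1] *= cfg.clique_background
        # additive loop dots
        lf = loops_stage[loops_stage["chrom"] == chrom]
        if len(lf):
            i = (lf["anchor1"] // LOOP_RES).to_numpy()
            j = (lf["anchor2"] // LOOP_RES).to_numpy()
            lam[i, j] += lf["intensity"].to_numpy()
            lam[j, i] += lf["intensity"].to_numpy()
        counts = rng.poisson(np.triu(lam))
        r, c = np.nonzero(counts)
        rows_all.append(r + off)
        cols_all.append(c + off)
        data_all.append(counts[r, c])

    # trans background: uniform random inter-chromosomal pairs
    if cfg.trans_contacts > 0:
        rng = np.random.default_rng([cfg.seed % (2**31), 53, si])
        i = rng.integers(0, n_total, cfg.trans_contacts)
        j = rng.integers(0, n_total, cfg.trans_contacts)
        chrom_of = np.repeat(
            np.arange(len(offsets)), [n for (_, n) in offsets.values()]
        )
        keep = chrom_of[i] != chrom_of[j]
        i, j = i[keep], j[keep]
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        rows_all.append(lo)
        cols_all.append(hi)
        data_all.append(np.ones(len(lo), dtype=np.int64))

    mat = sp.coo_matrix(
        (
            np.concatenate(data_all).astype(float),
            (np.concatenate(rows_all), np.concatenate(cols_all)),
        ),
        shape=(n_total, n_total),
    )
    return BinnedMatrix(LOOP_RES, bins, mat, stage=stage)


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


def simulate_expression(
    genome: GenomeModel, truth: TruthSet, config: SimulationConfig
) -> pd.DataFrame:
    """Negative-binomial FPKM table: genes x 4 stages x replicates (tidy).

    Counts are drawn per replicate with mean proportional to the planted
    FPKM and converted back to FPKM against that replicate's library size;
    with ``nb_dispersion == 0`` counts equal their means (noise-free limit).
    Columns: gene_id, stage, replicate, fpkm.
    """
    cfg = config
    plan = truth.expression_plan.set_index("gene_id")
    rng = np.random.default_rng([cfg.seed % (2**31), 61])
    gene_ids = plan.index.to_numpy()
    len_kb = plan["length_kb"].to_numpy()
    depth = 5.0  # expected counts per FPKM unit per transcript kb
    rows = []
    for stage in STAGES:
        fpkm = plan[f"fpkm_{stage}"].to_numpy(float)
        mu = fpkm * len_kb * depth
        expected_total = max(mu.sum(), 1.0)
        for rep in range(cfg.n_replicates):
            if cfg.nb_dispersion == 0:
                counts = mu
            else:
                size = 1.0 / cfg.nb_dispersion
                p = size / (size + np.maximum(mu, 1e-9))
                counts = rng.negative_binomial(size, p).astype(float)
            # library size relative to the design total: observed FPKM is
            # anchored to the planted scale while replicate-level library
            # variation is preserved
            lib_rel = max(counts.sum(), 1.0) / expected_total
            obs = counts / (len_kb * lib_rel * depth)
            rows.append(
                pd.DataFrame(
                    {
                        "gene_id": gene_ids,
                        "stage": stage,
                        "replicate": rep + 1,
                        "fpkm": obs,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Dataset bundle + file output
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig, resolutions=(5_000,)):
    """Convenience: genome + truth + per-stage matrices + expression."""
    genome, truth = simulate_genome(config)
    matrices = {
        stage: simulate_hic(genome, truth, stage, config) for stage in STAGES
    }
    expression = simulate_expression(genome, truth, config)
    return genome, truth, matrices, expression


def planted_loopset(truth: TruthSet, stage: str) -> LoopSet:
    """Planted loops as a LoopSet (counts = expected intensity, fdr = 0)."""
    f = truth.loops[stage]
    frame = pd.DataFrame(
        {
            "chrom": f["chrom"],
            "anchor1": f["anchor1"],
            "anchor2": f["anchor2"],
            "contact_count": f["intensity"].astype(int),
            "p_value": 0.0,
            "fdr": 0.0,
            "stage": stage,
            "kind": f["kind"],
        }
    )
    return LoopSet(frame, LOOP_RES)


def write_truth(truth: TruthSet, outdir):
    """Emit truth tables as TSVs under ``outdir/truth``."""
    import os

    d = os.path.join(str(outdir), "truth")
    os.makedirs(d, exist_ok=True)
    for stage in STAGES:
        truth.compartments[stage].to_csv(
            os.path.join(d, f"compartments_{stage}.tsv"), sep="\t", index=False
        )
        truth.tads[stage].to_csv(
            os.path.join(d, f"tads_{stage}.tsv"), sep="\t", index=False
        )
        truth.loops[stage].to_csv(
            os.path.join(d, f"loops_{stage}.tsv"), sep="\t", index=False
        )
        truth.tad_homology[stage].to_csv(
            os.path.join(d, f"tad_homology_{stage}.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            [
                {"chrom": c["chrom"], "tad_ids": ",".join(c["tad_ids"])}
                for c in truth.cliques[stage]
            ]
        ).to_csv(os.path.join(d, f"cliques_{stage}.tsv"), sep="\t", index=False)
    truth.homoeolog_pairs.to_csv(
        os.path.join(d, "homoeolog_pairs.tsv"), sep="\t", index=False
    )
    truth.nongene_homology.to_csv(
        os.path.join(d, "nongene_homology.tsv"), sep="\t", index=False
    )
    truth.similarity.to_csv(os.path.join(d, "similarity.tsv"), sep="\t", index=False)
    truth.expression_plan.to_csv(
        os.path.join(d, "expression_plan.tsv"), sep="\t", index=False
    )
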