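"""Insulation-score TAD-like structure calling at 20 kb, boundary conservation
across stages, boundary/interior feature assignment, and inter-subgenome
homoeologous vs. partitioned classification.

The caller is an insulation-score stand-in (not bit-compatible with any
external tool): the insulation of bin i is the log2 ratio of the mean
balanced contact in the w x w square straddling the bin ((i-w..i-1) x
(i+1..i+w)) to the chromosome-wide mean of that quantity. Boundaries are
local insulation minima passing a prominence threshold; TAD-like structures
are the intervals between consecutive boundaries, at least 3 bins (60 kb)
each. External TAD interval files may be supplied to bypass the caller.

A boundary is conserved between two stages iff the other stage has a boundary
within +-40 kb (two bin widths, inclusive); a TAD is conserved between two
stages iff both of its boundaries are. Across the four stages a TAD is
thoroughly conserved if conserved with all three other stages, relatively
conserved with one or two, and stage-specific with none.

Homoeologous TAD pairs between subgenomes contain precisely the same
homoeologous gene pairs; inconsistent content is partitioned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

from .genome_io import STAGES, BinnedMatrix, GenomicIntervalSet

CONSERVATION_TOL = 40_000  # two 20-kb bins, inclusive
MIN_TAD_BINS = 3


@dataclass
class InsulationTrack:
    bins: pd.DataFrame  # chrom, start
    score: np.ndarray  # log2 vs chromosome mean; NaN where undefined
    window: int  # bins
    resolution: int

    def frame(self) -> pd.DataFrame:
        out = self.bins.copy()
        out["insulation"] = self.score
        return out


@dataclass
class TadSet:
    """Non-overlapping TAD-like intervals for one stage."""

    frame: pd.DataFrame  # chrom, start, end, tad_id
    resolution: int = 20_000
    stage: str | None = None

    def __post_init__(self):
        f = self.frame
        for chrom, grp in f.groupby("chrom"):
            s = grp.sort_values("start")
            if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping TADs on {chrom}")
        if ((f["end"] - f["start"]) < MIN_TAD_BINS * self.resolution).any():
            raise ValueError("TAD below the 3-bin (60 kb) minimum size")

    def __len__(self) -> int:
        return len(self.frame)

    def bin_counts(self) -> pd.Series:
        """Bin count B per TAD (the size term of the clique statistic)."""
        f = self.frame
        return pd.Series(
            ((f["end"] - f["start"]) // self.resolution).to_numpy(),
            index=f["tad_id"],
        )

    def boundaries(self, chrom: str | None = None) -> pd.DataFrame:
        """Internal boundary positions (bp) per chromosome."""
        rows = []
        for c, grp in self.frame.groupby("chrom"):
            if chrom is not None and c != chrom:
                continue
            s = grp.sort_values("start")
            for b in s["start"].to_numpy()[1:]:
                rows.append({"chrom": c, "pos": int(b)})
        return pd.DataFrame(rows, columns=["chrom", "pos"])


def insulation_score(matrix: BinnedMatrix, window: int = 5) -> InsulationTrack:
    """Crane-style sliding-square insulation on a balanced 20-kb matrix."""
    if matrix.weights is None:
        raise ValueError("matrix must be balanced first (ice_balance)")
    w = int(window)
    n = matrix.n_bins
    score = np.full(n, np.nan)
    for chrom in dict.fromkeys(matrix.bins["chrom"]):
        lo, hi = matrix.chrom_range(chrom)
        nb = hi - lo
        if w > nb // 2:
            raise ValueError(f"window {w} larger than half of {chrom} ({nb} bins)")
        dense = matrix.chrom_dense(chrom, balanced=True)
        raw = np.full(nb, np.nan)
        # cumulative 2D sums for O(1) square queries
        c2 = np.zeros((nb + 1, nb + 1))
        c2[1:, 1:] = dense.cumsum(0).cumsum(1)
        for i in range(w, nb - w):
            r0, r1 = i - w, i  # rows i-w .. i-1
            q0, q1 = i + 1, i + 1 + w  # cols i+1 .. i+w
            s = c2[r1, q1] - c2[r0, q1] - c2[r1, q0] + c2[r0, q0]
            raw[i] = s / (w * w)
        defined = ~np.isnan(raw)
        mean = raw[defined].mean() if defined.any() else np.nan
        if mean and mean > 0:
            with np.errstate(divide="ignore"):
                score[lo:hi][defined] = np.log2(raw[defined] / mean)
            score[lo:hi][raw == 0] = np.nan  # fully masked squares
    return InsulationTrack(
        bins=matrix.bins.copy(), score=score, window=w, resolution=matrix.resolution
    )


def call_tads(
    track: InsulationTrack,
    delta_window: int = 3,
    min_depth: float = 0.05,
    stage: str | None = None,
) -> TadSet:
    """TADs between insulation minima passing a prominence threshold.

    Within ``delta_window`` bins, the deeper minimum wins. Chromosomes with no
    internal boundary become a single structure (with a warning). Structures
    shorter than 3 bins are merged into the shallower neighbour side.
    """
    res = track.resolution
    rows = []
    for chrom in dict.fromkeys(track.bins["chrom"]):
        sel = (track.bins["chrom"] == chrom).to_numpy()
        s = track.score[sel]
        nb = len(s)
        filled = np.where(np.isnan(s), np.nanmax(s) if np.isfinite(np.nanmax(s)) else 0.0, s)
        minima, props = scipy.signal.find_peaks(
            -filled, prominence=min_depth, distance=max(1, delta_window)
        )
        bounds = sorted(int(b) for b in minima if not np.isnan(s[b]))
        if not bounds:
            warnings.warn(f"{chrom}: no boundary found; whole chromosome as one structure")
        # enforce minimum TAD size by dropping the shallower of close boundaries
        cleaned: list[int] = []
        for b in bounds:
            if cleaned and b - cleaned[-1] < MIN_TAD_BINS:
                if s[b] < s[cleaned[-1]]:
                    cleaned[-1] = b
            elif b < MIN_TAD_BINS or nb - b < MIN_TAD_BINS:
                continue
            else:
                cleaned.append(b)
        edges = [0] + cleaned + [nb]
        for k in range(len(edges) - 1):
            rows.append(
                {
                    "chrom": chrom,
                    "start": edges[k] * res,
                    "end": edges[k + 1] * res,
                    "tad_id": f"{chrom}.{k}",
                }
            )
    return TadSet(pd.DataFrame(rows), resolution=res, stage=stage)


def tadset_from_frame(frame: pd.DataFrame, resolution: int = 20_000, stage=None) -> TadSet:
    """Wrap externally supplied TAD intervals (e.g. planted truth or a BED)."""
    f = frame.copy()
    if "tad_id" not in f.columns:
        f["tad_id"] = [f"{c}.{k}" for k, c in enumerate(f["chrom"])]
    return TadSet(f[["chrom", "start", "end", "tad_id"]], resolution, stage)


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------


def conserved_boundaries(
    tads1: TadSet, tads2: TadSet, tol: int = CONSERVATION_TOL
) -> pd.DataFrame:
    """Flag each boundary of ``tads1`` as conserved iff ``tads2`` has a
    boundary within +-tol (inclusive) on the same chromosome."""
    if tads1.resolution != tads2.resolution:
        raise ValueError("TAD sets on different grids")
    b1 = tads1.boundaries()
    out_rows = []
    for chrom, grp in b1.groupby("chrom"):
        other = tads2.boundaries(chrom)["pos"].to_numpy()
        for pos in grp["pos"]:
            conserved = bool(len(other)) and bool(
                (np.abs(other - pos) <= tol).any()
            )
            out_rows.append({"chrom": chrom, "pos": pos, "conserved": conserved})
    return pd.DataFrame(out_rows, columns=["chrom", "pos", "conserved"])


def tad_conserved_between(
    tads1: TadSet, tads2: TadSet, tol: int = CONSERVATION_TOL
) -> pd.Series:
    """Per-TAD flag: conserved between the two stages iff both boundaries of
    the TAD lie within +-tol of a boundary (or chromosome edge) in the other
    stage."""
    flags = {}
    for chrom, grp in tads1.frame.groupby("chrom"):
        other = tads2.frame[tads2.frame["chrom"] == chrom]
        # chromosome edges count as boundaries on both sides
        pts = np.unique(
            np.concatenate([other["start"].to_numpy(), other["end"].to_numpy()])
        )
        for _, t in grp.iterrows():
            ok1 = (np.abs(pts - t["start"]) <= tol).any()
            ok2 = (np.abs(pts - t["end"]) <= tol).any()
            flags[t["tad_id"]] = bool(ok1 and ok2)
    return pd.Series(flags, name="conserved")


def tad_conservation(stage_sets: dict, tol: int = CONSERVATION_TOL) -> pd.DataFrame:
    """Conservation class per TAD per stage across the four stages.

    thoroughly_conserved = conserved with all other stages (pairwise rule);
    relatively_conserved = with 1-2 of them; stage_specific = with none.
    """
    rows = []
    for stage in STAGES:
        tads = stage_sets[stage]
        others = [s for s in STAGES if s != stage]
        per_other = {o: tad_conserved_between(tads, stage_sets[o], tol) for o in others}
        for tid in tads.frame["tad_id"]:
            n = sum(int(per_other[o].get(tid, False)) for o in others)
            cls = (
                "thoroughly_conserved"
                if n == len(others)
                else ("relatively_conserved" if n >= 1 else "stage_specific")
            )
            rows.append({"stage": stage, "tad_id": tid, "n_conserved_pairs": n, "class": cls})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Boundary/interior feature assignment
# ---------------------------------------------------------------------------


def boundary_interior_assignment(
    tads: TadSet, features: GenomicIntervalSet, boundary_halo: int = 1
) -> pd.DataFrame:
    """Label each feature 'boundary' or 'interior' by midpoint position.

    A feature is a boundary feature if its midpoint falls within a boundary
    bin +- ``boundary_halo`` bins; chromosome edges do not count as
    boundaries. Features outside any TAD chromosome keep label 'interior'.
    """
    res = tads.resolution
    f = features.frame
    mids = ((f["start"] + f["end"]) // 2).to_numpy()
    labels = np.full(len(f), "interior", dtype="U8")
    for chrom, grp in tads.frame.groupby("chrom"):
        bpos = tads.boundaries(chrom)["pos"].to_numpy()
        if not len(bpos):
            continue
        sel = (f["chrom"] == chrom).to_numpy()
        mb = mids[sel] // res
        hit = np.zeros(sel.sum(), dtype=bool)
        for b in bpos // res:
            hit |= np.abs(mb - b) <= boundary_halo
        lab = labels[sel]
        lab[hit] = "boundary"
        labels[sel] = lab
    out = f.copy()
    out["position"] = labels
    return out


def boundary_interior_test(values_boundary, values_interior) -> dict:
    """One-sided Mann-Whitney U: boundary values greater than interior."""
    u = scipy.stats.mannwhitneyu(
        values_boundary, values_interior, alternative="greater"
    )
    return {"statistic": float(u.statistic), "p_value": float(u.pvalue)}


# ---------------------------------------------------------------------------
# Inter-subgenome homology
# ---------------------------------------------------------------------------


@dataclass
class TadHomologyPair:
    at_tad: str
    dt_tads: tuple
    classification: str  # 'homoeologous' or 'partitioned'
    pair_ids: tuple = ()
    positions_at: dict = field(default_factory=dict)  # gene -> boundary/interior
    positions_dt: dict = field(default_factory=dict)


def classify_tad_homology(
    tads_at: TadSet,
    tads_dt: TadSet,
    homoeolog_pairs: pd.DataFrame,
    genes: GenomicIntervalSet,
    boundary_halo: int = 1,
) -> list[TadHomologyPair]:
    """Classify inter-subgenome TAD correspondence by homoeolog content.

    For each At TAD with homoeologous genes, the set of contained pair ids is
    compared with the Dt TADs containing the partner genes: an exact non-empty
    set match with a single Dt TAD is homoeologous; any other arrangement is
    partitioned. TADs without homoeologous genes are not classified.
    """
    gf = genes.frame.set_index("gene_id")
    mids = (gf["start"] + gf["end"]) // 2

    def tad_of(gene_id, tset: TadSet):
        if gene_id not in gf.index:
            return None
        chrom = gf.loc[gene_id, "chrom"]
        m = mids.loc[gene_id]
        hit = tset.frame[
            (tset.frame["chrom"] == chrom)
            & (tset.frame["start"] <= m)
            & (tset.frame["end"] > m)
        ]
        return hit.iloc[0]["tad_id"] if len(hit) else None

    at_of_pair = {}
    dt_of_pair = {}
    for _, p in homoeolog_pairs.iterrows():
        at_of_pair[p["pair_id"]] = tad_of(p["at_gene"], tads_at)
        dt_of_pair[p["pair_id"]] = tad_of(p["dt_gene"], tads_dt)
    sets_at: dict[str, set] = {}
    sets_dt: dict[str, set] = {}
    for pid in at_of_pair:
        if at_of_pair[pid] is not None:
            sets_at.setdefault(at_of_pair[pid], set()).add(pid)
        if dt_of_pair[pid] is not None:
            sets_dt.setdefault(dt_of_pair[pid], set()).add(pid)

    pos_at = _position_lookup(tads_at, genes, boundary_halo)
    pos_dt = _position_lookup(tads_dt, genes, boundary_halo)
    gene_of_pair_at = dict(zip(homoeolog_pairs["pair_id"], homoeolog_pairs["at_gene"]))
    gene_of_pair_dt = dict(zip(homoeolog_pairs["pair_id"], homoeolog_pairs["dt_gene"]))

    out = []
    for at_tad, pset in sets_at.items():
        partners = sorted({dt_of_pair[pid] for pid in pset if dt_of_pair[pid]})
        if not partners:
            continue
        exact = len(partners) == 1 and sets_dt.get(partners[0], set()) == pset
        cls = "homoeologous" if exact else "partitioned"
        out.append(
            TadHomologyPair(
                at_tad=at_tad,
                dt_tads=tuple(partners),
                classification=cls,
                pair_ids=tuple(sorted(pset)),
                positions_at={
                    pid: pos_at.get(gene_of_pair_at[pid], "interior") for pid in pset
                },
                positions_dt={
                    pid: pos_dt.get(gene_of_pair_dt[pid], "interior") for pid in pset
                },
            )
        )
    return out


def _position_lookup(tads: TadSet, genes: GenomicIntervalSet, halo: int) -> dict:
    assigned = boundary_interior_assignment(tads, genes, halo)
    if "gene_id" not in assigned.columns:
        return {}
    return dict(zip(assigned["gene_id"], assigned["position"]))


def positional_shift_bias(
    homology: list[TadHomologyPair], bias_calls: pd.DataFrame, n_permutations: int = 200, seed: int = 0
) -> dict:
    """2x2 association between positional shift (boundary<->interior between
    subgenomes) and expression bias, with odds ratio, chi-squared against a
    permutation baseline, and continuity correction for zero cells.

    ``bias_calls`` needs columns pair_id and bias ('At'/'Dt'/'none').
    """
    bias_of = dict(zip(bias_calls["pair_id"], bias_calls["bias"]))
    shifted, biased = [], []
    for h in homology:
        for pid in h.pair_ids:
            s = h.positions_at.get(pid) != h.positions_dt.get(pid)
            b = bias_of.get(pid, "none") != "none"
            shifted.append(s)
            biased.append(b)
    shifted = np.asarray(shifted)
    biased = np.asarray(biased)
    a = int((shifted & biased).sum())
    b_ = int((shifted & ~biased).sum())
    c = int((~shifted & biased).sum())
    d = int((~shifted & ~biased).sum())
    flagged = 0 in (a, b_, c, d)
    if flagged:
        odds = ((a + 0.5) * (d + 0.5)) / ((b_ + 0.5) * (c + 0.5))
        if b_ == 0 and c == 0 and a > 0 and d > 0:
            odds = np.inf
    else:
        odds = (a * d) / (b_ * c)
    chi2 = scipy.stats.chi2_contingency([[a, b_], [c, d]], correction=True)[0] if len(shifted) else np.nan
    # permutation baseline: shuffle bias over pairs
    rng = np.random.default_rng(seed)
    null = []
    for _ in range(n_permutations):
        perm = rng.permutation(biased)
        aa = int((shifted & perm).sum())
        bb = int((shifted & ~perm).sum())
        cc = int((~shifted & perm).sum())
        dd = int((~shifted & ~perm).sum())
        null.append(((aa + 0.5) * (dd + 0.5)) / ((bb + 0.5) * (cc + 0.5)))
    null = np.array(null)
    p_perm = float((null >= (odds if np.isfinite(odds) else null.max() + 1)).mean())
    return {
        "table": ((a, b_), (c, d)),
        "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
        "chi2": float(chi2),
        "p_permutation": p_perm,
        "continuity_corrected": flagged,
    }
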