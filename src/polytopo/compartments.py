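"""A/B compartment calling at 40 kb, switch-region detection, four-stage
trajectory classification and gene/peak overlays.

The caller follows the de-facto standard eigenvector route: per chromosome,
the balanced cis matrix is distance-normalized (observed/expected), turned
into a Pearson correlation map, and the leading eigenvector is taken as PC1.
The sign is oriented per chromosome so that the positive (A) side has the
higher mean gene density; PC1 > 0 is A, PC1 < 0 is B, exactly 0 falls to B
(conservative inactive call).

Trajectory categories over the four stages (0/5/10/20 DPA) partition all 16
four-letter strings: AAAA -> stable_A; BBBB -> stable_B; A...B -> AB;
B...A -> BA; A...A with at least one B -> ABA; B...B with at least one
A -> BAB. Switch regions between two stages are maximal runs of at least two
consecutive bins changing label, per the calling rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import STAGES, BinnedMatrix, GenomicIntervalSet, interval_bins

TRAJECTORY_CATEGORIES = ("stable_A", "stable_B", "AB", "BA", "ABA", "BAB")


@dataclass
class CompartmentTrack:
    """Per-bin PC1 score and A/B/masked label at one stage."""

    bins: pd.DataFrame  # chrom, start
    pc1: np.ndarray
    label: np.ndarray  # 'A', 'B' or '' (masked)
    resolution: int
    stage: str | None = None

    def frame(self) -> pd.DataFrame:
        out = self.bins.copy()
        out["pc1"] = self.pc1
        out["label"] = self.label
        return out


@dataclass
class SwitchRegion:
    chrom: str
    start: int
    end: int
    direction: str  # 'AtoB' or 'BtoA'
    n_bins: int
    gene_ids: tuple = ()


def call_compartments(
    matrix: BinnedMatrix,
    gene_density: np.ndarray,
    min_bins: int = 10,
) -> CompartmentTrack:
    """Call A/B compartments from a balanced 40-kb matrix.

    ``gene_density`` gives per-bin gene counts used to orient each
    chromosome's eigenvector (A = positive = gene dense). Masked bins (NaN
    weight) propagate; chromosomes with fewer than ``min_bins`` unmasked bins
    are masked entirely with a warning.
    """
    if matrix.weights is None:
        raise ValueError("matrix must be balanced first (ice_balance)")
    n = matrix.n_bins
    pc1 = np.full(n, np.nan)
    label = np.full(n, "", dtype="U1")
    gene_density = np.asarray(gene_density, dtype=float)
    if len(gene_density) != n:
        raise ValueError("gene_density length does not match bin count")
    for chrom in dict.fromkeys(matrix.bins["chrom"]):
        lo, hi = matrix.chrom_range(chrom)
        dense = matrix.chrom_dense(chrom, balanced=True)
        w = matrix.chrom_weights(chrom)
        ok = ~np.isnan(w)
        if ok.sum() < min_bins:
            warnings.warn(f"{chrom}: fewer than {min_bins} unmasked bins; masked")
            continue
        sub = dense[np.ix_(ok, ok)]
        oe = _observed_over_expected(sub)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(oe)
        corr[~np.isfinite(corr)] = 0.0
        vals, vecs = np.linalg.eigh(corr)
        v = vecs[:, -1]  # leading eigenvector
        dens = gene_density[lo:hi][ok]
        pos_dens = dens[v > 0].mean() if (v > 0).any() else -np.inf
        neg_dens = dens[v < 0].mean() if (v < 0).any() else -np.inf
        if neg_dens > pos_dens:
            v = -v
        full_v = np.full(hi - lo, np.nan)
        full_v[ok] = v
        pc1[lo:hi] = full_v
        lab = np.where(full_v > 0, "A", "B")
        lab[np.isnan(full_v)] = ""
        label[lo:hi] = lab
    return CompartmentTrack(
        bins=matrix.bins.copy(),
        pc1=pc1,
        label=label,
        resolution=matrix.resolution,
        stage=matrix.stage,
    )


def _observed_over_expected(dense: np.ndarray) -> np.ndarray:
    """Divide each diagonal by its mean (distance normalization)."""
    n = dense.shape[0]
    out = np.zeros_like(dense, dtype=float)
    for d in range(n):
        diag = np.diagonal(dense, d)
        m = diag.mean()
        vals = diag / m if m > 0 else 0.0
        idx = np.arange(n - d)
        out[idx, idx + d] = vals
        out[idx + d, idx] = vals
    return out


def pairwise_switch_regions(
    track1: CompartmentTrack,
    track2: CompartmentTrack,
    min_bins: int = 2,
    genes: GenomicIntervalSet | None = None,
) -> list[SwitchRegion]:
    """Maximal runs of >= min_bins bins switching label between two stages.

    Runs of A->B are reported as direction 'AtoB' and B->A as 'BtoA'; single
    switched bins are never emitted (the caller's minimum unit is two bins).
    """
    if not track1.bins.equals(track2.bins):
        raise ValueError("tracks are on different bin grids")
    res = track1.resolution
    states = np.full(len(track1.label), "", dtype="U4")
    ok = (track1.label != "") & (track2.label != "")
    states[ok & (track1.label == "A") & (track2.label == "B")] = "AtoB"
    states[ok & (track1.label == "B") & (track2.label == "A")] = "BtoA"
    regions = []
    chroms = track1.bins["chrom"].to_numpy()
    starts = track1.bins["start"].to_numpy()
    i = 0
    n = len(states)
    while i < n:
        if states[i] == "":
            i += 1
            continue
        j = i
        while j + 1 < n and states[j + 1] == states[i] and chroms[j + 1] == chroms[i]:
            j += 1
        run = j - i + 1
        if run >= min_bins:
            region = SwitchRegion(
                chrom=str(chroms[i]),
                start=int(starts[i]),
                end=int(starts[j]) + res,
                direction=str(states[i]),
                n_bins=run,
            )
            if genes is not None:
                f = genes.frame
                mids = (f["start"] + f["end"]) // 2
                inside = (
                    (f["chrom"] == region.chrom)
                    & (mids >= region.start)
                    & (mids < region.end)
                )
                if "gene_id" in f.columns:
                    region.gene_ids = tuple(f.loc[inside, "gene_id"])
            regions.append(region)
        i = j + 1
    return regions


def switch_size_summary(regions: list[SwitchRegion]) -> dict:
    """Total switched size in bp per direction."""
    out = {"AtoB": 0, "BtoA": 0}
    for r in regions:
        out[r.direction] += r.end - r.start
    return out


def classify_trajectory(trajectory: str) -> str:
    """Classify a four-letter A/B string into its trajectory category.

    stable_A/stable_B for constant strings; AB/BA by differing endpoints;
    ABA/BAB for excursions returning to the starting label.
    """
    if len(trajectory) != 4 or any(c not in "AB" for c in trajectory):
        raise ValueError(f"trajectory must be 4 letters over {{A,B}}: {trajectory!r}")
    first, last = trajectory[0], trajectory[-1]
    if trajectory == "AAAA":
        return "stable_A"
    if trajectory == "BBBB":
        return "stable_B"
    if first == "A" and last == "B":
        return "AB"
    if first == "B" and last == "A":
        return "BA"
    return "ABA" if first == "A" else "BAB"


def trajectories(tracks: dict) -> pd.DataFrame:
    """Per-bin four-stage trajectory strings and categories.

    ``tracks`` maps stage -> CompartmentTrack on a common grid. Bins masked at
    any stage are excluded (and counted in the ``n_excluded`` attribute).
    """
    stage_tracks = [tracks[s] for s in STAGES]
    base = stage_tracks[0].bins
    for t in stage_tracks[1:]:
        if not t.bins.equals(base):
            raise ValueError("tracks are on different bin grids")
    labels = np.stack([t.label for t in stage_tracks], axis=1)
    ok = (labels != "").all(axis=1)
    strings = np.array(["".join(row) for row in labels[ok]])
    cats = np.array([classify_trajectory(s) for s in strings]) if len(strings) else np.array([])
    out = base[ok].copy()
    out["trajectory"] = strings
    out["category"] = cats
    out.attrs["n_excluded"] = int((~ok).sum())
    return out.reset_index(drop=True)


def overlay(
    track: CompartmentTrack,
    genes: GenomicIntervalSet | None = None,
    peaks: dict | None = None,
    expression: pd.DataFrame | None = None,
    matrix: BinnedMatrix | None = None,
    overlap_rule: str = "midpoint",
) -> dict:
    """Per-label gene lists, mean expression and mark coverage fractions.

    A bin is "marked" by a peak set if any peak midpoint falls inside it
    (``overlap_rule='midpoint'``) or if any peak overlaps it by >= 1 bp
    (``overlap_rule='overlap'``). ``peaks`` maps mark name -> interval set.
    Expression (tidy gene_id/fpkm) is averaged over the genes of each label.
    """
    res = track.resolution
    out: dict = {"genes": {}, "mean_expression": {}, "marked_fraction": {}}
    starts = track.bins["start"].to_numpy()
    chroms = track.bins["chrom"].to_numpy()
    key = pd.MultiIndex.from_arrays([chroms, starts // res])
    bin_lookup = pd.Series(np.arange(len(starts)), index=key)
    gene_label: dict[str, str] = {}
    if genes is not None and len(genes):
        f = genes.frame
        mids = ((f["start"] + f["end"]) // 2) // res
        gidx = pd.MultiIndex.from_arrays([f["chrom"], mids])
        located = bin_lookup.reindex(gidx)
        for lab in ("A", "B"):
            sel = located.notna().to_numpy() & (
                track.label[located.fillna(0).astype(int)] == lab
            )
            ids = list(f.loc[sel.tolist(), "gene_id"]) if "gene_id" in f.columns else []
            out["genes"][lab] = ids
            for g in ids:
                gene_label[g] = lab
    else:
        out["genes"] = {"A": [], "B": []}
    if expression is not None and gene_label:
        e = expression.copy()
        e["lab"] = e["gene_id"].map(gene_label)
        means = e.dropna(subset=["lab"]).groupby("lab")["fpkm"].mean()
        out["mean_expression"] = means.to_dict()
    if peaks:
        for mark, pset in peaks.items():
            f = pset.frame
            if overlap_rule == "midpoint":
                mids = ((f["start"] + f["end"]) // 2) // res
                pidx = pd.MultiIndex.from_arrays([f["chrom"], mids])
                hits = bin_lookup.reindex(pidx).dropna().astype(int).unique()
            elif overlap_rule == "overlap":
                hit_set = set()
                for _, r in f.iterrows():
                    for b in range(r["start"] // res, (r["end"] - 1) // res + 1):
                        loc = bin_lookup.get((r["chrom"], b))
                        if loc is not None and not (
                            isinstance(loc, float) and np.isnan(loc)
                        ):
                            hit_set.add(int(loc))
                hits = np.array(sorted(hit_set), dtype=int)
            else:
                raise ValueError(f"unknown overlap rule {overlap_rule!r}")
            marked = np.zeros(len(starts), dtype=bool)
            marked[hits] = True
            fracs = {}
            for lab in ("A", "B"):
                sel = track.label == lab
                fracs[lab] = float(marked[sel].mean()) if sel.any() else np.nan
            out["marked_fraction"][mark] = fracs
    return out


def gene_density(matrix: BinnedMatrix, genes: GenomicIntervalSet) -> np.ndarray:
    """Per-bin gene counts (midpoint assignment) on the matrix's grid."""
    dens = np.zeros(matrix.n_bins)
    if genes is None or not len(genes):
        return dens
    ids = interval_bins(matrix, genes)
    np.add.at(dens, ids, 1.0)
    return dens
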