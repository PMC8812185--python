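"""TAD-clique detection from loop-mediated inter-TAD interactions.

Two TAD-like structures on the same chromosome interact when enough
qualifying loops (contact count > 5 and FDR < 0.1, strict) connect them; the
interaction strength is size-normalized. The default density form
``S = L / (B1 * B2)`` (loops per TAD bin-pair) removes the effect of
structure size: uniformly rescaling both structures while preserving loop
density leaves S unchanged, and larger S means stronger coupling, so the
S > 0.09 cutoff discards weak edges. The reciprocal form ``S = (B1*B2)/L``
is available as ``formula='as_printed'``.

A TAD clique is a fully connected set of >= 3 structures in the resulting
graph; each structure's k is the size of the largest maximal clique
containing it (k < 3 means non-clique). Between stages, structures are
classified as formation (non-clique -> clique), loss (clique -> non-clique),
expansion (3 <= k <= 5 -> k > 5), reduction (k > 5 -> 3 <= k <= 5), stable
or other.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .domains import TadSet
from .genome_io import LoopSet

CLIQUE_LOOP_MIN_COUNT = 5  # strict >
CLIQUE_LOOP_MAX_FDR = 0.1  # strict <
S_THRESHOLD = 0.09  # strict >
MIN_CLIQUE_K = 3

SIZE_CLASSES = ("non-clique", "3<=k<=5", "k>5")


def filter_clique_loops(loops: LoopSet) -> LoopSet:
    """Loops qualifying for inter-TAD interaction: count > 5 and FDR < 0.1."""
    f = loops.frame
    for col in ("contact_count", "fdr"):
        if col not in f.columns or f[col].isna().any():
            raise ValueError(f"loops missing {col}")
    keep = (f["contact_count"] > CLIQUE_LOOP_MIN_COUNT) & (f["fdr"] < CLIQUE_LOOP_MAX_FDR)
    return loops.subset(keep.to_numpy())


def interaction_strength(b1: int, b2: int, L: int, formula: str = "density") -> float:
    """Size-normalized interaction strength between two structures.

    density: S = L / (B1*B2); as_printed: S = (B1*B2) / L (undefined at L=0,
    returns NaN so the edge is omitted).
    """
    if b1 < 3 or b2 < 3:
        raise ValueError("TAD bin counts must be >= 3")
    if L < 0:
        raise ValueError("loop count must be >= 0")
    if formula == "density":
        return L / (b1 * b2)
    if formula == "as_printed":
        return (b1 * b2) / L if L > 0 else float("nan")
    raise ValueError(f"unknown formula {formula!r}")


def assign_loops_to_tad_pairs(tads: TadSet, loops: LoopSet) -> pd.DataFrame:
    """Count qualifying loops per (distinct) same-chromosome TAD pair.

    A loop joins the pair of TADs containing its two anchor-bin midpoints; an
    anchor in no TAD, or both anchors in the same TAD, contributes nothing.
    Returns tad_i, tad_j, L with tad_i < tad_j in genome order.
    """
    f = loops.frame
    res = loops.resolution
    rows = []
    for chrom, grp in f.groupby("chrom"):
        tf = tads.frame[tads.frame["chrom"] == chrom].sort_values("start")
        if not len(tf):
            continue
        starts = tf["start"].to_numpy()
        ends = tf["end"].to_numpy()
        ids = tf["tad_id"].to_numpy()

        def locate(pos):
            # midpoint of the anchor bin; tie at a shared boundary -> upstream
            mid = pos + res // 2
            k = np.searchsorted(starts, mid, side="right") - 1
            if k >= 0 and mid < ends[k]:
                return ids[k]
            return None

        for a1, a2 in zip(grp["anchor1"], grp["anchor2"]):
            t1, t2 = locate(a1), locate(a2)
            if t1 is None or t2 is None or t1 == t2:
                continue
            rows.append((chrom, *sorted((t1, t2), key=lambda t: int(t.split(".")[-1]))))
    if not rows:
        return pd.DataFrame(columns=["chrom", "tad_i", "tad_j", "L"])
    df = pd.DataFrame(rows, columns=["chrom", "tad_i", "tad_j"])
    return (
        df.groupby(["chrom", "tad_i", "tad_j"]).size().rename("L").reset_index()
    )


def build_clique_graph(
    tads: TadSet,
    loops: LoopSet,
    threshold: float = S_THRESHOLD,
    formula: str = "density",
) -> nx.Graph:
    """Graph over TADs with edges where S > threshold (strict).

    ``loops`` should already be filtered with :func:`filter_clique_loops`.
    Edge attributes: L, B1, B2, S.
    """
    pair_counts = assign_loops_to_tad_pairs(tads, loops)
    bins = tads.bin_counts()
    g = nx.Graph()
    g.add_nodes_from(tads.frame["tad_id"])
    for _, r in pair_counts.iterrows():
        b1, b2 = int(bins[r["tad_i"]]), int(bins[r["tad_j"]])
        s = interaction_strength(b1, b2, int(r["L"]), formula)
        if np.isnan(s):
            continue
        if s > threshold:
            g.add_edge(r["tad_i"], r["tad_j"], L=int(r["L"]), B1=b1, B2=b2, S=s)
    return g


@dataclass
class CliqueAssignment:
    """Per-TAD clique size k, memberships, size class and compartment context."""

    frame: pd.DataFrame  # tad_id, k, size_class, context
    cliques: list  # list of tuples of tad_ids (maximal cliques, size >= 3)
    stage: str | None = None

    def k_of(self, tad_id) -> int:
        row = self.frame[self.frame["tad_id"] == tad_id]
        return int(row.iloc[0]["k"]) if len(row) else 0


def size_class(k: int) -> str:
    if k < MIN_CLIQUE_K:
        return "non-clique"
    return "3<=k<=5" if k <= 5 else "k>5"


def enumerate_cliques(
    graph: nx.Graph,
    tads: TadSet | None = None,
    compartment_labels: dict | None = None,
    stage: str | None = None,
) -> CliqueAssignment:
    """Maximal cliques (Bron-Kerbosch via networkx) and per-TAD k.

    k is the maximum size over maximal cliques containing the TAD; k < 3
    means non-clique. ``compartment_labels`` maps tad_id -> 'A'/'B' (majority
    label of constituent bins) for the active/inactive context.
    """
    k = {n: 1 for n in graph.nodes}
    cliques = []
    for cl in nx.find_cliques(graph):
        for n in cl:
            k[n] = max(k[n], len(cl))
        if len(cl) >= MIN_CLIQUE_K:
            cliques.append(tuple(sorted(cl)))
    rows = []
    for n in graph.nodes:
        rows.append(
            {
                "tad_id": n,
                "k": k[n] if k[n] >= MIN_CLIQUE_K else 0,
                "size_class": size_class(k[n]),
                "context": (compartment_labels or {}).get(n, ""),
            }
        )
    return CliqueAssignment(frame=pd.DataFrame(rows), cliques=sorted(cliques), stage=stage)


def tad_compartment_context(tads: TadSet, comp_track) -> dict:
    """Majority A/B label over the 40-kb bins each TAD covers."""
    labels = comp_track.label
    starts = comp_track.bins["start"].to_numpy()
    chroms = comp_track.bins["chrom"].to_numpy()
    res = comp_track.resolution
    out = {}
    for _, t in tads.frame.iterrows():
        sel = (
            (chroms == t["chrom"]) & (starts >= t["start"] // res * res) & (starts < t["end"])
        )
        lab = labels[sel]
        n_a = (lab == "A").sum()
        n_b = (lab == "B").sum()
        out[t["tad_id"]] = "A" if n_a >= n_b else "B"
    return out


def clique_coverage(assignment: CliqueAssignment, tads: TadSet, genome_size: int) -> float:
    """Fraction of the genome covered by clique-member structures."""
    member = set(assignment.frame[assignment.frame["k"] >= MIN_CLIQUE_K]["tad_id"])
    f = tads.frame
    covered = (f[f["tad_id"].isin(member)]["end"] - f[f["tad_id"].isin(member)]["start"]).sum()
    return float(covered) / float(genome_size)


DYNAMICS_CATEGORIES = ("formation", "loss", "expansion", "reduction", "stable", "other")


def classify_transition(k1: int, k2: int) -> str:
    """Between-stage clique dynamics category for one structure."""
    c1, c2 = size_class(k1), size_class(k2)
    if c1 == "non-clique" and c2 != "non-clique":
        return "formation"
    if c1 != "non-clique" and c2 == "non-clique":
        return "loss"
    if c1 == "3<=k<=5" and c2 == "k>5":
        return "expansion"
    if c1 == "k>5" and c2 == "3<=k<=5":
        return "reduction"
    if c1 == c2:
        return "stable"
    return "other"


def clique_dynamics(
    assignment1: CliqueAssignment,
    assignment2: CliqueAssignment,
    tad_match: dict | None = None,
) -> pd.DataFrame:
    """Per-structure dynamics between two stages plus transition counts.

    ``tad_match`` maps stage-1 tad_id -> stage-2 tad_id for conserved
    structures (identity mapping by default); unmatched structures are
    excluded and counted in the ``n_unmatched`` attribute. Aggregate counts by
    stage-1 compartment context live in the ``by_context`` attribute.
    """
    f1 = assignment1.frame.set_index("tad_id")
    f2 = assignment2.frame.set_index("tad_id")
    if tad_match is None:
        tad_match = {t: t for t in f1.index if t in f2.index}
    rows = []
    unmatched = 0
    for t1 in f1.index:
        t2 = tad_match.get(t1)
        if t2 is None or t2 not in f2.index:
            unmatched += 1
            continue
        k1, k2 = int(f1.loc[t1, "k"]), int(f2.loc[t2, "k"])
        rows.append(
            {
                "tad_id": t1,
                "k1": k1,
                "k2": k2,
                "category": classify_transition(k1, k2),
                "context": f1.loc[t1, "context"],
            }
        )
    out = pd.DataFrame(rows, columns=["tad_id", "k1", "k2", "category", "context"])
    out.attrs["n_unmatched"] = unmatched
    out.attrs["by_context"] = (
        out.groupby(["context", "category"]).size().rename("n").reset_index()
        if len(out)
        else pd.DataFrame(columns=["context", "category", "n"])
    )
    return out


def clique_expression_coupling(
    assignment: CliqueAssignment,
    tads: TadSet,
    genes,
    expression: pd.DataFrame,
    stage: str | None = None,
) -> dict:
    """Expression summaries per clique size class plus a trend test.

    Genes are assigned to TADs by midpoint; their expression (mean FPKM over
    replicates, optionally one stage) is grouped by the TAD's size class.
    The trend statistic is Spearman's rho between ordinal class (0, 1, 2) and
    gene expression; empty classes are simply absent from the summary.
    """
    e = expression
    if stage is not None:
        e = e[e["stage"] == stage]
    mean_fpkm = e.groupby("gene_id")["fpkm"].mean()
    gf = genes.frame
    mids = (gf["start"] + gf["end"]) // 2
    klass = assignment.frame.set_index("tad_id")["size_class"]
    rows = []
    for chrom, grp in gf.groupby("chrom"):
        tf = tads.frame[tads.frame["chrom"] == chrom]
        starts = tf["start"].to_numpy()
        ends = tf["end"].to_numpy()
        ids = tf["tad_id"].to_numpy()
        gm = mids[grp.index].to_numpy()
        pos = np.searchsorted(starts, gm, side="right") - 1
        for row_i, (gi, p) in enumerate(zip(grp.index, pos)):
            if p < 0 or gm[row_i] >= ends[p]:
                continue
            gid = grp.loc[gi, "gene_id"]
            if gid not in mean_fpkm.index:
                continue
            sc = klass.get(ids[p])
            if sc is None:
                continue
            rows.append({"gene_id": gid, "size_class": sc, "fpkm": mean_fpkm[gid]})
    df = pd.DataFrame(rows, columns=["gene_id", "size_class", "fpkm"])
    summary = (
        df.groupby("size_class")["fpkm"].agg(["mean", "median", "count"]).reset_index()
    )
    ordinal = df["size_class"].map({c: i for i, c in enumerate(SIZE_CLASSES)})
    if df["size_class"].nunique() >= 2 and len(df) >= 3:
        rho, p = scipy.stats.spearmanr(ordinal, df["fpkm"])
    else:
        rho, p = np.nan, np.nan
    return {"per_gene": df, "summary": summary, "rho": float(rho) if rho == rho else np.nan, "p_value": float(p) if p == p else np.nan}
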