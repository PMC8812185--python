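"""Homoeolog pairing via collinear blocks plus reciprocal best hits,
expression-based classifications, and HG-HG networks with divergence.

Syntenic blocks are maximal collinear chains of significant similarity hits:
hits between one chromosome pair are chained by longest-increasing-subsequence
dynamic programming on gene ranks (both orientations, so whole-block
inversions form antiparallel blocks), with a rank-gap cap; a block needs at
least five chained genes. A homoeolog pair keeps genes that are each other's
best hit and whose hit lies inside a block — one-to-one by construction.

Expression semantics as printed in the emulated study: a gene is expressed
iff FPKM > 1 in all three replicates; differential expression between
adjacent stages uses |log2 FC| > 1 and FDR < 0.01 (strict; a Welch t-test on
log2(FPKM + eps) replaces the negative-binomial model, and external DE
tables can be ingested verbatim); subgenome bias at a stage uses FC >= 2 and
FDR <= 0.05 (inclusive). Bias trajectories over the four stages: conserved_At
(At-biased at all four), conserved_Dt, dynamic (biased somewhere but not
everywhere in one direction), none.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .genome_io import STAGES

MIN_BLOCK_GENES = 5
DE_MIN_LOG2FC = 1.0  # strict >
DE_MAX_FDR = 0.01  # strict <
BIAS_MIN_FC = 2.0  # inclusive >=
BIAS_MAX_FDR = 0.05  # inclusive <=
EXPRESSED_MIN_FPKM = 1.0  # strict >, in all replicates
FC_PSEUDOCOUNT = 0.01


# ---------------------------------------------------------------------------
# Synteny + pairing
# ---------------------------------------------------------------------------


def gene_ranks(genes) -> pd.DataFrame:
    """Per-chromosome integer rank of each gene by start position."""
    f = genes.frame.sort_values(["chrom", "start"]).reset_index(drop=True)
    f["rank"] = f.groupby("chrom").cumcount()
    return f[["gene_id", "chrom", "rank"]]


def find_syntenic_blocks(
    genes,
    similarity: pd.DataFrame,
    min_genes: int = MIN_BLOCK_GENES,
    max_gap: int = 10,
) -> pd.DataFrame:
    """Collinear blocks from a directed similarity table.

    Hits are chained per (query chromosome, subject chromosome) by longest
    monotone chains on subject rank (strictly increasing or strictly
    decreasing, so inverted blocks are found) with query- and subject-rank
    gaps capped at ``max_gap``. Chains are extracted greedily by score
    (chain length), removed, and re-chained until none of length >=
    ``min_genes`` remains. Returns one row per chained hit with a block_id.
    """
    ranks = gene_ranks(genes).set_index("gene_id")
    sim = similarity[similarity["query"] != similarity["subject"]].copy()
    sim = sim[(sim["query"].isin(ranks.index)) & (sim["subject"].isin(ranks.index))]
    sim["qchrom"] = ranks.loc[sim["query"], "chrom"].to_numpy()
    sim["schrom"] = ranks.loc[sim["subject"], "chrom"].to_numpy()
    sim["qrank"] = ranks.loc[sim["query"], "rank"].to_numpy()
    sim["srank"] = ranks.loc[sim["subject"], "rank"].to_numpy()
    # undirected hit identity: chain each unordered gene pair once
    key = [tuple(sorted(t)) for t in zip(sim["query"], sim["subject"])]
    sim["pair_key"] = key
    sim = sim.sort_values("score", ascending=False).drop_duplicates("pair_key")

    out_rows = []
    block_counter = 0
    for (qc, sc), grp in sim.groupby(["qchrom", "schrom"]):
        hits = grp.sort_values(["qrank", "srank"]).reset_index(drop=True)
        active = np.ones(len(hits), dtype=bool)
        while True:
            chain = _best_chain(hits, active, max_gap)
            if len(chain) < min_genes:
                break
            block_counter += 1
            for idx in chain:
                out_rows.append(
                    {
                        "query": hits.loc[idx, "query"],
                        "subject": hits.loc[idx, "subject"],
                        "block_id": f"b{block_counter:04d}",
                        "qchrom": qc,
                        "schrom": sc,
                    }
                )
                active[idx] = False
    return pd.DataFrame(out_rows, columns=["query", "subject", "block_id", "qchrom", "schrom"])


def _best_chain(hits: pd.DataFrame, active: np.ndarray, max_gap: int) -> list:
    """Longest monotone chain (either orientation) over the active hits."""
    idx = np.where(active)[0]
    if not len(idx):
        return []
    q = hits.loc[idx, "qrank"].to_numpy()
    s = hits.loc[idx, "srank"].to_numpy()
    best: list = []
    for sign in (1, -1):
        n = len(idx)
        length = np.ones(n, dtype=int)
        prev = np.full(n, -1)
        for i in range(n):
            for j in range(i):
                if (
                    q[i] > q[j]
                    and q[i] - q[j] <= max_gap
                    and sign * (s[i] - s[j]) > 0
                    and abs(s[i] - s[j]) <= max_gap
                    and length[j] + 1 > length[i]
                ):
                    length[i] = length[j] + 1
                    prev[i] = j
        k = int(np.argmax(length))
        chain = []
        while k >= 0:
            chain.append(idx[k])
            k = prev[k]
        chain.reverse()
        if len(chain) > len(best):
            best = chain
    return best


def reciprocal_best_pairs(
    similarity: pd.DataFrame, blocks: pd.DataFrame
) -> pd.DataFrame:
    """One-to-one homoeolog pairs: mutual best hits inside syntenic blocks.

    Ties on score break by lower significance value, then lexicographic
    subject id. Returns pair_id, at_gene, dt_gene, block_id (gene naming is
    caller-side; columns are query/subject oriented At -> Dt when ids allow,
    otherwise kept as given).
    """
    sim = similarity[similarity["query"] != similarity["subject"]].copy()
    sim = sim.sort_values(
        ["query", "score", "evalue", "subject"],
        ascending=[True, False, True, True],
    )
    best = sim.drop_duplicates("query").set_index("query")["subject"]
    in_block = {
        tuple(sorted(t)): b
        for t, b in zip(zip(blocks["query"], blocks["subject"]), blocks["block_id"])
    }
    pairs = []
    used = set()
    for q, s in best.items():
        if q in used or s in used:
            continue
        if best.get(s) != q:
            continue
        key = tuple(sorted((q, s)))
        if key not in in_block:
            continue
        a, d = (q, s) if q < s else (s, q)
        pairs.append({"at_gene": a, "dt_gene": d, "block_id": in_block[key]})
        used.update((q, s))
    out = pd.DataFrame(pairs, columns=["at_gene", "dt_gene", "block_id"])
    out = out.sort_values(["block_id", "at_gene"]).reset_index(drop=True)
    out.insert(0, "pair_id", [f"p{k + 1:05d}" for k in range(len(out))])
    return out


# ---------------------------------------------------------------------------
# Expression classifications
# ---------------------------------------------------------------------------


def expression_wide(expression: pd.DataFrame) -> pd.DataFrame:
    """Tidy (gene_id, stage, replicate, fpkm) -> wide with one column per
    (stage, replicate)."""
    return expression.pivot_table(
        index="gene_id", columns=["stage", "replicate"], values="fpkm"
    )


def expressed_flags(expression: pd.DataFrame) -> pd.DataFrame:
    """Expressed per stage iff FPKM > 1 in all replicates (strict)."""
    grp = expression.groupby(["gene_id", "stage"])["fpkm"].min().reset_index()
    grp["expressed"] = grp["fpkm"] > EXPRESSED_MIN_FPKM
    return grp.pivot(index="gene_id", columns="stage", values="expressed")


def de_standin(
    expression: pd.DataFrame, stage1: str, stage2: str, eps: float = FC_PSEUDOCOUNT
) -> pd.DataFrame:
    """Replicate-level DE between two stages (explicitly not DESeq2).

    Pooled-variance two-sample t-test on log2(FPKM + eps) across replicates, BH-adjusted; DE iff
    |log2FC| > 1 and FDR < 0.01 (strict). Zero-variance degenerate genes fall
    back to an exact-equality shortcut (p = 1 when means agree, p = 0
    otherwise), flagged in the ``degenerate`` column. Returns gene_id,
    log2fc, p_value, fdr, de, direction.
    """
    wide = expression_wide(expression)
    x1 = np.log2(wide[stage1].to_numpy(float) + eps)
    x2 = np.log2(wide[stage2].to_numpy(float) + eps)
    log2fc = x2.mean(axis=1) - x1.mean(axis=1)
    degenerate = (x1.std(axis=1) == 0) & (x2.std(axis=1) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = scipy.stats.ttest_ind(x2, x1, axis=1, equal_var=True)
    p = np.where(degenerate, np.where(log2fc == 0, 1.0, 0.0), p)
    p = np.nan_to_num(p, nan=1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    de = (np.abs(log2fc) > DE_MIN_LOG2FC) & (fdr < DE_MAX_FDR)
    return pd.DataFrame(
        {
            "gene_id": wide.index,
            "log2fc": log2fc,
            "p_value": p,
            "fdr": fdr,
            "de": de,
            "direction": np.where(~de, "none", np.where(log2fc > 0, "up", "down")),
            "degenerate": degenerate,
        }
    ).reset_index(drop=True)


def ingest_de_table(table: pd.DataFrame) -> pd.DataFrame:
    """Adopt an external DE table (e.g. DESeq2 output) verbatim; needs
    gene_id, log2fc and fdr columns; thresholds applied as printed."""
    out = table.copy()
    out["de"] = (out["log2fc"].abs() > DE_MIN_LOG2FC) & (out["fdr"] < DE_MAX_FDR)
    out["direction"] = np.where(
        ~out["de"], "none", np.where(out["log2fc"] > 0, "up", "down")
    )
    return out


def bias_calls(
    expression: pd.DataFrame,
    pairs: pd.DataFrame,
    stage: str,
    eps: float = FC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-pair subgenome bias at one stage.

    At bias iff mean At FPKM / mean Dt FPKM >= 2 and BH-FDR <= 0.05
    (inclusive); Dt bias symmetric. Pairs with both members silent (mean
    FPKM < 1 on both sides) are 'none' and flagged.
    """
    sub = expression[expression["stage"] == stage]
    wide = sub.pivot_table(index="gene_id", columns="replicate", values="fpkm")
    at = wide.reindex(pairs["at_gene"]).to_numpy(float)
    dt = wide.reindex(pairs["dt_gene"]).to_numpy(float)
    mean_at = np.nanmean(at, axis=1)
    mean_dt = np.nanmean(dt, axis=1)
    fc = (mean_at + eps) / (mean_dt + eps)
    la = np.log2(at + eps)
    ld = np.log2(dt + eps)
    degenerate = (np.nanstd(la, axis=1) == 0) & (np.nanstd(ld, axis=1) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = scipy.stats.ttest_ind(la, ld, axis=1, equal_var=True)
    p = np.where(degenerate, np.where(fc == 1.0, 1.0, 0.0), p)
    p = np.nan_to_num(p, nan=1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    silent = (mean_at < 1.0) & (mean_dt < 1.0)
    bias = np.full(len(pairs), "none", dtype=object)
    bias[(fc >= BIAS_MIN_FC) & (fdr <= BIAS_MAX_FDR)] = "At"
    bias[(1.0 / fc >= BIAS_MIN_FC) & (fdr <= BIAS_MAX_FDR)] = "Dt"
    bias[silent] = "none"
    return pd.DataFrame(
        {
            "pair_id": pairs["pair_id"],
            "stage": stage,
            "fc_at_over_dt": fc,
            "fdr": fdr,
            "bias": bias,
            "both_silent": silent,
        }
    ).reset_index(drop=True)


def bias_trajectory(calls_by_stage: dict) -> pd.DataFrame:
    """Four-stage bias trajectory per pair.

    conserved_At iff At-biased at all four stages; conserved_Dt symmetric;
    dynamic iff biased at >= 1 stage but not conserved; none otherwise.
    """
    per_stage = {s: calls_by_stage[s].set_index("pair_id")["bias"] for s in STAGES}
    pair_ids = per_stage[STAGES[0]].index
    rows = []
    for pid in pair_ids:
        seq = [per_stage[s].get(pid, "none") for s in STAGES]
        if all(b == "At" for b in seq):
            cat = "conserved_At"
        elif all(b == "Dt" for b in seq):
            cat = "conserved_Dt"
        elif any(b != "none" for b in seq):
            cat = "dynamic"
        else:
            cat = "none"
        rows.append({"pair_id": pid, "trajectory": cat, "sequence": "".join(
            {"At": "A", "Dt": "D", "none": "-"}[b] for b in seq
        )})
    return pd.DataFrame(rows)


def pair_change_category(direction_at: str, direction_dt: str) -> str:
    """Homoeolog-pair expression-change category between two stages.

    single: exactly one member differentially expressed; common: both DE in
    the same direction; opposite: both DE in opposite directions; none.
    """
    for d in (direction_at, direction_dt):
        if d not in ("up", "down", "none"):
            raise ValueError(f"direction must be up/down/none, got {d!r}")
    de_a = direction_at != "none"
    de_d = direction_dt != "none"
    if de_a and de_d:
        return "common" if direction_at == direction_dt else "opposite"
    if de_a or de_d:
        return "single"
    return "none"


def pair_change_categories(
    de: pd.DataFrame, pairs: pd.DataFrame
) -> pd.DataFrame:
    """Apply :func:`pair_change_category` over a DE table and pair list."""
    direction = de.set_index("gene_id")["direction"]
    rows = []
    for _, p in pairs.iterrows():
        da = direction.get(p["at_gene"], "none")
        dd = direction.get(p["dt_gene"], "none")
        rows.append(
            {
                "pair_id": p["pair_id"],
                "at_direction": da,
                "dt_direction": dd,
                "category": pair_change_category(da, dd),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# HG-HG networks
# ---------------------------------------------------------------------------


def build_hg_network(
    hg_loops: "pd.DataFrame | object",
    pairs: pd.DataFrame,
    genes,
    subgenome: str,
    genome=None,
):
    """Network over homoeolog pair ids from HG-HG loops within one subgenome.

    Nodes are pair ids (so the At and Dt networks share a vertex set and
    homoeologous genes occupy identical positions); an edge joins two pair
    ids when an HG-HG loop connects their member genes in this subgenome.
    Loops touching genes without a pair are excluded and counted in the
    graph attribute ``n_excluded``. Node degree is recorded.
    """
    import networkx as nx

    frame = hg_loops.frame if hasattr(hg_loops, "frame") else hg_loops
    col = "at_gene" if subgenome == "At" else "dt_gene"
    pair_of = dict(zip(pairs[col], pairs["pair_id"]))
    g = nx.Graph(subgenome=subgenome, n_excluded=0)
    g.add_nodes_from(pairs["pair_id"])
    sub = frame[frame.get("homoeolog_class", "") == "HG-HG"]
    for _, r in sub.iterrows():
        g1 = [x for x in str(r.get("hg_genes1", "")).split(",") if x]
        g2 = [x for x in str(r.get("hg_genes2", "")).split(",") if x]
        linked = False
        for a in g1:
            for b in g2:
                p1, p2 = pair_of.get(a), pair_of.get(b)
                if p1 is None or p2 is None or p1 == p2:
                    continue
                g.add_edge(p1, p2)
                linked = True
        if not linked:
            g.graph["n_excluded"] += 1
    return g


def network_divergence(net_a, net_b) -> float:
    """Fraction of edges of ``net_b`` absent from ``net_a`` (pair-id space).

    The paper-style statistic "interactions in the Dt network distinguished
    from the At network" is ``network_divergence(net_At, net_Dt)``.
    """
    edges_b = {frozenset(e) for e in net_b.edges}
    if not edges_b:
        return float("nan")
    edges_a = {frozenset(e) for e in net_a.edges}
    return len(edges_b - edges_a) / len(edges_b)


def shared_homoeologous_edges(net_a, net_b) -> set:
    """Edges present in both subgenome networks ("homoeologous loops")."""
    return {frozenset(e) for e in net_a.edges} & {frozenset(e) for e in net_b.edges}
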