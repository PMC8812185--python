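"""Call chromatin loops at 5 kb, classify their anchors, and detect TAD
cliques with the size-normalized interaction-strength statistic.

Loops keep FDR < 0.005 and count > 10; clique edges use the laxer count > 5
and FDR < 0.1 filter, then S = L/(B1*B2) > 0.09 defines an interaction and a
clique is a fully connected set of >= 3 structures.
"""

from polytopo import cliques, contacts, domains, loops
from polytopo.synthetic import SimulationConfig, simulate_genome, simulate_hic

cfg = SimulationConfig(
    seed=7, chromosomes=(("A01", 8_000_000, "At"), ("D01", 5_000_000, "Dt"))
)
genome, truth = simulate_genome(cfg)
m5 = simulate_hic(genome, truth, "0DPA", cfg)

calls = loops.call_loops_standin(m5)
sig = loops.filter_loops(calls)
print(f"candidate loops: {len(calls)}; significant (FDR<0.005, count>10): {len(sig)}")

tax = loops.classify_anchor_loops(sig, genome.genes)
print("\nanchor classes:")
print(tax.frame["anchor_class"].value_counts().to_string())
print("-> G-G loops join two gene-bearing anchors; N-N loops join none.")

tax = loops.classify_homoeolog_loops(
    tax, truth.homoeolog_pairs, genome.genes, truth.nongene_homology,
    {m: genome.peaks.get(("0DPA", m)) for m in ("H3K27ac", "H3K4me3", "H3K9me2")},
)
print("\nhomoeolog classes:")
print(tax.frame["homoeolog_class"].value_counts().to_string())

tads = domains.tadset_from_frame(truth.tads["0DPA"])
qualifying = cliques.filter_clique_loops(calls)
graph = cliques.build_clique_graph(tads, qualifying)
assignment = cliques.enumerate_cliques(graph)
member = (assignment.frame["k"] >= 3).sum()
print(f"\nclique graph: {graph.number_of_edges()} edges above S > 0.09; "
      f"{member} structures in {len(assignment.cliques)} maximal cliques")
for cl in assignment.cliques:
    print(f"  clique of {len(cl)}: {', '.join(cl)}")
planted = {tuple(sorted(c["tad_ids"])) for c in truth.cliques["0DPA"]}
found = set(assignment.cliques)
print(f"-> planted clique member-sets recovered: {len(planted & found)}/{len(planted)}")
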