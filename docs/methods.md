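# Methods

This note documents the models, estimators, parameter choices and known
limitations behind `polytopo`. Nothing here states an empirical result the
test suite or `scripts/acceptance.py` does not itself compute.

## Analysis pipeline

### Matrix model and balancing

Contact matrices are symmetric sparse counts over fixed-width bins; only the
upper triangle is stored, and coarser resolutions are exact aggregations of
the finest matrix (totals are conserved by construction). ICE balancing finds
per-bin weights `w` such that the row sums of `w_i m_ij w_j` are equal,
iterating `w ← w / sqrt(rowsum/mean)` until the coefficient of variation of
balanced row sums falls below `tol` (default 1e-5, max 200 iterations; on
non-convergence the best iterate is returned with a warning). Bins in the
lowest 2 % coverage quantile (and zero-coverage bins) are masked; masked bins
propagate into compartment and insulation calls. Weights are stored beside
the raw counts — balancing never alters them — which makes the procedure
scale-invariant and support-preserving.

### Contact decay, compactness, interaction range

The decay "strength" at gap *d* is `log10(mean contacts per observable bin
pair at gap d / global mean contacts per cis bin pair)` at 10 kb over
10 kb–100 Mb. The per-pair mean (rather than the raw per-gap sum) makes a
flat contact field score exactly 0 at every gap and keeps the shrinking
number of observable pairs (n − d) out of the fitted slope; the raw sums and
pair counts remain available on the curve object. The power-law exponent is
the negative least-squares slope of strength against log10 distance over
20 kb–2 Mb. Compactness is the total contacts between a 10-kb bin and all
bins within ±1 Mb (truncated and flagged at chromosome ends); interaction
ranges split into cis ≤ 2 Mb (inclusive), cis > 2 Mb, and trans.

### Compartments (40 kb)

Per chromosome: balanced matrix → observed/expected (each diagonal divided by
its mean) → Pearson correlation → leading eigenvector, oriented so the
positive side has higher mean gene density; PC1 > 0 is A, PC1 < 0 is B, and
exactly 0 falls to B (conservative inactive call). Orientation is per
chromosome. Chromosomes with fewer than 10 unmasked bins are masked whole.
Switch regions between two stages are maximal runs of ≥ 2 consecutive bins
changing label — single-bin flips are never reported. The four-stage
trajectory of a bin classifies by endpoints: constant strings are stable;
differing endpoints give AB or BA; excursions returning to the start give
ABA or BAB. The six categories partition all 16 strings
({stable: 2, AB: 4, BA: 4, ABA: 3, BAB: 3}).

### TAD-like structures (20 kb)

The insulation score of bin *i* is the log2 ratio of the mean balanced
contact in the w × w square spanning rows i−w…i−1 and columns i+1…i+w to the
chromosome-wide mean of that quantity; it is undefined within w bins of
chromosome ends. The default window is 5 bins (100 kb): plant TAD-like
structures run ~160–400 kb, and a square wider than the typical structure
averages across several domains and dilutes the boundary minima between
small adjacent structures. Boundaries are local minima with prominence
≥ 0.05 (deeper minimum wins within 3 bins); structures are the intervals
between consecutive boundaries, minimum 3 bins (60 kb). The caller is a
stand-in, not bit-compatible with any external tool; externally called
intervals can be wrapped with `tadset_from_frame`.

A boundary is conserved between two stages iff the other stage has a boundary
within ±40 kb (two bin widths, inclusive, on positions); a structure is
conserved between two stages iff both its boundaries are. Across four stages:
thoroughly conserved = conserved with all three others, relatively = 1–2,
stage-specific = 0. Features are boundary features when their midpoint falls
in a boundary bin ± 1 bin halo.

Inter-subgenome homology compares homoeolog-pair content: an At structure
whose pair-id set equals that of exactly one Dt structure (non-empty) is
homoeologous; any split or merged arrangement is partitioned; structures
without homoeologous genes are unclassified. The shift-vs-bias association is
summarized as a 2×2 table (positionally shifted × biased) with an odds
ratio (Haldane continuity correction at zero cells, flagged), a chi-squared
statistic and a permutation baseline.

### Loops (5 kb)

The stand-in caller is the distance-stratified shape of Fit-Hi-C without its
spline smoothing: per chromosome and gap *d* (2–600 bins by default, so the
diagonal and adjacent-bin ligation signal are excluded), expected(d) is the
mean count over all pairs at that gap; the p-value of an observed pair is the
binomial upper tail with success probability expected(d)/N over N total
tested contacts; BH correction runs over *all* testable pairs (zero-count
pairs cannot be rejected but count toward the total). Published-style filters
are strict: significant loops keep FDR < 0.005 **and** count > 10;
clique-qualifying loops keep count > 5 **and** FDR < 0.1.

Anchor taxonomy uses gene-midpoint-in-bin (an overlap variant exists behind a
flag): G-G / G-N / N-N by gene presence; HG-HG when both anchors carry
homoeolog-pair members; HG-HN when one does and the other is gene-free. HG-HN
subtypes consult the non-gene region correspondence map: a homologous
counterpart with an identical three-mark presence vector gives homo_same, a
differing vector homo_different, no counterpart non_homo ("same marks" is
identity of the presence/absence vector — the source analyses define no
quantitative sameness). Gene-rich windows have > 20 genes per 500 kb
(strict); loop conservation across stages is exact anchor-pair identity at
5 kb.

### TAD cliques

Edges join same-chromosome structure pairs with `S = L/(B₁·B₂) > 0.09`, L
counted from qualifying loops whose two anchors fall in the two structures.
The printed form of the statistic in the emulated study is (B₁×B₂)/L, but its
stated purpose — a *lower* cutoff that removes *low*-intensity interactions,
independent of structure size — is only coherent for the density form, which
is scale-invariant under uniform size rescaling; both forms are implemented
(`formula="as_printed"`). Maximal cliques come from networkx's Bron–Kerbosch;
a structure's k is the largest maximal clique containing it, k ≥ 3 required
for clique status, size classes non-clique / 3 ≤ k ≤ 5 / k > 5. Between
stages: loss (clique → non-clique), formation, expansion (3–5 → >5),
reduction (>5 → 3–5), stable, other; aggregated by the stage-1 compartment
context (majority A/B label over the structure's bins).

### Homoeology

Syntenic blocks: similarity hits between a chromosome pair are chained by
longest monotone subsequence on gene ranks — both orientations, so whole-block
inversions form antiparallel blocks — with query/subject rank gaps capped at
10; chains extract greedily until none of ≥ 5 genes remains. Pairs are
mutual best hits (score, then significance, then id as tie-breaks) whose hit
lies in a block; one-to-one by construction. Expression semantics as printed:
expressed = FPKM > 1 in all three replicates; DE = |log2 FC| > 1 and
FDR < 0.01 (strict) from a pooled-variance two-sample t-test on
log2(FPKM + 0.01) — explicitly a stand-in, not a negative-binomial model;
external DE tables are ingested verbatim. Bias = FC ≥ 2 and FDR ≤ 0.05
(inclusive) on mean FPKM with the same pseudo-count. Trajectories:
conserved_At/Dt (biased that way at all four stages), dynamic (biased
somewhere, not everywhere), none. HG-HG networks use homoeolog pair ids as
nodes, so the At and Dt networks share a vertex set; divergence is the
fraction of one network's edges absent from the other.

## Synthetic data: what it emulates and what it does not

The generator plants a two-subgenome, four-stage study: 2 At chromosomes of
20 Mb and 2 Dt chromosomes of 12 Mb (At larger and twice as TE-dense),
stages 0/5/10/20 DPA. Hi-C counts are Poisson draws from a multiplicative
intensity: power-law decay (exponent α = 1.0, ~10 expected counts at a one-bin
gap at 5 kb), ×1.6 for same-compartment bin pairs, ×2.0 within structures,
×1.5 across clique structure pairs, ×1.3 on Dt chromosomes (higher
compaction), plus *additive* dots for loops — 25 expected extra counts for
loop-level dots, 12 for the denser clique bundles (≈0.15 dots per structure
bin-pair, so S comfortably clears 0.09). Additive dots are the generator's
model because a multiplicative dot at megabase distance would contribute
negligible counts at this depth, making the planted object undetectable by
construction. Trans contacts are a thin uniform background.

Compartments are alternating blocks of 10–30 40-kb bins; Dt chromosomes
inherit their At partner's labels by coordinate scaling (homoeologous regions
share compartment status, and Dt gene density then orients Dt PC1). Per
adjacent stage, ≈2.5 % of bins flip in contiguous runs of ≥ 2 bins — chosen
to land the stable-compartment fraction in the low-90 % range the emulated
system shows. Structures tile each chromosome at 8–20 bins; per stage a
fraction of boundaries move by ±3 bins (8 %), drop (4 %) or appear. Dt
boundaries derive from the At gene grouping of that stage; ~30 % of
multi-gene groups are deliberately split on the Dt side (planted partitioned
class). Genes are placed inside structures (A-compartment structures carry
~5× the genes of B), with extra subgenome-specific boundary genes whose
expression is boosted 3×; homoeolog order is collinear apart from whole-block
inversions (recovered as antiparallel blocks) and ~10 % Dt-specific
insertions. Expression is negative-binomial (dispersion 0.02 — tight,
well-measured biological replicates; 0 gives the deterministic limit) over
three replicates; pair members share one profile so per-stage planted ratios
are exactly 1 or 4; ~30 % of pairs carry bias (half conserved, half dynamic).
Histone peaks couple to compartments (actives on A, H3K9me2 on B) and carry
the planted mark vectors of the non-gene homology map.

Passing tests on this bench show the estimators recover planted structure at
realistic effect sizes and depth; they do not show robustness to what the
generator omits: copy-number and mappability artifacts, restriction-fragment
bias, overdispersed Hi-C counts, trans compartment structure, assembly errors
in the gene order, or DESeq2-style information sharing across genes (the
3-replicate t-test is deliberately weaker at the strict DE threshold).

## Problem sizes and numerics

The acceptance benchmark runs the full 64-Mb genome (12,800 5-kb bins) over
four stages in about a minute; module tests use 8 + 5 Mb genomes. Recovery
rates quoted by the acceptance script: compartment agreement and boundary
recovery are measured at stage 0DPA; loop recovery is measured over
loop-level planted dots at the calling FDR (< 0.005) without the count
filter, since the count filter is a separate reporting threshold; clique
bundles are assessed by member-set recovery across all stages (the S
statistic tolerates individually missed dots by design). Degenerate inputs:
all-zero matrices are rejected; uniform insulation tracks yield one structure
per chromosome with a warning; zero-variance expression falls back to an
exact-equality test, flagged; infinite odds ratios are reported as such with
continuity-corrected estimates alongside.

## Known limitations

* The compartment caller assigns PC1 sign by gene density alone; on
  chromosomes where density differences are weak the orientation can flip.
* The insulation caller reports some spurious boundaries at Poisson noise
  minima (prominence 0.05 trades recall for precision); conservation classes
  on called (rather than imported) structures inherit that jitter.
* The loop caller's expected model is a per-gap mean, not a smoothed fit;
  broad planted enrichments (clique rectangles) can reach significance as
  individual pixels.
* `run_all` orchestrates the synthetic path; on real data the module
  functions are called directly on imported matrices, intervals and tables.
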