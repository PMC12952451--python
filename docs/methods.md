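# Methods

`hccnet` re-implements, as a tested library + CLI, a network-genomics
workflow for small hepatocellular-carcinoma (HCC) cohorts: rare-variant
filtering, per-patient module detection on a protein–protein interaction
(PPI) network, guilt-by-association gene prioritization from sorafenib
pharmacogene baits, and a sensitive-vs-resistant mutation-burden
comparison. This note records the model, the parameters that matter, the
numerical choices, what the synthetic generator does and does not emulate,
and the known limitations.

## Variant filtering

A variant is *rare non-synonymous* when both clauses hold:

1. population allele frequency (gnomAD exomes combined) is **strictly**
   below the threshold (default 0.01), with a missing AF treated as rare —
   absence from gnomAD is itself evidence of rarity and is logged;
2. the consequence term is one of the five high-impact truncating classes
   (`stop_gained`, `frameshift_variant`, `splice_acceptor_variant`,
   `splice_donor_variant`, `start_lost`) or `missense_variant`.

Consequence matching is case-insensitive on Sequence-Ontology-style terms;
the free-text alias "start loss" maps to `start_lost`. Unknown terms are
excluded, never errors. Coordinates follow the 1-based VCF convention.

**Zygosity classes.** Per patient × gene: homozygous calls count as
`n_homo`; two or more *distinct* heterozygous variants (distinct by
variant id) in one gene are called a putative compound heterozygote
(`n_com_hete = 1`), consuming two het records, with any further het
records counted in `n_hete`. This makes the bookkeeping conservative —
`2·n_com_hete + n_hete + n_homo` always equals the record count — and the
compound-het call is an *upper bound*, since no phasing information is
used: two het variants on the same haplotype would be miscalled.

## Network model

Edges carry STRING-style integer combined scores in [0, 1000]. Confidence
filtering removes edges with score < 700 (strict; 700 is retained),
isolated nodes, and everything outside the largest connected component.
The component restriction is a deliberate choice: it keeps the random-walk
transition matrix free of dangling columns and the Steiner stage on one
connected instance; the alternative (uniform teleport columns for dangling
nodes) is not used.

Two derived quantities:

- **edge cost** `c(e) = 1 − score/1000`, so costs lie in [0, 0.3] after
  the default filter — the "percentage" reading of the STRING combined
  score;
- **transition matrix** `W`: the *unweighted* adjacency normalized so each
  column sums to 1 (each neighbor of a degree-k node receives mass 1/k),
  over a lexicographic node ordering. A score-weighted normalization is
  available behind a flag but is not the default. The single-node graph
  gets a self-transition so the walk's fixed point is well defined.

## Prize-collecting Steiner tree (PCST)

Each patient's prize map sets `p(v) = (# filtered variants in gene v) /
(gene length in bases)`; genes with no variants have prize 0. Filtered
variants of both somatic and germline origin contribute (the prize formula
is origin-agnostic; a caller can pass either subset). Optionally, a fixed
bonus prize is added to differentially expressed genes (logFC > 2 and
FDR < 0.01, both strict); the default bonus is 0, i.e. variant-only
prizes. The solver minimizes, over trees `F` in the filtered network,

    o(F) = β · Σ_{v ∉ F} p(v) + Σ_{e ∈ F} c(e)

β (default 1) trades prize coverage against edge expenditure. With
realistic variant-derived prizes (~count/20 kb ≈ 5·10⁻⁵) and edge costs up
to 0.3, β = 1 typically yields single-gene trees; multi-gene modules
appear when prizes are large relative to β-scaled costs (many variants,
short genes, DE bonuses, or a larger β). β is exposed everywhere.

**Solver.** Instances with ≤ 15 nodes are solved exactly by enumerating
connected induced subgraphs (each connected node set is generated once via
anchored frontier expansion) and spanning each candidate set with its
minimum spanning tree on edge costs. Larger instances use a heuristic:
from each of the top-20 prize genes, grow a Dijkstra shortest-path tree on
edge costs and apply *strong pruning* — leaf-to-root dynamic programming
that keeps a child subtree only when its accumulated prize gain exceeds
the cost of the supporting edge; strong pruning is optimal for the tree it
is given. The best pruned tree across roots competes with the best single
node. A separate brute-force oracle (all node subsets + MST, refused above
12 nodes) serves as the correctness reference in the test suite; on random
≤ 10-node instances the solver matches it exactly, and the heuristic alone
is additionally checked never to beat it (and measured optimal on ~92% of
such instances).

**Numerical choices.** All tie-breaks are deterministic: lower objective,
then fewer nodes, then lexicographic node tuple; objective comparisons use
a 10⁻¹² guard against float MST-sum noise; every returned solution's
objective is re-derived from its node/edge sets and must agree to 10⁻⁹.
An all-zero prize map returns the lexicographically first node with
objective 0 and a warning; β = 0 likewise (excluding everything is free
and edges only cost).

## Random walk with restart (RWR)

From the bait set (the sorafenib pharmacogene panel), `p₀` puts equal mass
on the baits present in the network and the walk iterates

    p_{t+1} = (1 − γ) W p_t + γ p₀

until the L1 change is below `tol`. Defaults: γ = 0.15 (the common
network-propagation convention; the restart probability is not dictated by
the underlying study), tol = 10⁻¹⁰, max_iter = 1000. For γ ∈ (0, 1] the
map is an L1 contraction with factor (1 − γ), so iterations needed are
bounded by log(tol)/log(1 − γ) + 1 — asserted in tests, along with
probability conservation (Σp = 1 ± 10⁻⁹) and agreement to 10⁻⁸ with the
direct solve of (I − (1 − γ)W)p = γp₀ on small instances. The top-k cutoff
defaults to 5000; baits remain eligible for their own ranking unless
`exclude_seeds` is set, and ranking ties break lexicographically.

## Resistance comparison

The comparison unit is **carrier status**: a patient carries if ≥ 1
qualifying variant (somatic: non-synonymous; germline: *rare*
non-synonymous) falls in the panel (somatic: the pharmacogene panel;
germline: the RWR top-k candidate genes). Carriers per group form a 2×2
table tested with a two-sided Fisher exact test under the
point-probability definition — the sum of hypergeometric probabilities of
all tables with the observed margins that are no more likely than the
observed table — computed in exact rational arithmetic
(`fractions.Fraction`), so probability ties are decided exactly rather
than through a float tolerance. Degenerate margins give p = 1. On the
packaged 13-patient reference cohort (3 sensitive, 10 resistant) this
yields p = 0.4965… for the somatic table ((4,6),(0,3)) and p = 0.06993…
for the germline table ((7,3),(0,3)), displayed as 0.50 and 0.07 at the
report's 2-decimal rounding. No multiple-testing correction is applied:
one pre-specified test per origin.

## Synthetic generator

The generator emulates all five pipeline inputs at desk scale with full
planted truth, because real WGS cohorts of this kind are access-restricted:

- **network**: Barabási–Albert graph (attachment 2) over 300 genes;
  background scores clear the 700 filter with probability 0.5; a connected
  6-gene module (BFS-grown) has its spanning edges forced into [900, 1000]
  so it survives filtering.
- **cohort**: 16 patients (3 sensitive, 10 resistant, 3 untreated).
  Per-gene per-patient variant counts are Poisson — somatic rate 0.01,
  germline rate 0.002 per gene — giving a handful of qualifying somatic
  variants per patient, comparable to the reference cohort's panel counts.
  Each background variant passes the rare-non-synonymous filter with
  probability 0.6 (consequence and AF drawn accordingly; 15% of rare
  variants have missing AF). Resistant patients receive
  Poisson(`enrichment_rate`) extra qualifying germline variants on the
  42-gene panel; the default 2.0 implies a carrier probability of
  1 − e⁻² ≈ 0.86, matching 7–8 of 10 resistant carriers. The benchmark's
  "strong" enrichment is 4.0 (carrier probability ≈ 0.98), fixed from this
  model a priori. A 5-variant predisposition catalog is planted into 3
  carrier patients.
- **DE table**: an exact planted fraction (default 3.6%) of genes passes
  logFC > 2 & FDR < 0.01.
- gene lengths are log-normal (median 20 kb, σ_log 0.8), floored at 500 b.

Everything derives from one integer seed through tagged
`numpy.random.Generator` streams; the same seed reproduces byte-identical
files, and a JSON manifest records all planted truths (qualifying counts
per patient × gene × origin, module membership, enrichment draws, catalog
carriers, DE genes).

**What passing on synthetic data does not show.** The generator has
independent Poisson counts (no mutational signatures, hypermutators, or
gene–gene correlation), no linkage or phasing structure, uniform AF draws
rather than a site-frequency spectrum, and a clean scale-free-ish topology
rather than STRING's evidence-channel structure. Tests against it
establish algorithmic correctness and calibration under the stated model,
not robustness to real-cohort artifacts.

## Benchmark problem sizes

The seeded suites use 100 random ≤ 10-node instances for solver-vs-oracle
agreement, 20 random ≤ 50-node networks for the RWR linear-solve check,
and 20 / 50 / 50 replicates of the default 300-gene, 16-patient cohort for
planted-module recovery, enrichment power, and null calibration — sizes at
which the exact references are cheap and the whole reproduction runs in
seconds.

## Limitations

- Compound-heterozygote calls are unphased upper bounds.
- The PCST heuristic carries no global optimality guarantee above the
  exact-enumeration threshold; its quality is certified only at oracle
  scale and via the planted-recovery suite.
- The pipeline consumes annotated variant tables; calling, annotation and
  liftover are out of scope, as are STRING downloads and identifier
  orthology mapping (a gene-symbol network is expected).
- With three sensitive patients the Fisher test has little power; the
  germline comparison's p ≈ 0.07 on the reference cohort illustrates the
  resolution limit of cohorts this small.
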