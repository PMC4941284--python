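# Methods

This note records the model assumptions, parameter choices, numerical
conventions and known limitations of the `netpharm` pipeline.  It
states nothing that the test suite or `scripts/acceptance.py` does not
itself compute.

## Concordance scoring

The score of a (compound, gene) pair is the Pearson correlation, across
a panel of reference drugs, between the compound's chemical similarity
to each drug and the gene's network closeness to each drug's known
targets.  Assumptions baked into this model:

- **Distance kernel.**  Closeness is `Σ_t exp(−d²)` over the drug's
  targets, with `d` the unweighted shortest-path length, `d(g,g) = 0`,
  and unreachable targets contributing 0.  The Gaussian-type kernel
  decays fast enough that a gene two steps from a target (`exp(−4) ≈
  0.018`) is already fifty-fold down-weighted relative to the target
  itself; this keeps the closeness channel local.  The kernel is an
  argument of every scoring function, so the assumption is isolated
  and swappable.
- **Zero-variance convention.**  If either channel is constant across
  drugs, the pair scores 0 rather than NaN: a constant channel carries
  no evidence for or against the pairing, and a total ranking over all
  candidates must still exist.
- **Tie-break.**  Equal scores are ordered by gene symbol ascending.
  This is arbitrary but deterministic; rank outputs are reproducible
  bit-for-bit across runs and platforms.
- **Top-k calling.**  A herb's putative targets are the union of its
  compounds' top-25 genes by default.  The cutoff controls how
  selective the herb→target layer is: with the default synthetic
  conditions (2000 candidate genes, 12 compounds per herb), k = 25
  yields a formula-wide putative-target set of a few hundred genes,
  the scale at which this family of analyses operates; k = 100 would
  inflate it to over half the genome and drown the topology filter in
  noise.  The value is surfaced in `RunConfig`/CLI and echoed in every
  run report.

Pearson correlation is invariant under positive affine transforms of
either channel, so any monotone-linear rescaling of the similarity
input (min–max scaling into [0,1], unit changes) leaves all scores,
ranks, and downstream results unchanged.  This invariance is enforced
by property tests.

## Network assembly

Nodes: herbs, putative targets, known disease genes; a gene in both
target categories is one node with role `both` (the role partition is
exact, which keeps count arithmetic unambiguous: category totals that
count the overlap in both categories are reported separately as
`*_total`).  Edges: typed herb→target links plus the PPI edges whose
both endpoints are included genes.  Known disease genes with no direct
interaction inside the network and no putative status are dropped and
logged — the network is defined by direct interactions, and an
isolated node has none.  Herb→gene edges exist only via the putative
link, never directly from the known-disease list.

## Topology and major nodes

All four measures are computed on the untyped, undirected, simple
graph (herbs included):

- degree: incident edge count;
- betweenness: unnormalized, unweighted, each unordered pair counted
  once (a normalization flag divides by `(n−1)(n−2)/2`);
- closeness: harmonic centrality by default, `Σ_{u≠v} 1/d(v,u)` with
  `1/∞ = 0`.  Harmonic is the only classic-closeness variant that is
  finite and meaningful on graphs with several components, which
  assembled herb–target networks routinely are.  Two inverse-farness
  variants (`classic_inverse_farness`, `classic_times_n_minus_1`)
  are selectable because published analyses are often vague about
  their convention;
- k-coreness: the largest k such that the node survives iterative
  deletion of nodes with degree < k.

Thresholds are the per-column sample medians (even n: mean of the two
central order statistics).  A node is *major* iff its role is eligible
and all four values are **strictly** greater than the medians; sitting
exactly on any median excludes a node.  Herb nodes take part in the
metric computation and the medians but are not eligible by default:
they are structural super-hubs representing the formula, not candidate
targets.  The centralities and coreness are computed through igraph's
C core for speed; the test suite checks them exactly against an
independent brute-force BFS oracle on random graphs.

## Enrichment

One-sided hypergeometric over-representation: with universe size N,
pathway size K, query size n and overlap k, `p_raw = P(X ≥ k)` via the
survival function (log-space internally; `k = 0` gives exactly 1).
Bonferroni multiplies by the number of pathways tested — including
those with zero overlap — and caps at 1.  The universe defaults to the
union of all pathway members (the standard self-contained choice when
the original annotation background is unknown); `universe_mode: ppi`
switches to all network genes.  Query genes outside the universe are
dropped and logged.  Only over-representation is tested, and only
Bonferroni correction is offered; FDR alternatives are out of scope.

## Reliability (hit times / order)

Per herb, every candidate gene is ranked by hit times (number of the
herb's compounds whose top-k profile lists it) descending, ties broken
by mean concordance score descending, then symbol ascending; *order*
is the ordinal (1, 2, 3, …) position, so equal hit times still receive
distinct orders.  The rank is taken within **all** candidate genes of
the herb, not within a shortlist.  Hit times are monotone
non-decreasing in k by construction.

## Synthetic data: what it emulates, and what it does not

The generator emulates the six inputs of a formula study:

- **PPI network**: preferential attachment (`m = round(mean_degree/2)`,
  default mean degree 6 over 2000 genes) for a hub-heavy,
  PPI-like topology; Erdős–Rényi as the homogeneous alternative.  A
  mean degree above `n − 1` is rejected as degenerate (equal to
  `n − 1` is allowed: it is simply the complete graph).
- **Reference pharmacopeia**: 40 drugs with 1–5 targets each.  Each
  compound carries exactly **one** planted target; its similarity row
  is `s·z(clo(g,·)) + √(1−s²)·η + σ·ε` (standardized closeness of the
  planted gene mixed with independent Gaussian noise; `s` =
  `signal_strength`, σ = `noise_sd`), then min–max scaled into [0,1] —
  a positive affine map, so the planted Pearson concordance is
  preserved and equals ~`s/√(1+σ²)` in expectation, exactly 1 at
  `s = 1, σ = 0`.  A single planted target per compound is a modelling
  choice: one similarity row can encode one closeness profile exactly;
  splitting it across several genes would dilute the correlation and
  make the perfect-signal limit unattainable.
- **Planted pathway**: one of 20 gene sets (sizes 15–25) is designated
  as the disease pathway.  The planted targets are its best-connected
  members (top PPI degree), and every herb anchors each of them once —
  mirroring two features of real formula studies: druggable,
  well-studied targets sit on well-connected proteins, and the
  flagship targets of a formula are common to all its herbs.  The
  planted set size is `min(round(0.6·|pathway|), pathway slots per
  herb)`; 80% of each herb's compounds are pathway-anchored, the rest
  anchor random off-pathway genes so that off-pathway planted pairs
  also exist.
- **Disease genes**: 31, of which 30% are drawn from the planted
  pathway (within ±1 gene of the configured fraction).

Defaults (2000 genes, 5 herbs, 12 compounds/herb, 40 drugs, 20
pathways, signal 0.9, noise 0.1) were fixed once by a design-time power
analysis so that the default conditions produce networks of a few
hundred putative targets and give the planted pathway recoverable —
but not trivial — support; they are the study conditions under which
the acceptance checks run, not tuning knobs.

The generator is a pure function of its config (per-stage child seeds
derived from one master seed), so the full bundle is bit-reproducible.

**What passing the synthetic tests does *not* show about real data:**
chemical similarity here is constructed from network closeness plus
noise, so the two channels share no confounders — real fingerprints
correlate across related compounds and bias profiles toward chemical
families.  Gene closeness profiles in small-world PPI graphs are
heavily quantized (shortest paths of 1–4 steps), so near-duplicate
genes (e.g. leaves sharing a hub) are genuinely indistinguishable to
the closeness channel; the synthetic planted targets are chosen
connected enough to be distinguishable, which real targets need not
be.  Curation biases of real PPI and pathway databases, symbol-mapping
losses, and annotation-background mismatches (the universe problem in
over-representation analysis) are all absent.

## Numerical and degenerate-input conventions

- Concordance requires ≥ 3 reference drugs; fewer is an error.
- A drug with no targets mapping into the PPI network is an error
  naming the drug; individual unmapped targets are dropped and logged.
- An empty candidate set, empty gene-set collection, a query disjoint
  from the universe, and a disease list entirely outside the gene
  universe are errors; isolated known-disease genes are silently (but
  logged) pruned.
- `significance_alpha` is open-interval (0,1) at the pipeline level;
  the `enrich` function itself accepts α = 1 as "flag everything",
  which is useful for exploratory runs.
- All reported tables are deterministically sorted; run reports are
  byte-identical for identical configuration and seed (the output
  directory is excluded from the config echo for exactly this reason).
- Gene symbols are normalized on ingest: upper-case, whitespace and
  hyphens stripped, common Greek letters transliterated (so `PPAR-γ`
  and `pparg` collide to `PPARG`).

## Problem sizes used by the test suite and acceptance script

Unit tests run on miniature bundles (150 genes, 12 drugs, 2 herbs).
The recovery checks use the full default conditions over 50 seeds
(rank recovery and pathway recovery) and 20 seeds per signal level for
the monotonicity trend.  The acceptance script performs one full
default-scale run at the given seed plus a 25-seed recovery sweep; a
complete invocation takes well under a minute on one CPU.

## Known limitations

- The betweenness/closeness conventions of graphical network-analysis
  tools vary; the variants shipped here cover the common choices but
  cannot claim to match any specific GUI tool's internal definition.
- Concordance is a linear association measure; rank-based variants
  (Spearman) are not implemented.
- The reliability "order" statistic ranks within a herb's full
  candidate list; with thousands of candidates the orders of rarely
  hit genes are dominated by the mean-score tie-break.
- No weighted-edge centralities, eigenvector/PageRank measures, FDR
  correction, or visualization; similarity matrices are inputs, never
  computed.
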