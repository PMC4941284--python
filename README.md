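# netpharm

A network-pharmacology pipeline for multi-herb formulas.  Given a
formula's compounds, a panel of reference drugs with known targets, a
protein–protein interaction (PPI) network, a disease-gene list and a
pathway collection, `netpharm` answers the question: *which proteins
does the formula plausibly act on, and which biological pathways do
those proteins implicate?*

It is aimed at computational systems-biology work on traditional
multi-component medicines (and, more generally, any polypharmacology
setting where per-compound targets must be inferred rather than
measured), where the standard analysis chain is: predict compound
targets, build a compound/herb–target–disease network, pick out the
topologically dominant nodes, and run pathway over-representation on
them.

## Method

**1. Concordance scoring (putative target profiles).**  For compound
*c* and candidate gene *g*, two vectors are compared across the
reference drugs *d*:

- the chemical-similarity channel `sim(c, d)` (supplied as input — the
  package does not compute fingerprints), and
- the network-closeness channel
  `clo(g, d) = Σ_{t ∈ targets(d)} exp(−dist(g, t)²)`,
  where `dist` is the unweighted shortest-path length in the PPI
  network (unreachable targets contribute 0).

The concordance score is the Pearson correlation across drugs,

```
score(c, g) = corr_d( sim(c, d), clo(g, d) )  ∈ [−1, 1]
```

A gene that is close in the network to exactly those drugs the compound
chemically resembles gets a high score.  Ranking all candidates gives
the compound's *putative target profile*; a herb's putative targets are
the union of its compounds' top-*k* genes (default *k* = 25), and a
gene's *hit times* under a herb is the number of that herb's compounds
listing it.

**2. Tripartite network.**  Nodes are herbs, putative targets, and
known disease genes (genes in both target categories get the single
role `both`); edges are herb→target links plus the direct PPI edges
among the included genes.  Known disease genes with no direct
interaction in the network are pruned.

**3. Major nodes.**  Four measures are computed on the untyped graph:
degree, unnormalized shortest-path betweenness, harmonic closeness
`Σ_u 1/dist(v, u)`, and k-coreness.  A node is *major* when all four
values are strictly greater than the respective column medians.

**4. Enrichment.**  The major genes are tested for over-representation
in each pathway with the one-sided hypergeometric test
`P(X ≥ k)`, `X ~ Hypergeom(N, K, n)`, Bonferroni-corrected by the
number of pathways tested (significance: corrected p < 0.05).

**5. Reliability.**  For targets of interest, per herb: hit times and
the target's ordinal rank among all of the herb's candidate genes
(ties broken by mean concordance, then symbol), rendered `hits(order)`.

Because the real inputs of such studies are rarely redistributable, the
package includes a first-class synthetic-data generator that emulates
all six inputs with a planted compound→target signal of tunable
strength and one planted pathway, so that every stage can be validated
against known ground truth.

## Worked example

```
netpharm run-all --seed 1 -o results/run1
```

runs the whole chain on a synthetic bundle (2000 genes, 5 herbs,
12 compounds each, 40 reference drugs, 20 pathways) and prints:

```
{
  "betweenness": 52.31912648137947,
  "closeness": 258.9500000000011,
  "degree": 4.0,
  "k_core": 4.0
}
major nodes: 168; significant pathways: 1
```

The four numbers are the medians used as thresholds by the major-node
filter.  The run report (`results/run1/report.json`) shows a network of
597 nodes — 5 herbs, 581 putative targets and 29 known disease genes,
18 of which overlap — from which 168 major nodes are selected (159
putative-only, 9 in the overlap).  Enrichment of those major genes
recovers exactly one significant pathway, the planted one:

```
PW01  k=8  K=15  p_raw=3.9e-05  p_bonf=0.00079
```

The reliability table for the top pathway's major genes
(`reliability_table.txt`) uses the `hits(order)` rendering, e.g.
`2(10)` = listed by two of the herb's compounds, tenth-ranked gene of
that herb:

```
herb     HERB1   HERB2   HERB3   HERB4   HERB5
G0019    2(10)  1(143)  1(116)  1(132)   1(56)
G0038   1(101)    2(2)   1(75)   1(67)   1(50)
...
```

Every stage can also be run separately (`netpharm simulate / score /
assemble / topology / enrich / reliability`) on the serialized
artifacts, and the library functions mirror the CLI one-to-one.  User
data replaces the simulator by pointing `RunConfig.input_dir` (or the
stage commands) at a directory with the same plain-text formats: PPI
edge list TSV, compound×drug similarity TSV, drug→target TSV,
herb→compound TSV, disease-gene list, and a GMT pathway collection.

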