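# Methods

This note documents the models implemented in `synscreen`, the defaults
and why they were chosen, the numerical conventions, what the synthetic
fixtures do and do not emulate, and known limitations.

## Scoring model

### Networks and centrality

The background PPI graph is undirected, unweighted and simple: duplicate
edges collapse, self-loops are dropped at load time, node identifiers
are opaque case-sensitive strings (mapping gene symbols to accessions is
the caller's responsibility). The disease signaling network is the
subgraph induced by the disease driver genes with isolated nodes
removed; induction is idempotent and fails loudly when no edges remain.

Each node's centrality score is CS = Bn + Cn + Pr with three
conventions chosen to make CS comparable across network sizes:

- **Bn** — betweenness normalized by (n−1)(n−2)/2, so Bn ∈ [0, 1];
- **Cn** — Wasserman–Faust component-scaled closeness (the reachable-set
  average scaled by the reachable fraction), which stays well defined if
  induction leaves several components;
- **Pr** — PageRank with uniform teleport, damping 0.85, computed by
  power iteration to an L1 tolerance of 1e−10 (after isolate removal an
  undirected graph has no dangling nodes, so the scores sum to 1).

Betweenness and closeness are delegated to networkx with exactly these
conventions; PageRank is implemented directly so the iteration tolerance
is under our control. All three are verified against brute-force oracles
(exhaustive BFS path counting, dense power iteration) on random graphs.

### Target-network synergy

S_tnetwork is a symmetric pair of centrality-weighted means of the
distance kernel exp(−D/n²), where D is the minimum hop distance from one
drug's target to the other drug's target set and n is the size of the
*other* mapped target set (the cross-pairing of sizes is kept exactly as
the formula states). Design choices:

- **Kernel sign.** The decaying kernel exp(−D/n²) is the default: the
  score is meant to reward closely connected hub targets, and the
  decaying form is the one that does so; the growing form exp(+D/n²)
  remains available as `exponent_sign: literal`. Under the default the
  score lies in [0, 2] and equals 2 iff the mapped target sets coincide.
- **Unreachable targets** contribute a kernel factor of 0 — the
  continuous limit of the decay kernel at infinite distance.
- **Targets outside the scoring network** are excluded from the sums and
  reported via a structured warning; a drug with no mapped target at all
  yields an undefined score, which the screen downgrades to 0 rather
  than dropping the candidate.
- **Scoring graph.** Centralities and distances live on the induced
  disease subnetwork by default (`scoring_graph: disease`); options
  `background` and `disease_plus_targets` (disease genes plus both
  drugs' targets, recomputed per pair) cover target sets that fall
  mostly outside the disease network.

### Functional synergy

Term information content uses cumulative annotation frequencies —
Freq(term) counts annotations to the term or any descendant, which is
the standard convention and guarantees Freq(parent) ≥ Freq(child) —
normalized by the corpus maximum: p = Freq/MaxFreq ∈ (0, 1]. Term pairs
score with Lin's ratio through the **most informative common ancestor**
(minimum p). The printed alternative of maximizing p over common
ancestors is degenerate — on a rooted DAG the root (p = 1) always wins
and every similarity collapses to 0 — so it is kept only behind
`mica_rule: literal_max`. Identical terms score 1 by definition; two
distinct terms with p = 1 score 0; terms with no annotated common
ancestor score 0 with a warning.

Genes may carry several annotations; gene pairs aggregate the term-pair
cross product by `max` (default), best-match average, or plain average.
The set-level score sums gene-pair similarities over ordered cross pairs
and divides by (m+n)(m+n−1); since 2mn ≤ (m+n)(m+n−1) for m, n ≥ 1 the
score lies in [0, 1], reaching 1 only at m = n = 1 with identical
annotations. Frequencies default to the whole annotation corpus
(`corpus_scope: all_annotations`); `target_union` recomputes them from
the screened drugs' targets only.

Logarithms are base 2 throughout.

### Chemical similarity

- **2D.** SMILES are assumed canonical on input (an external
  canonicalizer can be run beforehand; the core stays dependency-free
  and deterministic). Ring-closure labels — single digits and `%nn`
  pairs outside square brackets — are rewritten to `0`/`%00`; digits
  inside brackets (isotopes, charges, H counts) are untouched. LINGO
  length q = 4; a string shorter than q is its own single LINGO, so the
  window count is always max(len − q + 1, 1). The profile similarity is
  the count-based Tanimoto-style mean over the union of observed LINGOs.
- **3D.** The overlap of two pre-aligned typed site sets is a Gaussian
  sum over same-type pairs, O = Σ exp(−d²/σ²) with σ = 1 Å by default —
  a generic surrogate for proprietary volume-overlap scores. The
  similarity is O(a,b)/max(O(a,a), O(b,b)); because the Gaussian
  cross-sum is not guaranteed below the larger self-overlap the ratio is
  clamped to [0, 1]. Conformer generation and alignment are out of
  scope: site coordinates are consumed pre-aligned. Missing site data
  scores 0 by default (`missing_3d: zero`) so the screen degrades
  gracefully to the remaining axes; `skip_axis` reports the 3D part as
  NaN and lets S_similarity fall back to the 2D score.

### Ranking

The combination rule is deliberately simple: each axis is min–max
normalized across the candidate panel (a constant axis maps to the
neutral 0.5 rather than dividing by zero), and candidates are ordered by
the diagonal projection (x+y+z)/√3. The projection orders identically to
the normalized sum; a Euclidean-norm rule is available for comparison
(`total_rule`). Ties break lexicographically by drug identifier so
output is deterministic; ranks are a gapless permutation 1..N. Per-axis
failures downgrade the axis to 0 with a structured warning instead of
excluding the candidate, so partial data never silently shrinks a
screen.

## Trial statistics

The trial module uses Wald normal-approximation machinery throughout:
group proportions with Wald CIs clamped to [0, 1]; the risk difference
p₁ − p₂ with SE = √(p₁q₁/n₁ + p₂q₂/n₂); the Pearson chi-square on the
2×2 table via N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) with an optional Yates
continuity correction (default off); and the classical two-proportion
sample size n = (z_{α/2}√(2p̄q̄) + z_β√(p₁q₁+p₂q₂))²/δ², rounded up and
inflated by 1/(1 − dropout). On the bundled ACR20 example (30/51 vs
48/61 responders) the uncorrected chi-square is 5.1847 (P = 0.023,
Yates: 4.288); the 50%/+26-point/80%-power/10%-dropout design gives 59
per group. Closed forms are cross-checked in the tests against
statsmodels and scipy.

## Synthetic fixtures

The generators are pure functions of (parameters, seed) — identical
seeds reproduce byte-identical files — and exist to exercise the
formulas, not to mimic disease biology:

- **Networks**: Barabási–Albert (default, 60 nodes, 2 attachments —
  scale-free like real PPI degree distributions) or Erdős–Rényi made
  connected by chaining components. Disease genes are a BFS ball around
  the main hub (half the nodes), so the induced disease subnetwork is
  connected by construction.
- **Ontology**: a complete tree of depth 4 and branching 3; one filler
  annotation per term keeps every term informative and makes cumulative
  frequencies strictly decrease with depth; each network gene is
  annotated to one seeded-random term.
- **Drug panel**: the reference drug targets hub nodes; decoys draw
  targets, toy-library SMILES and random typed sites uniformly. The
  optional planted synergist copies the reference's targets and SMILES
  and jitters its site coordinates by ~0.05 Å, so it should dominate
  every axis.
- **Gold instance**: a five-node path, a four-term ontology with
  annotation probabilities {1, 1/2, 1/4, 1/8}, SMILES `CCCCC`/`CCCC`,
  and one same-type site pair 1 Å apart. Every expected value
  (2e⁻², 0.4, 2/3, e⁻¹) is derived by hand in the manifest and asserted
  to 1e−5 by the tests and the acceptance script.

What passing these tests shows: the formulas, conventions and plumbing
are implemented correctly and deterministically. What it does not show:
that the scores predict clinical synergy on real pharmacology — the
fixtures have no biology in them, real target predictions are noisy, and
real pharmacophore data depend on conformer generation and alignment
choices that are out of scope here.

Problem sizes in the shipped tests and acceptance script (12-node oracle
graphs, 60-node screens, 100-seed recovery runs) were chosen so the full
suite completes in seconds while still exercising every code path; all
generators scale to larger instances through their parameters.

## Numerical conventions and degenerate inputs

- PageRank: tolerance 1e−10 (L1), max 10,000 iterations, uniform
  teleport.
- Distances are exact BFS hop counts; no weighted or diffusion variants.
- Empty target sets, empty site sets, unannotated terms, zero-margin
  contingency tables and infeasible design parameters raise typed errors
  with machine-checkable codes; recoverable conditions (unmapped
  targets, unannotated genes, missing structure data) warn with codes
  and degrade the affected axis to 0.
- Output tables are TSV with a fixed column order and floats at 6
  significant digits; rewriting identical results is byte-identical.

## Known limitations

- The centrality conventions and PageRank parameters for published
  screens of this kind are rarely reported; results are only comparable
  under the documented defaults.
- The 3D score is a Gaussian surrogate; absolute values are not
  comparable with proprietary volume-overlap implementations, only the
  induced ordering on a fixed input set is meaningful.
- Single-proportion Wald CIs can differ in the last decimal from other
  CI families (score, exact) that published trials sometimes use without
  saying so; the between-group difference is the robust quantity here.
- The screen treats axes as exchangeable after normalization; no
  axis weighting is offered because there is no principled default.
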