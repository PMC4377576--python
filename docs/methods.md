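# Methods

## The inference chain

The pipeline estimates the target space of a multi-compound agent in four
stages.

**1. Compound→target concordance scoring.** The scoring follows the
drugCIPHER-CS idea: drugs with similar chemical structure tend to bind
functionally related proteins, and functional relatedness between proteins
can be read off their distance in the protein interaction network. Both
notions are made comparable by expressing them against a fixed reference drug
panel. For compound *q* and protein *p*:

- chemical vector `x_i = |fp(q) ∩ fp(d_i)| / |fp(q) ∪ fp(d_i)|` (Tanimoto on
  binary fingerprints — the field-standard choice for 2D similarity);
- functional vector `y_i(p) = Σ_t κ(dist(p, t))` over drug *d_i*'s targets
  *t*, with κ a strictly decreasing distance kernel, κ(0) = 1.

The likelihood score is the Pearson correlation of *x* and *y(p)*. Scores
live in [−1, 1]; a protein is up-ranked only when its network proximity
pattern across the whole panel matches the compound's chemical similarity
pattern, which intrinsically down-weights promiscuous hub proteins that are
close to every drug's targets.

The kernel default is Gaussian-in-distance, κ(d) = exp(−d²), evaluated on
unweighted shortest-path lengths; unreachable targets and targets absent
from the network contribute 0. The kernel is isolated behind `KernelSpec`
(an exponential alternative exp(−d) is included) because only the strict
monotonicity matters for the sign structure of the score; on two-point
panels any strictly decreasing kernel yields identical rankings.

Undefined correlations — either vector constant, e.g. an isolated protein
with an all-zero proximity vector — are flagged rather than raised, and rank
after all defined scores. Ties are broken by symbol so rankings are
bit-reproducible; the tie comparison rounds scores to 1e-12 so that
mathematically exact ties (e.g. the ±1 correlations of two-point vectors)
are not split by floating-point noise.

**2. Herb profiles and the putative target space.** Per-herb target profiles
are the top k = 100 proteins by the herb-level score, where a protein's herb
score is the maximum over the herb's compounds (maximum chosen as the most
permissive aggregation — a single strong binder suffices for a formula-level
hypothesis; the source analyses leave this rule unstated). The profiles feed
the herb-overlap analysis only. The *putative target space* used for network
screening is the full ranked proteome (every protein with a defined score
for at least one compound), matching how the original analysis counted its
putative targets; callers can intersect with an external druggable list if
they have one.

**3. Topological screening.** The merged PPI is induced on putative ∪ known
disease targets; symbols absent from the PPI are kept as isolated nodes (they
can never pass the strict thresholds). Hubs are nodes with degree strictly
greater than twice the median degree. On the induced hub subnetwork, four
features are recomputed per node:

| feature | definition | scale |
|---|---|---|
| degree | incident edges | count |
| betweenness | shortest-path betweenness | normalised by (n−1)(n−2)/2 per connected component, ∈ [0,1] |
| closeness | Wasserman–Faust corrected closeness (reachable-set correction) | reported ×100 |
| k-core index | largest k surviving recursive deletion of degree < k vertices | integer |

Major hubs strictly exceed the median of all four features; candidate
targets are major hubs ∩ putative targets. The normalisation and scaling
choices are conventional and provably irrelevant to the screen: each
threshold is the median of the same quantity, so any strictly increasing
per-feature transform leaves the hub and major-hub sets unchanged (this
invariance is tested). Strict ">" is used in both screens; medians are
computed over the hub subnetwork, not the full network.

**4. Enrichment.** One-sided hypergeometric over-representation (equivalently
Fisher exact, greater) of the candidate set in each gene set, computed with
scipy's survival function; the universe defaults to all PPI proteins and is
overridable. Bonferroni multiplicity m counts the gene sets with nonzero
universe intersection. An optional EASE-style penalisation (test k−1 instead
of k) is off by default. Exact reported p-values from annotation services are
snapshot-dependent and are not reproduction targets.

## Synthetic data generator

The generator produces inputs with the statistical structure the chain
assumes, at the scale of the motivating study (preset `study_scale`):

| parameter | default | rationale |
|---|---|---|
| proteome | 1746 proteins | size of the druggable proteome in the motivating analysis |
| PPI model | preferential attachment, per-node attachment m ~ Geometric(1/8) | scale-free degree distribution with mean degree ~16, the density of merged multi-database human interactomes; the heavy-tailed attachment yields a deep, graded k-core hierarchy (a fixed-m model is m-degenerate — every core index saturates at m and the median k-core screen degenerates) |
| panel | 50 drugs × 4 targets | targets drawn from a module of 8 proteins within pairwise distance ≤ 2 (a centre plus neighbours), encoding "functionally related targets are network-local" |
| herbs | 5 herbs with 22/122/39/65/203 compounds (451 total) | per-herb compound counts of the motivating formula |
| compound fingerprints | length 512, 48 on-bits, per-bit flip rate 0.05 | each compound is a noisy copy of one parent panel drug; 5% noise keeps parent Tanimoto ≈ 0.6 vs ≈ 0.06 background |
| disease targets | 208, half drawn from planted drug modules | known-target list size of the motivating disease; the module half makes the disease recoverable |
| gene sets | 50 random (size 10–100) + `PLANTED_DISEASE` | the planted set equals the disease target set — an end-to-end positive control |

One root seed spawns independent per-stage substreams
(`numpy.random.SeedSequence.spawn`), so changing, say, the number of gene
sets cannot perturb the network; the whole bundle is a pure function of the
configuration. A `toy` preset (50 proteins) exists for fast tests and smoke
runs; at that size the screening cascade is usually empty, which is
expected.

**What the generator does not emulate.** Fingerprints are abstract bit sets
(no rings, scaffolds or chemistry); the PPI has no study bias, no false
positive/negative annotation structure, and drug modules are balls around a
centre rather than curated complexes or pathways; disease targets outside
the planted half are uniform. Passing tests therefore show the chain
recovers planted signal of the assumed form — not that the assumptions hold
for any particular real interactome or formula.

## Numerical and degenerate-input choices

- Gene identifiers are case-normalised symbols; no cross-database identifier
  mapping is attempted (none is recoverable from the motivating analyses).
- Self-loops are dropped on load with a logged count; edge provenance is a
  tag set per edge, never parallel edges.
- Tanimoto of two empty fingerprints is 0 (logged), not an error.
- Empty known-target unions warn rather than raise; an empty putative ∪
  known union, an empty universe, and correlation on vectors shorter than 2
  raise.
- The hypergeometric tail validates 0 ≤ k ≤ min(K, n) ≤ N and is exact to
  the brute-force summation for all N ≤ 30 (tested exhaustively).
- `run_all` writes every intermediate in a plain-text format and a
  `summary.json` that is byte-identical across reruns of the same
  configuration; dropped-record counts are part of the summary.

## Known limitations

- **Strict-median screening can be empty.** The k-core index is coarse; on
  realisations where more than half the hubs share the top core value, no
  node strictly exceeds the k-core median and the major-hub set is empty
  (about 1 in 12 seeds at study scale). This is a property of the strict
  four-median rule itself, faithfully implemented; downstream stages handle
  the empty set gracefully.
- The concordance score needs a panel of ≥ 2 drugs, and its resolution grows
  with panel diversity; panels whose drugs share targets produce correlated
  functional vectors and flatter rankings.
- The herb aggregation rule (max) and the proteome-wide putative set are
  documented design choices where the motivating analyses are silent; both
  are isolated and easily overridden.
- Problem sizes in the test suite are chosen to keep the full run to a few
  minutes: oracle comparisons use 100 random graphs of ≤ 8 nodes (where
  brute-force enumeration is exact and fast), calibration uses 1000
  replicates on a 1000-gene universe, and the planted-recovery check runs
  the full 451-compound, 1746-protein preset once.
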