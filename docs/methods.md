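# Methods

## Problem and model

`mina` operationalises a network-proximity hypothesis: genes predisposing
to the same heritable disorder tend to lie close together in the
whole-genome molecular interaction network, so a small set of established
disease genes (*seeds*) can nominate new candidates — the *connector*
genes needed to wire the seeds into one subnetwork. The workflow has
three statistical layers: a combinatorial search, a network-enrichment
score, and an LD-aware association test of the connectors.

Only **direct** interactions (physical relations: bind, cleave,
phosphorylate) are used for the search; indirect regulatory edges
(activate, inhibit) are parsed and retained but filtered out before
analysis. Edges are undirected: the action labels are annotations, not
algorithmic inputs, because the connector objective is purely
topological. Gene symbols are matched case-insensitively and stored
uppercase; unknown interaction kinds are conservatively demoted to
indirect so they cannot leak into the direct subgraph.

## Connector search

The search problem: among subnetworks with at most `max_nodes` genes
(default 35, the conventional fixed network size of commercial pathway
tools) whose induced direct subgraph is connected, maximise the number
of seeds contained, then minimise the number of non-seed connectors.
This is a node-budgeted Steiner problem and NP-hard, so the
implementation is a greedy heuristic chosen for determinism and
auditability:

1. distances are unweighted shortest-path hops in the direct subgraph,
   computed by BFS with sorted neighbour expansion (so results are
   independent of input order) and cached per source;
2. starting from each seed in turn, the tree repeatedly attaches the
   uncovered seed whose shortest path to the tree fits the remaining
   budget, preferring paths that (i) cover more uncovered seeds,
   (ii) add fewer new connectors, (iii) carry higher summed interactome
   degree, (iv) are lexicographically first — every tie at every choice
   point is broken lexicographically, so runs are bit-reproducible;
3. a pruning pass removes connectors that are redundant in the induced
   subgraph (the induced edges often short-circuit path detours);
4. the best multi-start result under the (seeds, −connectors) objective
   is kept.

Nearest-terminal insertion is the classic 2-approximation for Steiner
trees; with multi-start and pruning the heuristic matched exhaustive
subset search on 199 of 200 random ≤ 12-node instances in our
validation (the one miss is a tie between two components holding equally
many seeds, where the heuristic's lexicographic component choice picks
the costlier one).

Seeds missing from the interactome are reported on the result and
excluded from the seed total used for scoring — silently dropping them
would bias the enrichment p. Seeds split across graph components are
handled by searching the component holding most seeds and reporting the
rest as unplaced. When the minimal connecting structure is smaller than
the budget, optional *padding* fills the remaining slots with
highest-degree neighbours of current members, reproducing the
fixed-35-member network shape; padding is the default in the CLI and
pipeline (disable with `--no-pad` / `pad: false`) but off in the library
function, whose contract is the pure objective. With nine seeds and a
saturated budget, a padded network therefore always has 26 connectors.

Iterative extraction (`rank_networks`) removes the connectors of each
extracted network from the working graph, re-seeds the unplaced seeds,
and repeats; results are ranked by score descending.

## Network score

For a network of `n` genes holding `k` of the `K` seeds in an
interactome of `N` genes, the enrichment p is the hypergeometric upper
tail `P(X ≥ k)` and the score is `−log10 p` (score 2 ⇔ p = 0.01). The
universe is the loaded interactome, not the genome, because that is the
population the search draws from. The empirical null re-runs the search
on random seed sets of the same size:

* `uniform` — drawn uniformly without replacement;
* `degree_matched` (default) — each random gene is drawn from the degree
  decile of one observed seed. Deciles are rank-based (nodes sorted by
  degree and split into ten equal groups) rather than value-based, since
  scale-free degree distributions collapse value quantiles. Degree
  matching is the conservative standard for interactome nulls, where
  hubs otherwise dominate.

The empirical p uses the add-one rule
`(1 + #{permuted ≥ observed}) / (n_permutations + 1)`, which can never
report zero. A known limitation: the score is a coarsely discrete
statistic (it depends only on the small integers `n` and `k`, giving on
the order of ten distinct values under the null), so with ties counted
in the upper tail the empirical p is *conservative* — `P(p ≤ t) ≤ t`
holds, exact uniformity does not. The test suite asserts the
conservative validity; a uniformity check of the same p-values fails for
exactly this reason, which is a property of any permutation test on a
heavily tied statistic, not an implementation artifact.

`annotation_enrichment` provides a generic one-sided Fisher exact test
per annotation term with Benjamini–Hochberg adjustment; its output is
entirely determined by the annotation the user supplies.

## GWAS validation and replication

Gene windows extend the annotated gene body 100 kb up- and downstream
(clipped at position 1); a SNP belongs to every gene whose window
contains it. BED input (0-based half-open) is converted to the internal
1-based inclusive convention on read.

Independent SNPs per gene are the connected components of the graph
linking SNP pairs with D′ ≥ 0.8 (threshold inclusive); transitive
clustering was chosen over greedy tagging because it is
order-independent. D′ is computed from 2×2 haplotype counts as
`|D| / D_max` with the standard sign-dependent normaliser, or read from
a precomputed table; obtaining reference-panel haplotypes is the user's
concern, keeping the tool fully offline.

Per-gene correction is Bonferroni with the gene's independent-SNP count
as denominator, applied to the gene's smallest p-value and capped at 1;
genes with no assigned SNPs are reported untested rather than dropped.
SNPs whose per-gene corrected p clears 0.05 are carried into the
replication dataset, where the Bonferroni denominator is the number of
independent candidate SNPs carried forward. p-values recorded as 0 are
floored at the dataset's smallest positive value with a warning.

Per-gene correction controls each gene's error rate, not the family of
candidates: with ~26 candidates a few false validations are expected by
design, and it is the replication pass that controls the candidate-wide
error. The pipeline therefore treats "validated" (primary dataset) and
"replicated" (secondary dataset) as distinct statuses in the report.

## Synthetic data

The generator emulates the study conditions end to end with controlled
ground truth:

* **Interactome** — a Barabási–Albert preferential-attachment background
  (attachment parameter 2) over the non-seed genes gives the scale-free,
  hub-dominated topology of real interactomes. A connected scaffold of
  planted connector genes (default 8) is embedded in the background and
  each of the default 9 seeds attaches to one planted connector
  round-robin, so every connector anchors at least one seed and the
  planted module is the exact optimum of the search objective. Noise
  edges (10% of the structured edge count) are added uniformly among the
  *non-seed* genes: noise on the terminals themselves would change the
  true optimum and make the planted "truth" label wrong, so the design
  keeps the benchmark identifiable at any noise level. A further 5%
  indirect edges (touching any genes, seeds included) exercise the
  direct-interaction filter. Default universe: 500 genes — large enough
  for saturated 35-node networks and heavy-tailed degrees, small enough
  that the full test suite runs in minutes.
* **GWAS** — each gene carries 10 SNPs spread over its ±100 kb window,
  grouped into LD blocks of 5 with within-block D′ = 0.9 and zero
  across blocks. A block shares a single p ~ U(0,1): each SNP's marginal
  p is uniform while the within-block dependence matches the high D′,
  which is what makes the per-gene Bonferroni over block counts
  calibrated (≈ 5% of null genes flagged at α = 0.05, confirmed by
  simulation in the tests). The causal gene (default: the first planted
  connector) carries `causal_p` (default 10⁻⁶) across its first block.
  The replication dataset redraws all null blocks with a shifted RNG
  stream; only the planted signal persists.
* Genes sit on one synthetic chromosome spaced 250 kb apart, so default
  windows never overlap; real genomes' overlapping windows are exercised
  by dedicated unit fixtures instead.

What the synthetic data does *not* model: realistic genome coordinates
or recombination maps, coalescent LD decay (the association layer only
consumes pairwise D′, so block-constant LD is the minimal sufficient
structure), directed or weighted interactions, and literature bias in
interactome coverage. Passing the planted-recovery tests therefore shows
the machinery is correct under its stated model, not that real
interactomes satisfy the model.

## Numerical choices and degenerate inputs

* Hypergeometric tails come from `scipy.stats.hypergeom.sf`; p-values
  are clamped to `(0, 1]` before the log transform.
* `k = 0` seeds gives p = 1, score 0; bound violations raise rather
  than clip.
* Hub flagging uses a strict comparison against the requested percentile
  of the whole-interactome degree distribution, so a degenerate
  all-equal-degree network flags nobody; percentile 0 is the documented
  flag-everything case.
* Self-loops are dropped with a warning; duplicate edge records collapse
  with reference counts summed; a pair recorded as both direct and
  indirect survives direct filtering once, as direct.
* D′ of a monomorphic locus raises (`undefined D-prime`); D = 0 returns
  D′ = 0 without touching the normaliser.
* All randomness flows through `numpy.random.default_rng` seeds carried
  in `SyntheticSpec.rng_seed` / `rng_seed` arguments; identical seeds
  give bit-identical outputs, and pipeline reruns are byte-identical.

## Validation problem sizes

The packaged checks use deliberately scaled problem sizes chosen as the
package's own test conditions: exhaustive-search equivalence on 200
random graphs of ≤ 12 nodes; LD clustering against a graph-components
oracle on all LD graphs of ≤ 6 SNPs; null calibration with 200
replicates × 99 permutations on a 300-gene interactome with a shared
shortest-path cache; end-to-end planted-truth recovery over 100 seeded
replicates at the generator defaults above.
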