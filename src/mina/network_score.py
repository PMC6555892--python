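"""Non-randomness of a candidate network.

Two complementary measures:

* an analytic enrichment probability — the upper-tail hypergeometric
  chance that a network of ``n`` genes drawn from the loaded interactome
  (universe ``N``) captures at least the observed number ``k`` of the
  ``K`` seed genes — reported as a *network score*, ``-log10(p)``, so a
  score of 2 means a 1-in-100 chance of arising at random;
* an empirical permutation null — re-run the connector search on
  randomly drawn seed sets (uniform or degree-decile matched) and rank
  the observed score among the permuted ones.

The universe is the interactome node set, not the genome: the random
draw the score models happens on the network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MinaError
from .interactome import Interactome


@dataclass(frozen=True)
class NetworkScore:
    """Enrichment probability and its -log10 score."""

    p_enrichment: float
    score: float
    p_empirical: float | None = None
    n_permutations: int | None = None

    @classmethod
    def from_p(cls, p_enrichment: float) -> "NetworkScore":
        if not 0.0 < p_enrichment <= 1.0:
            raise MinaError("enrichment p must be in (0, 1]")
        return cls(p_enrichment=p_enrichment, score=-math.log10(p_enrichment))


def enrichment_score(
    n_network: int,
    k_seeds_in: int,
    N_universe: int,
    K_seeds_total: int,
) -> NetworkScore:
    """Hypergeometric upper-tail enrichment of seeds in a network.

    ``p = P(X >= k_seeds_in)`` for ``X ~ Hypergeom(N_universe,
    K_seeds_total, n_network)``; the score is ``-log10(p)``.  A network
    containing no seeds scores 0 (p = 1).
    """
    if not 0 <= k_seeds_in <= min(n_network, K_seeds_total):
        raise MinaError(
            f"k_seeds_in={k_seeds_in} outside [0, min(n={n_network}, K={K_seeds_total})]"
        )
    if n_network > N_universe or K_seeds_total > N_universe:
        raise MinaError("network or seed count exceeds universe size")
    if n_network < 0 or N_universe < 1:
        raise MinaError("sizes must be positive")
    p = float(stats.hypergeom.sf(k_seeds_in - 1, N_universe, K_seeds_total, n_network))
    p = min(1.0, max(p, 5e-324))
    return NetworkScore.from_p(p)


@dataclass
class PermutationNull:
    """Empirical score distribution under randomly drawn seed sets."""

    scores: np.ndarray
    observed_score: float
    p_empirical: float
    n_permutations: int
    matching: str


def permutation_null(
    net: Interactome,
    seeds=None,
    *,
    seed_count: int | None = None,
    n_permutations: int = 999,
    matching: str = "degree_matched",
    rng_seed: int = 0,
    max_nodes: int = 35,
    pad: bool = False,
    observed_score: float | None = None,
    paths=None,
) -> PermutationNull:
    """Permutation test of a network score against random seed sets.

    For each permutation, ``seed_count`` genes are drawn from the
    interactome — uniformly, or stratified by degree decile so each
    random gene matches the degree bin of one observed seed — the
    connector search is re-run, and its enrichment score recorded.  The
    empirical p uses the add-one rule
    ``(1 + #{permuted >= observed}) / (n_permutations + 1)``.

    ``seeds`` (the observed seed set) is required for degree matching
    and, unless ``observed_score`` is given, to compute the observed
    score; with uniform matching and an explicit ``observed_score`` a
    bare ``seed_count`` suffices.
    """
    from .connector_search import (
        SeedSet,
        ShortestPathCache,
        find_connector_network,
    )

    if matching not in ("uniform", "degree_matched"):
        raise MinaError(f"unknown matching scheme {matching!r}")
    if n_permutations < 1:
        raise MinaError("n_permutations must be >= 1")

    nodes = sorted(net.nodes)
    if seeds is not None and not isinstance(seeds, SeedSet):
        seeds = SeedSet(tuple(seeds))
    if seeds is not None:
        seed_count = len([s for s in seeds if s in net])
    if seed_count is None:
        raise MinaError("provide seeds or seed_count")
    if seed_count > len(nodes):
        raise MinaError("seed_count exceeds interactome size")
    if matching == "degree_matched" and seeds is None:
        raise MinaError("degree matching requires the observed seed set")

    if paths is None:
        paths = ShortestPathCache(net.graph)
    if observed_score is None:
        if seeds is None:
            raise MinaError("provide seeds or observed_score")
        observed_score = find_connector_network(
            net, seeds, max_nodes=max_nodes, pad=pad, paths=paths
        ).score

    rng = np.random.default_rng(rng_seed)
    sampler = _make_sampler(net, nodes, seeds, seed_count, matching)
    scores = np.empty(n_permutations)
    for i in range(n_permutations):
        drawn = sampler(rng)
        network = find_connector_network(
            net, SeedSet(tuple(drawn)), max_nodes=max_nodes, pad=pad, paths=paths
        )
        scores[i] = network.score
    p_emp = (1.0 + int(np.sum(scores >= observed_score))) / (n_permutations + 1.0)
    return PermutationNull(
        scores=scores,
        observed_score=float(observed_score),
        p_empirical=float(p_emp),
        n_permutations=n_permutations,
        matching=matching,
    )


def _make_sampler(net, nodes, seeds, seed_count, matching):
    if matching == "uniform":
        pool = np.array(nodes)

        def sample(rng):
            return rng.choice(pool, size=seed_count, replace=False)

        return sample

    # degree-decile matching: each random gene is drawn from the degree
    # decile of one observed seed, without replacement across the draw.
    # Deciles are rank-based (nodes sorted by degree, split into ten
    # equal groups) so heavy-tailed degree distributions still stratify.
    order = sorted(nodes, key=lambda n: (net.graph.degree[n], n))
    bin_of = {n: (10 * i) // len(order) for i, n in enumerate(order)}
    bins: dict[int, list[str]] = {}
    for n in nodes:
        bins.setdefault(bin_of[n], []).append(n)
    seed_bins = [bin_of[s] for s in seeds if s in net]

    def sample(rng):
        chosen: list[str] = []
        taken: set[str] = set()
        for b in seed_bins:
            pool = [n for n in bins[b] if n not in taken]
            step = 1
            while not pool:  # decile exhausted: widen to neighbouring bins
                lo, hi = b - step, b + step
                pool = [
                    n
                    for bb in (lo, hi)
                    if bb in bins
                    for n in bins[bb]
                    if n not in taken
                ]
                step += 1
            pick = pool[rng.integers(len(pool))]
            chosen.append(pick)
            taken.add(pick)
        return chosen

    return sample


def annotation_enrichment(
    gene_set: set[str],
    annotation: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of a gene set in annotation terms.

    Returns one row per term — overlap size, Fisher p (greater tail) and
    a Benjamini-Hochberg adjusted q — sorted by p ascending.  Purely
    generic: results depend entirely on the annotation supplied.
    """
    if not universe:
        raise MinaError("empty universe")
    gene_set = {g.upper() for g in gene_set}
    universe = {g.upper() for g in universe}
    if not gene_set <= universe:
        raise MinaError("gene_set not contained in universe")
    rows = []
    for term in sorted(annotation):
        members = {g.upper() for g in annotation[term]} & universe
        a = len(gene_set & members)
        b = len(gene_set - members)
        c = len(members - gene_set)
        d = len(universe) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"term": term, "overlap": a, "p_fisher": float(p)})
    df = pd.DataFrame(rows)
    if len(df):
        df["q_bh"] = stats.false_discovery_control(df["p_fisher"], method="bh")
        df = df.sort_values(["p_fisher", "term"]).reset_index(drop=True)
    return df
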