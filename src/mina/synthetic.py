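"""Synthetic inputs with planted ground truth.

Every pipeline stage is testable offline: this module generates

* an interactome — a scale-free preferential-attachment background over
  the non-seed genes, a connected scaffold of *planted connector* genes,
  seed genes each wired to at least one planted connector, and uniform
  random noise edges on top;
* gene coordinates on one synthetic chromosome, spaced widely enough
  that the default +/-100 kb association windows never overlap;
* GWAS summary statistics with block-constant LD — SNPs fall into LD
  blocks sharing one D' value (and one association p-value, i.e.
  complete within-block dependence), across blocks D' = 0 — plus an
  optional planted causal gene whose index block carries a small p;
* a matching replication dataset in which only the causal signal
  persists.

Defaults emulate the motivating study's conditions: nine seed genes on
a whole-genome-scale network, a handful of connector genes linking
them, and per-gene SNP panels whose LD leaves a few independent tests.
The block-constant LD model is deliberately minimal — the association
layer only ever consumes pairwise D', so richer coalescent structure
would add nothing the pipeline could see.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import MinaError
from .gwas_assoc import GeneRecord, LdTable, SnpAssociation
from .interactome import Interactome

# fraction of extra regulatory (indirect) edges added so the
# direct-interaction filter always has something to remove
_INDIRECT_FRACTION = 0.05

_GENE_LENGTH = 20_000   # bases
_GENE_SPACING = 250_000  # window half-width is 100 kb, so windows never overlap


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study.

    ``noise_edge_fraction`` is the number of uniform random extra edges
    as a fraction of the structured edge count; ``ld_block_size`` SNPs
    share one LD block (within-block D' = ``within_block_dprime``,
    across blocks 0).  ``causal_gene`` defaults to the first planted
    connector; set it to ``""`` for a fully null study.
    """

    n_genes: int = 500
    attachment_parameter: int = 2
    n_seeds: int = 9
    n_planted_connectors: int = 8
    noise_edge_fraction: float = 0.1
    n_snps_per_gene: int = 10
    ld_block_size: int = 5
    within_block_dprime: float = 0.9
    causal_gene: str | None = None
    causal_p: float = 1e-6
    rng_seed: int = 17

    def __post_init__(self):
        if self.n_seeds < 1 or self.n_planted_connectors < 1:
            raise MinaError("need at least one seed and one planted connector")
        if self.n_seeds + self.n_planted_connectors > self.n_genes:
            raise MinaError("seeds + planted connectors exceed n_genes")
        if not 0.0 <= self.within_block_dprime <= 1.0:
            raise MinaError("within_block_dprime must be in [0, 1]")
        if self.noise_edge_fraction < 0:
            raise MinaError("noise_edge_fraction must be >= 0")
        if self.n_genes - self.n_seeds <= self.attachment_parameter:
            raise MinaError("background too small for attachment parameter")


def gene_names(spec: SyntheticSpec) -> list[str]:
    return [f"G{i:04d}" for i in range(spec.n_genes)]


def make_interactome(spec: SyntheticSpec) -> tuple[Interactome, dict]:
    """Generate the interactome and its planted truth.

    Seeds are the first ``n_seeds`` gene names and receive no background
    edges of their own: each attaches (directly) to one planted
    connector, round-robin, so with at least as many seeds as connectors
    every connector anchors a seed and the minimal Steiner structure is
    exactly the planted scaffold.  Noise edges may touch any gene.
    Reproducible from ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    names = gene_names(spec)
    seeds = names[: spec.n_seeds]
    background_names = names[spec.n_seeds :]

    ba_seed = int(rng.integers(2**31))
    background = nx.barabasi_albert_graph(
        len(background_names), spec.attachment_parameter, seed=ba_seed
    )
    net = Interactome()
    for name in names:
        net.add_node(name)
    for i, j in background.edges:
        net.add_edge(background_names[i], background_names[j], "direct", "binding")

    # planted connectors: a random connected scaffold inside the background
    connectors = sorted(
        str(g)
        for g in rng.choice(
            background_names, size=spec.n_planted_connectors, replace=False
        )
    )
    order = list(rng.permutation(connectors))
    for a, b in zip(order, order[1:]):
        net.add_edge(a, b, "direct", "binding")

    for i, seed in enumerate(seeds):
        net.add_edge(seed, connectors[i % len(connectors)], "direct", "binding")

    # noise rewires the background only: seeds keep their designed wiring,
    # so the planted module stays the identifiable optimum at any noise level
    n_structured = net.number_of_edges()
    n_noise = round(spec.noise_edge_fraction * n_structured)
    added = 0
    while added < n_noise:
        a, b = rng.choice(background_names, size=2, replace=False)
        if not net.has_edge(a, b):
            net.add_edge(a, b, "direct", "binding")
            added += 1

    n_indirect = round(_INDIRECT_FRACTION * n_structured)
    added = 0
    while added < n_indirect:
        a, b = rng.choice(names, size=2, replace=False)
        if not net.has_edge(a, b):
            net.add_edge(a, b, "indirect", "activate")
            added += 1

    truth = {"seeds": list(seeds), "connectors": list(connectors)}
    return net, truth


def make_genes(spec: SyntheticSpec) -> list[GeneRecord]:
    """Lay the genes along one synthetic chromosome, widely spaced."""
    genes = []
    for i, name in enumerate(gene_names(spec)):
        start = i * _GENE_SPACING + 1
        genes.append(
            GeneRecord(symbol=name, chrom="chr1", start=start,
                       end=start + _GENE_LENGTH - 1)
        )
    return genes


def make_gwas(
    spec: SyntheticSpec,
    genes: list[GeneRecord],
    truth: dict | None = None,
    rng_seed: int | None = None,
) -> tuple[list[SnpAssociation], LdTable, dict]:
    """Generate summary statistics and an LD table over the gene set.

    Each gene carries ``n_snps_per_gene`` SNPs spread across its window,
    grouped into LD blocks of ``ld_block_size``.  Null blocks draw one
    p ~ Uniform(0, 1) shared by the block's SNPs (so each SNP's marginal
    p is uniform while the per-block dependence matches the high
    within-block D'); the causal gene's first block carries ``causal_p``
    at its index SNP (and, being in complete LD, across the block).
    """
    rng = np.random.default_rng(spec.rng_seed if rng_seed is None else rng_seed)
    causal = spec.causal_gene
    if causal is None:
        if truth is None or not truth.get("connectors"):
            raise MinaError("causal_gene unset and no planted connectors supplied")
        causal = truth["connectors"][0]
    if causal and causal not in {g.symbol for g in genes}:
        raise MinaError(f"causal gene {causal!r} not in gene list")

    snps: list[SnpAssociation] = []
    ld = LdTable()
    causal_snp = None
    for gi, gene in enumerate(genes):
        ws, we = gene.window()
        positions = np.linspace(ws, we, spec.n_snps_per_gene).astype(int)
        ids = [f"rs{gi:04d}{j:02d}" for j in range(spec.n_snps_per_gene)]
        blocks = [
            ids[b : b + spec.ld_block_size]
            for b in range(0, len(ids), spec.ld_block_size)
        ]
        for bi, block in enumerate(blocks):
            p_block = float(rng.uniform()) or 5e-324  # keep p in (0, 1]
            if gene.symbol == causal and bi == 0:
                p_block = spec.causal_p
                causal_snp = block[0]
            for a_i, a in enumerate(block):
                for b in block[a_i + 1 :]:
                    ld.set(a, b, spec.within_block_dprime)
            for snp_id, pos in zip(block, positions[ids.index(block[0]) :]):
                snps.append(
                    SnpAssociation(
                        snp_id=snp_id, chrom=gene.chrom, pos=int(pos),
                        p_value=p_block,
                    )
                )
    gwas_truth = {"causal_gene": causal or None, "causal_snp": causal_snp}
    return snps, ld, gwas_truth


def write_bundle(spec: SyntheticSpec, out_dir: str | Path) -> dict:
    """Write a complete input bundle for the pipeline.

    Produces ``edges.tsv``, ``seeds.txt``, ``genes.bed``, ``gwas.tsv``,
    ``gwas_replication.tsv``, ``ld.tsv`` and ``truth.json`` under
    ``out_dir``; returns the truth dictionary.
    """
    from .interactome import write_network

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net, truth = make_interactome(spec)
    genes = make_genes(spec)
    primary, ld, gwas_truth = make_gwas(spec, genes, truth)
    replication, _, _ = make_gwas(spec, genes, truth, rng_seed=spec.rng_seed + 1)
    truth = {**truth, **gwas_truth, "spec": asdict(spec)}

    write_network(net, out / "edges.tsv", dialect="tsv")
    (out / "seeds.txt").write_text("\n".join(truth["seeds"]) + "\n")
    with open(out / "genes.bed", "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.symbol}\n")
    _write_gwas(primary, out / "gwas.tsv")
    _write_gwas(replication, out / "gwas_replication.tsv")
    with open(out / "ld.tsv", "w") as fh:
        fh.write("SNP_A\tSNP_B\tDPRIME\n")
        for a, b, v in ld.items():
            fh.write(f"{a}\t{b}\t{v:g}\n")
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return truth


def _write_gwas(snps: list[SnpAssociation], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("SNP\tCHR\tPOS\tP\n")
        for s in snps:
            fh.write(f"{s.snp_id}\t{s.chrom}\t{s.pos}\t{s.p_value:.10g}\n")
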