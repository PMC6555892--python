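"""End-to-end orchestration: seeds -> networks -> score -> association.

``run`` executes the whole workflow in order — read the seed list,
build and score-rank connector networks, select the top-ranked one,
assign GWAS SNPs to the candidate (connector) genes through their
windows, validate per-gene association in the primary dataset, and
replicate the significant SNPs in a second dataset when one is given.
The report records every parameter and a SHA-256 checksum of every
input, so a rerun with identical inputs is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import gwas_assoc, network_score
from .connector_search import SeedSet, find_connector_network, rank_networks
from .errors import MinaError
from .interactome import read_edge_list, write_network


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    edges: str
    seeds: str
    genes: str
    gwas: str
    ld: str
    gwas_replication: str | None = None
    edges_dialect: str = "tsv"
    max_nodes: int = 35
    max_networks: int = 10
    pad: bool = True
    window_kb: int = 100
    dprime_threshold: float = 0.8
    permutations: int = 99
    matching: str = "degree_matched"
    rng_seed: int = 17

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise MinaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("edges", "seeds", "genes", "gwas", "ld"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise MinaError(f"config: {name} file not found: {path}")
        if self.gwas_replication and not Path(self.gwas_replication).exists():
            raise MinaError(
                f"config: replication file not found: {self.gwas_replication}"
            )
        if self.max_nodes < 2:
            raise MinaError("config: max_nodes must be >= 2")
        if not 0.0 <= self.dprime_threshold <= 1.0:
            raise MinaError("config: dprime_threshold must be in [0, 1]")
        if self.window_kb < 0:
            raise MinaError("config: window_kb must be >= 0")


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(value):
    if isinstance(value, float) and math.isnan(value):
        return None
    return value


def run(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the pipeline; returns (and optionally writes) the report.

    Outputs under ``out_dir``: ``report.json``, ``network.graphml`` and
    ``network_nodes.tsv`` for the selected network, ``gene_association.tsv``
    and, when replication ran, ``replication.tsv``.  Files are written
    atomically (temp file + rename) and removed again if a later stage
    fails.
    """
    config.validate()
    written: list[Path] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    try:
        return _run_stages(config, out, written)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, MinaError):
            raise
        raise MinaError(f"pipeline failed: {exc}") from exc


def _run_stages(config: RunConfig, out: Path | None, written: list[Path]) -> dict:
    # step 1-2: load inputs, build and rank candidate networks
    try:
        net = read_edge_list(config.edges, dialect=config.edges_dialect)
        seeds = SeedSet.from_file(config.seeds)
    except MinaError as exc:
        raise MinaError(f"[input] {exc}") from exc
    direct = net.direct_subgraph()
    try:
        ranked = rank_networks(
            direct,
            seeds,
            max_nodes=config.max_nodes,
            max_networks=config.max_networks,
            pad=config.pad,
        )
    except MinaError as exc:
        raise MinaError(f"[network] {exc}") from exc

    # step 3: the largest, highest-scoring network carries forward
    selected = ranked[0]
    null = network_score.permutation_null(
        direct,
        seeds=SeedSet(tuple(s for s in seeds if s in direct)),
        n_permutations=config.permutations,
        matching=config.matching,
        rng_seed=config.rng_seed,
        max_nodes=config.max_nodes,
        pad=False,
        observed_score=None,
    ) if config.permutations > 0 else None

    # step 4: candidate genes are the connectors; windows and SNPs
    try:
        all_genes = gwas_assoc.read_gene_bed(config.genes)
        gwas = gwas_assoc.read_gwas(config.gwas)
        ld = gwas_assoc.LdTable.from_tsv(config.ld)
    except MinaError as exc:
        raise MinaError(f"[association-input] {exc}") from exc
    candidates = sorted(selected.connector_nodes)
    candidate_genes = [g for g in all_genes if g.symbol in candidates]
    missing_coords = sorted(set(candidates) - {g.symbol for g in candidate_genes})

    # step 5: validation in the primary dataset
    summary = gwas_assoc.summarize_genes(
        candidate_genes, gwas, ld,
        window_kb=config.window_kb, threshold=config.dprime_threshold,
    )
    carried = gwas_assoc.significant_snps(
        candidate_genes, gwas, ld,
        window_kb=config.window_kb, threshold=config.dprime_threshold,
    )

    # step 6: replication in the secondary dataset, when provided
    replication = None
    if config.gwas_replication:
        try:
            second = gwas_assoc.read_gwas(config.gwas_replication)
        except MinaError as exc:
            raise MinaError(f"[replication] {exc}") from exc
        replication = gwas_assoc.replicate(
            carried, second, ld, threshold=config.dprime_threshold
        )

    report = {
        "parameters": asdict(config),
        "inputs": {
            name: {"path": str(getattr(config, name)),
                   "sha256": _checksum(getattr(config, name))}
            for name in ("edges", "seeds", "genes", "gwas", "ld")
        },
        "networks": [
            {
                "rank": n.rank,
                "n_nodes": n.n_nodes,
                "seed_nodes": sorted(n.seed_nodes),
                "connector_nodes": sorted(n.connector_nodes),
                "score": n.score,
            }
            for n in ranked
        ],
        "selected_network": {
            "rank": selected.rank,
            "n_nodes": selected.n_nodes,
            "seed_nodes": sorted(selected.seed_nodes),
            "connector_nodes": candidates,
            "score": selected.score,
            "missing_seeds": list(selected.missing_seeds),
            "unplaced_seeds": list(selected.unplaced_seeds),
        },
        "permutation_null": (
            {
                "p_empirical": null.p_empirical,
                "observed_score": null.observed_score,
                "n_permutations": null.n_permutations,
                "matching": null.matching,
            }
            if null is not None
            else {"status": "not run"}
        ),
        "validation": {
            "candidates_without_coordinates": missing_coords,
            "genes": [
                {k: _jsonable(v) for k, v in row.items()}
                for row in summary.to_dict(orient="records")
            ],
            "significant_genes": sorted(
                summary.loc[summary["significant"], "symbol"]
            ),
        },
        "replication": (
            {
                "snps": [
                    {k: _jsonable(v) for k, v in row.items()}
                    for row in replication.to_dict(orient="records")
                ],
                "replicated_genes": sorted(
                    replication.loc[
                        replication["status"] == "replicated", "gene"
                    ].unique()
                ),
            }
            if replication is not None
            else {"status": "not run"}
        ),
    }
    if config.gwas_replication:
        report["inputs"]["gwas_replication"] = {
            "path": str(config.gwas_replication),
            "sha256": _checksum(config.gwas_replication),
        }

    if out is not None:
        _atomic_write(
            out / "report.json",
            json.dumps(report, indent=2, sort_keys=True) + "\n",
            written,
        )
        graphml = out / "network.graphml"
        write_network(selected, graphml, dialect="graphml")
        written.append(graphml)
        _atomic_write(
            out / "network_nodes.tsv",
            _node_table(selected, direct),
            written,
        )
        _atomic_write(
            out / "gene_association.tsv",
            summary.to_csv(sep="\t", index=False),
            written,
        )
        if replication is not None:
            _atomic_write(
                out / "replication.tsv",
                replication.to_csv(sep="\t", index=False),
                written,
            )
    return report


def _node_table(network, interactome) -> str:
    lines = ["gene\trole\tdegree_in_network\tdegree_in_interactome"]
    for gene in sorted(network.nodes):
        role = "seed" if gene in network.seed_nodes else "connector"
        lines.append(
            f"{gene}\t{role}\t{network.graph.degree[gene]}"
            f"\t{interactome.graph.degree[gene]}"
        )
    return "\n".join(lines) + "\n"


def _atomic_write(path: Path, text: str, written: list[Path]) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    tmp.replace(path)
    written.append(path)
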