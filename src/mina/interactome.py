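"""Graph model for whole-genome molecular interaction networks.

An :class:`Interactome` is an undirected graph over gene symbols.  Each
edge carries one or more *interaction kinds* — ``direct`` for physical
molecular relations (binding, cleavage, phosphorylation) or ``indirect``
for regulatory ones (activation, inhibition) — together with a free-text
action label and a reference count.  Connector-network search operates on
the direct subgraph only; the indirect edges are kept so the loaded
network remains a faithful record of its source.

Gene symbols are case-normalised to uppercase on input, self-loops are
dropped with a warning, and duplicate records of the same edge are
collapsed with their reference counts summed.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import MinaError, ParseError

DIRECT = "direct"
INDIRECT = "indirect"
_KINDS = (DIRECT, INDIRECT)


class Interactome:
    """Undirected labelled interaction graph over gene symbols.

    Parameters
    ----------
    graph
        Optional pre-built :class:`networkx.Graph`.  Edge attributes must
        follow the internal convention: ``kinds`` maps interaction kind to
        a reference count, ``actions`` maps kind to an action label.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- construction -------------------------------------------------

    def add_node(self, symbol: str) -> str:
        sym = _normalise(symbol)
        self.graph.add_node(sym)
        return sym

    def add_edge(
        self,
        a: str,
        b: str,
        kind: str = DIRECT,
        action: str = "",
        nref: int = 1,
    ) -> bool:
        """Add one interaction record; returns False for a dropped self-loop.

        Unknown kinds are conservatively mapped to ``indirect`` with a
        warning.  Repeated records of the same (pair, kind) accumulate
        their reference counts.
        """
        a, b = _normalise(a), _normalise(b)
        if a == b:
            warnings.warn(f"self-loop {a}-{b} dropped", stacklevel=2)
            self.graph.add_node(a)
            return False
        kind = kind.strip().lower()
        if kind not in _KINDS:
            warnings.warn(
                f"unknown interaction kind {kind!r} for {a}-{b}; treated as indirect",
                stacklevel=2,
            )
            kind = INDIRECT
        if nref < 0:
            raise MinaError(f"negative reference count for edge {a}-{b}")
        if self.graph.has_edge(a, b):
            data = self.graph.edges[a, b]
            data["kinds"][kind] = data["kinds"].get(kind, 0) + nref
            data["actions"].setdefault(kind, action)
        else:
            self.graph.add_edge(a, b, kinds={kind: nref}, actions={kind: action})
        return True

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_kinds(self, a: str, b: str) -> dict[str, int]:
        return dict(self.graph.edges[_normalise(a), _normalise(b)]["kinds"])

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(_normalise(a), _normalise(b))

    def __contains__(self, symbol: str) -> bool:
        return _normalise(symbol) in self.graph

    def __eq__(self, other) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        if self.nodes != other.nodes:
            return False
        mine = {frozenset(e): d["kinds"] for *e, d in self.graph.edges(data=True)}
        theirs = {frozenset(e): d["kinds"] for *e, d in other.graph.edges(data=True)}
        return mine == theirs

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<Interactome {self.number_of_nodes()} genes,"
            f" {self.number_of_edges()} edges>"
        )

    # -- the direct-interaction filter --------------------------------

    def direct_subgraph(self) -> "Interactome":
        """Subgraph restricted to physical (direct) interactions.

        Every node is retained — an isolated gene is still a candidate
        with zero degree — but only edges carrying the ``direct`` kind
        survive, and they survive with that kind alone.  The operation is
        idempotent.
        """
        out = nx.Graph()
        out.add_nodes_from(self.graph.nodes)
        for a, b, data in self.graph.edges(data=True):
            if DIRECT in data["kinds"]:
                out.add_edge(
                    a,
                    b,
                    kinds={DIRECT: data["kinds"][DIRECT]},
                    actions={DIRECT: data["actions"].get(DIRECT, "")},
                )
        return Interactome(out)


def _normalise(symbol: str) -> str:
    sym = symbol.strip().upper()
    if not sym:
        raise MinaError("empty gene symbol")
    return sym


# ---------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------

def read_edge_list(
    path: str | Path,
    dialect: str = "tsv",
    sif_kind_map: Mapping[str, str] | None = None,
) -> Interactome:
    """Read an interaction network from a TSV edge list or a SIF file.

    TSV columns are ``geneA geneB kind [action [nref]]``; lines starting
    with ``#`` are comments and a single-token line declares an isolated
    node.  SIF lines are ``nodeA relation nodeB...``
    (whitespace-separated, multiple targets allowed); the relation is kept
    as the action label and mapped to direct/indirect through
    ``sif_kind_map`` (unmapped relations become indirect with a warning).
    """
    path = Path(path)
    if dialect not in ("tsv", "sif"):
        raise MinaError(f"unknown edge-list dialect {dialect!r}")
    net = Interactome()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if dialect == "tsv":
                _parse_tsv_line(net, line, lineno, path)
            else:
                _parse_sif_line(net, line, lineno, path, sif_kind_map or {})
    if net.number_of_nodes() == 0:
        raise ParseError(f"{path}: empty interactome")
    return net


def _parse_tsv_line(net: Interactome, line: str, lineno: int, path: Path) -> None:
    fields = line.split("\t")
    if len(fields) == 1 and " " in line:  # tolerate space-separated files
        fields = line.split()
    if len(fields) == 1:  # single token: an isolated node
        net.add_node(fields[0])
        return
    if len(fields) < 3:
        raise ParseError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
    a, b, kind = fields[0], fields[1], fields[2]
    action = fields[3] if len(fields) > 3 else ""
    try:
        nref = int(fields[4]) if len(fields) > 4 else 1
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer reference count {fields[4]!r}")
    try:
        net.add_edge(a, b, kind=kind, action=action, nref=nref)
    except MinaError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from exc


def _parse_sif_line(
    net: Interactome,
    line: str,
    lineno: int,
    path: Path,
    kind_map: Mapping[str, str],
) -> None:
    fields = line.split()
    if len(fields) == 1:
        net.add_node(fields[0])
        return
    if len(fields) < 3:
        raise ParseError(f"{path}:{lineno}: SIF line needs 'node relation node'")
    src, relation = fields[0], fields[1]
    kind = kind_map.get(relation, INDIRECT)
    if relation not in kind_map:
        warnings.warn(
            f"{path}:{lineno}: SIF relation {relation!r} not in kind map;"
            " treated as indirect",
            stacklevel=3,
        )
    for target in fields[2:]:
        try:
            net.add_edge(src, target, kind=kind, action=relation)
        except MinaError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc


def read_graphml(path: str | Path) -> tuple[Interactome, dict[str, str]]:
    """Read a GraphML file written by :func:`write_network`.

    Returns the interactome together with the node role map
    (``seed``/``connector``) when the file carries one.
    """
    g = nx.read_graphml(Path(path))
    net = Interactome()
    roles: dict[str, str] = {}
    for node, data in g.nodes(data=True):
        sym = net.add_node(node)
        if "role" in data:
            roles[sym] = data["role"]
    for a, b, data in g.edges(data=True):
        for kind in str(data.get("kind", DIRECT)).split("|"):
            net.add_edge(
                a,
                b,
                kind=kind,
                action=str(data.get("action", "")),
                nref=int(data.get("nref", 1)),
            )
    return net, roles


# ---------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------

def write_network(net, path: str | Path, dialect: str = "tsv") -> None:
    """Write a network to ``tsv``, ``sif`` or ``graphml``.

    Accepts an :class:`Interactome` or a
    :class:`~mina.connector_search.CandidateNetwork`; candidate networks
    carry ``seed``/``role`` node attributes in GraphML output.
    Writing then re-reading reproduces nodes, edges and seed flags.
    """
    path = Path(path)
    graph, roles = _as_graph(net)
    if dialect == "tsv":
        _write_tsv(graph, path)
    elif dialect == "sif":
        _write_sif(graph, path)
    elif dialect == "graphml":
        _write_graphml(graph, roles, path)
    else:
        raise MinaError(f"unknown output dialect {dialect!r}")


def _as_graph(net) -> tuple[nx.Graph, dict[str, str] | None]:
    if isinstance(net, Interactome):
        return net.graph, None
    # duck-typed CandidateNetwork
    if hasattr(net, "graph") and hasattr(net, "seed_nodes"):
        roles = {
            n: ("seed" if n in net.seed_nodes else "connector") for n in net.graph
        }
        return net.graph, roles
    raise MinaError(f"cannot write object of type {type(net).__name__}")


def _sorted_edges(graph: nx.Graph) -> Iterable[tuple[str, str, dict]]:
    for a, b, data in sorted(
        graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))
    ):
        a, b = sorted((a, b))
        yield a, b, data


def _write_tsv(graph: nx.Graph, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# geneA\tgeneB\tkind\taction\tnref\n")
        for a, b, data in _sorted_edges(graph):
            for kind in sorted(data["kinds"]):
                action = data.get("actions", {}).get(kind, "")
                fh.write(f"{a}\t{b}\t{kind}\t{action}\t{data['kinds'][kind]}\n")
        connected = {n for e in graph.edges for n in e}
        for node in sorted(set(graph.nodes) - connected):
            fh.write(f"{node}\n")


def _write_sif(graph: nx.Graph, path: Path) -> None:
    # the interaction kind doubles as the SIF relation, so the identity
    # kind map reads the file back losslessly
    with open(path, "w") as fh:
        for a, b, data in _sorted_edges(graph):
            for kind in sorted(data["kinds"]):
                fh.write(f"{a} {kind} {b}\n")
        connected = {n for e in graph.edges for n in e}
        for node in sorted(set(graph.nodes) - connected):
            fh.write(f"{node}\n")


def _write_graphml(graph: nx.Graph, roles: dict[str, str] | None, path: Path) -> None:
    out = nx.Graph()
    for node in graph.nodes:
        attrs = {}
        if roles is not None:
            attrs = {"role": roles[node], "seed": roles[node] == "seed"}
        out.add_node(node, **attrs)
    for a, b, data in graph.edges(data=True):
        kinds = data["kinds"]
        out.add_edge(
            a,
            b,
            kind="|".join(sorted(kinds)),
            action=next(iter(data.get("actions", {}).values()), ""),
            nref=sum(kinds.values()),
        )
    nx.write_graphml(out, path)
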