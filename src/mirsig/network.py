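"""Signed regulatory hub networks over predicted target genes.

Given a direction group's target genes and a gene-gene edge table
(activation/inhibition), the hub network is the induced subgraph with
every gene lacking a regulatory connection to another retained gene
removed. Filtering is a single pass — if a gene has any neighbor inside
the gene set, that neighbor is mutually connected and both survive, so no
iterative pruning (k-core) is performed. Connection counts are
direction- and mode-agnostic by default: parallel activation and
inhibition edges to the same neighbor count once.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import DomainError, FormatError

logger = logging.getLogger(__name__)

_MODE_TOKENS = {
    "A": "activation",
    "I": "inhibition",
    "activation": "activation",
    "inhibition": "inhibition",
}

# node annotation by miRNA group: targets of up-miRNAs are predicted down
GROUP_TO_DIRECTION = {"up": "down_in_bm", "down": "up_in_bm"}


@dataclass(frozen=True)
class RegulatoryEdge:
    source: str
    target: str
    mode: str  # activation | inhibition

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise FormatError(f"self-loop on {self.source!r}")
        if self.mode not in ("activation", "inhibition"):
            raise FormatError(f"unknown edge mode {self.mode!r}")


@dataclass
class ParsedEdges:
    edges: list[RegulatoryEdge]
    n_duplicates: int


@dataclass
class HubNetwork:
    """Filtered induced regulatory subgraph with per-node connection counts."""

    nodes: pd.DataFrame  # index gene_symbol; predicted_direction, connection_count
    edges: list[RegulatoryEdge] = field(default_factory=list)

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.nodes.index)

    def max_connection_gene(self) -> str | None:
        if self.nodes.empty:
            return None
        return self.nodes["connection_count"].idxmax()


def load_edges(path) -> ParsedEdges:
    """Read a `source<TAB>mode<TAB>target` edge table.

    Mode tokens A/I or activation/inhibition. Exact duplicate
    (source, mode, target) rows are collapsed with a logged count; unknown
    modes and self-loops are format errors.
    """
    edges: list[RegulatoryEdge] = []
    seen: set[tuple[str, str, str]] = set()
    n_duplicates = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and [p.lower() for p in parts] == ["source", "mode", "target"]:
                continue  # optional header
            if len(parts) != 3:
                raise FormatError(f"line {lineno}: expected 3 tab-separated fields")
            source, mode_token, target = parts
            if mode_token not in _MODE_TOKENS:
                raise FormatError(f"line {lineno}: unknown mode {mode_token!r}")
            mode = _MODE_TOKENS[mode_token]
            key = (source, mode, target)
            if key in seen:
                n_duplicates += 1
                continue
            seen.add(key)
            edges.append(RegulatoryEdge(source=source, target=target, mode=mode))
    if n_duplicates:
        logger.warning("collapsed %d duplicate edge rows", n_duplicates)
    return ParsedEdges(edges=edges, n_duplicates=n_duplicates)


def build_hub(
    gene_set,
    mirna_group: str,
    edges,
    count_mode: str = "neighbors",
) -> HubNetwork:
    """Induce the regulatory subgraph on ``gene_set`` and drop isolated genes.

    ``mirna_group`` is the direction of the miRNA group ("up" or "down")
    whose targets these genes are; every retained node is annotated with
    the group's predicted gene direction (targets of up-miRNAs are
    ``down_in_bm`` and vice versa). ``count_mode="neighbors"`` counts
    distinct neighbor genes; ``"edges"`` counts incident induced edges,
    so parallel activation/inhibition links count separately.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise DomainError("gene_set must be non-empty")
    if mirna_group not in GROUP_TO_DIRECTION:
        raise DomainError(f"mirna_group must be 'up' or 'down', got {mirna_group!r}")
    if count_mode not in ("neighbors", "edges"):
        raise DomainError(f"unknown count_mode {count_mode!r}")

    induced = [
        e for e in edges if e.source in gene_set and e.target in gene_set
    ]
    neighbors: dict[str, set[str]] = {}
    edge_count: dict[str, int] = {}
    for e in induced:
        neighbors.setdefault(e.source, set()).add(e.target)
        neighbors.setdefault(e.target, set()).add(e.source)
        edge_count[e.source] = edge_count.get(e.source, 0) + 1
        edge_count[e.target] = edge_count.get(e.target, 0) + 1

    retained = sorted(neighbors)  # single pass: any connected node survives
    direction = GROUP_TO_DIRECTION[mirna_group]
    if count_mode == "neighbors":
        counts = [len(neighbors[g]) for g in retained]
    else:
        counts = [edge_count[g] for g in retained]
    nodes = pd.DataFrame(
        {"predicted_direction": direction, "connection_count": counts},
        index=pd.Index(retained, name="gene_symbol"),
    )
    return HubNetwork(nodes=nodes, edges=induced)


# -- serialization -------------------------------------------------------------


def _to_digraph(net: HubNetwork) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    for gene, row in net.nodes.iterrows():
        g.add_node(
            gene,
            predicted_direction=row["predicted_direction"],
            connection_count=int(row["connection_count"]),
        )
    for e in net.edges:
        g.add_edge(e.source, e.target, mode=e.mode)
    return g


def export_network(net: HubNetwork, path, format: str = "graphml") -> None:
    """Lossless export of a hub network: graphml, json or tsv."""
    if format == "graphml":
        nx.write_graphml(_to_digraph(net), path)
    elif format == "json":
        doc = {
            "nodes": [
                {
                    "gene_symbol": gene,
                    "predicted_direction": row["predicted_direction"],
                    "connection_count": int(row["connection_count"]),
                }
                for gene, row in net.nodes.iterrows()
            ],
            "edges": [
                {"source": e.source, "mode": e.mode, "target": e.target}
                for e in net.edges
            ],
        }
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")
    elif format == "tsv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("record\tgene_or_source\tdirection_or_mode\tcount_or_target\n")
            for gene, row in net.nodes.iterrows():
                fh.write(
                    f"node\t{gene}\t{row['predicted_direction']}\t"
                    f"{int(row['connection_count'])}\n"
                )
            for e in net.edges:
                fh.write(f"edge\t{e.source}\t{e.mode}\t{e.target}\n")
    else:
        raise DomainError(f"unknown export format {format!r}")


def import_network(path, format: str = "graphml") -> HubNetwork:
    """Read back a hub network written by :func:`export_network`."""
    if format == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        nodes = pd.DataFrame(
            {
                "predicted_direction": [
                    g.nodes[n]["predicted_direction"] for n in g.nodes
                ],
                "connection_count": [
                    int(g.nodes[n]["connection_count"]) for n in g.nodes
                ],
            },
            index=pd.Index(list(g.nodes), name="gene_symbol"),
        )
        edges = [
            RegulatoryEdge(source=u, target=v, mode=d["mode"])
            for u, v, d in g.edges(data=True)
        ]
    elif format == "json":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        nodes = pd.DataFrame(
            {
                "predicted_direction": [n["predicted_direction"] for n in doc["nodes"]],
                "connection_count": [n["connection_count"] for n in doc["nodes"]],
            },
            index=pd.Index(
                [n["gene_symbol"] for n in doc["nodes"]], name="gene_symbol"
            ),
        )
        edges = [
            RegulatoryEdge(source=e["source"], target=e["target"], mode=e["mode"])
            for e in doc["edges"]
        ]
    elif format == "tsv":
        node_rows, edges = [], []
        with open(path, encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                record, a, b, c = line.rstrip("\n").split("\t")
                if record == "node":
                    node_rows.append((a, b, int(c)))
                else:
                    edges.append(RegulatoryEdge(source=a, target=c, mode=b))
        nodes = pd.DataFrame(
            {
                "predicted_direction": [r[1] for r in node_rows],
                "connection_count": [r[2] for r in node_rows],
            },
            index=pd.Index([r[0] for r in node_rows], name="gene_symbol"),
        )
    else:
        raise DomainError(f"unknown import format {format!r}")
    return HubNetwork(nodes=nodes, edges=edges)
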