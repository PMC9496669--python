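"""Microbiota-substrate-metabolite-target (MSMT) multipartite networks.

Each chain records one conversion path: a gut microbe ferments a dietary
substrate into a metabolite that acts on a protein target.  Chains induce a
four-layer graph with edges only between adjacent layers
(microbe-substrate, substrate-metabolite, metabolite-target).  Unresolved
members appear as distinct ``Unknown N`` placeholder nodes — they are real
nodes, never merged with each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence
from xml.sax.saxutils import escape

import pandas as pd

__all__ = [
    "ROLES",
    "MSMTChain",
    "MSMTNetwork",
    "MSMTSummary",
    "assemble_msmt",
    "summarize_msmt",
    "read_chain_table",
    "write_node_table",
    "write_edge_table",
    "write_graphml",
]

log = logging.getLogger(__name__)

ROLES = ("microbe", "substrate", "metabolite", "target")

#: a node is a (label, role) pair; identical labels in different roles are
#: distinct nodes
Node = tuple[str, str]
Edge = tuple[Node, Node]

_ADJACENT = {
    ("microbe", "substrate"),
    ("substrate", "metabolite"),
    ("metabolite", "target"),
}


@dataclass(frozen=True)
class MSMTChain:
    """One microbe -> substrate -> metabolite -> target path record."""

    microbe: str
    substrate: str
    metabolite: str
    target: str

    def __post_init__(self) -> None:
        if not str(self.target).strip():
            raise ValueError("chain with empty target")
        for role in ("microbe", "substrate", "metabolite"):
            if not str(getattr(self, role)).strip():
                raise ValueError(f"partial chain: empty {role} (placeholders like "
                                 f"'Unknown 1' are allowed, blanks are not)")

    def links(self) -> list[Edge]:
        """The three consecutive adjacent-role links this chain contributes."""
        m = (self.microbe.strip(), "microbe")
        s = (self.substrate.strip(), "substrate")
        x = (self.metabolite.strip(), "metabolite")
        t = (self.target.strip().upper(), "target")
        return [(m, s), (s, x), (x, t)]


@dataclass(frozen=True)
class MSMTNetwork:
    """Deduplicated multipartite graph induced by a set of chains."""

    nodes: frozenset[Node]
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        for (la, ra), (lb, rb) in self.edges:
            if (ra, rb) not in _ADJACENT:
                raise ValueError(f"edge between non-adjacent roles {ra!r}-{rb!r}")
            if (la, ra) not in self.nodes or (lb, rb) not in self.nodes:
                raise ValueError("edge endpoint outside node set")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_degree(self) -> dict[Node, int]:
        deg = dict.fromkeys(self.nodes, 0)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def nodes_by_role(self, role: str) -> list[str]:
        return sorted(label for label, r in self.nodes if r == role)


def assemble_msmt(chains: Sequence[MSMTChain]) -> MSMTNetwork:
    """Merge chains into the deduplicated multipartite network.

    The same label in the same role appears once across all chains; edges are
    deduplicated; role adjacency is guaranteed by construction.
    """
    if not chains:
        raise ValueError("no chains to assemble")
    nodes: set[Node] = set()
    edges: set[Edge] = set()
    for chain in chains:
        for a, b in chain.links():
            nodes.update((a, b))
            edges.add((a, b))
    return MSMTNetwork(frozenset(nodes), frozenset(edges))


@dataclass
class MSMTSummary:
    role_counts: dict[str, int]
    n_nodes: int
    n_edges: int
    degree_table: pd.DataFrame  # columns label, role, degree; degree descending


def summarize_msmt(net: MSMTNetwork) -> MSMTSummary:
    """Per-role node counts, edge count, and the degree table (node size in
    the rendered network encodes this edge count)."""
    deg = net.node_degree()
    rows = [
        {"label": label, "role": role, "degree": deg[(label, role)]}
        for label, role in sorted(net.nodes, key=lambda n: (n[1], n[0]))
    ]
    table = pd.DataFrame(rows, columns=["label", "role", "degree"])
    table = table.sort_values(
        ["degree", "role", "label"], ascending=[False, True, True]
    ).reset_index(drop=True)
    role_counts = {role: sum(1 for _, r in net.nodes if r == role) for role in ROLES}
    return MSMTSummary(role_counts, net.n_nodes, net.n_edges, table)


def read_chain_table(path: str | Path) -> list[MSMTChain]:
    """Four-column TSV ``microbe substrate metabolite target``; ``#`` comment
    lines and a header row are skipped."""
    path = Path(path)
    chains: list[MSMTChain] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if fields[0].lower() == "microbe":
                continue
            if len(fields) != 4:
                raise ValueError(
                    f"{path.name} line {lineno}: expected 4 columns, got {len(fields)}"
                )
            chains.append(MSMTChain(*fields))
    return chains


def write_node_table(net: MSMTNetwork, path: str | Path) -> None:
    summarize_msmt(net).degree_table.to_csv(path, sep="\t", index=False)


def write_edge_table(net: MSMTNetwork, path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {"source": a[0], "source_role": a[1], "target": b[0], "target_role": b[1]}
            for (a, b) in sorted(net.edges)
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


def write_graphml(net: MSMTNetwork, path: str | Path) -> None:
    """Minimal GraphML export with a ``role`` node attribute for coloring."""
    ids = {node: f"n{i}" for i, node in enumerate(sorted(net.nodes))}
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<graphml xmlns="http://graphml.graphdrawing.org/xmlns">',
        '  <key id="role" for="node" attr.name="role" attr.type="string"/>',
        '  <key id="label" for="node" attr.name="label" attr.type="string"/>',
        '  <graph edgedefault="undirected">',
    ]
    for (label, role), nid in ids.items():
        lines.append(
            f'    <node id="{nid}"><data key="role">{escape(role)}</data>'
            f'<data key="label">{escape(label)}</data></node>'
        )
    for a, b in sorted(net.edges):
        lines.append(f'    <edge source="{ids[a]}" target="{ids[b]}"/>')
    lines += ["  </graph>", "</graphml>", ""]
    Path(path).write_text("\n".join(lines))
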