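"""Protein-protein interaction graphs and native centrality computation.

The screening cascade treats a STRING-style export as a simple undirected,
unweighted graph over HGNC-style gene symbols.  Degree centrality (DC) is the
number of incident edges; betweenness centrality (BC) is computed with
Brandes' single-source accumulation over unweighted shortest paths, endpoints
excluded, each unordered pair counted once, and is max-normalized so the top
node scores exactly 1 (the convention used by the reporting tables this
package reproduces, not Freeman's ``2/((n-1)(n-2))`` scaling).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PPIGraph",
    "CentralityTable",
    "build_graph",
    "read_edge_list",
    "remove_isolates",
    "induced_subgraph",
    "degree_centrality",
    "betweenness_centrality",
    "normalize_bc",
    "write_centrality_tsv",
    "write_sif",
]

log = logging.getLogger(__name__)

#: canonical undirected edge: lexicographically sorted symbol pair
Edge = tuple[str, str]


def _canon(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PPIGraph:
    """Simple undirected unweighted graph over gene symbols.

    Invariants: no self-loops, no parallel edges, every edge endpoint is a
    member of ``nodes``, and ``(a, b)`` and ``(b, a)`` denote the same edge.
    """

    nodes: frozenset[str]
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a > b:
                raise ValueError(f"non-canonical edge ({a!r}, {b!r})")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge endpoint outside node set: ({a!r}, {b!r})")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[str, list[str]]:
        """Sorted adjacency lists (sorted keys are the iteration contract
        that makes centrality output bit-reproducible across runs)."""
        adj: dict[str, list[str]] = {v: [] for v in sorted(self.nodes)}
        for a, b in sorted(self.edges):
            adj[a].append(b)
            adj[b].append(a)
        for v in adj:
            adj[v].sort()
        return adj

    def degree(self) -> dict[str, int]:
        deg = dict.fromkeys(self.nodes, 0)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def has_edge(self, a: str, b: str) -> bool:
        return _canon(a, b) in self.edges


@dataclass
class CentralityTable:
    """Per-node centrality values backed by a pandas frame.

    Columns (present when populated): ``dc`` (int edge count), ``bc_raw``
    (Brandes pair dependency), ``bc_norm`` (``bc_raw / max(bc_raw)``),
    ``dc_rank`` / ``bc_rank`` (1-based descending competition ranks; tied
    values share the minimum rank).  Index: gene symbol, sorted.
    """

    frame: pd.DataFrame

    @classmethod
    def from_dc(cls, dc: Mapping[str, int]) -> "CentralityTable":
        frame = pd.DataFrame({"dc": pd.Series(dc, dtype=int)}).sort_index()
        frame.index.name = "target"
        frame["dc_rank"] = _competition_rank(frame["dc"])
        return cls(frame)

    @classmethod
    def from_bc(cls, bc_raw: Mapping[str, float]) -> "CentralityTable":
        frame = pd.DataFrame({"bc_raw": pd.Series(bc_raw, dtype=float)}).sort_index()
        frame.index.name = "target"
        frame["bc_rank"] = _competition_rank(frame["bc_raw"])
        return cls(frame)

    @classmethod
    def from_bc_norm(cls, bc_norm: Mapping[str, float]) -> "CentralityTable":
        """Build from already max-scaled values (e.g. a published table);
        ``bc_raw`` is set to the same values, which preserves ordering."""
        frame = pd.DataFrame({"bc_norm": pd.Series(bc_norm, dtype=float)}).sort_index()
        frame.index.name = "target"
        frame["bc_raw"] = frame["bc_norm"]
        frame["bc_rank"] = _competition_rank(frame["bc_raw"])
        return cls(frame)

    def merge(self, other: "CentralityTable") -> "CentralityTable":
        """Combine column sets of two tables over the same node set."""
        if not self.frame.index.equals(other.frame.index):
            raise ValueError("cannot merge centrality tables over different node sets")
        cols = other.frame.columns.difference(self.frame.columns)
        return CentralityTable(self.frame.join(other.frame[cols]))

    @property
    def targets(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)


def _competition_rank(values: pd.Series) -> pd.Series:
    return values.rank(method="min", ascending=False).astype(int)


def build_graph(edge_rows: Iterable[Sequence[str]]) -> PPIGraph:
    """Build a :class:`PPIGraph` from an iterable of symbol pairs.

    Symbols are stripped and upper-cased; duplicate rows and reversed
    duplicates collapse to one edge; self-loop rows are dropped with a
    warning.  Raises ``ValueError`` for rows that are not pairs.
    """
    nodes: set[str] = set()
    edges: set[Edge] = set()
    for i, row in enumerate(edge_rows, start=1):
        if len(row) != 2:
            raise ValueError(f"edge row {i}: expected 2 columns, got {len(row)}")
        a, b = (str(row[0]).strip().upper(), str(row[1]).strip().upper())
        if not a or not b:
            raise ValueError(f"edge row {i}: empty symbol")
        if a == b:
            log.warning("edge row %d: dropping self-loop on %s", i, a)
            continue
        nodes.update((a, b))
        edges.add(_canon(a, b))
    return PPIGraph(frozenset(nodes), frozenset(edges))


def read_edge_list(path: str | Path) -> PPIGraph:
    """Read a STRING-dialect edge list: TSV ``protein1<TAB>protein2`` with an
    optional third ``score`` column (ignored — the cascade is unweighted) and
    ``#``-prefixed comment lines."""
    path = Path(path)
    rows: list[tuple[str, str]] = []
    scores_seen = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 3:
                scores_seen = True
                fields = fields[:2]
            if len(fields) != 2:
                raise ValueError(
                    f"{path.name} line {lineno}: expected 2 columns, got {len(fields)}"
                )
            a, b = fields
            if lineno == 1 and a.strip().lower() in {"protein1", "node1", "source"}:
                continue  # header row
            rows.append((a, b))
    if scores_seen:
        log.warning("%s: third (confidence score) column ignored; edges are unweighted", path.name)
    return build_graph(rows)


def remove_isolates(graph: PPIGraph, universe) -> tuple[PPIGraph, list[str]]:
    """Restrict ``graph`` to the members of ``universe`` that touch at least
    one edge (both endpoints within the universe).

    Returns the connected-to-something subgraph and the sorted list of
    universe members with degree zero, mirroring the screening step in which
    a handful of query targets show no interaction and leave the network.
    ``universe`` is anything iterable over gene symbols (e.g. a TargetSet).
    """
    members = frozenset(getattr(universe, "members", universe))
    edges = frozenset(e for e in graph.edges if e[0] in members and e[1] in members)
    connected = frozenset(v for e in edges for v in e)
    isolates = sorted(members - connected)
    return PPIGraph(connected, edges), isolates


def induced_subgraph(graph: PPIGraph, nodes: Iterable[str]) -> PPIGraph:
    """Subgraph induced by ``nodes`` (all retained, even if isolated)."""
    keep = frozenset(nodes) & graph.nodes
    edges = frozenset(e for e in graph.edges if e[0] in keep and e[1] in keep)
    return PPIGraph(keep, edges)


def degree_centrality(graph: PPIGraph) -> CentralityTable:
    """DC: the number of edges on each node."""
    if not graph.nodes:
        raise ValueError("empty network")
    return CentralityTable.from_dc(graph.degree())


def betweenness_centrality(graph: PPIGraph) -> CentralityTable:
    """Brandes betweenness over unweighted shortest paths.

    Endpoints are excluded, disconnected pairs contribute zero, and each
    unordered source-target pair is counted once (accumulate over every
    source, then halve).  Iteration is in sorted node order so the floating
    accumulation is bit-reproducible.  The returned table carries ``bc_raw``
    and ``bc_norm`` (see :func:`normalize_bc`).
    """
    if not graph.nodes:
        raise ValueError("empty network")
    adj = graph.adjacency()
    nodes = list(adj)
    bc = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        # single-source shortest-path counts
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in nodes}
        sigma = dict.fromkeys(nodes, 0)
        sigma[s] = 1
        dist = dict.fromkeys(nodes, -1)
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        # back-propagation of pair dependencies
        delta = dict.fromkeys(nodes, 0.0)
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    for v in bc:
        bc[v] *= 0.5  # each unordered pair was seen from both endpoints
    return normalize_bc(CentralityTable.from_bc(bc))


def normalize_bc(table: CentralityTable) -> CentralityTable:
    """Max-scale ``bc_raw`` into ``bc_norm`` so the top node scores exactly 1
    (all zeros stay zero).  Ordering is preserved."""
    if "bc_raw" not in table.frame.columns:
        raise ValueError("bc_raw not populated")
    frame = table.frame.copy()
    peak = frame["bc_raw"].max()
    frame["bc_norm"] = frame["bc_raw"] / peak if peak > 0 else 0.0
    frame["bc_rank"] = _competition_rank(frame["bc_raw"])
    return CentralityTable(frame)


def write_centrality_tsv(table: CentralityTable, path: str | Path) -> None:
    """Write ``target dc bc_raw bc_norm dc_rank bc_rank`` (missing columns
    blank); BC values printed to six decimals, the report precision."""
    cols = ["dc", "bc_raw", "bc_norm", "dc_rank", "bc_rank"]
    frame = table.frame.reindex(columns=cols)
    out = frame.copy()
    for col in ("bc_raw", "bc_norm"):
        out[col] = frame[col].map(lambda x: "" if pd.isna(x) else f"{x:.6f}")
    for col in ("dc", "dc_rank", "bc_rank"):
        out[col] = frame[col].map(lambda x: "" if pd.isna(x) else str(int(x)))
    out.to_csv(path, sep="\t")


def write_sif(graph: PPIGraph, path: str | Path) -> None:
    """SIF export (``A pp B``) for network-viewer interoperability."""
    with Path(path).open("w") as fh:
        for a, b in sorted(graph.edges):
            fh.write(f"{a}\tpp\t{b}\n")
        for v in sorted(graph.nodes - {x for e in graph.edges for x in e}):
            fh.write(f"{v}\n")
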