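"""Synthetic inputs with the statistical structure the cascade assumes.

Everything a stage ingests can be generated here without network access:
sparse undirected PPI graphs with heavy-tailed degree sequences and
controllable ties at the percentile cutoff, target universes with exact
planted intersection cardinalities, and MSMT chain sets with a stated
fraction of ``Unknown N`` placeholders.  One explicit seeded generator is
threaded through every function; the seed fully determines the output.
Loaders for the small in-package report-table fixtures live here too.

Generated symbols look like ``T000001`` so they never collide with real gene
symbols in mixed tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence, Union

import numpy as np

from .cascade import TargetSet
from .graph import CentralityTable, PPIGraph, build_graph
from .msmt import MSMTChain

__all__ = [
    "ErdosRenyi",
    "Configuration",
    "PlantedBridge",
    "SyntheticSpec",
    "OverlapSpec",
    "ChainSpec",
    "gen_ppi",
    "gen_target_universe",
    "gen_msmt_chains",
    "gen_demo_ppi",
    "table2_tail_degree_sequence",
    "is_graphical",
    "load_fixture",
    "FIXTURE_NAMES",
]


# ---------------------------------------------------------------------------
# edge models


@dataclass(frozen=True)
class ErdosRenyi:
    """G(n, p): every unordered pair is an edge independently with prob p."""

    p: float


@dataclass(frozen=True)
class Configuration:
    """Simple graph realizing an exact degree sequence (Havel-Hakimi
    construction followed by seeded degree-preserving edge swaps)."""

    degree_seq: tuple[int, ...]


@dataclass(frozen=True)
class PlantedBridge:
    """Two dense communities joined only through one bridge node.

    The bridge is adjacent to every community member, so every
    cross-community shortest path (length 2) runs through it alone and its
    betweenness dominates by construction whenever ``c1 * c2`` exceeds the
    largest within-community pair count.
    """

    c1: int
    c2: int
    p: float = 0.6


EdgeModel = Union[ErdosRenyi, Configuration, PlantedBridge]


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int
    n_nodes: int
    edge_model: EdgeModel
    tie_block: Optional[tuple[int, int]] = None  # (rank_position, block_size)


def _symbols(n: int, prefix: str = "T") -> list[str]:
    return [f"{prefix}{i:06d}" for i in range(1, n + 1)]


def is_graphical(degree_seq: Sequence[int]) -> bool:
    """Erdős–Gallai check that a degree sequence admits a simple graph."""
    seq = sorted((int(d) for d in degree_seq), reverse=True)
    if not seq:
        return True
    if seq[-1] < 0 or sum(seq) % 2 == 1:
        return False
    n = len(seq)
    prefix = np.cumsum(seq)
    for k in range(1, n + 1):
        rhs = k * (k - 1) + sum(min(d, k) for d in seq[k:])
        if prefix[k - 1] > rhs:
            return False
    return True


def _havel_hakimi_edges(degree_seq: Sequence[int]) -> list[tuple[int, int]]:
    """Deterministic simple-graph construction; raises if not graphical."""
    if not is_graphical(degree_seq):
        raise ValueError("degree sequence is not graphical")
    remaining = [[int(d), i] for i, d in enumerate(degree_seq)]
    edges: list[tuple[int, int]] = []
    while True:
        remaining.sort(key=lambda x: (-x[0], x[1]))
        d, v = remaining[0]
        if d == 0:
            break
        if d > len(remaining) - 1:
            raise ValueError("degree sequence is not graphical")
        remaining[0][0] = 0
        for slot in remaining[1 : d + 1]:
            if slot[0] == 0:
                raise ValueError("degree sequence is not graphical")
            slot[0] -= 1
            a, b = sorted((v, slot[1]))
            edges.append((a, b))
    return edges


def _edge_swaps(edges: list[tuple[int, int]], rng: np.random.Generator,
                n_swaps: int) -> list[tuple[int, int]]:
    """Degree-preserving double-edge swaps keeping the graph simple."""
    edge_set = {tuple(sorted(e)) for e in edges}
    edge_list = sorted(edge_set)
    for _ in range(n_swaps):
        i, j = rng.integers(0, len(edge_list), size=2)
        (a, b), (c, d) = edge_list[i], edge_list[j]
        if len({a, b, c, d}) < 4:
            continue
        e1, e2 = tuple(sorted((a, c))), tuple(sorted((b, d)))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.update((e1, e2))
        edge_list[i], edge_list[j] = e1, e2
    return sorted(edge_set)


def gen_ppi(spec: SyntheticSpec) -> list[tuple[str, str]]:
    """Generate edge rows (symbol pairs) for the requested edge model.

    The rows use the same dialect the pipeline ingests, so they can be fed
    straight to ``build_graph`` or written as a TSV.
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.edge_model
    if isinstance(model, ErdosRenyi):
        syms = _symbols(spec.n_nodes)
        rows = [
            (syms[i], syms[j])
            for i in range(spec.n_nodes)
            for j in range(i + 1, spec.n_nodes)
            if rng.random() < model.p
        ]
    elif isinstance(model, Configuration):
        seq = model.degree_seq
        if len(seq) != spec.n_nodes:
            raise ValueError("degree sequence length must equal n_nodes")
        syms = _symbols(spec.n_nodes)
        edges = _havel_hakimi_edges(seq)
        edges = _edge_swaps(edges, rng, n_swaps=4 * len(edges))
        rows = [(syms[a], syms[b]) for a, b in edges]
    elif isinstance(model, PlantedBridge):
        a = [f"A{i:04d}" for i in range(model.c1)]
        b = [f"B{i:04d}" for i in range(model.c2)]
        rows = []
        for community in (a, b):
            # spanning path guarantees connectivity; ER edges add density
            for u, v in zip(community, community[1:]):
                rows.append((u, v))
            for i in range(len(community)):
                for j in range(i + 2, len(community)):
                    if rng.random() < model.p:
                        rows.append((community[i], community[j]))
        rows.extend(("BRIDGE", v) for v in a + b)
    else:
        raise TypeError(f"unknown edge model {model!r}")
    return rows


def table2_tail_degree_sequence(seed: int = 0) -> tuple[int, ...]:
    """A 337-value degree sequence whose upper tail is the packaged
    106-entry DC table (97 values >= 15, nine tied at 14) padded with 231
    seeded filler degrees <= 13; parity-adjusted so the sequence is
    graphical and constructible."""
    table = load_fixture("table2_dc")
    top = [int(v) for v in table.frame["dc"].sort_values(ascending=False)]
    rng = np.random.default_rng(seed)
    fillers = [int(d) for d in rng.integers(3, 13, size=231)]  # all <= 12 < 14
    seq = top + fillers
    if sum(seq) % 2 == 1:
        fillers[0] += 1  # still <= 13
        seq = top + fillers
    return tuple(seq)


def gen_demo_ppi(seed: int = 0) -> tuple[list[tuple[str, str]], TargetSet]:
    """Synthetic paper-shaped demo network for end-to-end runs.

    This is a constructed stand-in for the (undeposited) real PPI export: a
    342-target universe in which five designated query targets touch no edge,
    AKT1 is adjacent to every connected node, and ALB and IL6 are secondary
    hubs with strictly nested neighborhoods (ALB covers a superset fraction),
    so the screening cascade provably retains the three named hubs with BC
    order AKT1 > ALB > IL6.  Returns (edge rows, target universe).
    """
    rng = np.random.default_rng(seed)
    named = list(load_fixture("table2_dc").frame.index)  # 106 real symbols
    fillers = _symbols(231, prefix="X")
    isolates = ["NMUR2", "PAM", "BRS3", "UTS2R", "SSTR4"]
    connected = sorted(set(named) | set(fillers))
    universe = TargetSet.from_symbols("demo_universe", connected + isolates)

    rows: list[tuple[str, str]] = []
    others = [v for v in connected if v != "AKT1"]
    rows.extend(("AKT1", v) for v in others)
    core = [v for v in named if v not in {"AKT1", "ALB", "IL6"}]
    for hub, frac_core, frac_filler in (("ALB", 0.75, 0.30), ("IL6", 0.50, 0.15)):
        for v in core:
            if rng.random() < frac_core:
                rows.append((hub, v))
        for v in fillers:
            if rng.random() < frac_filler:
                rows.append((hub, v))
    for i in range(len(core)):
        for j in range(i + 1, len(core)):
            if rng.random() < 0.25:
                rows.append((core[i], core[j]))
    for i in range(len(fillers)):
        for j in range(i + 1, len(fillers)):
            if rng.random() < 0.01:
                rows.append((fillers[i], fillers[j]))
    return rows, universe


# ---------------------------------------------------------------------------
# target universes with exact overlap cardinalities


@dataclass(frozen=True)
class OverlapSpec:
    """Exact cardinalities for two or three target sets.

    ``sizes`` are total set sizes; ``pairwise`` maps name pairs to exact
    intersection sizes; ``triple`` (three sets only) is |A∩B∩C|.
    """

    names: tuple[str, ...]
    sizes: tuple[int, ...]
    pairwise: dict[tuple[str, str], int] = field(default_factory=dict)
    triple: int = 0

    def __post_init__(self) -> None:
        if not 2 <= len(self.names) <= 3 or len(self.sizes) != len(self.names):
            raise ValueError("overlap spec needs 2 or 3 named sizes")


def _region_counts(spec: OverlapSpec) -> dict[tuple[bool, ...], int]:
    names, sizes = spec.names, spec.sizes
    pair = {frozenset(k): v for k, v in spec.pairwise.items()}

    def pw(i: int, j: int) -> int:
        return pair.get(frozenset((names[i], names[j])), 0)

    if len(names) == 2:
        k = pw(0, 1)
        regions = {
            (True, False): sizes[0] - k,
            (False, True): sizes[1] - k,
            (True, True): k,
        }
    else:
        t = spec.triple
        ab, ac, bc = pw(0, 1), pw(0, 2), pw(1, 2)
        regions = {
            (True, True, True): t,
            (True, True, False): ab - t,
            (True, False, True): ac - t,
            (False, True, True): bc - t,
            (True, False, False): sizes[0] - ab - ac + t,
            (False, True, False): sizes[1] - ab - bc + t,
            (False, False, True): sizes[2] - ac - bc + t,
        }
    if any(v < 0 for v in regions.values()):
        raise ValueError(f"infeasible overlap spec: negative region in {regions}")
    return regions


def gen_target_universe(spec: OverlapSpec, seed: int) -> list[TargetSet]:
    """Synthetic symbol sets achieving the requested cardinalities exactly.

    The seed shuffles which symbols land in which region; the region sizes
    are guaranteed by construction.
    """
    rng = np.random.default_rng(seed)
    regions = _region_counts(spec)
    total = sum(regions.values())
    pool = _symbols(total)
    rng.shuffle(pool)
    members: dict[str, set[str]] = {name: set() for name in spec.names}
    cursor = 0
    for pattern in sorted(regions):
        count = regions[pattern]
        chunk = pool[cursor : cursor + count]
        cursor += count
        for name, inside in zip(spec.names, pattern):
            if inside:
                members[name].update(chunk)
    return [TargetSet.from_symbols(name, members[name]) for name in spec.names]


# ---------------------------------------------------------------------------
# MSMT chains


@dataclass(frozen=True)
class ChainSpec:
    n_chains: int
    unknown_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_chains <= 0:
            raise ValueError("n_chains must be positive")
        if not 0.0 <= self.unknown_fraction <= 1.0:
            raise ValueError("unknown_fraction must be in [0, 1]")


def gen_msmt_chains(spec: ChainSpec, seed: int) -> list[MSMTChain]:
    """Random chains over synthetic label pools.

    A fraction of the microbe/substrate/metabolite slots become distinct
    ``Unknown N`` placeholders (targets are always named gene symbols).
    """
    rng = np.random.default_rng(seed)
    n = spec.n_chains
    pools = {
        "microbe": [f"Microbe {i}" for i in range(1, n + 1)],
        "substrate": [f"Substrate {i}" for i in range(1, n + 1)],
        "metabolite": [f"Metabolite {i}" for i in range(1, n + 1)],
        "target": _symbols(max(3, n // 2)),
    }
    unknown_counter = 0
    chains = []
    for _ in range(n):
        record = {}
        for role in ("microbe", "substrate", "metabolite"):
            if rng.random() < spec.unknown_fraction:
                unknown_counter += 1
                record[role] = f"Unknown {unknown_counter}"
            else:
                record[role] = pools[role][int(rng.integers(len(pools[role])))]
        record["target"] = pools["target"][int(rng.integers(len(pools["target"])))]
        chains.append(MSMTChain(**record))
    return chains


# ---------------------------------------------------------------------------
# in-package fixtures

FIXTURE_NAMES = ("table2_dc", "table3_bc", "table4_ligands", "msmt_paper", "equol_smiles")


def _data_text(filename: str) -> str:
    return resources.files("msmt_netpharm.data").joinpath(filename).read_text()


def load_fixture(name: str):
    """Load one of the packaged report-table fixtures as a typed object.

    ``table2_dc`` -> :class:`CentralityTable` (106 rows, dc populated);
    ``table3_bc`` -> :class:`CentralityTable` (32 rows, max-scaled bc);
    ``table4_ligands`` -> list of (name, cid, smiles) tuples;
    ``msmt_paper`` -> list of :class:`MSMTChain`;
    ``equol_smiles`` -> a single (name, cid, smiles) tuple.
    """
    if name == "table2_dc":
        rows = _parse_rows(_data_text("table2_dc.tsv"), 3)
        return CentralityTable.from_dc({target: int(dc) for _, target, dc in rows})
    if name == "table3_bc":
        rows = _parse_rows(_data_text("table3_bc.tsv"), 3)
        return CentralityTable.from_bc_norm({target: float(bc) for _, target, bc in rows})
    if name == "table4_ligands":
        rows = _parse_rows(_data_text("table4_ligands.tsv"), 3)
        return [(n, int(cid), smi) for n, cid, smi in rows]
    if name == "msmt_paper":
        rows = _parse_rows(_data_text("msmt_paper.tsv"), 4)
        return [MSMTChain(*row) for row in rows]
    if name == "equol_smiles":
        ligands = load_fixture("table4_ligands")
        return next(entry for entry in ligands if entry[0] == "Equol")
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")


def _parse_rows(text: str, n_cols: int) -> list[tuple[str, ...]]:
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = tuple(f.strip() for f in line.split("\t"))
        if fields[0].lower() in {"rank", "name", "microbe"}:
            continue
        if len(fields) != n_cols:
            raise ValueError(f"fixture row has {len(fields)} columns, expected {n_cols}")
        rows.append(fields)
    return rows
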