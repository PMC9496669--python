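"""Target-set screening: intersections, percentile filters, core selection.

The cascade narrows a metabolite-predicted target universe in stages: overlap
of two ligand-based prediction services, overlap with disease-associated
targets, then two topological filters that keep the top 30% of nodes by
degree centrality and, on the resulting subnetwork, the top 30% by
betweenness centrality.  Core targets are the highest-BC survivors, by
default restricted to targets with at least one metabolite association.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .graph import CentralityTable

__all__ = [
    "TargetSet",
    "FilterRule",
    "FilterReport",
    "read_target_list",
    "intersect",
    "union",
    "venn_counts",
    "filter_top_fraction",
    "filter_with_report",
    "select_core",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetSet:
    """A named collection of unique, uppercase gene symbols."""

    name: str
    members: frozenset[str]

    @classmethod
    def from_symbols(cls, name: str, symbols: Iterable[str]) -> "TargetSet":
        cleaned = {str(s).strip().upper() for s in symbols}
        cleaned.discard("")
        return cls(name, frozenset(cleaned))

    def __post_init__(self) -> None:
        if any(not s or s != s.strip() for s in self.members):
            raise ValueError("target set contains empty or unstripped symbols")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.members

    def __iter__(self):
        return iter(sorted(self.members))

    def sorted(self) -> list[str]:
        return sorted(self.members)


def read_target_list(path: str | Path, name: Optional[str] = None) -> TargetSet:
    """Plain-text list, one symbol per line, ``#`` comments allowed."""
    path = Path(path)
    symbols = []
    with path.open() as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                symbols.append(line)
    return TargetSet.from_symbols(name or path.stem, symbols)


def intersect(a: TargetSet, b: TargetSet) -> TargetSet:
    """Overlap of two target sets; name records provenance ``a∩b``."""
    return TargetSet(f"{a.name}∩{b.name}", a.members & b.members)


def union(a: TargetSet, b: TargetSet) -> TargetSet:
    """Plain symbol-deduplicating union (e.g. merging two disease-target
    catalogues)."""
    return TargetSet(f"{a.name}∪{b.name}", a.members | b.members)


def venn_counts(sets: Sequence[TargetSet]) -> dict[str, int]:
    """Exclusive-region cardinalities for 2-3 sets.

    Keys are ``&``-joined set names for each non-empty membership pattern
    (e.g. ``"SEA"``, ``"SEA&STP"``); values partition the union.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_counts supports 2 or 3 sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("set names must be distinct")
    counts: dict[str, int] = {}
    for pattern in product([True, False], repeat=len(sets)):
        if any(pattern):
            key = "&".join(n for n, inside in zip(names, pattern) if inside)
            counts[key] = 0
    universe = frozenset().union(*(s.members for s in sets))
    for symbol in universe:
        pattern = tuple(symbol in s.members for s in sets)
        key = "&".join(n for n, inside in zip(names, pattern) if inside)
        counts[key] += 1
    return counts


@dataclass(frozen=True)
class FilterRule:
    """Top-fraction retention rule for a centrality metric.

    ``fraction`` in (0, 1] (the cascade uses 0.30); ``rank_rounding`` is how
    ``fraction × N`` becomes an integer cutoff rank k; ``tie_policy`` decides
    whether nodes tied with the k-th value are all retained (``include_ties``)
    or the list is cut at exactly k (``strict_rank``).
    """

    fraction: float = 0.30
    rank_rounding: str = "ceiling"  # ceiling | nearest
    tie_policy: str = "include_ties"  # include_ties | strict_rank

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.rank_rounding not in {"ceiling", "nearest"}:
            raise ValueError(f"unknown rank_rounding {self.rank_rounding!r}")
        if self.tie_policy not in {"include_ties", "strict_rank"}:
            raise ValueError(f"unknown tie_policy {self.tie_policy!r}")

    def cutoff_rank(self, n: int) -> int:
        x = self.fraction * n
        k = math.ceil(x) if self.rank_rounding == "ceiling" else math.floor(x + 0.5)
        return max(1, k)


@dataclass
class FilterReport:
    stage: str
    n_in: int
    k: int
    cutoff_value: float
    ties_at_cutoff: int
    n_out: int
    members: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


_METRIC_COLUMN = {"dc": "dc", "bc": "bc_norm"}


def filter_with_report(
    table: CentralityTable,
    metric: str,
    rule: FilterRule,
    stage: Optional[str] = None,
) -> tuple[TargetSet, FilterReport]:
    """Apply a top-fraction rule to one centrality metric.

    Nodes are sorted by the metric descending (symbol ascending breaks ties
    for deterministic ordering only; membership never depends on the
    tie-break).  ``strict_rank`` keeps exactly the first k; ``include_ties``
    keeps every node whose metric is >= the k-th node's value.
    """
    if metric not in _METRIC_COLUMN:
        raise ValueError(f"metric must be one of {sorted(_METRIC_COLUMN)}, got {metric!r}")
    column = _METRIC_COLUMN[metric]
    if column not in table.frame.columns:
        column = "bc_raw" if metric == "bc" and "bc_raw" in table.frame.columns else column
    if column not in table.frame.columns:
        raise ValueError(f"centrality table has no {metric!r} values")
    frame = table.frame
    if len(frame) == 0:
        raise ValueError("empty centrality table")
    if frame[column].isna().any():
        raise ValueError(f"{metric!r} not populated for all nodes")

    ordered = frame[column].sort_index().sort_values(ascending=False, kind="mergesort")
    k = rule.cutoff_rank(len(ordered))
    cutoff_value = float(ordered.iloc[k - 1])
    if rule.tie_policy == "strict_rank":
        kept = list(ordered.index[:k])
    else:
        kept = list(ordered.index[ordered.values >= cutoff_value])
    ties = int((ordered == cutoff_value).sum())
    report = FilterReport(
        stage=stage or f"top_{rule.fraction:g}_{metric}",
        n_in=len(ordered),
        k=k,
        cutoff_value=cutoff_value,
        ties_at_cutoff=ties,
        n_out=len(kept),
        members=sorted(kept),
    )
    log.info(
        "filter %s: N_in=%d k=%d cutoff=%g ties=%d N_out=%d",
        report.stage, report.n_in, report.k, report.cutoff_value,
        report.ties_at_cutoff, report.n_out,
    )
    return TargetSet.from_symbols(report.stage, kept), report


def filter_top_fraction(table: CentralityTable, metric: str, rule: FilterRule) -> TargetSet:
    """See :func:`filter_with_report`; returns only the retained set."""
    kept, _ = filter_with_report(table, metric, rule)
    return kept


def select_core(
    table: CentralityTable,
    k: int,
    evidence: Optional[TargetSet] = None,
) -> list[str]:
    """Top-k targets by normalized betweenness centrality.

    When ``evidence`` is given (targets carrying at least one metabolite
    association in the chain table), ranking is restricted to those targets —
    the documented reconstruction of how the reported core trio differs from
    the literal top of the BC table; callers see this via logging.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    column = "bc_norm" if "bc_norm" in table.frame.columns else "bc_raw"
    if column not in table.frame.columns:
        raise ValueError("bc not populated")
    frame = table.frame
    if evidence is not None:
        eligible = frame.loc[frame.index.intersection(sorted(evidence.members))]
        log.info(
            "core selection restricted to %d metabolite-linked targets (of %d)",
            len(eligible), len(frame),
        )
    else:
        eligible = frame
    if k > len(eligible):
        raise ValueError(f"k={k} exceeds {len(eligible)} eligible nodes")
    ordered = eligible[column].sort_index().sort_values(ascending=False, kind="mergesort")
    return list(ordered.index[:k])
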