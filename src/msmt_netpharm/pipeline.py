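"""End-to-end orchestration of the screening workflow.

Stage order: intersect prediction-service target sets -> overlap with
disease-associated targets -> build the PPI graph -> drop isolated query
targets -> degree centrality -> top-30% DC filter -> betweenness centrality
on the DC-filtered induced subgraph -> top-30% BC filter -> core-target
selection (metabolite-evidence-restricted by default) -> MSMT assembly ->
drug-likeness report per metabolite.  Every stage logs input/output sizes
and writes its artifact; the run ends with one machine-readable summary.

BC in the second filter is computed on the induced subgraph of DC survivors,
not inherited from the full network — the reading of a "subnetwork" filter
that this package adopts (it changes BC values, and is therefore stated).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import cascade, chem, graph, msmt

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run.

    File inputs: a STRING-dialect edge list; either two prediction-service
    target lists (``targets_a``/``targets_b``, intersected) or a ready-made
    ``targets_common`` list; optionally a disease-target list intersected
    next; an MSMT chain table; a SMILES table for the metabolite panel.
    """

    edges: str
    targets_common: Optional[str] = None
    targets_a: Optional[str] = None
    targets_b: Optional[str] = None
    targets_disease: Optional[str] = None
    chains: Optional[str] = None
    smiles: Optional[str] = None
    dc_rule: cascade.FilterRule = field(default_factory=cascade.FilterRule)
    bc_rule: cascade.FilterRule = field(default_factory=cascade.FilterRule)
    core_k: int = 3
    evidence_restriction: bool = True
    outdir: str = "msmt_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.targets_common is None and not (self.targets_a and self.targets_b):
            raise ValueError("config needs targets_common or both targets_a and targets_b")
        for key in ("edges", "targets_common", "targets_a", "targets_b",
                    "targets_disease", "chains", "smiles"):
            value = getattr(self, key)
            if value is not None and not Path(value).exists():
                raise ValueError(f"config file for {key!r} does not exist: {value}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for rule_key in ("dc_rule", "bc_rule"):
            if rule_key in raw:
                raw[rule_key] = cascade.FilterRule(**raw[rule_key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = {}
        for key, value in self.__dict__.items():
            if isinstance(value, cascade.FilterRule):
                raw[key] = {
                    "fraction": value.fraction,
                    "rank_rounding": value.rank_rounding,
                    "tie_policy": value.tie_policy,
                }
            else:
                raw[key] = value
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


def _stage(name: str):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage name is the contract
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return wrapped
    return decorate


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full cascade; returns the summary dict (also written to
    ``summary.json`` in the output directory, alongside per-stage artifacts
    and the resolved config for provenance)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    # -- stage: target universe --------------------------------------------
    common = _stage("intersect")(_load_common)(config)
    log.info("stage intersect: %d common targets", len(common))

    # -- stage: PPI graph ---------------------------------------------------
    ppi = _stage("build_graph")(graph.read_edge_list)(config.edges)
    ppi, isolates = _stage("remove_isolates")(graph.remove_isolates)(ppi, common)
    log.info("stage ppi: %d nodes, %d edges, %d isolates dropped",
             ppi.n_nodes, ppi.n_edges, len(isolates))
    graph.write_sif(ppi, outdir / "ppi.sif")

    # -- stage: DC filter ---------------------------------------------------
    dc_table = _stage("degree_centrality")(graph.degree_centrality)(ppi)
    dc_set, dc_report = _stage("filter_dc")(cascade.filter_with_report)(
        dc_table, "dc", config.dc_rule, stage="dc_top_fraction")
    (outdir / "filter_dc.json").write_text(dc_report.to_json())

    # -- stage: BC filter on the induced DC subnetwork ----------------------
    sub = graph.induced_subgraph(ppi, dc_set.members)
    bc_table = _stage("betweenness_centrality")(graph.betweenness_centrality)(sub)
    bc_set, bc_report = _stage("filter_bc")(cascade.filter_with_report)(
        bc_table, "bc", config.bc_rule, stage="bc_top_fraction")
    (outdir / "filter_bc.json").write_text(bc_report.to_json())
    graph.write_centrality_tsv(
        graph.degree_centrality(sub).merge(bc_table), outdir / "centrality.tsv")

    # -- stage: MSMT + evidence --------------------------------------------
    chains = []
    if config.chains:
        chains = _stage("read_chains")(msmt.read_chain_table)(config.chains)
    evidence = None
    net = None
    if chains:
        evidence = cascade.TargetSet.from_symbols(
            "metabolite_evidence", (c.target for c in chains))
    else:
        log.warning("no MSMT chains supplied; MSMT stage skipped")

    # -- stage: core selection ---------------------------------------------
    final_table = graph.CentralityTable(
        bc_table.frame.loc[sorted(bc_set.members)])
    restriction = evidence if config.evidence_restriction else None
    if restriction is not None:
        n_eligible = len(restriction.members & set(final_table.targets))
        if n_eligible < config.core_k:
            log.warning(
                "only %d metabolite-linked targets survive the BC filter; "
                "core selection falls back to the unrestricted table", n_eligible)
            restriction = None
    core = _stage("select_core")(cascade.select_core)(
        final_table, config.core_k, restriction)
    if config.evidence_restriction and evidence is not None:
        log.info("core targets restricted to metabolite-linked evidence set "
                 "(reconstruction flag: the unrestricted BC leaders may differ)")

    # -- stage: MSMT assembly ----------------------------------------------
    msmt_nodes = msmt_edges = 0
    if chains:
        core_chains = [c for c in chains if c.target.upper() in set(core)] or chains
        net = _stage("assemble_msmt")(msmt.assemble_msmt)(core_chains)
        msmt.write_node_table(net, outdir / "msmt_nodes.tsv")
        msmt.write_edge_table(net, outdir / "msmt_edges.tsv")
        msmt.write_graphml(net, outdir / "msmt.graphml")
        msmt_nodes, msmt_edges = net.n_nodes, net.n_edges
        log.info("stage msmt: %d nodes, %d edges", msmt_nodes, msmt_edges)

    # -- stage: drug-likeness ----------------------------------------------
    descriptor_table = []
    if config.smiles:
        molecules = _stage("read_smiles")(chem.read_smiles_table)(config.smiles)
        reports = [_stage("lipinski_report")(chem.lipinski_report)(m) for m in molecules]
        descriptor_table = [r.to_dict() for r in reports]
        chem.report_table(reports).to_csv(outdir / "descriptors.tsv", sep="\t", index=False)

    summary = {
        "n_common": len(common),
        "n_isolates": len(isolates),
        "isolates": isolates,
        "n_ppi_nodes": ppi.n_nodes,
        "n_ppi_edges": ppi.n_edges,
        "n_dc_subnet": dc_report.n_out,
        "n_bc_subnet": bc_report.n_out,
        "core_targets": core,
        "msmt_nodes": msmt_nodes,
        "msmt_edges": msmt_edges,
        "descriptor_table": descriptor_table,
        "seed": config.seed,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _load_common(config: PipelineConfig) -> cascade.TargetSet:
    if config.targets_common:
        common = cascade.read_target_list(config.targets_common, "common")
    else:
        a = cascade.read_target_list(config.targets_a)
        b = cascade.read_target_list(config.targets_b)
        common = cascade.intersect(a, b)
    if config.targets_disease:
        disease = cascade.read_target_list(config.targets_disease, "disease")
        common = cascade.intersect(common, disease)
    return common
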