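# msmt-netpharm

A tested, reusable implementation of the network-pharmacology screening
cascade used in gut-microbiome drug-discovery studies: starting from target
sets predicted for microbial metabolites, the pipeline intersects them with
disease-associated targets, builds a protein–protein interaction (PPI)
network, narrows it with two topological filters, assembles the
microbiota–substrate–metabolite–target (MSMT) multipartite network around
the surviving core targets, and scores each metabolite with rule-based
drug-likeness descriptors.

It is written for computational biologists who receive the upstream inputs
as files — prediction-service hit lists, a STRING-style edge-list export, a
curated chain table, a SMILES panel — and want the downstream screening
logic to be reproducible, scriptable, and testable offline.

## The method

**Target cascade.** Let A and B be metabolite-target sets from two
ligand-based prediction services and D a disease-target catalogue. The
candidate universe is `(A ∩ B) ∩ D`. On the PPI graph `G = (V, E)` over
this universe (isolated targets are dropped and reported), two filters run
in sequence:

1. *Degree filter.* Degree centrality `DC(v)` is the number of edges on
   `v`. With `k = ⌈0.30·|V|⌉`, every node whose DC is at least the k-th
   largest value is retained (ties at the cutoff are included by default).
2. *Betweenness filter.* On the subgraph induced by the DC survivors,
   betweenness centrality

   `BC(v) = Σ_{s≠v≠t} σ_st(v) / σ_st`

   is computed natively with Brandes' algorithm over unweighted shortest
   paths (each unordered pair counted once, endpoints excluded) and
   max-scaled so the top node scores exactly 1.000000. The same top-30%
   rule is applied.

Core targets are the top-k (default 3) BC survivors, by default restricted
to targets carrying at least one metabolite association in the chain table
— a documented reconstruction choice, flagged at run time, because the
highest-BC nodes overall need not be metabolite-linked.

**MSMT network.** Each chain row `microbe → substrate → metabolite →
target` contributes exactly three adjacent-layer links. Labels are
deduplicated per role; `Unknown N` placeholders are genuine, never-merged
nodes. Node degree in the assembled multipartite graph is the quantity the
published network figures encode as circle size.

**Drug-likeness.** For each metabolite the package computes molecular
weight (periodic-table sum), Lipinski H-bond acceptor/donor counts (N+O
atoms; H on N/O), the Moriguchi 13-descriptor MlogP regression, Ertl
fragment-based TPSA, the rule-of-five violation count over
{MW ≤ 500, HBA ≤ 10, HBD ≤ 5, MlogP ≤ 4.15}, and the Abbott
bioavailability score (discrete levels 0.11/0.17/0.55/0.56/0.85). RDKit is
used for SMILES parsing and atom typing only; every descriptor on top of
the parsed structure is implemented here (see `docs/methods.md`).

## Worked example

The package ships a synthetic paper-shaped demo network (342 targets, five
of them interaction-free) plus the in-package chain table and metabolite
panel. Running the pipeline end to end:

```python
from msmt_netpharm.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    edges="edges.tsv",            # STRING-dialect TSV (demo: synth.gen_demo_ppi)
    targets_common="common.txt",  # 342 candidate targets, one per line
    chains="chains.tsv",          # microbe/substrate/metabolite/target TSV
    smiles="smiles.tsv",          # name <TAB> cid <TAB> smiles
    outdir="run", seed=0,
)
summary = run_pipeline(config)
```

prints (abridged `summary.json`):

```json
{
  "n_common": 342,
  "n_isolates": 5,
  "n_ppi_nodes": 337,
  "n_ppi_edges": 2144,
  "n_dc_subnet": 102,
  "n_bc_subnet": 31,
  "core_targets": ["AKT1", "ALB", "IL6"],
  "msmt_nodes": 25,
  "msmt_edges": 23
}
```

Reading: of 342 candidate targets, 5 touch no interaction and leave the
network; the 30% degree filter keeps 102 of the remaining 337; the 30%
betweenness filter keeps 31 of those; the three core targets are the
metabolite-linked BC leaders; and the chain table around them assembles
into a 25-node, 23-edge MSMT network. The descriptor table (also in the
summary) reports, e.g., for equol: MW 242.27, HBA 3, HBD 2, MlogP 2.2,
TPSA 49.69 Å², 0 rule-of-five violations, bioavailability score 0.55.

The same workflow is available from the shell:

```bash
msmt-netpharm pipeline --config run.yaml
msmt-netpharm chem --smiles smiles.tsv --out descriptors.tsv
msmt-netpharm cascade --edges ppi.tsv --targets common.txt \
    --fraction 0.30 --rounding ceiling --ties include
```

## Layout

```
src/msmt_netpharm/
  graph.py      PPI graphs, native degree/Brandes betweenness, ranks, TSV/SIF IO
  cascade.py    target sets, venn regions, top-fraction filters, core selection
  msmt.py       chain records, multipartite assembly, summaries, GraphML export
  chem.py       descriptor suite and rule verdicts
  synth.py      seeded generators (ER / configuration / planted-bridge graphs,
                exact-overlap universes, chain sets) and fixture loaders
  pipeline.py   end-to-end orchestration with per-stage artifacts
  cli.py        click command-line interface
  data/         in-package report-table fixtures (plain TSV)
```
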