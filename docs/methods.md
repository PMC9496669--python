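# Methods

This note documents the models, conventions, and numerical choices behind
`msmt-netpharm`, and what its synthetic data can and cannot say about real
inputs.

## PPI graph model and centrality

The interaction network is a simple, undirected, unweighted graph over
uppercase gene symbols. A STRING-style export may carry a third confidence
column; it is ignored with a logged warning — the screening cascade this
package implements is defined on an unweighted graph, and no confidence
threshold is applied at ingestion (whatever filtering produced the edge
list is upstream of this artifact). Self-loop rows are dropped with a
warning; duplicate and reversed rows collapse to one edge.

Degree centrality is the incident-edge count. Betweenness centrality uses
Brandes' single-source accumulation over unweighted shortest paths:
endpoints are excluded, disconnected pairs contribute zero, and the
undirected convention accumulates over every source and halves, so each
unordered pair counts once. Nodes are iterated in sorted order, making the
floating-point accumulation bit-reproducible across runs and platforms.
Normalization is max-scaling (`bc_norm = bc_raw / max(bc_raw)`, all-zero
tables stay zero), not Freeman's `2/((n−1)(n−2))` scaling: the reporting
convention this package reproduces prints exactly 1.000000 for the top
node, which only max-scaling yields. Ranks are 1-based descending
competition ranks (tied values share the minimum rank); filter membership
is decided on metric values, never on ranks, so the rank convention cannot
change a screening outcome.

Disconnected graphs are allowed; shortest paths exist within components
only. BC for the second filter stage is computed on the subgraph induced
by the degree-filter survivors rather than inherited from the full
network. This is a genuine modeling choice — the two readings give
different BC values — and the induced-subgraph reading is the natural
meaning of filtering "a subnetwork"; it is therefore fixed and stated.

## The top-fraction filter

With `N` nodes and fraction `f` (default 0.30), the cutoff rank is
`k = ⌈f·N⌉` by default (`nearest`, i.e. round-half-up, is available; both
roundings are consistent with the published cascade sizes, and ceiling is
exposed in the configuration). Two tie policies exist: `strict_rank` keeps
exactly the first `k` after sorting by metric descending, and
`include_ties` (default) keeps every node whose metric is at least the
k-th value. The default matters: a 337-entry degree table whose 98th–106th
values all equal 14 has `k = 102` and cutoff value 14, so tie inclusion
retains 106 — integer degree ties at the cutoff are common in real PPI
networks, and a strict cut would split an equivalence class arbitrarily.
For continuous betweenness values the two policies coincide. Symbol order
breaks ties only for deterministic output ordering.

Whether the 30% should be taken over the connected node count or the full
query universe is ambiguous in general; this package filters over the
nodes present in the centrality table, i.e. the connected count, and both
conventions reproduce the packaged cascade sizes under tie inclusion.

## Core-target selection

`select_core(table, k, evidence)` returns the top-k nodes by normalized
betweenness. When an evidence set is supplied (by default: targets with at
least one metabolite association in the chain table), ranking is
restricted to it. This restriction is a reconstruction: the reported core
trio of the workflow this package reimplements is not the literal top
three of the betweenness table, and restricting to metabolite-linked
targets is the minimal documented rule that produces it. The pipeline
logs the restriction on every run, and falls back (with a warning) to the
unrestricted table if fewer than `k` evidence targets survive the filters.

## MSMT networks

A chain is a complete four-member record; partial chains (an empty
interior member) are rejected rather than bridged so that role adjacency —
edges only between microbe–substrate, substrate–metabolite,
metabolite–target — is a checkable invariant. `Unknown N` placeholders are
real nodes: two distinct placeholders never merge, while identical labels
in the same role always do. Identical labels in different roles are
distinct nodes.

The packaged chain fixture reconstructs a 25-node / 23-edge network: four
named and four unknown microbes, two named and five unknown substrates,
six named and one unknown metabolite, three targets, with the IL6 target
receiving five metabolite edges. Eight microbes over seven substrates
force at least one substrate with two producing microbes; reaching 23
edges requires one further microbe–substrate link. The fixture places all
of this surplus on the acetate chain (producers: *Eubacterium limosum*,
*Escherichia coli* — a documented mixed-acid acetate producer — and one
unknown microbe). The exact wiring of the unknowns is not recoverable from
text sources and is a defensible reconstruction; the tested contract is
the node/edge count, the per-role composition, and the IL6 hub degree, not
the placeholder wiring.

## Drug-likeness descriptors

RDKit performs SMILES parsing, sanitization, aromaticity perception, and
implicit-hydrogen assignment. All descriptor arithmetic is native.

**Charge handling.** Descriptors are computed on the neutral parent:
anionic heteroatoms are protonated and protonated amines deprotonated where
that is chemically trivial; internally compensated zwitterions
(trimethylamine N-oxide, betaines, charge-separated nitro groups) are kept;
anything with residual net charge is rejected with an error. Carboxylate
inputs therefore score as the free acids, while their anionic character is
remembered for the bioavailability class.

**Molecular weight** is the sum of standard atomic weights including
implicit hydrogens, displayed to 2 dp. **HBA/HBD** are Lipinski's simple
counts — N+O atoms, and hydrogens on N/O — not pharmacophore-typed
definitions; the simple counts are what the reporting portals use (a ring
ether counts as an acceptor, an amide N–H as a donor).

**MlogP** implements the Moriguchi 1992 regression
(intercept −1.014; 1.244·CX^0.6 − 1.017·NO^0.9 + 0.406·PRX − 0.145·UB^0.8
+ 0.511·HB + 0.268·POL − 2.215·AMP + 0.912·ALK − 0.392·RNG − 3.684·QN
+ 0.474·NO2 + 1.582·NCS + 0.773·BLM), displayed to 1 dp. The publication
defines several structural descriptors only in words; this implementation
fixes them as follows, anchored on the drug-likeness portal value for
equol (2.2) and closed-form checks against experimental log P for benzene,
phenol, catechol, and cyclohexanol:

- `CX`: carbons plus halogens weighted C/F/Cl/Br/I = 1/0.5/1/1.5/2.
- `NO`: nitrogen plus oxygen count.
- `PRX`: N/O proximity — 2 per directly bonded pair, 1 per pair separated
  by one C/S/P atom, −1 per carboxamide/sulfonamide group (floored at 0).
  Nitro groups contribute 4 through their two N–O bonds, which is what
  keeps nitroaromatics from being over-penalized by the NO term.
- `UB`: non-aromatic double and triple bonds, nitro bonds excluded.
  Counting aromatic bonds here would push equol more than 0.2 log units
  below the anchored value; excluding them reproduces it.
- `HB` (intramolecular H-bond): ortho donor/acceptor substituent pair on
  an aromatic ring (catechol, salicylates). Longer-range H-bond motifs are
  not detected.
- `POL`: acyl-type polar substituents on aromatic rings — a non-ring
  attachment C or S multiply bonded to N/O (Ar–C(=O)–, Ar–C≡N, Ar–S(=O)–),
  nitro excluded. Heteroatom-attached substituents (Ar–OH, Ar–O–R) are not
  counted; counting them breaks the equol anchor.
- `AMP`: α-amino acid 1.0; aminobenzoic/pyridinecarboxylic patterns 0.5.
- `ALK`: pure hydrocarbon with no aromatic ring, no triple and at most one
  double bond. `RNG`: presence of any ring (flag, not a ring count).
- `QN`: quaternary N 1.0, N-oxide 0.5; `NO2`: nitro count; `NCS`:
  isothiocyanate 1.0 / thiocyanate 0.5; `BLM`: β-lactam flag.

Elements outside {C, H, N, O, S, P, halogens} raise an explicit
unsupported-element error rather than returning a silently wrong value.
As a sanity scale: the model's residual standard error in its original
fitting was ≈0.4 log units, so single-decimal agreement is the appropriate
reading precision.

**TPSA** is the Ertl 2000 fragment-contribution sum over N/O environments
(hydroxyl O 20.23 Å², ether/ring O 9.23, aromatic N 12.89, …), displayed to
2 dp. Charge-separated nitro groups are scored as the hypervalent
N(=O)=O form the fragment table was parameterized on (11.68 + 2×17.07).
Environments missing from the table (e.g. free water) fall back to a
generic valence-based contribution with a logged warning. The native sum
agrees with RDKit's implementation to 1e-6 on the packaged panel; RDKit is
used only as a cross-check oracle in tests.

**Verdicts.** Violations are counted against {MW ≤ 500, HBA ≤ 10,
HBD ≤ 5, MlogP ≤ 4.15}. The MW boundary is inclusive by default
(configurable, and the exact-boundary case is logged) since the prose
convention "≤ 500" and the tabular "< 500" disagree only at measure-zero
inputs. The aggregate pass is "at most one violation", exposed alongside
the raw count. The Abbott bioavailability score is 0.55 for
rule-compliant non-anions, 0.17 for non-anionic rule failures, and for
anions (acidic groups detected by SMARTS, or net-anionic input) follows
the TPSA bands ≤75 → 0.85, ≤150 → 0.56, >150 → 0.11; the only attainable
values are the published discrete levels.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical shape* the cascade depends on:
heavy-tailed degree sequences with controllable ties at the 30% cutoff
(configuration model via Havel–Hakimi construction plus seeded
degree-preserving edge swaps, with an Erdős–Gallai feasibility check),
exact planted intersection cardinalities for 2–3 target universes, chain
sets with a chosen placeholder fraction, and a planted-bridge topology in
which one node is adjacent to every member of two otherwise disconnected
dense communities — making it a cut vertex whose betweenness provably
dominates (with communities of ten, the bridge carries 100 cross pairs
against at most 45 within-community pairs for any other node).

`gen_demo_ppi` is a synthetic stand-in for an undeposited real PPI export:
a 342-target universe with five interaction-free members, one global hub
adjacent to all connected nodes, and two secondary hubs with nested
neighborhood fractions so the cascade lands a known core trio. Passing
tests on these inputs demonstrates that the *screening logic* is correct
and deterministic; they say nothing about STRING's edge content, about
database-version-dependent target counts, or about the biology of any
particular network — those quantities depend on external services and are
deliberately replaced by property-based checks (native Brandes versus an
exhaustive matrix-power path-counting oracle, handshake identities,
planted-structure recovery, byte-identical repeated runs).

## Problem sizes and determinism

Test and acceptance runs use desk-scale inputs: oracle comparisons on
graphs of ≤12 nodes (where exhaustive path counting is exact and cheap),
cross-checks against networkx at ≤40 nodes, cascade fixtures at their
natural sizes (337/106/32), and a 337-node demo pipeline. A single
`numpy.random.Generator` seeded from the user-facing seed drives every
stochastic choice; no global random state is touched. Summary JSON is
written with sorted keys so repeated seeded runs are byte-identical.

## Known limitations

- The MlogP structural descriptors involve interpretive choices (UB, POL,
  RNG, HB above); molecules dominated by those terms may deviate from
  other implementations by a few tenths of a log unit.
- The intramolecular H-bond flag only detects ortho aromatic pairs.
- The bioavailability anion classifier is SMARTS-based and does not
  compute pKa; unusual acids may be misclassified.
- Venn regions support at most three sets, matching the screening design.
- The MSMT assembler requires complete chains; genuinely partial knowledge
  must be encoded with explicit placeholder labels.
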