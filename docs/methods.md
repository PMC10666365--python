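# Methods

## The model in brief

`melanocore` treats a curated signed interaction map as the ground truth
topology and asks which small feedback structures matter, how they jointly
regulate an ordinal EMT phenotype, and where sustained interventions move
that phenotype. The pipeline is deterministic end to end: given the same
inputs and seeds it produces byte-identical outputs.

## Motif mining and topology

Feedback motifs are simple directed 3-cycles; self-loops and 2-cycles never
qualify, and loops of other lengths are out of scope. Each motif is stored
in a canonical rotation beginning at its lexicographically smallest node,
which makes equality, deduplication and output order well defined. The loop
sign is the product of the nonzero edge signs; a cycle containing an
"unidentified" (sign 0) edge is kept but marked `undetermined`, since
curated maps retain such edges and dropping them silently would bias the
motif census (an `exclude_neutral` switch removes them).

Node degree counts in- and out-edges, ignoring signs. Betweenness is
computed on the directed graph and normalized by (n−1)(n−2), so it lies in
[0, 1]. Note that on the 3-node path A→B→C this yields 0.5 for B (B
mediates one of the two ordered pairs that exclude it), which is the value
the tests freeze.

## Motif ranking

Raw node properties are aggregated to motif level by the arithmetic mean
(configurable to sum): the mean keeps motifs of hubs and motifs of modest
nodes on one scale, and the disease-pathway term is a plain membership
count in {0..3}. Each term is normalized by the batch maximum — including
the DP term, normalized by the maximum observed count rather than the
constant 3 — so rescaling any one raw feature across the whole batch leaves
scores unchanged, and a term whose batch maximum is zero contributes
nothing instead of dividing by zero. The topological pair (degree,
betweenness) shares a halved weight so topology cannot dominate the three
non-topological terms. Scores are linear in the weight vector.

The bundled 13-scenario grid (uniform; one weight doubled; one weight
alone; adjacent weight pairs doubled) is a documented stand-in for
user-supplied weighting schemes: the scenario file format accepts any list
of non-negative, not-all-zero weight quadruples, and selection takes the
top k (default 10) per scenario with deterministic tie-breaking (score
descending, canonical motif id ascending) before deduplicating the union.

## Core assembly

The selected motifs are merged as a node/edge union. Receptors — an input
list, since curated receptor sets are hand-picked — are added when they are
first neighbors (either direction) of a core node, with the connecting
edges copied from the full map; non-adjacent receptors are skipped with a
warning. The four EMT markers are mandatory outputs: they are always added,
with every direct edge between a marker and the core (including
marker-to-marker edges such as the canonical ZEB1 ⊣ CDH1 repression).
Layers are then assigned input / regulatory / output-marker. Assembly is
idempotent, and the core is provably a signed subgraph of the full map.

## Boolean calibration

Fold-change signs carry the biological state: positive log2FC ⇒ state 1,
negative ⇒ 0. A missing fold change is *unknown*, never zero, and a zero
fold change is likewise treated as signless. Gates are restricted to pure
OR-of-literals and AND-of-literals (a literal is the regulator or its
negation for inhibiting edges): nodes without regulators become clamped
inputs (free when unmeasured), single-regulator nodes become identities,
and multi-regulator nodes take whichever of OR/AND reproduces the target's
fold-change sign on the regulators' sign states. Ties go to OR — treating
independent regulation as the default — and are recorded in the calibration
report, as are nodes where neither candidate matches (kept as OR, flagged
`unresolved-or`) and nodes with no usable fold changes. Mixed gate forms
are deliberately out of scope; the report makes the places where they might
matter visible. Sign-0 edges are excluded from gates by default; a flag
admits them as activators.

## Three-valued dynamics

States are {0, 1, unknown} with Kleene semantics: AND is 0 if any literal
is 0, 1 if all are 1, else unknown; OR dually; NOT flips and preserves
unknown. The logical steady state (LSS) starts from clamps-known /
rest-unknown and re-evaluates all gates to a fixed point; because the
operators are monotone in the information order the result is unique and
update-order independent. Clamped nodes override their gates at every step,
which is also how perturbations are modeled (sustained interventions, not
transient flips).

Kleene propagation is *sound* — every value it determines holds in all
completions of the free inputs — but not *complete*: a node fed by
reconvergent paths of opposite parity (e.g. X = B OR C with B = A and
C = NOT A) is constant in truth yet stays unknown, because the propagation
never case-splits on A. The test suite therefore checks soundness against
exhaustive enumeration on arbitrary acyclic models and exact equality on
models without reconvergent paths, where completeness is a theorem. This
mirrors the behavior of standard logical-steady-state implementations.

Cyclic cores may leave the LSS partial. For calibration checks the
convention is: compute the LSS, seed the remaining unknown nodes with their
fold-change-sign states, run the synchronous map to its attractor, and
compare a reached fixed point against the data (falling back to the
clamp-determined values when the attractor cycles). Screening itself uses
the LSS only, keeping results order-free; synchronous simulation is exposed
separately and returns the attractor (fixed point or cycle) with a default
step budget of 4× the node count — ample for cores of this size, and an
explicit error otherwise.

## EMT readout and screening

`EMT = ZEB1 + NOT(CDH1) + VIM + SNAI1` maps marker states to an ordinal
level 0–4; unknown markers widen the value to a tight integer interval, and
interval arithmetic carries through deltas. The level is monotone:
non-decreasing in ZEB1, VIM, SNAI1 and non-increasing in CDH1.

Screens are exhaustive and deterministic: every candidate × {0, 1} singly,
every unordered pair × {0, 1}² doubly (capped at 10,000 evaluations with an
explicit error), sorted by EMT then intervention. Minimal-intervention
search returns all size ≤ 2 clamp sets achieving the reachable extreme,
smallest first, dropping supersets of reported winners. Candidates default
to the regulatory layer minus the four markers; receptor inputs can be
included on request.

The robustness analysis flips each candidate to the opposite of its
baseline steady-state value (both values when the baseline is unknown) and
calls the node fragile iff the EMT level moves (interval midpoints compared
when unknowns persist). Its default candidate set is the *protein* nodes of
the regulatory layer: the analysis models failures as mutation-type events
on genes and proteins, so miRNA nodes are excluded by default — on the
bundled fixture this yields the fragile pair {AKT1, MDM2}, while
`include_mirna=True` also surfaces MIR25, whose clamping is already covered
by the perturbation screen.

## Synthetic data and the bundled fixture

The generator emits, from a single seed: a random signed digraph over
`n_nodes` regulatory nodes at `edge_density` with `n_planted_loops`
3-cycles inserted (defaults 30 nodes, 5 loops, density 0.05, sign mix
0.6/0.3/0.1 activation/inhibition/neutral — sparse, inhibition-rich
proportions typical of curated signaling maps); `n_receptors` (default 10,
matching the real core's receptor count) in-degree-0 receptors wired into
loop nodes; and four marker nodes fed by regulatory nodes, with the
epithelial marker predominantly repressed whenever the sign mix allows
inhibition. A ground-truth Boolean model assigns random AND/OR gates and
random input clamps, and fold changes are emitted *from its own steady
state*: sign from the LSS value, magnitude log-normal around
`fc_magnitude` (default 1.5, i.e. roughly 3-fold changes — magnitudes are
decorative for the logic but exercise the |FC| ranking term), with an
`fc_noise` fraction of signs flipped and unknown-LSS nodes emitted as
missing. At zero noise, calibration therefore matches every determined node
and gate inference recovers every planted gate that is distinguishable
(i.e. AND and OR differ on the realized regulator states); recovery
degrades as noise rises.

What the generator does **not** emulate: expression count noise and
normalization (fold changes are the entry point), dosage or intermediate
activation levels (all-or-none logic), time-resolved dynamics, and the
hand-curated biology of a real map. Passing tests show the algorithms are
correct on data satisfying the model's assumptions, not that the
assumptions hold for any particular dataset.

The bundled melanoma-style fixture is a hand-built minimal core — 22 nodes,
26 edges, not a reconstruction of the full published 48-node core, whose
edge list ships only as supplementary data users can supply as SIF. It
wires the ten receptor proteins into an eight-node regulatory layer built
around the mechanistic claims of the melanoma literature: AKT1 → VIM,
AKT1 → MDM2, MDM2 ⊣ CDH1 with MIR25 repressing CDH1 in parallel, the
CDH1 ⊣ CTNNB1 → SNAI1 relay with a redundant CDH1 ⊣ SNAI2 → SNAI1 arm, an
MDM2–p53 negative feedback loop, and redundant receptor drive into E2F1,
TP53, TWIST1 and MIR25 so that no single peripheral failure moves the
phenotype. Four receptors are deliberately unmeasured (missing fold
changes) to exercise free inputs and Kleene short-circuiting. Its
calibrated model yields baseline markers (1, 0, 0, 1), EMT 3; MDM2 or MIR25
inhibition → (1, 1, 0, 0), EMT 1 (with MDM2 remaining active under MIR25
inhibition, as the two repress CDH1 independently); AKT1 activation →
(1, 0, 1, 1), EMT 4; fragile set {AKT1, MDM2}.

## Numerical and degenerate-input choices

Scores are plain double arithmetic (the per-term oracle test agrees to
1e-12); no tolerance parameters exist elsewhere — logic is exact. Duplicate
network edges follow a keep-first/error policy, but sign-conflicting
duplicates are always an error. Empty networks enumerate to empty motif
lists; scoring an empty feature batch is an error; selection with fewer
motifs than k takes all and warns. Motifs with no fold-change data anywhere
score zero on the |FC| term rather than being dropped. All warnings use the
standard `warnings` machinery so callers can promote them to errors.

## Problem sizes

Default test and acceptance runs use networks of 5–60 nodes, 100-seed
oracle sweeps, and 20-seed recovery experiments with 60-node networks —
sizes at which the brute-force oracles (all-triple cycle iteration,
exhaustive free-input enumeration, explicit shortest-path counting) remain
exact and fast while still exercising every code path the full-map analysis
uses. The same code runs unchanged on map-scale inputs (hundreds of nodes,
thousands of edges); only the double-screen cap guards combinatorial
blow-up.

## Known limitations

* Gate space is pure AND/OR of literals; biologically plausible mixed gates
  are flagged, not fitted.
* The LSS leaves feedback-only information unknown by design; conclusions
  about cyclic subnetworks rest on the fold-change-seeded convention made
  explicit above.
* Ordinal EMT weighting is uniform across the four markers; no attempt is
  made to calibrate marker weights against invasion phenotypes.
* Perturbations are permanent clamps; transient or dosage-dependent
  interventions are out of scope.
* The ranking treats motif features as independent evidence; correlated
  annotations (e.g. degree and prioritization score both reflecting study
  bias) are not decorrelated.
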