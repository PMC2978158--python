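# Methods

## Constraint-based model and solvers

A model is a compartmentalized stoichiometric network: metabolites are
identified by `(base id, compartment)` with the eight-letter compartment
alphabet `{c,e,m,g,l,r,x,n}` (cytosol, extracellular, mitochondrion,
Golgi, lysosome, endoplasmic reticulum — some source dialects label this
compartment "ribosome" — peroxisome, nucleus); reactions carry signed
stoichiometries, flux bounds in mmol/gDW/hr, a boolean
gene–protein–reaction (GPR) rule, and a subsystem label. The default
bound convention is (0, 1000) for irreversible and (−1000, 1000) for
reversible reactions; files that omit bounds get these defaults.

FBA and FVA are solved as plain LPs with the HiGHS solvers behind
`scipy.optimize.linprog`; the gap-filling problem is a MILP solved by
`scipy.optimize.milp`. Reversible reactions are kept as single variables
with signed bounds (no splitting) — the optima are identical and the
formulation smaller. All per-reaction and per-gene loops run in the
model's insertion order, so repeated runs are bit-reproducible.

Numerical conventions (all overridable per call):

| quantity | default | rationale |
|---|---|---|
| essentiality threshold ε_ess | 1e-6 flux | "zero growth" needs a cutoff well above LP feasibility noise (~1e-9) and far below any genuine growth value |
| active-reaction tolerance | 1e-6 | same scale separation, used for FVA activity tallies |
| FVA objective fraction | 1.0 | "while contributing to maximal production"; a 1e-9 absolute relaxation on the floor absorbs solver tolerance |
| validation pass threshold | 1e-6 flux | functionality = non-zero producibility |
| capacity-change tolerance | rel 1e-6, abs floor 1e-9 | LP noise must not create spurious down/up counts |
| gap-fill ε / big-M | 1.0 / 1000 | target must carry unit flux; M equals the global bound so the coupling is never binding for honest solutions |

## Projection semantics

A gene with no homolog is treated as *absent* for GPR evaluation, so a
reaction survives whenever isozymes cover it; this is the only reading
consistent with isozyme rescue of normal-phenotype knockouts. Retained
rules are rewritten leaf-by-leaf into the target namespace (leaf → OR of
homologs) with constant-folding; a rule that folds to false can only
belong to a removed reaction.

Decompartmentalization merges all intracellular compartments into one
but keeps the extracellular space by default, because a full merge would
delete every exchange reaction and make growth simulation meaningless; a
full single-compartment merge is available via `keep_extracellular=False`.
Reactions whose stoichiometry cancels (pure intracellular transport) are
dropped; duplicates merge with the OR of their GPRs, since either enzyme
suffices once location is lost.

Dead ends are metabolites that — accounting for reversibility — can only
ever be produced or only ever consumed (orphans touched by no producing
and no consuming reaction also count).

## Gap filling

The MILP minimizes the number of added database reactions subject to
steady state of the combined network and target flux ≥ ε, with
|v_j| ≤ M·y_j coupling each candidate to its indicator. After each
optimum, an integer cut Σ_{j∈Y} y_j ≤ |Y|−1 excludes the found set and
the MILP re-solves; cardinality is therefore non-decreasing across
iterations. A per-reaction cut variant (ban every used reaction) is
available; the whole-solution cut is the default since it yields the
"next-best distinct solution" enumeration that repeated-iteration usage
implies. Database reactions are compartment-free and instantiated in the
cytosol; transport/exchange candidates generated by
`build_transport_exchange_db` carry explicit compartments and bridge to
the boundary. Acceptance filters are mechanical stand-ins for the manual
review step: reject a solution if an added reaction is the reverse of a
reaction flagged forward-only in the database or irreversible in the
model, or if it lacks the organism-evidence flag (a boolean column in
the database dialect).

## Validation and curation

Each validation test is evaluated on a fresh copy: the test medium is
applied, a demand reaction for the target metabolite is auto-created
(and exists only for that test), and the objective is maximized. Tests
are therefore order-independent. Compartment-specific tests are skipped
on collapsed models (auto-detected as ≤1 intracellular compartment in
use). Failure diagnosis searches the projection-removed pool greedily —
single restorations first, then pairs — capped at subsets of size 2 and
10⁴ trial combinations per failing test: the manual curation process it
mirrors is unbounded, a tool must not be. The loop terminates when the
battery passes, when no candidate helps, or after a bounded number of
rounds; the pass fraction never decreases across rounds.

## Knockout phenotype statistics

Capacity change is classified from Δv_max only (the FVA maximum), the
published convention; a full-range-width variant can be built from the
same `FVAResult`s but is not the default. The subsystem shift statistic
is a single-value chi-square with 1 df against an even down/up split,
upper-tail p, **no continuity correction** — the printed p-values of the
reference tables match the uncorrected statistic (three cells of that
table are truncated at four decimals, which the tests acknowledge).
Significance is Bonferroni α/k with α = 0.05 and k = 10 major
subsystems; tallies of "significant metabolism subsections" exclude the
Transporters subsystem, the only convention that reproduces the
published per-knockout counts (6, 2, 0, 7).

Activity-profile trees use Jaccard distance between active-reaction sets
(two empty sets are at distance 0) and average-linkage agglomeration;
labels are sorted before clustering for deterministic tie-breaks, and
the tree is emitted as newick with branch lengths. Distance and linkage
are package choices — the original figures do not state theirs — and are
recorded in output metadata.

## Synthetic generator

The generator emulates the structure the pipeline was built for:
boundary exchanges → non-gene-associated uptake transports → linear
conversion chains (every third pathway routed through the mitochondrion
with transport steps) → biomass precursors → one biomass reaction
consuming all precursors. Defaults: 10 pathways × 8 conversions,
3 compartments, 100 decoy branches, 5 planted blocked reactions,
~310 reactions total — large enough to exercise compartment logic and
subsystem statistics, small enough for exhaustive oracles (vertex
enumeration, truth tables, subset enumeration) to be feasible.

Ground truth is guaranteed, not estimated:

* **essential genes** are exactly the dedicated single-gene bridge
  enzymes on unique precursor paths; all other sole-path reactions draw
  only isozyme-pair or empty rules, and single-gene/complex rules are
  confined to decoy branches biomass never needs;
* **blocked reactions** connect orphan metabolite pairs, so their FVA
  range is (0,0) and the orphans are the only dead ends;
* **validation tests** target one precursor each (plus
  compartment-specific tests on mitochondrial intermediates) and record
  the exact reaction dependency set.

GPR fractions default to 35% isozyme pairs, 20% complexes, 40%
non-gene-associated — the non-gene-associated share matching the roughly
40% observed in curated mammalian reconstructions. The minimal medium
opens only nutrient uptakes at 10 mmol/gDW/hr (a typical glucose-scale
uptake), so wild-type growth equals 10; the rich medium opens every
exchange at the global bound. Homology tables retain each gene
independently at the species' retention rate (mouse-like default 0.97),
mapping to one target id, or two with probability 0.2.

What the generator does *not* emulate: mass/charge-balanced chemistry
(coefficients are small integers), realistic network redundancy (paths
are deliberately unique where ground truth requires it), database
identifier semantics, and the scale of genome-wide reconstructions.
Passing tests therefore demonstrate algorithmic correctness of each
stage and of their composition — not predictive accuracy on real
organisms, which depends on curation quality of the real inputs.

## Problem sizes used in checks

The automated checks run the full synthetic pipeline at the default
~310-reaction scale; exhaustive oracles run on reduced instances chosen
for tractability of the oracle, not the implementation: vertex
enumeration on networks of ≤ 8 reactions, knockout re-solve
cross-checks on a ~30-reaction model, gap-fill minimality by subset
enumeration over databases of ≤ 12 reactions.

## Pipeline configuration

`orthoflux pipeline --config cfg.yaml --out run/` reads a flat YAML
mapping: `seed` (root seed for all randomness), `retention` (homology
retention rate), `approach` (`A`|`B`), `compartments`
(`full`|`collapsed`). Outputs land in `run/models/` and `run/reports/`;
every report carries the seed and a hash of the configuration. Exit
status distinguishes validation failure from execution error.

## Known limitations

* The gap-filler's big-M coupling can, in principle, admit numerically
  marginal solutions on badly scaled inputs; ε = 1 and M = 1000 keep the
  default formulation benign.
* The curation search is greedy per failing test and bounded at pair
  depth; interacting gaps needing ≥3 simultaneous restorations are
  reported as unresolvable rather than searched.
* Collapsed-model detection is structural (one intracellular compartment
  in use); models that are conceptually collapsed but retain unused
  compartment codes should pass `skip_compartment_specific` explicitly.
* Reproduction of the published mouse-model counts requires the original
  deposited inputs (see README); they are not bundled.
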