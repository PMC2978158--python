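"""Synthetic reconstructions with provable ground truth.

The generator emits a compartmentalized source model shaped like a
mammalian reconstruction in miniature: boundary exchanges feed nutrient
metabolites into the cytosol through non-gene-associated transports,
linear conversion pathways (some routed through the mitochondrion) build
one biomass precursor each, and a single biomass reaction consumes all
precursors. GPRs carry isozymes (OR pairs) and enzyme complexes (AND
pairs) at configurable fractions, plus a non-gene-associated share.

Ground truth is guaranteed by construction, not estimated:

* essential genes are exactly the dedicated single-gene "bridge"
  enzymes placed on the unique path to one precursor — every other
  pathway reaction is either isozyme-covered or non-gene-associated,
  and complexes/single genes appear only on decoy branches that biomass
  never needs;
* planted blocked reactions connect orphan metabolites touched by
  nothing else, so their FVA range is (0, 0) and the orphans are the
  model's only dead ends;
* each validation test targets one precursor (or a mitochondrial
  intermediate, flagged compartment-specific) and records the exact
  reaction set it depends on.

Everything is seed-deterministic; regenerating with the same spec gives
byte-identical files in the pipeline's own dialects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gpr import GPRExpression, parse_gpr
from .model import (
    MediumCondition,
    MetabolicModel,
    ModelError,
    Reaction,
)
from .phenotype import MAJOR_SUBSYSTEMS
from .projection import HomologyTable
from .validation import ValidationTest

#: The nine metabolism labels (Transporters excluded) used round-robin.
_PATHWAY_SUBSYSTEMS = tuple(s for s in MAJOR_SUBSYSTEMS if s != "Transporters")


@dataclass
class SyntheticSpec:
    """Tunable shape of a generated reconstruction."""

    n_pathways: int = 10  # = biomass precursors
    chain_length: int = 8  # conversions per pathway
    n_essential: int = 5  # pathways carrying a single-gene bridge enzyme
    n_decoys: int = 100  # side branches off the pathways
    n_blocked: int = 5  # planted zero-flux reactions
    isozyme_fraction: float = 0.35
    complex_fraction: float = 0.2
    non_gene_fraction: float = 0.4
    mito_every: int = 3  # every k-th pathway routes through the mitochondrion
    uptake_rate: float = 10.0  # minimal-medium uptake bound (mmol/gDW/hr)
    seed: int = 0

    def validate(self) -> None:
        for f in (self.isozyme_fraction, self.complex_fraction, self.non_gene_fraction):
            if not 0 <= f <= 1:
                raise ModelError("GPR fractions must be in [0, 1]")
        if self.n_essential > self.n_pathways:
            raise ModelError("more essential bridges than pathways")
        if self.n_pathways < 1 or self.chain_length < 1:
            raise ModelError("need at least one pathway and one conversion step")


@dataclass
class GroundTruth:
    essential_genes: set[str] = field(default_factory=set)
    blocked_reactions: set[str] = field(default_factory=set)
    dead_end_metabolites: set[str] = field(default_factory=set)
    kind_tags: dict[str, str] = field(default_factory=dict)
    subsystem_map: dict[str, str] = field(default_factory=dict)
    pathway_reactions: dict[int, list[str]] = field(default_factory=dict)
    precursors: list[str] = field(default_factory=list)
    test_dependencies: dict[str, set[str]] = field(default_factory=dict)
    rich_medium: MediumCondition | None = None
    minimal_medium: MediumCondition | None = None
    planted_gaps: set[str] = field(default_factory=set)


def _draw_gpr(rng: np.random.Generator, spec: SyntheticSpec, fresh, *, safe: bool):
    """Draw a GPR. ``safe=True`` (sole-path reactions) only allows isozyme
    pairs or empty rules, so no accidental essential genes arise."""
    u = rng.random()
    if safe:
        cut = spec.isozyme_fraction / max(
            spec.isozyme_fraction + spec.non_gene_fraction, 1e-12
        )
        if u < cut:
            return parse_gpr(f"{fresh()} or {fresh()}")
        return GPRExpression()
    if u < spec.non_gene_fraction:
        return GPRExpression()
    u2 = rng.random()
    if u2 < spec.isozyme_fraction:
        return parse_gpr(f"{fresh()} or {fresh()}")
    if u2 < spec.isozyme_fraction + spec.complex_fraction:
        return parse_gpr(f"{fresh()} and {fresh()}")
    return GPRExpression(parse_gpr(fresh()).root)


def generate_source_model(spec: SyntheticSpec) -> tuple[MetabolicModel, GroundTruth]:
    """Build the source reconstruction and its ground-truth manifest."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    model = MetabolicModel(id=f"synth{spec.seed}", compartments=("c", "e", "m"))
    truth = GroundTruth()

    counter = [0]

    def fresh() -> str:
        counter[0] += 1
        return f"g{counter[0]:04d}"

    def add(rid, stoich, lower, upper, gpr, subsystem, kind, pathway=None):
        model.add_reaction(
            Reaction(rid, stoich, lower, upper, gpr=gpr, subsystem=subsystem)
        )
        truth.kind_tags[rid] = kind
        truth.subsystem_map[rid] = subsystem
        if pathway is not None:
            truth.pathway_reactions.setdefault(pathway, []).append(rid)

    biomass_stoich: dict[str, float] = {}
    exchange_ids: list[str] = []

    for i in range(spec.n_pathways):
        sub = _PATHWAY_SUBSYSTEMS[i % len(_PATHWAY_SUBSYSTEMS)]
        nut = f"n{i:02d}"
        ex_id = f"EX_{nut}"
        add(ex_id, {f"{nut}[e]": -1.0}, -1000.0, 1000.0,
            GPRExpression(), "Transporters", "exchange", pathway=i)
        exchange_ids.append(ex_id)
        add(f"T_{nut}", {f"{nut}[e]": -1.0, f"{nut}[c]": 1.0}, -1000.0, 1000.0,
            GPRExpression(), "Transporters", "transport", pathway=i)

        via_mito = spec.mito_every > 0 and i % spec.mito_every == 1
        mid_step = spec.chain_length // 2 + 1
        bridge_step = mid_step if not via_mito else 1
        prev = f"{nut}[c]"
        prev_comp = "c"
        for j in range(1, spec.chain_length + 1):
            met = f"p{i:02d}" if j == spec.chain_length else f"m{i:02d}_{j}"
            comp = "m" if (via_mito and j == mid_step) else "c"
            if comp != prev_comp:
                base = prev.split("[")[0]
                add(f"T_{base}_{prev_comp}{comp}",
                    {prev: -1.0, f"{base}[{comp}]": 1.0}, -1000.0, 1000.0,
                    GPRExpression(), "Transporters", "transport", pathway=i)
                prev = f"{base}[{comp}]"
                prev_comp = comp
            cur = f"{met}[{comp}]"
            rid = f"C_{i:02d}_{j}"
            if i < spec.n_essential and j == bridge_step:
                gene = f"ess{i:02d}"
                gpr = parse_gpr(gene)
                truth.essential_genes.add(gene)
            else:
                gpr = _draw_gpr(rng, spec, fresh, safe=True)
            add(rid, {prev: -1.0, cur: 1.0}, 0.0, 1000.0, gpr, sub,
                "metabolic", pathway=i)
            prev = cur
            prev_comp = comp
        if prev_comp != "c":
            base = prev.split("[")[0]
            add(f"T_{base}_{prev_comp}c", {prev: -1.0, f"{base}[c]": 1.0},
                -1000.0, 1000.0, GPRExpression(), "Transporters", "transport",
                pathway=i)
            prev = f"{base}[c]"
        truth.precursors.append(prev)
        biomass_stoich[prev] = -1.0

    # decoy side branches: hang off a random pathway nutrient, drained by a
    # demand so they are flux-capable but never needed for biomass
    for q in range(spec.n_decoys):
        i = int(rng.integers(spec.n_pathways))
        dmet = f"d{q:03d}[c]"
        add(f"D_{q:03d}", {f"n{i:02d}[c]": -1.0, dmet: 1.0}, 0.0, 1000.0,
            _draw_gpr(rng, spec, fresh, safe=False), "Transporters", "metabolic")
        add(f"DM_d{q:03d}", {dmet: -1.0}, 0.0, 1000.0,
            GPRExpression(), "Transporters", "demand")

    # planted blocked reactions over orphan metabolites
    for q in range(spec.n_blocked):
        a, b = f"orphA{q:02d}[c]", f"orphB{q:02d}[c]"
        rid = f"B_{q:02d}"
        add(rid, {a: -1.0, b: 1.0}, 0.0, 1000.0,
            GPRExpression(), "Secondary Metabolites Metabolism", "metabolic")
        truth.blocked_reactions.add(rid)
        truth.dead_end_metabolites.update((a, b))

    add("BIOMASS", biomass_stoich, 0.0, 1000.0, GPRExpression(),
        "Biomass", "biomass")
    model.objective_id = "BIOMASS"
    truth.kind_tags["BIOMASS"] = "biomass"

    truth.rich_medium = MediumCondition(
        bounds={rid: (-1000.0, 1000.0) for rid in exchange_ids}, id="rich"
    )
    truth.minimal_medium = MediumCondition(
        bounds={rid: (-spec.uptake_rate, 1000.0) for rid in exchange_ids},
        id="minimal",
    )

    model.validate()
    return model, truth


def generate_homology_table(
    spec: SyntheticSpec,
    model: MetabolicModel,
    retention: float = 0.97,
    species: str = "target",
    seed: int | None = None,
) -> HomologyTable:
    """Retain each source gene independently with probability ``retention``,
    mapping it to one or two synthetic target-namespace ids."""
    if not 0 <= retention <= 1:
        raise ModelError("retention must be in [0, 1]")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    mapping: dict[str, set[str]] = {}
    for g in model.genes:
        if rng.random() < retention:
            targets = {f"t_{g}"}
            if rng.random() < 0.2:
                targets.add(f"t_{g}_b")
            mapping[g] = targets
    return HomologyTable(mapping=mapping, species=species, provenance="synthetic")


def plant_gaps(
    model: MetabolicModel,
    truth: GroundTruth,
    k: int,
    seed: int = 0,
) -> tuple[MetabolicModel, list[str]]:
    """Remove ``k`` sole-path conversion reactions (one per pathway) so the
    model can no longer produce biomass; returns (gapped model, removed)."""
    if k == 0:
        return model.copy(), []
    rng = np.random.default_rng(seed)
    pathways = sorted(truth.pathway_reactions)
    if k > len(pathways):
        raise ModelError(f"cannot plant {k} gaps across {len(pathways)} pathways")
    chosen_paths = rng.choice(pathways, size=k, replace=False)
    removed: list[str] = []
    out = model.copy()
    for i in sorted(int(p) for p in chosen_paths):
        conv = [r for r in truth.pathway_reactions[i] if r.startswith("C_")]
        rid = conv[int(rng.integers(len(conv)))]
        del out.reactions[rid]
        removed.append(rid)
    truth.planted_gaps = set(removed)
    from .flux import solve_fba
    from .model import apply_medium

    check = apply_medium(out, truth.rich_medium)
    sol = solve_fba(check)
    if sol.optimal and sol.objective > 1e-6:
        raise ModelError("planted gaps failed to break biomass production")
    return out, removed


def generate_test_battery(
    model: MetabolicModel,
    truth: GroundTruth,
) -> list[ValidationTest]:
    """One producibility test per biomass precursor, plus one
    compartment-specific test per mitochondrial intermediate; dependency
    sets (the pathway reactions each test needs) are recorded in the
    ground truth."""
    tests: list[ValidationTest] = []
    medium = truth.rich_medium
    for i, prec in enumerate(truth.precursors):
        tid = f"test_prec_{i:02d}"
        tests.append(
            ValidationTest(
                id=tid,
                description=f"produce biomass precursor {prec}",
                target=prec,
                medium=medium,
            )
        )
        truth.test_dependencies[tid] = set(truth.pathway_reactions[i])
    for i in sorted(truth.pathway_reactions):
        mito = [
            rid
            for rid in truth.pathway_reactions[i]
            if any(mid.endswith("[m]") for mid in model.reactions[rid].stoichiometry)
            and rid.startswith("C_")
        ]
        if not mito:
            continue
        target = next(
            mid
            for mid in model.reactions[mito[0]].stoichiometry
            if mid.endswith("[m]") and model.reactions[mito[0]].stoichiometry[mid] > 0
        )
        tid = f"test_mito_{i:02d}"
        tests.append(
            ValidationTest(
                id=tid,
                description=f"produce mitochondrial intermediate {target}",
                target=target,
                medium=medium,
                compartment_specific=True,
            )
        )
        deps = set()
        for rid in truth.pathway_reactions[i]:
            deps.add(rid)
            if rid == mito[0]:
                break
        truth.test_dependencies[tid] = deps
    return tests


def generate_decoy_db(
    n: int = 50,
    seed: int = 0,
    evidence_rate: float = 0.8,
):
    """A universal-database of nonsense reactions over fresh metabolites —
    decoys that can never restore biomass production."""
    from .gapfill import DBReaction, UniversalReactionDB

    rng = np.random.default_rng(seed)
    db = UniversalReactionDB()
    for q in range(n):
        a, b = f"u{q:03d}a", f"u{q:03d}b"
        db.add(
            DBReaction(
                id=f"U_{q:03d}",
                stoichiometry={a: -1.0, b: 1.0},
                reversible=bool(rng.random() < 0.5),
                evidence=bool(rng.random() < evidence_rate),
                source=f"SYN{q:05d}",
            )
        )
    return db


def db_entry_for(model_reaction: Reaction, evidence: bool = True):
    """Compartment-free database version of a model reaction (used to seed
    a universal db that contains a planted gap's fix)."""
    from .gapfill import DBReaction
    from .model import Metabolite

    stoich: dict[str, float] = {}
    for mid, coef in model_reaction.stoichiometry.items():
        base = Metabolite.parse_id(mid)[0]
        stoich[base] = stoich.get(base, 0.0) + coef
    return DBReaction(
        id=f"DB_{model_reaction.id}",
        stoichiometry={m: c for m, c in stoich.items() if c != 0},
        reversible=model_reaction.reversible,
        evidence=evidence,
        source=f"SRC_{model_reaction.id}",
    )
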