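"""Orthology-based projection of a source reconstruction onto a target species.

Two projection rules are provided. Approach A keeps a gene-associated
reaction iff its GPR still evaluates true when exactly the source genes
with at least one target homolog are "present" (so an isozyme with a
mapped partner rescues the reaction), and keeps every non-gene-associated
reaction. Approach B applies the same GPR rule but keeps, among the
non-gene-associated reactions, only transporters, demand/sink, exchange
and biomass reactions — dropping bare metabolic reactions without gene
support.

Retained GPRs are rewritten into the target gene namespace (each source
leaf becomes an OR over its homologs). A decompartmentalized variant of a
model merges all intracellular compartments into one while keeping the
extracellular space, so exchanges and media stay meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .gpr import translate_gpr
from .model import Gene, MetabolicModel, Metabolite, Reaction, classify_reaction


@dataclass
class HomologyTable:
    """Map from source gene ids to sets of target-species gene ids.

    A source gene absent from the mapping is treated exactly like one
    mapping to the empty set (no homolog found).
    """

    mapping: dict[str, set[str]] = field(default_factory=dict)
    species: str = ""
    provenance: str = ""

    def mapped_source_genes(self) -> set[str]:
        return {g for g, t in self.mapping.items() if t}

    def targets(self, source_gene: str) -> set[str]:
        return set(self.mapping.get(source_gene, ()))


@dataclass
class ProjectionReport:
    """Bookkeeping of one projection: what survived and what was removed."""

    retained: list[str]
    removed: list[str]
    counts: dict[str, int]
    gene_ratio: float
    reaction_ratio: float

    def summary(self) -> dict:
        return {
            "retained": len(self.retained),
            "removed": len(self.removed),
            "gene_ratio": self.gene_ratio,
            "reaction_ratio": self.reaction_ratio,
            **self.counts,
        }


def _project(
    source: MetabolicModel,
    table: HomologyTable,
    keep_non_gene_kinds: set[str] | None,
) -> tuple[MetabolicModel, ProjectionReport]:
    present = table.mapped_source_genes() & set(source.genes)
    out = MetabolicModel(
        id=f"{source.id}_{table.species or 'target'}",
        objective_id=source.objective_id,
        compartments=source.compartments,
        extracellular=source.extracellular,
    )
    retained, removed = [], []
    counts = {
        "gene_associated_retained": 0,
        "gene_associated_removed": 0,
        "non_gene_associated_retained": 0,
        "non_gene_associated_removed": 0,
    }
    for rid, r in source.reactions.items():
        if r.gpr.is_empty:
            kind = classify_reaction(r, source)
            keep = keep_non_gene_kinds is None or kind in keep_non_gene_kinds
            key = "non_gene_associated_" + ("retained" if keep else "removed")
        else:
            keep = r.gpr.evaluate(present)
            key = "gene_associated_" + ("retained" if keep else "removed")
        counts[key] += 1
        if not keep:
            removed.append(rid)
            continue
        retained.append(rid)
        new = r.copy()
        if not r.gpr.is_empty:
            translated = translate_gpr(r.gpr, {g: table.targets(g) for g in r.gpr.genes()})
            assert translated is not None  # keep implies satisfiable under mapping
            new.gpr = translated
        out.add_reaction(new)

    # carry over gene display names where the table is 1:1-ish
    n_source_genes = len(source.genes)
    n_mapped = len(present)
    gene_ratio = n_mapped / n_source_genes if n_source_genes else 1.0
    reaction_ratio = len(retained) / len(source.reactions) if source.reactions else 1.0
    if out.objective_id is not None and out.objective_id not in out.reactions:
        out.objective_id = None
    report = ProjectionReport(retained, removed, counts, gene_ratio, reaction_ratio)
    return out, report


def project_model_A(
    source: MetabolicModel, table: HomologyTable
) -> tuple[MetabolicModel, ProjectionReport]:
    """Projection keeping all non-gene-associated reactions."""
    return _project(source, table, keep_non_gene_kinds=None)


def project_model_B(
    source: MetabolicModel, table: HomologyTable
) -> tuple[MetabolicModel, ProjectionReport]:
    """Projection dropping non-gene-associated metabolic reactions.

    Transport, demand, sink, exchange and biomass reactions are retained
    even without gene support; a non-gene-associated reaction inside a
    metabolic pathway is removed.
    """
    keep = {"transport", "demand", "sink", "exchange", "biomass"}
    return _project(source, table, keep_non_gene_kinds=keep)


# ---------------------------------------------------------------------------
# decompartmentalization
# ---------------------------------------------------------------------------

def decompartmentalize(
    model: MetabolicModel,
    merged_code: str = "c",
    keep_extracellular: bool = True,
) -> MetabolicModel:
    """Merge all intracellular compartments into one.

    The extracellular space is kept by default so exchange reactions and
    media remain meaningful (set ``keep_extracellular=False`` for a full
    single-compartment merge). Reactions whose stoichiometry cancels out
    (pure intracellular transport) are removed; reactions that become
    duplicates — identical stoichiometry and direction — are merged,
    keeping the OR of their GPRs since either enzyme suffices once
    location is lost.
    """
    ext = model.extracellular
    out = MetabolicModel(
        id=f"{model.id}_collapsed",
        objective_id=model.objective_id,
        compartments=(merged_code, ext) if keep_extracellular else (merged_code,),
        extracellular=ext if keep_extracellular else merged_code,
    )

    def remap(mid: str) -> str:
        base, comp = Metabolite.parse_id(mid)
        if keep_extracellular and comp == ext:
            return mid
        return f"{base}[{merged_code}]"

    from .gpr import BoolOp, GPRExpression

    seen: dict[tuple, str] = {}
    for rid, r in model.reactions.items():
        stoich: dict[str, float] = {}
        for mid, coef in r.stoichiometry.items():
            key = remap(mid)
            stoich[key] = stoich.get(key, 0.0) + coef
        stoich = {m: c for m, c in stoich.items() if c != 0}
        if not stoich:
            if model.objective_id == rid:
                out.objective_id = None
            continue
        sig = (
            tuple(sorted(stoich.items())),
            r.lower < 0,
            r.upper > 0,
        )
        if sig in seen and rid != model.objective_id:
            prev = out.reactions[seen[sig]]
            prev.lower = min(prev.lower, r.lower)
            prev.upper = max(prev.upper, r.upper)
            if not r.gpr.is_empty:
                if prev.gpr.is_empty:
                    prev.gpr = GPRExpression(r.gpr.root)
                elif r.gpr.to_string() != prev.gpr.to_string():
                    prev.gpr = GPRExpression(BoolOp("or", (prev.gpr.root, r.gpr.root)))
            continue
        new = r.copy()
        new.stoichiometry = stoich
        out.add_reaction(new)
        if rid != model.objective_id:
            seen[sig] = rid
    return out


# ---------------------------------------------------------------------------
# dead ends
# ---------------------------------------------------------------------------

def count_dead_ends(model: MetabolicModel) -> set[str]:
    """Metabolites that, accounting for reversibility, can only ever be
    produced or only ever consumed — so no steady-state flux can pass
    through them."""
    producible: set[str] = set()
    consumable: set[str] = set()
    for r in model.reactions.values():
        fwd = r.upper > 0
        rev = r.lower < 0
        for mid, coef in r.stoichiometry.items():
            if coef > 0:
                if fwd:
                    producible.add(mid)
                if rev:
                    consumable.add(mid)
            else:
                if fwd:
                    consumable.add(mid)
                if rev:
                    producible.add(mid)
    return {
        mid
        for mid in model.metabolites
        if (mid in producible) != (mid in consumable)
        or (mid not in producible and mid not in consumable)
    }
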