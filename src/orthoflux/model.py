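"""Core constraint-based model types.

A :class:`MetabolicModel` is a compartmentalized stoichiometric network:
genes, metabolites and bounded reactions with GPR rules, subsystem labels
and a single biomass objective. The stoichiometric matrix S (metabolites x
reactions) is implied by the reaction coefficients; steady state means
S·v = 0 with each flux v_i inside its (lower, upper) bounds in
mmol/gDW/hr. The conventional global bound magnitude is 1000.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

from .gpr import GPRExpression

#: Default compartment codes: cytoplasm, extracellular, mitochondria,
#: Golgi, lysosome, endoplasmic reticulum (some source dialects label the
#: same code "ribosome"), peroxisome, nucleus.
DEFAULT_COMPARTMENTS = ("c", "e", "m", "g", "l", "r", "x", "n")

#: Boundary compartment: metabolites here are exchanged with the medium.
EXTRACELLULAR = "e"

DEFAULT_BOUND = 1000.0

REACTION_KINDS = ("metabolic", "transport", "exchange", "demand", "sink", "biomass")


class ModelError(ValueError):
    """Structural problem in a model or a file describing one."""


@dataclass(frozen=True)
class Gene:
    id: str
    name: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ModelError("gene id must be non-empty")


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in one compartment; identity is (base_id, compartment)."""

    base_id: str
    compartment: str
    formula: str | None = None
    charge: int | None = None

    @property
    def id(self) -> str:
        return f"{self.base_id}[{self.compartment}]"

    @staticmethod
    def parse_id(met_id: str) -> tuple[str, str]:
        """Split ``"glc[c]"`` into ``("glc", "c")``."""
        if met_id.endswith("]") and "[" in met_id:
            base, _, comp = met_id[:-1].rpartition("[")
            if base and comp:
                return base, comp
        raise ModelError(f"metabolite id {met_id!r} lacks a [compartment] suffix")


@dataclass
class Reaction:
    """A bounded flux: stoichiometry maps metabolite ids to nonzero coefficients
    (negative = substrate). Reversibility is encoded by lower < 0 < upper."""

    id: str
    stoichiometry: dict[str, float]
    lower: float = 0.0
    upper: float = DEFAULT_BOUND
    gpr: GPRExpression = field(default_factory=GPRExpression)
    subsystem: str = ""
    name: str | None = None

    def __post_init__(self):
        if self.lower > self.upper:
            raise ModelError(f"reaction {self.id}: lower bound exceeds upper bound")
        if any(c == 0 for c in self.stoichiometry.values()):
            raise ModelError(f"reaction {self.id}: zero stoichiometric coefficient")

    @property
    def reversible(self) -> bool:
        return self.lower < 0 < self.upper

    @property
    def gene_associated(self) -> bool:
        return not self.gpr.is_empty

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    """Genes, metabolites and reactions keyed by id, plus the objective
    (biomass) reaction id. Insertion order of reactions is preserved and
    used everywhere a deterministic ordering is needed."""

    id: str = "model"
    genes: dict[str, Gene] = field(default_factory=dict)
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    objective_id: str | None = None
    compartments: tuple[str, ...] = DEFAULT_COMPARTMENTS
    extracellular: str = EXTRACELLULAR

    # -- construction -------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                base, comp = Metabolite.parse_id(mid)
                self.metabolites[mid] = Metabolite(base, comp)
        for g in rxn.gpr.genes():
            self.genes.setdefault(g, Gene(g))
        self.reactions[rxn.id] = rxn

    def copy(self) -> "MetabolicModel":
        m = MetabolicModel(
            id=self.id,
            genes=dict(self.genes),
            metabolites=dict(self.metabolites),
            reactions={rid: r.copy() for rid, r in self.reactions.items()},
            objective_id=self.objective_id,
            compartments=self.compartments,
            extracellular=self.extracellular,
        )
        return m

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        """Check referential integrity; raises :class:`ModelError`."""
        for rid, r in self.reactions.items():
            if not r.stoichiometry:
                raise ModelError(f"reaction {rid} has empty stoichiometry")
            for mid in r.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelError(f"reaction {rid} references unknown metabolite {mid}")
            for g in r.gpr.genes():
                if g not in self.genes:
                    raise ModelError(f"reaction {rid} references unknown gene {g}")
        if self.objective_id is not None and self.objective_id not in self.reactions:
            raise ModelError(f"objective {self.objective_id!r} not in model")

    # -- numeric view -------------------------------------------------
    def reaction_order(self) -> list[str]:
        return list(self.reactions)

    def metabolite_order(self) -> list[str]:
        return list(self.metabolites)

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """S with shape (n_metabolites, n_reactions) in model order."""
        mrow = {mid: i for i, mid in enumerate(self.metabolites)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(self.reactions.values()):
            for mid, coef in r.stoichiometry.items():
                rows.append(mrow[mid])
                cols.append(j)
                vals.append(coef)
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower for r in self.reactions.values()])
        ub = np.array([r.upper for r in self.reactions.values()])
        return lb, ub

    # -- classification helpers ---------------------------------------
    def exchange_ids(self) -> list[str]:
        return [rid for rid, r in self.reactions.items()
                if classify_reaction(r, self) == "exchange"]


def classify_reaction(rxn: Reaction, model: MetabolicModel) -> str:
    """Tag a reaction as exchange / demand / sink / transport / biomass / metabolic.

    * exchange: touches exactly one metabolite, extracellular;
    * demand: one intracellular metabolite, irreversible drain;
    * sink: one intracellular metabolite, reversible;
    * transport: the multiset of (base id, |coef|) on each side matches
      across compartments — the metabolite moves without chemical change;
    * biomass: the model objective;
    * metabolic: everything else.
    """
    if model.objective_id is not None and rxn.id == model.objective_id:
        return "biomass"
    mids = list(rxn.stoichiometry)
    if len(mids) == 1:
        base, comp = Metabolite.parse_id(mids[0])
        if comp == model.extracellular:
            return "exchange"
        return "sink" if rxn.reversible else "demand"
    subs = sorted(
        (Metabolite.parse_id(m)[0], abs(c))
        for m, c in rxn.stoichiometry.items() if c < 0
    )
    prods = sorted(
        (Metabolite.parse_id(m)[0], abs(c))
        for m, c in rxn.stoichiometry.items() if c > 0
    )
    comps = {Metabolite.parse_id(m)[1] for m in mids}
    if subs == prods and subs and len(comps) >= 2:
        return "transport"
    return "metabolic"


@dataclass
class MediumCondition:
    """Exchange bounds defining a growth condition.

    ``bounds`` maps exchange-reaction ids to (lower, upper); any exchange
    not listed has its uptake closed (lower = 0) and secretion left at the
    default bound. A negative lower bound is an allowed uptake rate.
    """

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    id: str = "medium"
    default_secretion: float = DEFAULT_BOUND


def unrestricted_medium(model: MetabolicModel, uptake: float = DEFAULT_BOUND) -> MediumCondition:
    """Open every exchange to uptake at -`uptake`: the draft-model screening
    condition (uptake of all extracellular metabolites allowed)."""
    return MediumCondition(
        bounds={rid: (-uptake, DEFAULT_BOUND) for rid in model.exchange_ids()},
        id="unrestricted",
    )


def apply_medium(model: MetabolicModel, medium: MediumCondition) -> MetabolicModel:
    """Return a copy with exchange bounds set from the medium.

    All exchange uptakes not listed are closed; non-exchange reactions are
    untouched. Listing a non-exchange reaction id is an error.
    """
    exchanges = set(model.exchange_ids())
    for rid in medium.bounds:
        if rid not in model.reactions:
            raise ModelError(f"medium lists unknown reaction {rid!r}")
        if rid not in exchanges:
            raise ModelError(f"medium lists non-exchange reaction {rid!r}")
    out = model.copy()
    for rid in exchanges:
        r = out.reactions[rid]
        if rid in medium.bounds:
            lo, hi = medium.bounds[rid]
            r.lower, r.upper = float(lo), float(hi)
        else:
            r.lower = 0.0
            r.upper = min(r.upper, medium.default_secretion) if r.upper > 0 else r.upper
            r.upper = max(r.upper, 0.0)
    return out
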