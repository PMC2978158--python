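"""Minimal-addition gap filling over a universal reaction database.

Given a model that cannot carry flux through a target reaction (e.g.
biomass), find the smallest set of database reactions whose addition
restores producibility. This is the classic MILP formulation: a binary
indicator y_j per candidate reaction, |v_j| <= M*y_j coupling, steady
state over the combined network, target flux >= epsilon, minimize
sum(y). After each optimum an integer cut excludes the found set and
the MILP is re-solved, enumerating alternate solutions of non-decreasing
cardinality; a configurable number of iterations is run and each
solution is then screened by mechanical acceptance filters
(no de-facto reversal of a known irreversible reaction; organism
evidence required).

Database reactions are compartment-free; they are instantiated in the
model's cytosolic compartment, with transport/exchange candidates
(which carry explicit compartment suffixes) bridging to the medium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .flux import solve_fba
from .model import DEFAULT_BOUND, MetabolicModel, ModelError, Reaction
from .gpr import GPRExpression

#: Minimum target flux a gap-fill solution must enable.
DEFAULT_EPSILON = 1.0

#: Big-M linking flux to the binary indicator; the global bound magnitude.
DEFAULT_BIG_M = 1000.0


@dataclass
class DBReaction:
    """A universal-database entry. Stoichiometry keys are base metabolite
    ids (no compartment); keys already carrying ``[comp]`` are honored as
    written (used by transport/exchange candidates)."""

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = True
    evidence: bool = False
    source: str = ""


@dataclass
class UniversalReactionDB:
    reactions: dict[str, DBReaction] = field(default_factory=dict)

    def add(self, rxn: DBReaction) -> None:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate db reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn

    def copy(self) -> "UniversalReactionDB":
        return UniversalReactionDB(dict(self.reactions))


@dataclass
class GapFillSolution:
    added: frozenset[str]
    objective_flux: float
    iteration: int
    accepted: bool | None = None
    reject_reason: str | None = None


@dataclass
class GapFillReport:
    solutions: list[GapFillSolution]
    n_iterations: int

    def frequencies(self) -> dict[str, int]:
        freq: dict[str, int] = {}
        for s in self.solutions:
            for rid in s.added:
                freq[rid] = freq.get(rid, 0) + 1
        return freq

    def accepted_solutions(self) -> list[GapFillSolution]:
        return [s for s in self.solutions if s.accepted]


# ---------------------------------------------------------------------------
# db file dialect
# ---------------------------------------------------------------------------

def write_db_tsv(db: UniversalReactionDB, path: str | Path) -> None:
    from .io import format_equation

    rows = [
        {
            "reaction_id": r.id,
            "equation": _format_db_equation(r),
            "reversible": int(r.reversible),
            "evidence": int(r.evidence),
            "source": r.source,
        }
        for r in db.reactions.values()
    ]
    pd.DataFrame(
        rows, columns=["reaction_id", "equation", "reversible", "evidence", "source"]
    ).to_csv(path, sep="\t", index=False)


def _format_db_equation(r: DBReaction) -> str:
    def side(items):
        return " + ".join(
            (m if abs(c) == 1 else f"{abs(c):g} {m}") for m, c in items
        )

    subs = [(m, c) for m, c in r.stoichiometry.items() if c < 0]
    prods = [(m, c) for m, c in r.stoichiometry.items() if c > 0]
    arrow = "<->" if r.reversible else "->"
    return f"{side(subs)} {arrow} {side(prods)}".strip()


def read_db_tsv(path: str | Path) -> UniversalReactionDB:
    df = pd.read_csv(path, sep="\t")
    db = UniversalReactionDB()
    for _, row in df.iterrows():
        eq = str(row["equation"])
        arrow = "<->" if "<->" in eq or "<=>" in eq else "->"
        stoich = _parse_db_equation(eq)
        db.add(
            DBReaction(
                id=str(row["reaction_id"]),
                stoichiometry=stoich,
                reversible=arrow == "<->" or bool(int(row["reversible"])),
                evidence=bool(int(row["evidence"])),
                source="" if pd.isna(row.get("source")) else str(row["source"]),
            )
        )
    return db


def _parse_db_equation(text: str) -> dict[str, float]:
    import re

    for arrow in ("<->", "<=>", "->", "=>"):
        if arrow in text:
            left, right = text.split(arrow, 1)
            break
    else:
        raise ModelError(f"db equation {text!r} has no arrow")
    out: dict[str, float] = {}
    for chunk, sign in ((left, -1.0), (right, +1.0)):
        chunk = chunk.strip()
        if not chunk:
            continue
        for term in chunk.split("+"):
            term = term.strip()
            m = re.match(r"^(\d+(?:\.\d+)?)\s+(.+)$", term)
            coef, mid = (float(m.group(1)), m.group(2).strip()) if m else (1.0, term)
            out[mid] = out.get(mid, 0.0) + sign * coef
    return {m: c for m, c in out.items() if c != 0}


# ---------------------------------------------------------------------------
# transport / exchange augmentation
# ---------------------------------------------------------------------------

def build_transport_exchange_db(
    model: MetabolicModel,
    db: UniversalReactionDB,
    compartment: str = "c",
) -> UniversalReactionDB:
    """Augment a database with one reversible exchange and one reversible
    uptake transport per metabolite not already covered, so gap filling may
    import any metabolite from the boundary when that is the cheapest fix."""
    from .model import Metabolite, classify_reaction

    out = db.copy()
    ext = model.extracellular

    have_exchange: set[str] = set()
    have_transport: set[str] = set()
    for r in model.reactions.values():
        kind = classify_reaction(r, model)
        bases = {Metabolite.parse_id(m)[0] for m in r.stoichiometry}
        if kind == "exchange":
            have_exchange.update(bases)
        elif kind == "transport":
            comps = {Metabolite.parse_id(m)[1] for m in r.stoichiometry}
            if ext in comps:
                have_transport.update(bases)

    bases: set[str] = {Metabolite.parse_id(m)[0] for m in model.metabolites}
    for r in db.reactions.values():
        for m in r.stoichiometry:
            bases.add(Metabolite.parse_id(m)[0] if "[" in m else m)

    for base in sorted(bases):
        if base not in have_exchange:
            out.add(
                DBReaction(
                    id=f"EX_gf_{base}",
                    stoichiometry={f"{base}[{ext}]": -1.0},
                    reversible=True,
                    evidence=True,
                    source="boundary",
                )
            )
        if base not in have_transport:
            out.add(
                DBReaction(
                    id=f"TR_gf_{base}",
                    stoichiometry={f"{base}[{ext}]": -1.0, f"{base}[{compartment}]": 1.0},
                    reversible=True,
                    evidence=True,
                    source="boundary",
                )
            )
    return out


# ---------------------------------------------------------------------------
# the MILP
# ---------------------------------------------------------------------------

def _instantiate(db_rxn: DBReaction, compartment: str) -> dict[str, float]:
    return {
        (m if "[" in m else f"{m}[{compartment}]"): c
        for m, c in db_rxn.stoichiometry.items()
    }


def gapfill(
    model: MetabolicModel,
    db: UniversalReactionDB,
    target_id: str | None = None,
    n_iter: int = 40,
    epsilon: float = DEFAULT_EPSILON,
    big_m: float = DEFAULT_BIG_M,
    compartment: str = "c",
    cut: str = "solution",
) -> GapFillReport:
    """Enumerate minimal reaction additions enabling ``target_id`` flux.

    ``cut="solution"`` excludes each found set as a whole (the default:
    later iterations may reuse individual reactions in different
    combinations); ``cut="reaction"`` bans every used reaction outright.
    Returns immediately with a zero-addition solution when the model
    already reaches the target.
    """
    if cut not in ("solution", "reaction"):
        raise ValueError("cut must be 'solution' or 'reaction'")
    target = target_id or model.objective_id
    if target is None or target not in model.reactions:
        raise ModelError(f"gap-fill target {target!r} not in model")
    if not db.reactions:
        raise ModelError("universal database is empty")

    base_sol = solve_fba(model, target)
    if base_sol.optimal and base_sol.objective >= epsilon:
        return GapFillReport(
            [GapFillSolution(frozenset(), base_sol.objective, 0)], n_iterations=0
        )

    order = model.reaction_order()
    db_order = sorted(db.reactions)
    n, d = len(order), len(db_order)

    met_index: dict[str, int] = {mid: i for i, mid in enumerate(model.metabolites)}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for j, r in enumerate(model.reactions.values()):
        for mid, coef in r.stoichiometry.items():
            rows.append(met_index[mid])
            cols.append(j)
            vals.append(coef)
    for j, rid in enumerate(db_order):
        stoich = _instantiate(db.reactions[rid], compartment)
        for mid, coef in stoich.items():
            if mid not in met_index:
                met_index[mid] = len(met_index)
            rows.append(met_index[mid])
            cols.append(n + j)
            vals.append(coef)
    n_mets = len(met_index)
    S = sparse.csr_matrix((vals, (rows, cols)), shape=(n_mets, n + d + d))

    lb = np.zeros(n + d + d)
    ub = np.zeros(n + d + d)
    mlb, mub = model.bounds_arrays()
    lb[:n], ub[:n] = mlb, mub
    j_t = order.index(target)
    if ub[j_t] < epsilon:
        raise ModelError(
            f"target {target} upper bound {ub[j_t]} below required flux {epsilon}"
        )
    lb[j_t] = max(lb[j_t], epsilon)
    for j, rid in enumerate(db_order):
        r = db.reactions[rid]
        lb[n + j] = -big_m if r.reversible else 0.0
        ub[n + j] = big_m
    ub[n + d :] = 1.0  # binaries

    # coupling rows: v_j - M y_j <= 0 and -v_j - M y_j <= 0 (if reversible)
    c_rows, c_cols, c_vals, c_ub = [], [], [], []
    row = 0
    for j, rid in enumerate(db_order):
        c_rows += [row, row]
        c_cols += [n + j, n + d + j]
        c_vals += [1.0, -big_m]
        c_ub.append(0.0)
        row += 1
        if db.reactions[rid].reversible:
            c_rows += [row, row]
            c_cols += [n + j, n + d + j]
            c_vals += [-1.0, -big_m]
            c_ub.append(0.0)
            row += 1
    A_couple = sparse.csr_matrix((c_vals, (c_rows, c_cols)), shape=(row, n + d + d))

    c = np.zeros(n + d + d)
    c[n + d :] = 1.0
    integrality = np.zeros(n + d + d)
    integrality[n + d :] = 1.0

    constraints = [
        LinearConstraint(S, np.zeros(n_mets), np.zeros(n_mets)),
        LinearConstraint(A_couple, -np.inf, np.array(c_ub)),
    ]
    cuts: list[LinearConstraint] = []

    solutions: list[GapFillSolution] = []
    for it in range(1, n_iter + 1):
        res = milp(
            c,
            constraints=constraints + cuts,
            integrality=integrality,
            bounds=Bounds(lb, ub),
        )
        if res.status != 0 or res.x is None:
            break
        y = res.x[n + d :]
        chosen = [db_order[j] for j in range(d) if y[j] > 0.5]
        v_target = float(res.x[j_t])
        solutions.append(GapFillSolution(frozenset(chosen), v_target, it))
        idx = np.array([n + d + db_order.index(r) for r in chosen], dtype=int)
        a = sparse.csr_matrix(
            (np.ones(len(idx)), (np.zeros(len(idx), dtype=int), idx)),
            shape=(1, n + d + d),
        )
        if cut == "solution":
            cuts.append(LinearConstraint(a, -np.inf, len(chosen) - 1))
        else:
            cuts.append(LinearConstraint(a, -np.inf, 0.0))
    return GapFillReport(solutions, n_iterations=len(solutions))


# ---------------------------------------------------------------------------
# acceptance filters
# ---------------------------------------------------------------------------

def _base_stoich(stoich: dict[str, float]) -> tuple:
    from .model import Metabolite

    items = {}
    for m, coef in stoich.items():
        base = Metabolite.parse_id(m)[0] if "[" in m else m
        items[base] = items.get(base, 0.0) + coef
    return tuple(sorted((m, c) for m, c in items.items() if c != 0))


def filter_solutions(
    report: GapFillReport,
    model: MetabolicModel,
    db: UniversalReactionDB,
) -> GapFillReport:
    """Mark each solution accepted or rejected.

    Rejection reasons: (i) an added reaction is the reverse of a reaction
    flagged forward-only in the database or irreversible in the model;
    (ii) an added reaction lacks the organism-evidence flag.
    """
    forward_only: set[tuple] = set()
    for r in db.reactions.values():
        if not r.reversible:
            forward_only.add(_base_stoich(r.stoichiometry))
    for r in model.reactions.values():
        if not r.reversible:
            forward_only.add(_base_stoich(r.stoichiometry))

    for sol in report.solutions:
        reason = None
        for rid in sorted(sol.added):
            r = db.reactions[rid]
            reversed_sig = _base_stoich({m: -c for m, c in r.stoichiometry.items()})
            if reversed_sig in forward_only:
                reason = f"(i) {rid} reverses a known irreversible reaction"
                break
            if not r.evidence:
                reason = f"(ii) {rid} lacks organism evidence"
                break
        sol.accepted = reason is None
        sol.reject_reason = reason
    return report


def apply_solution(
    model: MetabolicModel,
    db: UniversalReactionDB,
    solution: GapFillSolution,
    compartment: str = "c",
    big_m: float = DEFAULT_BIG_M,
) -> MetabolicModel:
    """Return a copy of the model with the solution's reactions added."""
    out = model.copy()
    for rid in sorted(solution.added):
        r = db.reactions[rid]
        out.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=_instantiate(r, compartment),
                lower=-big_m if r.reversible else 0.0,
                upper=big_m,
                gpr=GPRExpression(),
                subsystem="gap-filled",
            )
        )
    return out
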