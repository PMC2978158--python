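"""Linear-programming core: FBA, FVA, gene deletion, essentiality.

Flux balance analysis (FBA) maximizes the flux through an objective
reaction Z (typically biomass) subject to steady-state mass balance
S·v = 0 and per-reaction bounds. Flux variability analysis (FVA) then
reports, for each reaction, the minimum and maximum flux attainable
while the objective is held at (a fraction of) its optimum. Reversible
reactions are handled natively with signed bounds; all per-reaction
loops run in the model's deterministic insertion order.

Solved with the HiGHS solvers behind :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import MediumCondition, MetabolicModel, ModelError, apply_medium

#: Flux below this magnitude counts as "zero growth" in essentiality calls.
ESSENTIALITY_THRESHOLD = 1e-6

#: |v| above this counts a reaction as active in FVA-based tallies.
ACTIVITY_TOLERANCE = 1e-6


class SolverError(RuntimeError):
    """The LP solver failed for a reason other than infeasibility."""


@dataclass
class FluxSolution:
    objective: float
    fluxes: dict[str, float]
    status: str  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FVAResult:
    """Per-reaction (v_min, v_max) at a fixed objective level."""

    ranges: dict[str, tuple[float, float]]
    fraction: float
    reference_objective: float

    def v_max(self, rid: str) -> float:
        return self.ranges[rid][1]

    def active_ids(self, tol: float = ACTIVITY_TOLERANCE) -> list[str]:
        return [
            rid
            for rid, (lo, hi) in self.ranges.items()
            if max(abs(lo), abs(hi)) > tol
        ]


@dataclass
class DeletionResult:
    gene: str
    disabled_reactions: list[str]
    objective: float
    essential: bool


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "error"}


def _lp(c, A_eq, b_eq, bounds):
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    status = _STATUS.get(res.status, "error")
    if status in ("iteration_limit", "error"):
        raise SolverError(res.message)
    return res, status


def solve_fba(model: MetabolicModel, objective_id: str | None = None) -> FluxSolution:
    """Maximize the objective reaction's flux at steady state."""
    obj = objective_id or model.objective_id
    if obj is None or obj not in model.reactions:
        raise ModelError(f"objective {obj!r} not in model")
    order = model.reaction_order()
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = np.zeros(len(order))
    c[order.index(obj)] = -1.0  # linprog minimizes
    res, status = _lp(c, S, np.zeros(S.shape[0]), np.column_stack([lb, ub]))
    if status != "optimal":
        return FluxSolution(float("nan"), {}, status)
    fluxes = dict(zip(order, res.x))
    return FluxSolution(float(fluxes[obj]), fluxes, "optimal")


def run_fva(
    model: MetabolicModel,
    objective_id: str | None = None,
    fraction: float = 1.0,
    reactions: list[str] | None = None,
) -> FVAResult:
    """Min/max flux per reaction with the objective held at
    ``fraction * Z*``; ``fraction=1.0`` is the "while contributing to
    maximal production" condition."""
    obj = objective_id or model.objective_id
    ref = solve_fba(model, obj)
    if not ref.optimal:
        raise ModelError(f"model infeasible; cannot run FVA ({ref.status})")
    order = model.reaction_order()
    idx = {rid: j for j, rid in enumerate(order)}
    S = model.stoichiometric_matrix()
    b = np.zeros(S.shape[0])
    lb, ub = model.bounds_arrays()
    j_obj = idx[obj]
    # fix the objective from below; tiny relaxation absorbs solver tolerance
    floor = fraction * ref.objective - 1e-9
    lb = lb.copy()
    lb[j_obj] = max(lb[j_obj], floor)
    bounds = np.column_stack([lb, ub])

    targets = reactions if reactions is not None else order
    ranges: dict[str, tuple[float, float]] = {}
    c = np.zeros(len(order))
    for rid in targets:
        j = idx[rid]
        if lb[j] == ub[j]:
            ranges[rid] = (float(lb[j]), float(ub[j]))
            continue
        c[j] = 1.0
        lo_res, st1 = _lp(c, S, b, bounds)
        c[j] = -1.0
        hi_res, st2 = _lp(c, S, b, bounds)
        c[j] = 0.0
        if st1 != "optimal" or st2 != "optimal":
            raise SolverError(f"FVA subproblem for {rid} ended {st1}/{st2}")
        lo = float(lo_res.x[j])
        hi = float(hi_res.x[j])
        if lo > hi:  # numerically inverted by solver tolerance
            lo, hi = hi, lo
        ranges[rid] = (lo, hi)
    return FVAResult(ranges, fraction, ref.objective)


def count_active(fva: FVAResult, tol: float = ACTIVITY_TOLERANCE) -> int:
    """Number of reactions able to carry non-zero flux (Table-1-style N)."""
    return len(fva.active_ids(tol))


def delete_gene(model: MetabolicModel, gene: str) -> MetabolicModel:
    """Knockout: reactions whose GPR fails without the gene get bounds (0,0)."""
    if gene not in model.genes:
        raise ModelError(f"unknown gene {gene!r}")
    present = set(model.genes) - {gene}
    out = model.copy()
    for r in out.reactions.values():
        if not r.gpr.is_empty and not r.gpr.evaluate(present):
            r.lower = 0.0
            r.upper = 0.0
    return out


def disabled_by(model: MetabolicModel, gene: str) -> list[str]:
    present = set(model.genes) - {gene}
    return [
        rid
        for rid, r in model.reactions.items()
        if not r.gpr.is_empty and not r.gpr.evaluate(present)
    ]


def essentiality_screen(
    model: MetabolicModel,
    medium: MediumCondition | None = None,
    threshold: float = ESSENTIALITY_THRESHOLD,
    genes: list[str] | None = None,
) -> list[DeletionResult]:
    """Single-gene knockouts for every gene; a gene is essential iff the
    knockout optimum falls below ``threshold`` (numerically zero growth).

    Requires positive wild-type growth under the medium.
    """
    m = apply_medium(model, medium) if medium is not None else model
    wt = solve_fba(m)
    if not wt.optimal or wt.objective < threshold:
        raise ModelError("wild type does not grow under this medium")
    results: list[DeletionResult] = []
    for g in genes if genes is not None else list(m.genes):
        disabled = disabled_by(m, g)
        if not disabled:
            results.append(DeletionResult(g, [], wt.objective, False))
            continue
        ko = delete_gene(m, g)
        sol = solve_fba(ko)
        opt = sol.objective if sol.optimal else 0.0
        results.append(DeletionResult(g, disabled, opt, opt < threshold))
    return results


def essential_genes(results: list[DeletionResult]) -> set[str]:
    return {r.gene for r in results if r.essential}
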