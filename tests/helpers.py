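"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's own solution paths:
LP optima come from exhaustive vertex enumeration, GPR evaluation from
Python's own boolean `eval`, and knockout growth from cobra's solver on
a model rebuilt from scratch.
"""

from __future__ import annotations

import itertools

import numpy as np

from orthoflux.model import MetabolicModel


# ---------------------------------------------------------------------------
# vertex-enumeration LP oracle
# ---------------------------------------------------------------------------

def fba_vertex_oracle(model: MetabolicModel, objective_id: str) -> float:
    """Maximize the objective over {S v = 0, lb <= v <= ub} by enumerating
    polytope vertices: every vertex fixes n - rank(S) variables at a bound
    with the rest solved from the equalities. Finite bounds keep the
    polytope bounded, so the optimum sits on a vertex."""
    order = model.reaction_order()
    S = model.stoichiometric_matrix().toarray()
    lb, ub = model.bounds_arrays()
    n = len(order)
    rank = np.linalg.matrix_rank(S) if S.size else 0
    j_obj = order.index(objective_id)
    n_fix = n - rank
    best = None
    for fixed_tuple in itertools.combinations(range(n), n_fix):
        fixed_idx = list(fixed_tuple)
        free_idx = [j for j in range(n) if j not in fixed_idx]
        A = S[:, free_idx]
        if free_idx and np.linalg.matrix_rank(A) < len(free_idx):
            continue
        for choice in itertools.product((0, 1), repeat=n_fix):
            v = np.zeros(n)
            for j, c in zip(fixed_idx, choice):
                v[j] = lb[j] if c == 0 else ub[j]
            if free_idx:
                rhs = -S[:, fixed_idx] @ v[fixed_idx]
                sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
                v[free_idx] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            if best is None or v[j_obj] > best:
                best = v[j_obj]
    assert best is not None, "oracle found no feasible vertex"
    return float(best)


def random_small_network(rng: np.random.Generator, n_rxns: int = 5, n_mets: int = 3):
    """A random bounded flux polytope; v = 0 is always feasible."""
    from orthoflux.model import Metabolite, Reaction

    model = MetabolicModel(id="rand", compartments=("c", "e"))
    for m in range(n_mets):
        model.add_metabolite(Metabolite(f"x{m}", "c"))
    for j in range(n_rxns):
        stoich = {}
        for m in rng.choice(n_mets, size=min(2, n_mets), replace=False):
            coef = int(rng.integers(1, 3)) * (1 if rng.random() < 0.5 else -1)
            stoich[f"x{m}[c]"] = float(coef)
        lower = float(rng.choice([-10.0, 0.0]))
        upper = float(rng.choice([5.0, 10.0]))
        model.add_reaction(Reaction(f"r{j}", stoich, lower, upper))
    return model


# ---------------------------------------------------------------------------
# GPR truth oracle via Python eval
# ---------------------------------------------------------------------------

def eval_gpr_text(text: str, present: set[str]) -> bool:
    """Evaluate a GPR rule string with Python's boolean machinery."""
    if not text.strip():
        return True
    import re

    def sub(m):
        tok = m.group(0)
        if tok.lower() in ("and", "or"):
            return tok.lower()
        return str(tok in present)

    expr = re.sub(r"[^\s()]+", sub, text)
    return bool(eval(expr))  # noqa: S307 - controlled inputs


# ---------------------------------------------------------------------------
# cobra bridge
# ---------------------------------------------------------------------------

def to_cobra(model: MetabolicModel):
    """Rebuild the model in cobra from first principles (ids, stoichiometry,
    bounds, GPR strings), for use as an independent FBA implementation."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for mid, met in model.metabolites.items():
        cmet = cobra.Metabolite(mid.replace("[", "_").replace("]", ""),
                                compartment=met.compartment)
        mets[mid] = cmet
    for rid, r in model.reactions.items():
        cr = cobra.Reaction(rid, lower_bound=r.lower, upper_bound=r.upper)
        cm.add_reactions([cr])
        cr.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        if not r.gpr.is_empty:
            cr.gene_reaction_rule = r.gpr.to_string()
    if model.objective_id:
        cm.objective = cm.reactions.get_by_id(model.objective_id)
    return cm
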