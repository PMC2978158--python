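"""FBA-based functionality test batteries and the iterative curation loop.

A validation test asks whether the model can produce a target metabolite
(through an auto-created demand reaction) or drive a named reaction under
a given medium. A battery is a set of such tests run independently, each
on a fresh copy of the model. When tests fail after orthology projection,
the curation loop searches the pool of projection-removed reactions for
minimal restorations (singles, then bounded pairs) that make failing
tests pass, mirroring the evidence-driven manual re-addition step of
reconstruction curation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .flux import solve_fba
from .gpr import GPRExpression
from .model import (
    DEFAULT_BOUND,
    MediumCondition,
    MetabolicModel,
    ModelError,
    Reaction,
    apply_medium,
)

#: Minimum flux on the test objective for "functionality".
DEFAULT_PASS_THRESHOLD = 1e-6

#: Curation search caps: restoration subsets up to this size, at most this
#: many candidate combinations per failing test.
MAX_RESTORE_DEPTH = 2
MAX_COMBINATIONS = 10_000


@dataclass
class ValidationTest:
    id: str
    description: str
    target: str  # metabolite id like "chol[c]" or an existing reaction id
    medium: MediumCondition
    threshold: float = DEFAULT_PASS_THRESHOLD
    compartment_specific: bool = False


@dataclass
class TestResult:
    test_id: str
    status: str  # pass | fail | error | skipped
    flux: float = 0.0


@dataclass
class ValidationOutcome:
    results: list[TestResult]

    @property
    def applicable(self) -> list[TestResult]:
        return [r for r in self.results if r.status in ("pass", "fail")]

    @property
    def pass_fraction(self) -> float:
        app = self.applicable
        if not app:
            return 1.0
        return sum(r.status == "pass" for r in app) / len(app)

    def failed_ids(self) -> list[str]:
        return [r.test_id for r in self.results if r.status == "fail"]


@dataclass
class CurationAction:
    """Restore one projection-removed reaction, with the tests it fixes."""

    reaction_id: str
    fixes: list[str] = field(default_factory=list)
    evidence: str = ""


def _is_collapsed(model: MetabolicModel) -> bool:
    from .model import Metabolite

    intracellular = {
        Metabolite.parse_id(mid)[1]
        for mid in model.metabolites
        if Metabolite.parse_id(mid)[1] != model.extracellular
    }
    return len(intracellular) <= 1


def run_test(model: MetabolicModel, test: ValidationTest) -> TestResult:
    """Evaluate one test on a fresh copy: apply medium, maximize the target."""
    work = apply_medium(model, test.medium)
    if test.target in work.reactions:
        objective = test.target
    elif test.target in work.metabolites:
        objective = f"DM_validation_{test.id}"
        work.add_reaction(
            Reaction(
                id=objective,
                stoichiometry={test.target: -1.0},
                lower=0.0,
                upper=DEFAULT_BOUND,
                gpr=GPRExpression(),
                subsystem="validation",
            )
        )
    else:
        return TestResult(test.id, "error")
    sol = solve_fba(work, objective)
    flux = sol.objective if sol.optimal else 0.0
    return TestResult(test.id, "pass" if flux >= test.threshold else "fail", flux)


def run_battery(
    model: MetabolicModel,
    tests: list[ValidationTest],
    skip_compartment_specific: bool | None = None,
) -> ValidationOutcome:
    """Run every test independently; compartment-specific tests are skipped
    on collapsed (single-intracellular-compartment) models, auto-detected
    unless overridden."""
    skip = (
        _is_collapsed(model)
        if skip_compartment_specific is None
        else skip_compartment_specific
    )
    results = []
    for t in tests:
        if skip and t.compartment_specific:
            results.append(TestResult(t.id, "skipped"))
        else:
            results.append(run_test(model, t))
    return ValidationOutcome(results)


def diagnose_failures(
    model: MetabolicModel,
    outcome: ValidationOutcome,
    removed_pool: list[Reaction],
    tests: list[ValidationTest],
    max_depth: int = MAX_RESTORE_DEPTH,
    max_combinations: int = MAX_COMBINATIONS,
) -> tuple[list[CurationAction], list[str]]:
    """For each failing test, search the removed pool for a minimal
    restoration (single reactions first, then pairs up to the caps) that
    makes it pass. Returns (candidate actions, unresolvable test ids)."""
    tests_by_id = {t.id: t for t in tests}
    actions: dict[str, CurationAction] = {}
    unresolvable: list[str] = []
    pool = [r for r in removed_pool if r.id not in model.reactions]

    for tid in outcome.failed_ids():
        test = tests_by_id[tid]
        found = False
        budget = max_combinations
        for depth in range(1, max_depth + 1):
            if found or budget <= 0:
                break
            for combo in itertools.combinations(pool, depth):
                budget -= 1
                if budget < 0:
                    break
                trial = model.copy()
                for rxn in combo:
                    trial.add_reaction(rxn.copy())
                if run_test(trial, test).status == "pass":
                    for rxn in combo:
                        act = actions.setdefault(
                            rxn.id,
                            CurationAction(rxn.id, evidence=f"restores test {tid}"),
                        )
                        act.fixes.append(tid)
                    found = True
                    break
        if not found:
            unresolvable.append(tid)
    return list(actions.values()), unresolvable


def apply_curation(
    model: MetabolicModel,
    actions: list[CurationAction],
    source: MetabolicModel,
) -> MetabolicModel:
    """Restore reactions named by the actions from the source model, with
    their original bounds, GPR and subsystem."""
    out = model.copy()
    for act in actions:
        if act.reaction_id in out.reactions:
            raise ModelError(f"curation collision: {act.reaction_id} already present")
        if act.reaction_id not in source.reactions:
            raise ModelError(f"curation action names unknown reaction {act.reaction_id}")
        out.add_reaction(source.reactions[act.reaction_id].copy())
    out.validate()
    return out


def curation_loop(
    model: MetabolicModel,
    tests: list[ValidationTest],
    removed_pool: list[Reaction],
    source: MetabolicModel,
    max_rounds: int = 10,
) -> tuple[MetabolicModel, ValidationOutcome, list[CurationAction]]:
    """Iterate diagnose → restore → revalidate until the battery passes or
    no further progress is possible."""
    applied: list[CurationAction] = []
    current = model
    outcome = run_battery(current, tests)
    for _ in range(max_rounds):
        if not outcome.failed_ids():
            break
        candidates, _unresolved = diagnose_failures(
            current, outcome, removed_pool, tests
        )
        if not candidates:
            break
        current = apply_curation(current, candidates, source)
        applied.extend(candidates)
        new_outcome = run_battery(current, tests)
        if new_outcome.pass_fraction <= outcome.pass_fraction and not candidates:
            break
        outcome = new_outcome
    return current, outcome, applied


# ---------------------------------------------------------------------------
# battery file dialect
# ---------------------------------------------------------------------------

def write_battery_tsv(tests: list[ValidationTest], path: str | Path) -> None:
    rows = [
        {
            "test_id": t.id,
            "description": t.description,
            "target": t.target,
            "medium_id": t.medium.id,
            "compartment_specific": int(t.compartment_specific),
        }
        for t in tests
    ]
    pd.DataFrame(
        rows,
        columns=["test_id", "description", "target", "medium_id", "compartment_specific"],
    ).to_csv(path, sep="\t", index=False)


def read_battery_tsv(
    path: str | Path, media: dict[str, MediumCondition]
) -> list[ValidationTest]:
    df = pd.read_csv(path, sep="\t")
    tests = []
    for _, row in df.iterrows():
        mid = str(row["medium_id"])
        if mid not in media:
            raise ModelError(f"battery references unknown medium {mid!r}")
        tests.append(
            ValidationTest(
                id=str(row["test_id"]),
                description=str(row["description"]),
                target=str(row["target"]),
                medium=media[mid],
                compartment_specific=bool(int(row["compartment_specific"])),
            )
        )
    return tests
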