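"""Readers and writers for the file formats the pipeline touches.

SBML is handled through libsbml. Writing emits Level 3 + fbc version 2
(flux bounds as shared parameters, GPRs as gene-product associations,
the biomass objective as an fbc objective). Reading auto-detects the
dialect: fbc models are read through the plugin; legacy Level 2 models
carry GPRs in ``GENE_ASSOCIATION`` notes and bounds in kinetic-law
parameters, the convention of early constraint-based reconstructions.

The tabular dialects are plain TSV:

* reaction table — reaction id, equation (compartment-suffixed ids,
  e.g. ``glc[e] -> glc[c]``), lower, upper, GPR string, subsystem,
  objective flag;
* medium — exchange id, lower, upper;
* homology — source gene, target species, target gene (one row/pair);
* universal reaction database — id, equation, reversible flag,
  organism-evidence flag, source id;
* validation battery — test id, description, target, medium id,
  compartment-specific flag.
"""

from __future__ import annotations

import re
from pathlib import Path

import libsbml
import pandas as pd

from .gpr import GPRExpression, parse_gpr
from .model import (
    DEFAULT_BOUND,
    MediumCondition,
    Metabolite,
    MetabolicModel,
    ModelError,
    Reaction,
)

# ---------------------------------------------------------------------------
# equation strings
# ---------------------------------------------------------------------------

_ARROWS = ("<->", "<=>", "->", "=>")


def format_equation(stoich: dict[str, float], reversible: bool) -> str:
    def side(items):
        parts = []
        for mid, coef in items:
            c = abs(coef)
            parts.append(mid if c == 1 else f"{c:g} {mid}")
        return " + ".join(parts)

    subs = [(m, c) for m, c in stoich.items() if c < 0]
    prods = [(m, c) for m, c in stoich.items() if c > 0]
    arrow = "<->" if reversible else "->"
    return f"{side(subs)} {arrow} {side(prods)}".strip()


def parse_equation(text: str) -> dict[str, float]:
    """Parse ``"2 a[c] + b[c] -> c[c]"`` into a stoichiometry map."""
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise ModelError(f"equation {text!r} has no reaction arrow")
    left, right = text.split(arrow, 1)

    def side(chunk: str, sign: float, out: dict[str, float]):
        chunk = chunk.strip()
        if not chunk:
            return
        for term in chunk.split("+"):
            term = term.strip()
            if not term:
                raise ModelError(f"empty term in equation {text!r}")
            m = re.match(r"^(\d+(?:\.\d+)?)\s+(.+)$", term)
            if m:
                coef, mid = float(m.group(1)), m.group(2).strip()
            else:
                coef, mid = 1.0, term
            Metabolite.parse_id(mid)  # validates the [compartment] suffix
            out[mid] = out.get(mid, 0.0) + sign * coef

    stoich: dict[str, float] = {}
    side(left, -1.0, stoich)
    side(right, +1.0, stoich)
    return {m: c for m, c in stoich.items() if c != 0}


# ---------------------------------------------------------------------------
# TSV reaction table
# ---------------------------------------------------------------------------

_TSV_COLS = ["reaction_id", "equation", "lower", "upper", "gpr", "subsystem", "objective"]


def write_model_tsv(model: MetabolicModel, path: str | Path) -> None:
    rows = []
    for rid, r in model.reactions.items():
        rows.append(
            {
                "reaction_id": rid,
                "equation": format_equation(r.stoichiometry, r.reversible),
                "lower": r.lower,
                "upper": r.upper,
                "gpr": r.gpr.to_string(),
                "subsystem": r.subsystem,
                "objective": int(rid == model.objective_id),
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLS).to_csv(path, sep="\t", index=False)


def read_model_tsv(path: str | Path, model_id: str | None = None) -> MetabolicModel:
    df = pd.read_csv(path, sep="\t", dtype={"gpr": str, "subsystem": str})
    model = MetabolicModel(id=model_id or Path(path).stem)
    seen: set[str] = set()
    for _, row in df.iterrows():
        rid = str(row["reaction_id"])
        if rid in seen:
            raise ModelError(f"duplicate reaction id {rid!r} in {path}")
        seen.add(rid)
        gpr_text = "" if pd.isna(row.get("gpr")) else str(row["gpr"])
        subsystem = "" if pd.isna(row.get("subsystem")) else str(row["subsystem"])
        rxn = Reaction(
            id=rid,
            stoichiometry=parse_equation(str(row["equation"])),
            lower=float(row["lower"]),
            upper=float(row["upper"]),
            gpr=parse_gpr(gpr_text),
            subsystem=subsystem,
        )
        model.add_reaction(rxn)
        if "objective" in df.columns and int(row["objective"]):
            model.objective_id = rid
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

_SID_RE = re.compile(r"[^A-Za-z0-9_]")


def _sid(prefix: str, raw: str) -> str:
    s = _SID_RE.sub("_", raw)
    if not s or not (s[0].isalpha() or s[0] == "_"):
        s = "_" + s
    return prefix + s


def _check(status, what: str):
    if status is None:
        raise ModelError(f"libsbml failed: {what}")


def write_model_sbml(model: MetabolicModel, path: str | Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sid("", model.id))
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    comps = sorted({m.compartment for m in model.metabolites.values()})
    for c in comps:
        co = sm.createCompartment()
        co.setId(_sid("", c))
        co.setConstant(True)

    sid_of_met: dict[str, str] = {}
    used: set[str] = set()
    for mid, met in model.metabolites.items():
        sid = _sid("M_", f"{met.base_id}_{met.compartment}")
        while sid in used:
            sid += "_"
        used.add(sid)
        sid_of_met[mid] = sid
        sp = sm.createSpecies()
        sp.setId(sid)
        sp.setName(mid)  # carries the bracketed id for lossless round-trip
        sp.setCompartment(_sid("", met.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    for gid in model.genes:
        gp = mplug.createGeneProduct()
        gp.setId(_sid("G_", gid))
        gp.setLabel(gid)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rid, r in model.reactions.items():
        rx = sm.createReaction()
        rx.setId(_sid("R_", rid))
        rx.setName(rid)
        rx.setReversible(r.reversible)
        rx.setFast(False)
        if r.subsystem:
            rx.setNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>SUBSYSTEM: {r.subsystem}</p></body>"
            )
        for mid, coef in r.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(sid_of_met[mid])
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower))
        rplug.setUpperFluxBound(bound_param(r.upper))
        if not r.gpr.is_empty:
            gpa = rplug.createGeneProductAssociation()
            infix = r.gpr.to_string()
            for g in sorted(r.gpr.genes(), key=len, reverse=True):
                infix = re.sub(rf"(?<![\w]){re.escape(g)}(?![\w])", _sid("G_", g), infix)
            gpa.setAssociation(infix, True, False)

    if model.objective_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        fo = obj.createFluxObjective()
        fo.setReaction(_sid("R_", model.objective_id))
        fo.setCoefficient(1.0)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise ModelError(f"could not write SBML to {path}")


def _notes_field(notes: str, key: str) -> str | None:
    m = re.search(rf"{key}:\s*([^<\n]*)", notes)
    return m.group(1).strip() if m else None


def read_model_sbml(path: str | Path, model_id: str | None = None) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise ModelError(
                    f"SBML parse error in {path}: {err.getMessage().strip()}"
                )
    sm = doc.getModel()
    if sm is None:
        raise ModelError(f"no model element in {path}")
    mplug = sm.getPlugin("fbc")
    has_fbc = mplug is not None and (
        sm.getLevel() >= 3 or mplug.getNumGeneProducts() > 0
    )

    model = MetabolicModel(id=model_id or (sm.getId() or Path(path).stem))

    gene_label: dict[str, str] = {}
    if has_fbc:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_label[gp.getId()] = gp.getLabel() or gp.getId()

    met_id: dict[str, str] = {}
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        name = sp.getName()
        if name and "[" in name and name.endswith("]"):
            mid = name
        else:
            raw = sp.getId()
            raw = raw[2:] if raw.startswith("M_") else raw
            comp = sp.getCompartment() or "c"
            # legacy dialect: trailing _<compartment> on the species id
            if raw.endswith(f"_{comp}"):
                raw = raw[: -(len(comp) + 1)]
            mid = f"{raw}[{comp}]"
        met_id[sp.getId()] = mid
        base, comp = Metabolite.parse_id(mid)
        if mid not in model.metabolites:
            model.add_metabolite(Metabolite(base, comp))

    param_val = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }

    for i in range(sm.getNumReactions()):
        rx = sm.getReaction(i)
        rid = rx.getName() or rx.getId()
        if rid.startswith("R_") and not rx.getName():
            rid = rid[2:]
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            stoich[met_id[ref.getSpecies()]] = (
                stoich.get(met_id[ref.getSpecies()], 0.0) - ref.getStoichiometry()
            )
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            stoich[met_id[ref.getSpecies()]] = (
                stoich.get(met_id[ref.getSpecies()], 0.0) + ref.getStoichiometry()
            )
        stoich = {m: c for m, c in stoich.items() if c != 0}

        lower = -DEFAULT_BOUND if rx.getReversible() else 0.0
        upper = DEFAULT_BOUND
        gpr = GPRExpression()
        subsystem = ""
        rplug = rx.getPlugin("fbc")
        if has_fbc and rplug is not None and rplug.isSetLowerFluxBound():
            lower = param_val.get(rplug.getLowerFluxBound(), lower)
            upper = param_val.get(rplug.getUpperFluxBound(), upper)
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None and gpa.getAssociation() is not None:
                infix = gpa.getAssociation().toInfix()
                for sid, label in sorted(
                    gene_label.items(), key=lambda kv: len(kv[0]), reverse=True
                ):
                    infix = re.sub(rf"(?<![\w]){re.escape(sid)}(?![\w])", label, infix)
                gpr = parse_gpr(infix)
        else:
            kl = rx.getKineticLaw()
            if kl is not None:
                for j in range(kl.getNumParameters()):
                    par = kl.getParameter(j)
                    if par.getId() == "LOWER_BOUND":
                        lower = par.getValue()
                    elif par.getId() == "UPPER_BOUND":
                        upper = par.getValue()
            notes = rx.getNotesString() or ""
            assoc = _notes_field(notes, "GENE_ASSOCIATION")
            if assoc:
                gpr = parse_gpr(assoc)
            subsystem = _notes_field(notes, "SUBSYSTEM") or ""
        if not subsystem:
            notes = rx.getNotesString() or ""
            subsystem = _notes_field(notes, "SUBSYSTEM") or ""

        if rid in model.reactions:
            raise ModelError(f"duplicate reaction id {rid!r} in {path}")
        model.add_reaction(
            Reaction(rid, stoich, lower, upper, gpr=gpr, subsystem=subsystem)
        )

    if has_fbc and mplug.getNumObjectives() > 0:
        obj = mplug.getActiveObjective() or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            target = obj.getFluxObjective(0).getReaction()
            for i in range(sm.getNumReactions()):
                rx = sm.getReaction(i)
                if rx.getId() == target:
                    model.objective_id = rx.getName() or (
                        rx.getId()[2:] if rx.getId().startswith("R_") else rx.getId()
                    )
    if model.objective_id is None:
        # legacy dialect: objective flagged in the kinetic law
        for i in range(sm.getNumReactions()):
            rx = sm.getReaction(i)
            kl = rx.getKineticLaw()
            if kl is not None:
                for j in range(kl.getNumParameters()):
                    par = kl.getParameter(j)
                    if par.getId() == "OBJECTIVE_COEFFICIENT" and par.getValue() != 0:
                        model.objective_id = rx.getName() or rx.getId()
    model.validate()
    return model


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model; format inferred from the extension when not given."""
    fmt = format or ("sbml" if str(path).endswith((".xml", ".sbml")) else "tsv")
    if fmt == "sbml":
        return read_model_sbml(path)
    if fmt == "tsv":
        return read_model_tsv(path)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    fmt = format or ("sbml" if str(path).endswith((".xml", ".sbml")) else "tsv")
    if fmt == "sbml":
        write_model_sbml(model, path)
    elif fmt == "tsv":
        write_model_tsv(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


# ---------------------------------------------------------------------------
# medium / homology / battery TSVs
# ---------------------------------------------------------------------------

def write_medium_tsv(medium: MediumCondition, path: str | Path) -> None:
    rows = [
        {"exchange_id": rid, "lower": lo, "upper": hi}
        for rid, (lo, hi) in medium.bounds.items()
    ]
    pd.DataFrame(rows, columns=["exchange_id", "lower", "upper"]).to_csv(
        path, sep="\t", index=False
    )


def read_medium_tsv(path: str | Path, medium_id: str | None = None) -> MediumCondition:
    df = pd.read_csv(path, sep="\t")
    return MediumCondition(
        bounds={
            str(r["exchange_id"]): (float(r["lower"]), float(r["upper"]))
            for _, r in df.iterrows()
        },
        id=medium_id or Path(path).stem,
    )


def write_homology_tsv(table, path: str | Path) -> None:
    rows = []
    for src, targets in table.mapping.items():
        for t in sorted(targets):
            rows.append({"source_gene": src, "target_species": table.species, "target_gene": t})
        if not targets:
            pass  # unmapped genes are simply absent (same semantics)
    pd.DataFrame(rows, columns=["source_gene", "target_species", "target_gene"]).to_csv(
        path, sep="\t", index=False
    )


def read_homology_tsv(path: str | Path):
    from .projection import HomologyTable

    df = pd.read_csv(path, sep="\t")
    mapping: dict[str, set[str]] = {}
    species = ""
    for _, r in df.iterrows():
        species = str(r["target_species"])
        mapping.setdefault(str(r["source_gene"]), set()).add(str(r["target_gene"]))
    return HomologyTable(mapping=mapping, species=species)
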