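"""Readers and writers for SBML (Level 3 + FBC), COBRA JSON and tabular models.

The three dialects cover the formats constraint-based larval models ship in.
Round-trips are structurally exact: ids, names, stoichiometry, bounds,
formulas, GPR strings and the objective survive ``read(write(m))`` for every
format.  JSON and tabular round-trips are numerically bitwise exact; SBML
stores doubles at 15 significant digits (XML serialization), i.e. exact to
about 1 part in 1e15.  Bounds absent from a file default to ±1000
mmol/larva/day.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import libsbml
import pandas as pd

from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
)

__all__ = ["read_model", "write_model", "ParseError"]

_FORMATS = ("sbml", "json", "tabular")


class ParseError(ValueError):
    """A model file is malformed; the message names the offending element."""


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    if suffix in (".xlsx", ".csv") or path.is_dir():
        return "tabular"
    raise ValueError(f"cannot infer model format from path {path}")


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a metabolic model, validating all structural invariants."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        model = _read_sbml(path)
    elif fmt == "json":
        model = _read_json(path)
    else:
        model = _read_tabular(path)
    model.validate()
    return model


def write_model(model: MetabolicModel, path: str | Path,
                format: str | None = None) -> None:
    """Write a model such that :func:`read_model` restores it exactly."""
    model.validate()
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        _write_sbml(model, path)
    elif fmt == "json":
        _write_json(model, path)
    else:
        _write_tabular(model, path)


# ---------------------------------------------------------------------------
# COBRA JSON
# ---------------------------------------------------------------------------

def _read_json(path: Path) -> MetabolicModel:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})")
    try:
        metabolites = [
            Metabolite(
                id=m["id"], name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula") or None,
                charge=m.get("charge"),
            )
            for m in doc["metabolites"]
        ]
        objective = None
        reactions = []
        for r in doc["reactions"]:
            reactions.append(Reaction(
                id=r["id"], name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                gpr=r.get("gene_reaction_rule", ""),
                subsystem=r.get("subsystem", ""),
            ))
            if r.get("objective_coefficient", 0):
                objective = r["id"]
    except KeyError as exc:
        raise ParseError(f"{path}: missing required JSON key {exc}")
    return MetabolicModel(
        id=doc.get("id", path.stem),
        metabolites=metabolites,
        reactions=reactions,
        compartments=doc.get("compartments", {}),
        objective=objective,
        objective_direction=doc.get("objective_direction", "maximize"),
        genes=[g["id"] for g in doc.get("genes", [])],
    )


def _write_json(model: MetabolicModel, path: Path) -> None:
    doc = {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment,
             **({"formula": m.formula} if m.formula else {}),
             **({"charge": m.charge} if m.charge is not None else {})}
            for m in model.metabolites
        ],
        "reactions": [
            {"id": r.id, "name": r.name, "metabolites": r.stoichiometry,
             "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
             "gene_reaction_rule": r.gpr, "subsystem": r.subsystem,
             "objective_coefficient": 1.0 if r.id == model.objective else 0.0}
            for r in model.reactions
        ],
        "genes": [{"id": g, "name": g} for g in model.genes],
        "compartments": model.compartments,
    }
    if model.objective_direction != "maximize":
        doc["objective_direction"] = model.objective_direction
    path.write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC
# ---------------------------------------------------------------------------

_SBML_PREFIXES = {"species": "M_", "reaction": "R_", "gene": "G_"}
_SID_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sid(kind: str, raw: str) -> str:
    return _SBML_PREFIXES[kind] + _SID_BAD.sub("__", raw)


def _unsid(kind: str, sid: str) -> str:
    prefix = _SBML_PREFIXES[kind]
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_SID_BAD.sub("__", model.id))
    sbml_model.setName(model.id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for code, name in (model.compartments or {"c": "cytosol"}).items():
        comp = sbml_model.createCompartment()
        comp.setId(code)
        comp.setName(name)
        comp.setConstant(True)

    for met in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(_sid("species", met.id))
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        if met.formula:
            splug.setChemicalFormula(met.formula)
        if met.charge is not None:
            splug.setCharge(met.charge)

    for gene in model.genes:
        gp = mplug.createGeneProduct()
        gp.setId(_sid("gene", gene))
        gp.setLabel(gene)

    bounds_seen: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value in bounds_seen:
            return bounds_seen[value]
        pid = f"fb_{len(bounds_seen)}"
        par = sbml_model.createParameter()
        par.setId(pid)
        par.setValue(value)
        par.setConstant(True)
        bounds_seen[value] = pid
        return pid

    for rxn in model.reactions:
        sr = sbml_model.createReaction()
        sr.setId(_sid("reaction", rxn.id))
        sr.setName(rxn.name)
        sr.setFast(False)
        sr.setReversible(rxn.lower_bound < 0)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        for met_id, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(_sid("species", met_id))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        notes = []
        if rxn.gpr:
            notes.append(f"GENE_ASSOCIATION: {rxn.gpr}")
        if rxn.subsystem:
            notes.append(f"SUBSYSTEM: {rxn.subsystem}")
        if notes:
            body = "".join(f"<p>{n}</p>" for n in notes)
            sr.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
            )

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType(model.objective_direction)
    flux_obj = objective.createFluxObjective()
    flux_obj.setReaction(_sid("reaction", model.objective))
    flux_obj.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


def _notes_fields(sr) -> dict[str, str]:
    out: dict[str, str] = {}
    if not sr.isSetNotes():
        return out
    text = sr.getNotesString()
    for match in re.finditer(r"<p>\s*([A-Z_]+):\s*(.*?)\s*</p>", text, re.S):
        out[match.group(1)] = match.group(2)
    return out


def _read_sbml(path: Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ParseError(
            f"{path}: SBML error at line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ParseError(f"{path}: document contains no <model> element")
    mplug = sbml_model.getPlugin("fbc")

    compartments = {
        c.getId(): c.getName() or c.getId()
        for c in sbml_model.getListOfCompartments()
    }
    metabolites = []
    for sp in sbml_model.getListOfSpecies():
        splug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        metabolites.append(Metabolite(
            id=_unsid("species", sp.getId()), name=sp.getName(),
            compartment=sp.getCompartment(), formula=formula, charge=charge,
        ))

    params = {
        p.getId(): p.getValue() for p in sbml_model.getListOfParameters()
    }
    reactions = []
    for sr in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in sr.getListOfReactants():
            met = _unsid("species", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for ref in sr.getListOfProducts():
            met = _unsid("species", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = params.get(rplug.getLowerFluxBound(), lb)
            if rplug.isSetUpperFluxBound():
                ub = params.get(rplug.getUpperFluxBound(), ub)
        notes = _notes_fields(sr)
        reactions.append(Reaction(
            id=_unsid("reaction", sr.getId()), name=sr.getName(),
            stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
            gpr=notes.get("GENE_ASSOCIATION", ""),
            subsystem=notes.get("SUBSYSTEM", ""),
        ))

    objective_id = None
    direction = "maximize"
    if mplug is not None and mplug.getNumObjectives():
        active = mplug.getActiveObjective() or mplug.getObjective(0)
        direction = active.getType()
        if direction == "maximize" or direction == "minimize":
            pass
        if active.getNumFluxObjectives():
            objective_id = _unsid(
                "reaction", active.getFluxObjective(0).getReaction()
            )
    genes = []
    if mplug is not None:
        genes = [
            gp.getLabel() or _unsid("gene", gp.getId())
            for gp in mplug.getListOfGeneProducts()
        ]
    return MetabolicModel(
        id=sbml_model.getName() or sbml_model.getId(),
        metabolites=metabolites,
        reactions=reactions,
        compartments=compartments,
        objective=objective_id,
        objective_direction=direction,
        genes=genes,
    )


# ---------------------------------------------------------------------------
# Tabular dialect (CSV directory or XLSX workbook)
# ---------------------------------------------------------------------------
#
# Sheets/files:
#   metabolites: id, name, compartment, formula, charge
#   reactions:   id, name, equation, lower_bound, upper_bound, gpr, subsystem
#   objective:   reaction_id, direction
#   compartments (optional): code, name
# Equations use "2 A + B -> C" syntax; "<=>" is accepted as a synonym of
# "->" on read (reversibility is carried by the bounds, not the arrow).

_ARROW = re.compile(r"->|<=>|<->")


def _format_equation(stoich: dict[str, float]) -> str:
    def side(items):
        # repr keeps full double precision so the S matrix round-trips exactly
        return " + ".join(
            (f"{repr(abs(c))} {m}" if abs(c) != 1 else m) for m, c in items
        )
    subs = [(m, c) for m, c in stoich.items() if c < 0]
    prods = [(m, c) for m, c in stoich.items() if c > 0]
    return f"{side(subs)} -> {side(prods)}"


def _parse_equation(text: str, rxn_id: str) -> dict[str, float]:
    parts = _ARROW.split(text)
    if len(parts) != 2:
        raise ParseError(
            f"reaction {rxn_id!r}: equation {text!r} needs exactly one arrow"
        )
    stoich: dict[str, float] = {}
    for sign, side in zip((-1.0, 1.0), parts):
        side = side.strip()
        if not side:
            continue
        for term in side.split("+"):
            tokens = term.split()
            if not tokens:
                raise ParseError(
                    f"reaction {rxn_id!r}: empty term in equation {text!r}"
                )
            if len(tokens) == 1:
                coef, met = 1.0, tokens[0]
            elif len(tokens) == 2:
                try:
                    coef = float(tokens[0])
                except ValueError:
                    raise ParseError(
                        f"reaction {rxn_id!r}: bad coefficient {tokens[0]!r}"
                    )
                met = tokens[1]
            else:
                raise ParseError(
                    f"reaction {rxn_id!r}: unparseable term {term!r}"
                )
            stoich[met] = stoich.get(met, 0.0) + sign * coef
    return {m: c for m, c in stoich.items() if c != 0}


def _tables_from_model(model: MetabolicModel) -> dict[str, pd.DataFrame]:
    mets = pd.DataFrame([
        {"id": m.id, "name": m.name, "compartment": m.compartment,
         "formula": m.formula or "", "charge": "" if m.charge is None else m.charge}
        for m in model.metabolites
    ])
    rxns = pd.DataFrame([
        {"id": r.id, "name": r.name,
         "equation": _format_equation(r.stoichiometry),
         "lower_bound": repr(r.lower_bound), "upper_bound": repr(r.upper_bound),
         "gpr": r.gpr, "subsystem": r.subsystem}
        for r in model.reactions
    ])
    objective = pd.DataFrame([
        {"reaction_id": model.objective,
         "direction": model.objective_direction}
    ])
    comps = pd.DataFrame(
        [{"code": k, "name": v} for k, v in model.compartments.items()]
    )
    genes = pd.DataFrame([{"id": g} for g in model.genes])
    return {"metabolites": mets, "reactions": rxns, "objective": objective,
            "compartments": comps, "genes": genes}


def _write_tabular(model: MetabolicModel, path: Path) -> None:
    tables = _tables_from_model(model)
    if path.suffix.lower() == ".xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            for name, frame in tables.items():
                frame.to_excel(writer, sheet_name=name, index=False)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for name, frame in tables.items():
            frame.to_csv(path / f"{name}.csv", index=False)


def _read_tables(path: Path) -> dict[str, pd.DataFrame]:
    if path.suffix.lower() == ".xlsx":
        sheets = pd.read_excel(path, sheet_name=None, dtype=str)
        return {k: v.fillna("") for k, v in sheets.items()}
    tables = {}
    for name in ("metabolites", "reactions", "objective", "compartments",
                 "genes"):
        f = path / f"{name}.csv"
        if f.exists():
            try:
                tables[name] = pd.read_csv(f, dtype=str).fillna("")
            except pd.errors.EmptyDataError:
                tables[name] = pd.DataFrame()
    return tables


def _read_tabular(path: Path) -> MetabolicModel:
    tables = _read_tables(path)
    for required in ("metabolites", "reactions", "objective"):
        if required not in tables:
            raise ParseError(f"{path}: tabular model lacks {required!r} table")
    metabolites = [
        Metabolite(
            id=row["id"], name=row.get("name", ""),
            compartment=row.get("compartment", "c") or "c",
            formula=row.get("formula") or None,
            charge=int(float(row["charge"])) if row.get("charge", "") != "" else None,
        )
        for _, row in tables["metabolites"].iterrows()
    ]
    reactions = []
    for _, row in tables["reactions"].iterrows():
        lb = float(row["lower_bound"]) if row.get("lower_bound", "") != "" \
            else -DEFAULT_BOUND
        ub = float(row["upper_bound"]) if row.get("upper_bound", "") != "" \
            else DEFAULT_BOUND
        reactions.append(Reaction(
            id=row["id"], name=row.get("name", ""),
            stoichiometry=_parse_equation(row["equation"], row["id"]),
            lower_bound=lb, upper_bound=ub,
            gpr=row.get("gpr", ""), subsystem=row.get("subsystem", ""),
        ))
    obj_table = tables["objective"]
    if not len(obj_table):
        raise ParseError(f"{path}: empty objective table")
    objective = obj_table.iloc[0]["reaction_id"]
    direction = obj_table.iloc[0].get("direction", "maximize") or "maximize"
    compartments = {}
    if "compartments" in tables and len(tables["compartments"]):
        compartments = dict(
            zip(tables["compartments"]["code"], tables["compartments"]["name"])
        )
    genes = []
    if "genes" in tables and len(tables["genes"]):
        genes = list(tables["genes"]["id"])
    return MetabolicModel(
        id=path.stem, metabolites=metabolites, reactions=reactions,
        compartments=compartments, objective=objective,
        objective_direction=direction, genes=genes,
    )
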