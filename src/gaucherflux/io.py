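"""Model file I/O: a documented JSON dialect and SBML Level 3 + FBC v2.

JSON dialect (schema tag ``gaucherflux-model-1``)::

    {
      "schema": "gaucherflux-model-1",
      "id": "toy",
      "metabolites": [{"id": "glc[e]", "name": "...", "formula": null}, ...],
      "reactions": [
        {"id": "HEX1",
         "stoichiometry": {"glc[c]": -1, "atp[c]": -1, "g6p[c]": 1, "adp[c]": 1},
         "lb": 0.0, "ub": 1000.0,
         "subsystem": "Glycolysis",
         "gpr": "HK1",
         "objective_coefficient": 0.0},
        ...
      ]
    }

Bounds are mandatory in both dialects: a reaction without explicit lb/ub is
a parse error, never silently defaulted.  Round-tripping a model through
either writer reproduces S, bounds and GPRs exactly.

SBML identifiers cannot contain brackets, so metabolite ids are encoded as
``M_<base>_<compartment>`` (e.g. ``glc[e]`` -> ``M_glc_e``), reactions get an
``R_`` prefix and genes a ``G_`` prefix; the readers reverse the encoding.
"""

from __future__ import annotations

import json
from pathlib import Path

import libsbml

from .gpr import GPRRule, parse_gpr
from .model import MetabolicModel, Metabolite, Reaction

JSON_SCHEMA = "gaucherflux-model-1"


class ModelParseError(ValueError):
    """Raised when a model file is malformed."""


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "schema": JSON_SCHEMA,
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "formula": m.formula}
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(r.stoichiometry),
                "lb": r.lb,
                "ub": r.ub,
                "subsystem": r.subsystem,
                "gpr": r.gpr.to_string(),
                "objective_coefficient": r.objective_coefficient,
            }
            for r in model.reactions.values()
        ],
    }


def model_from_dict(data: dict) -> MetabolicModel:
    if not isinstance(data, dict) or "reactions" not in data:
        raise ModelParseError("not a model document: missing 'reactions'")
    model = MetabolicModel(id=data.get("id", "model"))
    for entry in data.get("metabolites", []):
        try:
            model.add_metabolite(
                Metabolite(
                    id=entry["id"],
                    name=entry.get("name", ""),
                    formula=entry.get("formula"),
                )
            )
        except KeyError as exc:
            raise ModelParseError(f"metabolite entry missing field {exc}: {entry}") from None
    for entry in data["reactions"]:
        rid = entry.get("id", "<missing id>")
        for required in ("stoichiometry", "lb", "ub"):
            if required not in entry:
                raise ModelParseError(f"reaction {rid!r}: missing field {required!r}")
        if entry["lb"] is None or entry["ub"] is None:
            raise ModelParseError(f"reaction {rid!r}: bounds must be numeric, got null")
        model.add_reaction(
            Reaction(
                id=entry["id"],
                stoichiometry={k: float(v) for k, v in entry["stoichiometry"].items()},
                lb=float(entry["lb"]),
                ub=float(entry["ub"]),
                subsystem=entry.get("subsystem", ""),
                gpr=parse_gpr(entry.get("gpr", "")),
                objective_coefficient=float(entry.get("objective_coefficient", 0.0)),
            )
        )
    return model


def write_json_model(model: MetabolicModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=False) + "\n")


def read_json_model(path: str | Path) -> MetabolicModel:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"{path}: invalid JSON ({exc})") from None
    return model_from_dict(data)


# ---------------------------------------------------------------------------
# SBML L3 + FBC v2
# ---------------------------------------------------------------------------

def _encode_met(met_id: str) -> str:
    base, comp = met_id.rsplit("[", 1)
    return "M_" + _sanitize(base) + "_" + comp.rstrip("]")


def _sanitize(s: str) -> str:
    out = []
    for ch in s:
        out.append(ch if (ch.isalnum() or ch == "_") else "__")
    text = "".join(out)
    if text and text[0].isdigit():
        text = "_" + text
    return text


def _decode_met(sid: str, compartment: str) -> str:
    base = sid
    if base.startswith("M_"):
        base = base[2:]
    suffix = "_" + compartment
    if base.endswith(suffix):
        base = base[: -len(suffix)]
    if base.startswith("_") and base[1:2].isdigit():
        base = base[1:]
    return f"{base}[{compartment}]"


def _decode_plain(sid: str, prefix: str) -> str:
    out = sid[len(prefix):] if sid.startswith(prefix) else sid
    if out.startswith("_") and out[1:2].isdigit():
        out = out[1:]
    return out


def _gpr_to_association(rule: GPRRule, fbc_rxn, doc_assoc_parent) -> None:
    if rule.op == "gene":
        ref = doc_assoc_parent.createGeneProductRef()
        ref.setGeneProduct("G_" + _sanitize(rule.gene))
        return
    node = (
        doc_assoc_parent.createAnd() if rule.op == "and" else doc_assoc_parent.createOr()
    )
    for child in rule.children:
        _gpr_to_association(child, fbc_rxn, node)


def _association_to_gpr(assoc) -> GPRRule:
    if assoc is None:
        return GPRRule()
    if assoc.isGeneProductRef():
        return GPRRule(op="gene", gene=_decode_plain(assoc.getGeneProduct(), "G_"))
    op = "and" if assoc.isFbcAnd() else "or"
    children = tuple(
        _association_to_gpr(assoc.getAssociation(i))
        for i in range(assoc.getNumAssociations())
    )
    return GPRRule(op=op, children=children)


def write_sbml_model(model: MetabolicModel, path: str | Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sanitize(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites.values()})
    for comp in compartments:
        c = sbml_model.createCompartment()
        c.setId(comp)
        c.setConstant(True)
        c.setSize(1.0)

    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId(_encode_met(met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        if met.formula:
            spl = sp.getPlugin("fbc")
            spl.setChemicalFormula(met.formula)

    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId("G_" + _sanitize(gene))
        gp.setLabel(gene)

    bound_ids: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_ids:
            pid = f"bnd_{len(bound_ids)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_ids[value] = pid
        return bound_ids[value]

    for rxn in model.reactions.values():
        r = sbml_model.createReaction()
        r.setId("R_" + _sanitize(rxn.id))
        r.setName(rxn.id)
        r.setFast(False)
        r.setReversible(rxn.lb < 0)
        if rxn.subsystem:
            r.appendNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'><p>SUBSYSTEM: {rxn.subsystem}</p></body>"
            )
        for met_id, coef in rxn.stoichiometry.items():
            if coef < 0:
                sr = r.createReactant()
                sr.setStoichiometry(-coef)
            else:
                sr = r.createProduct()
                sr.setStoichiometry(coef)
            sr.setSpecies(_encode_met(met_id))
            sr.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lb))
        rplug.setUpperFluxBound(bound_param(rxn.ub))
        if not rxn.gpr.is_empty():
            ga = rplug.createGeneProductAssociation()
            _gpr_to_association(rxn.gpr, rplug, ga)

    objective_rxns = [r for r in model.reactions.values() if r.objective_coefficient]
    if objective_rxns:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        for rxn in objective_rxns:
            fo = obj.createFluxObjective()
            fo.setReaction("R_" + _sanitize(rxn.id))
            fo.setCoefficient(rxn.objective_coefficient)

    libsbml.writeSBMLToFile(doc, str(path))


def read_sbml_model(path: str | Path) -> MetabolicModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"{path}: SBML error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path}: no <model> element")
    mplug = sbml_model.getPlugin("fbc")

    model = MetabolicModel(id=sbml_model.getId() or "model")
    met_ids: dict[str, str] = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        met_id = _decode_met(sp.getId(), sp.getCompartment())
        met_ids[sp.getId()] = met_id
        spl = sp.getPlugin("fbc")
        formula = None
        if spl is not None and spl.isSetChemicalFormula():
            formula = spl.getChemicalFormula()
        name = sp.getName()
        model.add_metabolite(
            Metabolite(id=met_id, name="" if name == met_id else name, formula=formula)
        )

    objective_coefs: dict[str, float] = {}
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getActiveObjective() or mplug.getObjective(0)
        for i in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(i)
            objective_coefs[fo.getReaction()] = fo.getCoefficient()

    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        rplug = r.getPlugin("fbc")
        if (
            rplug is None
            or not rplug.isSetLowerFluxBound()
            or not rplug.isSetUpperFluxBound()
        ):
            raise ModelParseError(
                f"{path}: reaction {r.getId()!r} lacks fbc flux bounds "
                "(bounds are mandatory, no silent defaults)"
            )
        lb_param = sbml_model.getParameter(rplug.getLowerFluxBound())
        ub_param = sbml_model.getParameter(rplug.getUpperFluxBound())
        if lb_param is None or ub_param is None:
            raise ModelParseError(
                f"{path}: reaction {r.getId()!r} references a missing bound parameter"
            )
        stoich: dict[str, float] = {}
        for k in range(r.getNumReactants()):
            sr = r.getReactant(k)
            stoich[met_ids[sr.getSpecies()]] = stoich.get(met_ids[sr.getSpecies()], 0.0) - sr.getStoichiometry()
        for k in range(r.getNumProducts()):
            sr = r.getProduct(k)
            stoich[met_ids[sr.getSpecies()]] = stoich.get(met_ids[sr.getSpecies()], 0.0) + sr.getStoichiometry()
        subsystem = ""
        if r.isSetNotes():
            notes = r.getNotesString()
            marker = "SUBSYSTEM: "
            if marker in notes:
                subsystem = notes.split(marker, 1)[1].split("<", 1)[0].strip()
        gpr = GPRRule()
        if rplug.isSetGeneProductAssociation():
            gpr = _association_to_gpr(rplug.getGeneProductAssociation().getAssociation())
        model.add_reaction(
            Reaction(
                id=r.getName() or _decode_plain(r.getId(), "R_"),
                stoichiometry=stoich,
                lb=lb_param.getValue(),
                ub=ub_param.getValue(),
                subsystem=subsystem,
                gpr=gpr,
                objective_coefficient=objective_coefs.get(r.getId(), 0.0),
            )
        )
    return model


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a model from ``sbml-fbc`` or ``json`` (inferred from suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml-fbc"
    if format == "json":
        return read_json_model(path)
    if format == "sbml-fbc":
        return read_sbml_model(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml-fbc"
    if format == "json":
        write_json_model(model, path)
    elif format == "sbml-fbc":
        write_sbml_model(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")
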