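"""Model readers and writers.

Two dialects are supported: SBML Level 3 + FBC (through cobrapy/libsbml) for
interchange with the wider COBRA ecosystem, and a plain JSON dialect used for
text fixtures.  The JSON dialect is a direct serialization of the native
container::

    {
      "id": "toy",
      "compartments": ["c", "e"],
      "objective": "biomass",
      "metabolites": [{"id": "a_c", "compartment": "c", "mw": 100.0}, ...],
      "reactions": [{"id": "R1", "stoich": {"a_c": -1, "b_c": 1},
                     "lb": 0, "ub": 1000, "gpr": "g1 or g2",
                     "subsystem": "", "kind": "enzymatic"}, ...]
    }

Round-tripping either dialect preserves stoichiometry, bounds, GPR strings
and compartments.
"""

from __future__ import annotations

import json
from pathlib import Path

from .gpr import parse_gpr
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, ModelValidationError, Reaction


class ModelParseError(ValueError):
    """Raised when an input file cannot be parsed into a valid model."""


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "compartments": list(model.compartments),
        "objective": model.objective,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "mw": m.mw,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoich": dict(r.stoich),
                "lb": r.lb,
                "ub": r.ub,
                "gpr": str(r.gpr),
                "subsystem": r.subsystem,
                "kind": r.kind,
            }
            for r in model.reactions
        ],
    }


def model_from_dict(data: dict) -> MetabolicModel:
    try:
        model = MetabolicModel(
            id=data.get("id", "model"),
            compartments=list(data.get("compartments", [])),
            objective=data.get("objective"),
        )
        for m in data.get("metabolites", []):
            model.add_metabolite(
                Metabolite(
                    id=m["id"],
                    name=m.get("name", ""),
                    compartment=m.get("compartment", "c"),
                    formula=m.get("formula"),
                    mw=m.get("mw"),
                )
            )
        for r in data.get("reactions", []):
            model.add_reaction(
                Reaction(
                    id=r["id"],
                    stoich={k: float(v) for k, v in r["stoich"].items()},
                    lb=float(r.get("lb", 0.0)),
                    ub=float(r.get("ub", DEFAULT_BOUND)),
                    gpr=parse_gpr(r.get("gpr", "")),
                    subsystem=r.get("subsystem", ""),
                    kind=r.get("kind", "enzymatic"),
                )
            )
    except KeyError as exc:
        raise ModelParseError(f"missing required field {exc}") from exc
    try:
        model.validate()
    except ModelValidationError as exc:
        raise ModelParseError(str(exc)) from exc
    return model


# ---------------------------------------------------------------------------
# cobra bridge / SBML
# ---------------------------------------------------------------------------

def to_cobra(model: MetabolicModel):
    """Convert to a cobra.Model (used for SBML IO and as a test oracle)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(
            m.id, name=m.name or m.id, compartment=m.compartment or "c"
        )
        if m.formula:
            cmet.formula = m.formula
        mets[m.id] = cmet
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lb, upper_bound=r.ub)
        cr.subsystem = r.subsystem
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({mets[k]: v for k, v in r.stoich.items()})
        if not r.gpr.is_empty:
            cr.gene_reaction_rule = str(r.gpr)
    if model.objective is not None:
        cm.objective = model.objective
    return cm


def from_cobra(cm, kind_hints: dict[str, str] | None = None) -> MetabolicModel:
    """Convert a cobra.Model to the native container.

    Reaction kinds are inferred: single-metabolite boundary reactions become
    exchanges; reactions whose id contains "biomass" (or that carry the
    objective) become biomass reactions; everything else defaults to
    enzymatic unless overridden by ``kind_hints``.
    """
    kind_hints = kind_hints or {}
    model = MetabolicModel(id=cm.id or "model")
    model.compartments = sorted(cm.compartments) if cm.compartments else []
    for cmet in cm.metabolites:
        mw = None
        try:
            w = cmet.formula_weight
            mw = float(w) if w else None
        except Exception:
            mw = None
        model.add_metabolite(
            Metabolite(
                id=cmet.id,
                name=cmet.name or "",
                compartment=cmet.compartment or "c",
                formula=cmet.formula or None,
                mw=mw,
            )
        )
    objective_ids = {
        v.name for v in cm.objective.variables if not v.name.endswith("_reverse")
    }
    for cr in cm.reactions:
        if cr.id in kind_hints:
            kind = kind_hints[cr.id]
        elif len(cr.metabolites) == 1 and cr.boundary:
            kind = "exchange"
        elif "biomass" in cr.id.lower():
            kind = "biomass"
        else:
            kind = "enzymatic"
        model.add_reaction(
            Reaction(
                id=cr.id,
                stoich={m.id: c for m, c in cr.metabolites.items()},
                lb=cr.lower_bound,
                ub=cr.upper_bound,
                gpr=parse_gpr(cr.gene_reaction_rule or ""),
                subsystem=cr.subsystem or "",
                kind=kind,
            )
        )
    if objective_ids:
        for rid in objective_ids:
            base = rid
            if model.has_reaction(base):
                model.objective = base
                break
    try:
        model.validate()
    except ModelValidationError as exc:
        raise ModelParseError(str(exc)) from exc
    return model


# ---------------------------------------------------------------------------
# top-level entry points
# ---------------------------------------------------------------------------

def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    raise ModelParseError(f"cannot infer model dialect from {path.name!r}")


def read_model(path, dialect: str | None = None) -> MetabolicModel:
    """Read a model from SBML L3+FBC (``sbml``) or the JSON dialect (``json``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"{path.name}: invalid JSON near {exc.pos}") from exc
        return model_from_dict(data)
    if dialect == "sbml":
        import cobra.io

        try:
            cm = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # libsbml reports element-level messages
            raise ModelParseError(f"{path.name}: {exc}") from exc
        return from_cobra(cm)
    raise ModelParseError(f"unknown dialect {dialect!r}")


def write_model(model: MetabolicModel, path, dialect: str | None = None) -> None:
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "json":
        path.write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=True))
        return
    if dialect == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(to_cobra(model), str(path))
        return
    raise ModelParseError(f"unknown dialect {dialect!r}")
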