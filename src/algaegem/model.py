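"""Core data model for constraint-based metabolic networks.

The container mirrors the standard COBRA representation: metabolites with
compartments, reactions as signed stoichiometries with flux bounds in
mmol gDW^-1 h^-1, boolean GPR rules, and a single linear objective reaction.
Exchange reactions are written ``met <->`` with uptake as negative flux, so a
printed uptake capacity of 10 becomes a lower bound of -10.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace

from .gpr import GPRRule, parse_gpr

#: default magnitude for unbounded fluxes
DEFAULT_BOUND = 1000.0

#: canonical compartment vocabulary (at most eight compartments)
COMPARTMENTS = (
    "c",  # cytoplasm
    "h",  # chloroplast
    "l",  # lysosome / vacuole
    "m",  # mitochondrion
    "p",  # thylakoid / plastid
    "x",  # peroxisome
    "r",  # endoplasmic reticulum
    "e",  # extracellular
)

REACTION_KINDS = ("enzymatic", "transport", "exchange", "biomass", "demand")


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class ConfigurationError(ValueError):
    """Raised for bad run configuration (missing exchanges, compartments...)."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    mw: float | None = None  # g/mol; required for biomass / enzyme-pool math

    def __post_init__(self) -> None:
        if self.mw is not None and self.mw <= 0:
            raise ModelValidationError(f"metabolite {self.id}: mw must be > 0")


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]
    lb: float = 0.0
    ub: float = DEFAULT_BOUND
    gpr: GPRRule = field(default_factory=GPRRule)
    subsystem: str = ""
    kind: str = "enzymatic"

    def __post_init__(self) -> None:
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        if self.lb > self.ub:
            raise ModelValidationError(f"reaction {self.id}: lb > ub")
        if self.kind not in REACTION_KINDS:
            raise ModelValidationError(f"reaction {self.id}: unknown kind {self.kind!r}")
        if not self.stoich:
            raise ModelValidationError(f"reaction {self.id}: empty stoichiometry")
        if self.kind == "exchange" and len(self.stoich) != 1:
            raise ModelValidationError(
                f"exchange reaction {self.id} must touch exactly one metabolite"
            )

    @property
    def reversible(self) -> bool:
        return self.lb < 0 < self.ub

    @property
    def genes(self) -> frozenset[str]:
        return self.gpr.genes()

    def copy(self) -> "Reaction":
        return replace(self, stoich=dict(self.stoich))


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    compartments: list[str] = field(default_factory=list)
    objective: str | None = None
    id: str = "model"

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index()[met_id]
        except KeyError:
            raise KeyError(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index()[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction {rxn_id!r}") from None

    def _met_index(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    def _rxn_index(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index()

    @property
    def genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for r in self.reactions:
            out |= r.genes
        return out

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind == "exchange"]

    # -- structure -------------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self._met_index():
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self._rxn_index():
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        self.reactions.append(rxn)

    def remove_reactions(self, rxn_ids) -> None:
        drop = set(rxn_ids)
        self.reactions = [r for r in self.reactions if r.id not in drop]

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    def validate(self) -> None:
        """Check structural invariants; raise ModelValidationError on failure."""
        seen_m: set[str] = set()
        for m in self.metabolites:
            if m.id in seen_m:
                raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
            seen_m.add(m.id)
            if self.compartments and m.compartment not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {m.id}: compartment {m.compartment!r} "
                    "not in model compartment list"
                )
        if len(self.compartments) > len(COMPARTMENTS):
            raise ModelValidationError("more than eight compartments")
        seen_r: set[str] = set()
        for r in self.reactions:
            if r.id in seen_r:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            seen_r.add(r.id)
            for met_id in r.stoich:
                if met_id not in seen_m:
                    raise ModelValidationError(
                        f"reaction {r.id} references unknown metabolite {met_id!r}"
                    )
        if self.objective is not None and self.objective not in seen_r:
            raise ModelValidationError(f"objective reaction {self.objective!r} missing")


def split_reversible(model: MetabolicModel) -> tuple[MetabolicModel, dict[str, tuple[str, str]]]:
    """Split every reversible reaction into forward/backward irreversible halves.

    Returns the split model and a map parent-id -> (fwd-id, bwd-id).  The
    backward half has negated stoichiometry and bounds [0, -lb]; any feasible
    flux v of the parent equals v_fwd - v_bwd.  Irreversible reactions are
    left untouched and do not appear in the map.
    """
    out = model.copy()
    mapping: dict[str, tuple[str, str]] = {}
    new_reactions: list[Reaction] = []
    for r in out.reactions:
        if r.lb >= 0:
            new_reactions.append(r)
            continue
        fwd_id, bwd_id = f"{r.id}__fwd", f"{r.id}__bwd"
        fwd = replace(r, id=fwd_id, stoich=dict(r.stoich), lb=0.0, ub=max(r.ub, 0.0))
        bwd = replace(
            r,
            id=bwd_id,
            stoich={m: -c for m, c in r.stoich.items()},
            lb=0.0,
            ub=-r.lb,
        )
        new_reactions.extend([fwd, bwd])
        mapping[r.id] = (fwd_id, bwd_id)
        if out.objective == r.id:
            out.objective = fwd_id
    out.reactions = new_reactions
    return out, mapping


# ---------------------------------------------------------------------------
# growth conditions and media
# ---------------------------------------------------------------------------

#: media exchange registry: short name -> (exchange id, extracellular met id)
MEDIA_EXCHANGES = {
    "h2o": ("EX_h2o", "h2o_e"),
    "h": ("EX_h", "h_e"),
    "pi": ("EX_pi", "pi_e"),
    "nh4": ("EX_nh4", "nh4_e"),
    "so4": ("EX_so4", "so4_e"),
    "fe2": ("EX_fe2", "fe2_e"),
    "mg2": ("EX_mg2", "mg2_e"),
    "o2": ("EX_o2", "o2_e"),
    "photon": ("EX_photon", "photon_e"),
    "ac": ("EX_ac", "ac_e"),
    "co2": ("EX_co2", "co2_e"),
}

NUTRIENTS = ("h2o", "h", "pi", "nh4", "so4", "fe2", "mg2", "o2")
NUTRIENT_UPTAKE = 10.0  # mmol/gDW/h uptake capacity for the eight nutrients
ACETATE_UPTAKE = 2.0  # mmol/gDW/h under mixotrophic/heterotrophic growth

CONDITION_NAMES = ("auto_100", "auto_3k", "mixo", "hetero")

#: per-condition light bound magnitude, acetate uptake, and CO2 availability
_CONDITION_TABLE = {
    "auto_100": {"light": 100.0, "acetate": 0.0, "co2_open": True},
    "auto_3k": {"light": 3000.0, "acetate": 0.0, "co2_open": True},
    "mixo": {"light": 100.0, "acetate": ACETATE_UPTAKE, "co2_open": True},
    "hetero": {"light": 0.0, "acetate": ACETATE_UPTAKE, "co2_open": False},
}


@dataclass
class GrowthCondition:
    """Named growth condition with its biomass reaction and bound overrides."""

    name: str
    biomass_id: str
    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CONDITION_NAMES:
            raise ConfigurationError(
                f"unknown condition {self.name!r}; expected one of {CONDITION_NAMES}"
            )

    @property
    def light_bound(self) -> float:
        return _CONDITION_TABLE[self.name]["light"]

    @property
    def acetate_uptake(self) -> float:
        return _CONDITION_TABLE[self.name]["acetate"]

    @property
    def co2_open(self) -> bool:
        return _CONDITION_TABLE[self.name]["co2_open"]


def standard_condition(name: str, biomass_id: str | None = None) -> GrowthCondition:
    """Build a GrowthCondition with the conventional biomass reaction name."""
    return GrowthCondition(name=name, biomass_id=biomass_id or f"biomass_{name}")


def apply_condition(
    model: MetabolicModel, cond: GrowthCondition, strict: bool = False
) -> MetabolicModel:
    """Return a copy of the model with the condition's media bounds applied.

    The eight nutrient uptakes each allow up to 10 mmol/gDW/h; the photon
    exchange bound magnitude is 100 (auto_100, mixo), 3000 (auto_3k) or 0
    (hetero); acetate uptake is 2 (mixo, hetero) else 0; CO2 uptake is open
    for autotrophic/mixotrophic and closed for heterotrophic growth.  The
    objective is set to the condition's biomass reaction.  Applying the same
    condition twice is idempotent.
    """
    out = model.copy()
    index = out._rxn_index()

    if cond.biomass_id not in index:
        raise ConfigurationError(f"biomass reaction {cond.biomass_id!r} not in model")

    missing: list[str] = []

    def set_uptake(key: str, capacity: float) -> None:
        ex_id = MEDIA_EXCHANGES[key][0]
        rxn = index.get(ex_id)
        if rxn is None:
            missing.append(ex_id)
            return
        rxn.lb = -capacity

    for nutrient in NUTRIENTS:
        set_uptake(nutrient, NUTRIENT_UPTAKE)
    set_uptake("photon", cond.light_bound)
    set_uptake("ac", cond.acetate_uptake)
    set_uptake("co2", DEFAULT_BOUND if cond.co2_open else 0.0)

    if strict and missing:
        raise ConfigurationError(f"missing media exchange reactions: {sorted(set(missing))}")

    bad_overrides = [rid for rid in cond.bound_overrides if rid not in index]
    if bad_overrides:
        raise ConfigurationError(f"bound overrides reference missing reactions: {bad_overrides}")
    for rid, (lb, ub) in cond.bound_overrides.items():
        index[rid].lb, index[rid].ub = lb, ub

    out.objective = cond.biomass_id
    return out
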