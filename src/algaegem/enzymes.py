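"""MILP gap-filling against a universal pool and enzyme-constrained models.

Gap-filling selects a minimum-cardinality subset of a universal candidate
reaction pool whose addition lets the model reach biomass flux >= eps
(binary per candidate, big-M flux coupling, optional per-candidate penalty
weights for database preference).

Enzyme constraints follow the GECKO formulation: each enzymatic reaction's
flux is coupled to enzyme usage through v <= kcat * e, isozymes (OR branches
of the GPR) become parallel reaction copies each drawing its own enzyme,
complex subunits (AND) are each consumed at flux/kcat, and all enzyme draws
compete for a shared protein pool of P g protein per gDW.  kcat inputs in
s^-1 are converted to h^-1 (x3600) and molecular weights in kDa equal
g/mmol, so a single pool-limited reaction saturates at
3600 * kcat * P / MW mmol gDW^-1 h^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction
from .solve import STATUS_OPTIMAL, LinearProblem

DEFAULT_EPS = 1e-3
DEFAULT_BIG_M = 1000.0

PROTEIN_COMPARTMENT = "c"
POOL_MET = "prot_pool"
POOL_EXCHANGE = "prot_pool_exchange"


class GapfillError(RuntimeError):
    def __init__(self, message: str, unproducible: list[str] | None = None):
        super().__init__(message)
        self.unproducible = unproducible or []


@dataclass
class UniversalPool:
    """Candidate reactions for gap-filling, tagged with a source database."""

    reactions: list[Reaction] = field(default_factory=list)
    source: dict[str, str] = field(default_factory=dict)  # reaction id -> db id

    def ids(self) -> list[str]:
        return [r.id for r in self.reactions]


@dataclass
class ECModel:
    """Enzyme-constrained model plus bookkeeping."""

    model: MetabolicModel
    pool_reaction: str = POOL_EXCHANGE
    protein_ids: frozenset[str] = frozenset()
    kcats_per_h: dict[tuple[str, str], float] = field(default_factory=dict)
    pool_gram_per_gdw: float = 0.0


# ---------------------------------------------------------------------------
# gap-filling
# ---------------------------------------------------------------------------

def _biomass_feasible(model: MetabolicModel, biomass: str, eps: float) -> bool:
    lp = LinearProblem()
    for r in model.reactions:
        lp.add_var(r.id, r.lb, r.ub)
    balance: dict[str, dict[str, float]] = {}
    for r in model.reactions:
        for met, coeff in r.stoich.items():
            balance.setdefault(met, {})[r.id] = coeff
    for met, coeffs in balance.items():
        lp.add_constraint(coeffs, lb=0.0, ub=0.0)
    lp.set_objective({biomass: 1.0}, direction="max")
    return lp.optimize() == STATUS_OPTIMAL and lp.objective_value() >= eps - 1e-12


def _probe_precursors(model: MetabolicModel, biomass: str, eps: float) -> list[str]:
    """Which biomass precursors cannot be produced at eps, one demand at a time."""
    bio = model.reaction(biomass)
    bad = []
    for met, coeff in sorted(bio.stoich.items()):
        if coeff >= 0:
            continue
        probe = model.copy()
        probe.add_reaction(Reaction(f"DM_probe_{met}", {met: -1.0}, lb=0.0, ub=DEFAULT_BOUND,
                                    kind="demand"))
        if not _biomass_feasible(probe, f"DM_probe_{met}", eps):
            bad.append(met)
    return bad


def gapfill_milp(
    model: MetabolicModel,
    pool: UniversalPool,
    biomass: str | None = None,
    eps: float = DEFAULT_EPS,
    big_m: float = DEFAULT_BIG_M,
    penalties: dict[str, float] | None = None,
) -> list[str]:
    """Minimum-cardinality pool subset restoring biomass flux >= eps.

    Returns the sorted list of added candidate ids ([] if the model is
    already feasible).  Raises GapfillError, listing unproducible biomass
    precursors, when even the full pool cannot restore feasibility.
    Alternate optima resolve to the lexicographically smallest added set.
    """
    biomass = biomass if biomass is not None else model.objective
    if biomass is None:
        raise ValueError("no biomass reaction specified")
    if _biomass_feasible(model, biomass, eps):
        return []

    merged = model.copy()
    model_ids = {r.id for r in merged.reactions}
    clash = model_ids & set(pool.ids())
    if clash:
        raise ValueError(f"pool ids clash with model ids: {sorted(clash)}")
    met_index = {m.id for m in merged.metabolites}
    for r in pool.reactions:
        for met in r.stoich:
            if met not in met_index:
                merged.add_metabolite(Metabolite(met, compartment="c"))
                met_index.add(met)
        merged.add_reaction(r.copy())
    if not _biomass_feasible(merged, biomass, eps):
        bad = _probe_precursors(merged, biomass, eps)
        raise GapfillError(
            "biomass infeasible even with the entire universal pool; "
            f"unproducible precursors: {bad}",
            unproducible=bad,
        )

    candidates = sorted(pool.ids())
    penalties = penalties or {}
    lp = LinearProblem()
    for r in merged.reactions:
        lp.add_var(r.id, r.lb, r.ub)
    for cid in candidates:
        lp.add_binary(f"y_{cid}")
    balance: dict[str, dict[str, float]] = {}
    for r in merged.reactions:
        for met, coeff in r.stoich.items():
            balance.setdefault(met, {})[r.id] = coeff
    for met, coeffs in balance.items():
        lp.add_constraint(coeffs, lb=0.0, ub=0.0)
    lp.add_constraint({biomass: 1.0}, lb=eps)
    for cid in candidates:
        lp.add_constraint({cid: 1.0, f"y_{cid}": -big_m}, ub=0.0)
        if merged.reaction(cid).lb < 0:
            lp.add_constraint({cid: 1.0, f"y_{cid}": big_m}, lb=0.0)
    n = max(len(candidates), 1)
    lp.set_objective(
        {
            f"y_{cid}": penalties.get(cid, 1.0) + 1e-6 * (k / n)
            for k, cid in enumerate(candidates)
        },
        direction="min",
    )
    if lp.optimize() != STATUS_OPTIMAL:
        raise GapfillError("gap-filling MILP did not solve to optimality")
    added = sorted(cid for cid in candidates if lp.value(f"y_{cid}") > 0.5)

    # re-verify by LP: the added set restores feasibility
    verify = model.copy()
    met_index = {m.id for m in verify.metabolites}
    for r in pool.reactions:
        if r.id in added:
            for met in r.stoich:
                if met not in met_index:
                    verify.add_metabolite(Metabolite(met, compartment="c"))
                    met_index.add(met)
            verify.add_reaction(r.copy())
    if not _biomass_feasible(verify, biomass, eps):
        raise GapfillError("internal error: gap-fill verification failed")
    return added


# ---------------------------------------------------------------------------
# enzyme constraints (GECKO formulation)
# ---------------------------------------------------------------------------

def protein_met_id(protein: str) -> str:
    return f"prot_{protein}"


def apply_enzyme_constraints(
    model: MetabolicModel,
    kcats: dict[tuple[str, str], float],
    mws: dict[str, float],
    pool: float,
) -> ECModel:
    """Augment an irreversible model with GECKO-style enzyme constraints.

    ``kcats`` maps (reaction id, protein id) to turnover numbers in s^-1
    (must be > 0); ``mws`` maps protein id to molecular weight in kDa;
    ``pool`` is the total protein budget in g protein per gDW.  Reactions
    with no kcat entry are left unconstrained; within a constrained isozyme
    module, subunits lacking a kcat are unconstrained (documented GECKO
    convention).
    """
    reversible = [r.id for r in model.reactions if r.lb < 0]
    if reversible:
        raise ValueError(
            f"model must be split to irreversible reactions first; reversible: {reversible}"
        )
    for pair, k in kcats.items():
        if k <= 0:
            raise ValueError(f"kcat for {pair} must be > 0")
    constrained_rxns = {rid for rid, _ in kcats}
    needed_proteins: set[str] = set()

    out = MetabolicModel(id=f"{model.id}_ec", compartments=list(model.compartments),
                         objective=model.objective)
    for m in model.metabolites:
        out.add_metabolite(Metabolite(m.id, m.name, m.compartment, m.formula, m.mw))

    kcats_h: dict[tuple[str, str], float] = {}
    for r in model.reactions:
        if r.id not in constrained_rxns:
            out.add_reaction(r.copy())
            continue
        modules = r.gpr.isozyme_modules() or [frozenset()]
        copies = []
        for j, module in enumerate(modules):
            usage = {
                g: kcats[(r.id, g)] * 3600.0
                for g in sorted(module)
                if (r.id, g) in kcats
            }
            if len(modules) == 1:
                cid = r.id
            else:
                cid = f"{r.id}__enz{j + 1}"
            stoich = dict(r.stoich)
            for g, kh in usage.items():
                needed_proteins.add(g)
                kcats_h[(cid, g)] = kh
                stoich[protein_met_id(g)] = stoich.get(protein_met_id(g), 0.0) - 1.0 / kh
            copies.append(
                Reaction(cid, stoich, lb=0.0, ub=r.ub, gpr=r.gpr,
                         subsystem=r.subsystem, kind=r.kind)
            )
        for c in copies:
            out.add_reaction(c)

    out.add_metabolite(Metabolite(POOL_MET, name="protein pool",
                                  compartment=PROTEIN_COMPARTMENT))
    for g in sorted(needed_proteins):
        if g not in mws:
            raise ValueError(f"missing molecular weight (kDa) for protein {g!r}")
        out.add_metabolite(Metabolite(protein_met_id(g), name=f"enzyme {g}",
                                      compartment=PROTEIN_COMPARTMENT))
        # kDa == g/mmol, so drawing 1 mmol enzyme consumes MW grams of pool
        out.add_reaction(
            Reaction(f"draw_{protein_met_id(g)}",
                     {POOL_MET: -mws[g], protein_met_id(g): 1.0},
                     lb=0.0, ub=DEFAULT_BOUND, kind="demand")
        )
    out.add_reaction(
        Reaction(POOL_EXCHANGE, {POOL_MET: 1.0}, lb=0.0, ub=pool, kind="exchange")
    )
    return ECModel(
        model=out,
        pool_reaction=POOL_EXCHANGE,
        protein_ids=frozenset(needed_proteins),
        kcats_per_h=kcats_h,
        pool_gram_per_gdw=pool,
    )
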