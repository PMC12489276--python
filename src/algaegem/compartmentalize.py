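"""Multi-compartment network construction by parsimonious MILP.

The procedure takes an uncompartmentalized model plus a compartment
assignment (from localization voting) and proceeds in three steps:

1. *replication* — every reaction is instantiated once per assigned
   compartment over compartment-specific metabolite pools;
2. *transport enumeration* — a reversible 1:1 carrier is added for every
   unordered compartment pair of every metabolite present in more than one
   compartment;
3. *pruning* — a MILP retains the smallest set of replicated instances and
   candidate transports such that all designated biomass precursors can be
   produced simultaneously at steady state (flux floor ``eps``), with at
   least one instance kept per parent reaction and any curated
   pathway-compartment constraints (``fixed_keep``) respected.

Retention is encoded with binaries y (1 = retained) coupled to fluxes by
big-M bounds; the objective minimizes the number of retained added reactions,
with a tiny rank-weighted perturbation so alternate optima resolve to the
lexicographically smallest retained set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .model import MetabolicModel, Metabolite, Reaction
from .solve import STATUS_OPTIMAL, LinearProblem

#: default flux floor for precursor producibility, mmol/gDW/h
DEFAULT_EPS = 1e-3
#: default big-M flux cap; must exceed any realistic flux under uptake <= 10
DEFAULT_BIG_M = 1000.0


def pool_id(met_id: str, comp: str) -> str:
    return f"{met_id}__{comp}"


def instance_id(rxn_id: str, comp: str) -> str:
    return f"{rxn_id}__{comp}"


@dataclass
class ReplicatedModel:
    """Replicated network plus bookkeeping for the pruning MILP."""

    model: MetabolicModel
    #: instance id -> (parent reaction id, compartment)
    provenance: dict[str, tuple[str, str]] = field(default_factory=dict)
    #: parent id -> list of instance ids (non-exchange parents only)
    parent_instances: dict[str, list[str]] = field(default_factory=dict)
    #: candidate transport reaction ids
    transports: list[str] = field(default_factory=list)
    #: pool metabolite id -> (base metabolite id, compartment)
    pool_origin: dict[str, tuple[str, str]] = field(default_factory=dict)


@dataclass
class CompartmentalizationResult:
    model: MetabolicModel | None
    kept_instances: frozenset[str]
    removed_instances: frozenset[str]
    kept_transports: frozenset[str]
    removed_transports: frozenset[str]
    objective: int | None
    status: str
    unproducible: list[tuple[str, str]] = field(default_factory=list)


def replicate_by_assignment(
    model: MetabolicModel,
    assignment: dict[str, frozenset[str]],
    extracellular: str = "e",
) -> ReplicatedModel:
    """Instantiate each reaction once per assigned compartment.

    Metabolite pools are created per compartment.  Exchange reactions follow
    their assignment when present, otherwise they attach to the
    extracellular pool.  Raises KeyError if the assignment references an
    unknown reaction, and ValueError if a non-exchange reaction is missing
    from the assignment.
    """
    rxn_ids = {r.id for r in model.reactions}
    unknown = set(assignment) - rxn_ids
    if unknown:
        raise KeyError(f"assignment references unknown reactions: {sorted(unknown)}")
    missing = [
        r.id for r in model.reactions if r.kind != "exchange" and r.id not in assignment
    ]
    if missing:
        raise ValueError(f"assignment does not cover reactions: {missing}")

    comps: list[str] = []
    for comp_set in assignment.values():
        for c in sorted(comp_set):
            if c not in comps:
                comps.append(c)
    base_mets = model._met_index()

    rep = ReplicatedModel(model=MetabolicModel(id=f"{model.id}_replicated"))
    out = rep.model
    out.compartments = sorted(comps)

    def ensure_pool(met_id: str, comp: str) -> str:
        pid = pool_id(met_id, comp)
        if pid not in rep.pool_origin:
            base = base_mets[met_id]
            if comp not in out.compartments:
                out.compartments.append(comp)
                out.compartments.sort()
            out.add_metabolite(
                Metabolite(pid, name=base.name, compartment=comp, formula=base.formula, mw=base.mw)
            )
            rep.pool_origin[pid] = (met_id, comp)
        return pid

    for r in model.reactions:
        if r.id in assignment:
            target_comps = sorted(assignment[r.id])
        elif r.kind == "exchange":
            target_comps = [extracellular]
        for comp in target_comps:
            iid = instance_id(r.id, comp)
            stoich = {ensure_pool(m, comp): c for m, c in r.stoich.items()}
            out.add_reaction(
                Reaction(iid, stoich, lb=r.lb, ub=r.ub, gpr=r.gpr,
                         subsystem=r.subsystem, kind=r.kind)
            )
            rep.provenance[iid] = (r.id, comp)
            if r.kind != "exchange":
                rep.parent_instances.setdefault(r.id, []).append(iid)
    return rep


def enumerate_transport_candidates(
    rep: ReplicatedModel, metabolites: list[str] | None = None
) -> ReplicatedModel:
    """Add a reversible 1:1 transport per compartment pair of shared metabolites.

    For every base metabolite present in k >= 2 compartments, C(k, 2)
    candidates are added (restricted to ``metabolites`` when given).
    Transports conserve the carried metabolite (coefficients -1/+1), carry no
    GPR, and are typed kind=transport.  Idempotent.
    """
    by_base: dict[str, list[str]] = {}
    for pid, (base, comp) in rep.pool_origin.items():
        by_base.setdefault(base, []).append(comp)
    out = rep.model
    big = max((abs(r.ub) for r in out.reactions), default=DEFAULT_BIG_M)
    big = max(big, DEFAULT_BIG_M)
    for base in sorted(by_base):
        if metabolites is not None and base not in metabolites:
            continue
        comps = sorted(by_base[base])
        if len(comps) < 2:
            continue
        for c1, c2 in combinations(comps, 2):
            tid = f"T_{base}_{c1}_{c2}"
            if out.has_reaction(tid):
                continue
            out.add_reaction(
                Reaction(
                    tid,
                    {pool_id(base, c1): -1.0, pool_id(base, c2): 1.0},
                    lb=-big,
                    ub=big,
                    kind="transport",
                )
            )
            rep.transports.append(tid)
    return rep


def _removables(rep: ReplicatedModel) -> list[str]:
    inst = [i for instances in rep.parent_instances.values() for i in instances]
    return sorted(inst) + sorted(rep.transports)


def _build_milp(
    rep: ReplicatedModel,
    precursors: list[tuple[str, str]],
    eps: float,
    big_m: float,
    fixed_keep: frozenset[str],
    biomass: str | None,
    per_precursor: bool,
    require_instance_per_parent: bool,
    relax: bool = False,
) -> tuple[LinearProblem, list[str]]:
    model = rep.model
    removables = _removables(rep)
    lp = LinearProblem()

    blocks: list[tuple[str, list[tuple[str, str]]]] = (
        [(f"b{i}", [p]) for i, p in enumerate(precursors)]
        if per_precursor and precursors
        else [("b0", list(precursors))]
    )

    for rid in removables:
        if relax:
            lp.add_var(f"y_{rid}", 0.0, 1.0)
        else:
            lp.add_binary(f"y_{rid}")

    for tag, block_precursors in blocks:
        for r in model.reactions:
            lp.add_var(f"v_{tag}_{r.id}", r.lb, r.ub)
        demand_vars = []
        for met, comp in block_precursors:
            pid = pool_id(met, comp)
            if pid not in rep.pool_origin:
                raise KeyError(f"precursor {met}@{comp}: no such metabolite pool")
            dv = f"d_{tag}_{met}_{comp}"
            lp.add_var(dv, eps, big_m)
            demand_vars.append((dv, pid))
        balance: dict[str, dict[str, float]] = {}
        for r in model.reactions:
            for met, coeff in r.stoich.items():
                balance.setdefault(met, {})[f"v_{tag}_{r.id}"] = coeff
        for dv, pid in demand_vars:
            balance.setdefault(pid, {})[dv] = -1.0
        for met, coeffs in balance.items():
            lp.add_constraint(coeffs, lb=0.0, ub=0.0)
        if biomass is not None:
            lp.add_constraint({f"v_{tag}_{biomass}": 1.0}, lb=eps)
        for rid in removables:
            lp.add_constraint({f"v_{tag}_{rid}": 1.0, f"y_{rid}": -big_m}, ub=0.0)
            if model.reaction(rid).lb < 0:
                lp.add_constraint({f"v_{tag}_{rid}": 1.0, f"y_{rid}": big_m}, lb=0.0)

    if require_instance_per_parent:
        for parent, instances in rep.parent_instances.items():
            lp.add_constraint({f"y_{i}": 1.0 for i in instances}, lb=1.0)
    for rid in fixed_keep:
        if rid not in set(removables):
            raise KeyError(f"fixed_keep id {rid!r} is not a removable instance/transport")
        lp.add_constraint({f"y_{rid}": 1.0}, lb=1.0)

    n = max(len(removables), 1)
    weights = {
        f"y_{rid}": 1.0 + 1e-6 * (k / n) for k, rid in enumerate(removables)
    }
    lp.set_objective(weights, direction="min")
    return lp, removables


def prune_minimal(
    rep: ReplicatedModel,
    precursors: list[tuple[str, str]],
    eps: float = DEFAULT_EPS,
    big_m: float = DEFAULT_BIG_M,
    fixed_keep=frozenset(),
    biomass: str | None = None,
    per_precursor: bool = False,
    require_instance_per_parent: bool = True,
) -> CompartmentalizationResult:
    """Solve the minimal-additions MILP and return the pruned model.

    ``precursors`` is a list of (metabolite id, compartment) pairs whose
    simultaneous production at flux >= eps defines model functionality (a
    biomass reaction id can be supplied instead/in addition).  The returned
    objective is the provably optimal count of retained added reactions, and
    the pruned model is re-certified feasible by a direct LP solve.
    """
    fixed_keep = frozenset(fixed_keep)
    # feasibility pre-check with everything retained (pure LP)
    lp_relax, removables = _build_milp(
        rep, precursors, eps, big_m, fixed_keep, biomass, False,
        require_instance_per_parent, relax=True,
    )
    for rid in removables:
        lp_relax.set_bounds(f"y_{rid}", 1.0, 1.0)
    lp_relax.set_objective({}, direction="max")
    if lp_relax.optimize() != STATUS_OPTIMAL:
        unproducible = _probe_unproducible(rep, precursors, eps, big_m, biomass)
        return CompartmentalizationResult(
            model=None,
            kept_instances=frozenset(),
            removed_instances=frozenset(),
            kept_transports=frozenset(),
            removed_transports=frozenset(),
            objective=None,
            status="infeasible",
            unproducible=unproducible,
        )

    lp, removables = _build_milp(
        rep, precursors, eps, big_m, fixed_keep, biomass, per_precursor,
        require_instance_per_parent,
    )
    status = lp.optimize()
    if status != STATUS_OPTIMAL:
        return CompartmentalizationResult(
            model=None,
            kept_instances=frozenset(),
            removed_instances=frozenset(),
            kept_transports=frozenset(),
            removed_transports=frozenset(),
            objective=None,
            status=status,
        )

    kept = frozenset(rid for rid in removables if lp.value(f"y_{rid}") > 0.5)
    instance_ids = {i for inst in rep.parent_instances.values() for i in inst}
    kept_instances = frozenset(kept & instance_ids)
    kept_transports = frozenset(kept & set(rep.transports))
    removed_instances = frozenset(instance_ids - kept)
    removed_transports = frozenset(set(rep.transports) - kept)

    pruned = rep.model.copy()
    pruned.remove_reactions(removed_instances | removed_transports)
    used = {m for r in pruned.reactions for m in r.stoich}
    pruned.metabolites = [m for m in pruned.metabolites if m.id in used]
    pruned.id = rep.model.id.replace("_replicated", "") + "_compartmentalized"

    _certify(pruned, precursors, eps, biomass)

    return CompartmentalizationResult(
        model=pruned,
        kept_instances=kept_instances,
        removed_instances=removed_instances,
        kept_transports=kept_transports,
        removed_transports=removed_transports,
        objective=len(kept),
        status=status,
    )


def _probe_unproducible(rep, precursors, eps, big_m, biomass) -> list[tuple[str, str]]:
    bad = []
    for met, comp in precursors:
        lp, removables = _build_milp(
            rep, [(met, comp)], eps, big_m, frozenset(), biomass=None,
            per_precursor=False, require_instance_per_parent=False, relax=True,
        )
        for rid in removables:
            lp.set_bounds(f"y_{rid}", 1.0, 1.0)
        lp.set_objective({}, direction="max")
        if lp.optimize() != STATUS_OPTIMAL:
            bad.append((met, comp))
    return bad


def _certify(pruned: MetabolicModel, precursors, eps, biomass) -> None:
    """LP re-solve on the pruned model: all demands attainable simultaneously."""
    lp = LinearProblem()
    for r in pruned.reactions:
        lp.add_var(r.id, r.lb, r.ub)
    balance: dict[str, dict[str, float]] = {}
    for r in pruned.reactions:
        for met, coeff in r.stoich.items():
            balance.setdefault(met, {})[r.id] = coeff
    demand_names = []
    for met, comp in precursors:
        dv = f"d_{met}_{comp}"
        lp.add_var(dv, eps, None)
        balance.setdefault(pool_id(met, comp), {})[dv] = -1.0
        demand_names.append(dv)
    for met, coeffs in balance.items():
        lp.add_constraint(coeffs, lb=0.0, ub=0.0)
    if biomass is not None:
        lp.add_constraint({biomass: 1.0}, lb=eps)
    lp.set_objective({}, direction="max")
    if lp.optimize() != STATUS_OPTIMAL:
        raise RuntimeError(
            "internal error: pruned model failed the feasibility certificate"
        )
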