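"""Exhaustive reference solvers for small instances.

These enumerate keep/remove subsets directly and exist to validate the MILP
components on desk-scale problems (<= ~12 binary decisions); they share only
the generic LP layer with the MILP implementations, never their
formulations.  Subsets are visited in order of increasing cardinality with
early stopping, so the returned optimum is exact.
"""

from __future__ import annotations

from itertools import combinations

from .compartmentalize import ReplicatedModel, pool_id
from .model import MetabolicModel
from .solve import STATUS_OPTIMAL, LinearProblem
from .tic import FWD, _internal_unit_problem, _split_directions


def brute_force_compartment_minimum(
    rep: ReplicatedModel,
    precursors: list[tuple[str, str]],
    eps: float = 1e-3,
    require_instance_per_parent: bool = True,
) -> tuple[int | None, frozenset[str] | None]:
    """Smallest number of retained added reactions, by enumeration.

    Returns (minimum retained count, one optimal kept set), or (None, None)
    when no subset is feasible.
    """
    instances = sorted(i for inst in rep.parent_instances.values() for i in inst)
    removables = instances + sorted(rep.transports)
    model = rep.model

    lp = LinearProblem()
    for r in model.reactions:
        lp.add_var(r.id, r.lb, r.ub)
    balance: dict[str, dict[str, float]] = {}
    for r in model.reactions:
        for met, coeff in r.stoich.items():
            balance.setdefault(met, {})[r.id] = coeff
    for k, (met, comp) in enumerate(precursors):
        dv = f"d{k}"
        lp.add_var(dv, eps, None)
        balance.setdefault(pool_id(met, comp), {})[dv] = -1.0
    for met, coeffs in balance.items():
        lp.add_constraint(coeffs, lb=0.0, ub=0.0)
    lp.set_objective({}, direction="max")
    original = {rid: (model.reaction(rid).lb, model.reaction(rid).ub)
                for rid in removables}

    def feasible(kept: frozenset[str]) -> bool:
        for rid in removables:
            if rid in kept:
                lp.set_bounds(rid, *original[rid])
            else:
                lp.set_bounds(rid, 0.0, 0.0)
        return lp.optimize() == STATUS_OPTIMAL

    parents = list(rep.parent_instances.values())
    for k in range(len(removables) + 1):
        for combo in combinations(removables, k):
            kept = frozenset(combo)
            if require_instance_per_parent and any(
                not (set(inst) & kept) for inst in parents
            ):
                continue
            if feasible(kept):
                return k, kept
    return None, None


def brute_force_tic_minimum(
    model: MetabolicModel,
    biomass: str | None = None,
    eps: float = 1e-3,
    tol: float = 1e-6,
) -> tuple[int | None, frozenset[tuple[str, str]] | None]:
    """Smallest direction-removal set that kills all internal cycles while
    keeping biomass feasible, by enumeration over subsets of cycle-involved
    directions."""
    from .tic import find_tic_directions

    biomass = biomass if biomass is not None else model.objective
    tic_dirs = sorted(find_tic_directions(model, tol=tol))
    split, direction_of = _split_directions(model)
    dir_to_split = {v: k for k, v in direction_of.items()}

    # circulation check: unit-capped LP with chosen directions shut
    circ_lp, internal = _internal_unit_problem(split)
    tic_split_ids = [dir_to_split[d] for d in tic_dirs]

    def tic_free(removed: frozenset[tuple[str, str]]) -> bool:
        for d in tic_dirs:
            sid = dir_to_split[d]
            if d in removed:
                circ_lp.set_bounds(sid, 0.0, 0.0)
            else:
                r = split.reaction(sid)
                circ_lp.set_bounds(sid, 0.0, min(r.ub, 1.0))
        for sid in tic_split_ids:
            if direction_of[sid] in removed:
                continue
            circ_lp.set_objective({sid: 1.0}, direction="max")
            if circ_lp.optimize() == STATUS_OPTIMAL and circ_lp.objective_value() > tol:
                return False
        return True

    # biomass check on the split model with removed directions shut
    bio_lp = LinearProblem()
    for r in split.reactions:
        bio_lp.add_var(r.id, r.lb, r.ub)
    balance: dict[str, dict[str, float]] = {}
    for r in split.reactions:
        for met, coeff in r.stoich.items():
            balance.setdefault(met, {})[r.id] = coeff
    for met, coeffs in balance.items():
        bio_lp.add_constraint(coeffs, lb=0.0, ub=0.0)
    if biomass is not None and split.has_reaction(biomass):
        bio_lp.add_constraint({biomass: 1.0}, lb=eps)
    bio_lp.set_objective({}, direction="max")

    def biomass_ok(removed: frozenset[tuple[str, str]]) -> bool:
        if biomass is None:
            return True
        for d in tic_dirs:
            sid = dir_to_split[d]
            r = split.reaction(sid)
            if d in removed:
                bio_lp.set_bounds(sid, 0.0, 0.0)
            else:
                bio_lp.set_bounds(sid, r.lb, r.ub)
        return bio_lp.optimize() == STATUS_OPTIMAL

    for k in range(len(tic_dirs) + 1):
        for combo in combinations(tic_dirs, k):
            removed = frozenset(combo)
            if tic_free(removed) and biomass_ok(removed):
                return k, removed
    return None, None
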