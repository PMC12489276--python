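"""Detection and minimal removal of thermodynamically infeasible cycles.

A thermodynamically infeasible cycle (TIC, "type III loop") is a set of
internal reactions that can carry steady-state flux with every exchange
reaction closed.  Detection uses a per-direction LP sweep: with exchanges
shut and internal flux capped at unit magnitude, any direction whose maximum
flux exceeds tolerance participates in some cycle.

Removal is a lazy hitting-set MILP: an inner LP repeatedly exhibits a cycle
support among the retained directions, each support adds a covering cut, and
the master MILP picks a minimum-cardinality set of directions to remove
subject to all cuts plus an embedded flux block guaranteeing that biomass
production at flux >= eps survives the removal.  Reversible reactions are
split internally, so removing one direction converts a reversible reaction
to an irreversible one rather than deleting it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import MetabolicModel, split_reversible
from .solve import STATUS_OPTIMAL, LinearProblem

#: LP optimum below this is treated as zero flux
FLUX_TOL = 1e-6
DEFAULT_EPS = 1e-3
DEFAULT_BIG_M = 1000.0

#: direction labels; irreversible reactions only ever have a 'fwd' direction
FWD, BWD = "fwd", "bwd"


@dataclass
class TicReport:
    """Outcome of minimal TIC removal."""

    tic_reactions: frozenset[str]  # parent reaction ids involved in any TIC
    removed: frozenset[tuple[str, str]]  # (parent id, 'fwd'|'bwd') directions
    certificates: list[frozenset[tuple[str, str]]] = field(default_factory=list)
    status: str = STATUS_OPTIMAL
    iterations: int = 0
    model: MetabolicModel | None = None


def _split_directions(model: MetabolicModel):
    """Split reversibles; return (split model, direction id -> (parent, dir))."""
    split, mapping = split_reversible(model)
    direction_of: dict[str, tuple[str, str]] = {}
    split_ids = {fid for f, b in mapping.values() for fid in (f, b)}
    for parent, (fid, bid) in mapping.items():
        direction_of[fid] = (parent, FWD)
        direction_of[bid] = (parent, BWD)
    for r in split.reactions:
        if r.id not in split_ids:
            direction_of[r.id] = (r.id, FWD)
    return split, direction_of


def _internal_unit_problem(split: MetabolicModel) -> tuple[LinearProblem, list[str]]:
    """LP with exchanges closed and internal direction fluxes capped at 1."""
    lp = LinearProblem()
    internal = []
    for r in split.reactions:
        if r.kind in ("exchange", "demand"):
            lp.add_var(r.id, 0.0, 0.0)
        else:
            lp.add_var(r.id, 0.0, min(r.ub, 1.0))
            internal.append(r.id)
    balance: dict[str, dict[str, float]] = {}
    for r in split.reactions:
        for met, coeff in r.stoich.items():
            balance.setdefault(met, {})[r.id] = coeff
    for met, coeffs in balance.items():
        lp.add_constraint(coeffs, lb=0.0, ub=0.0)
    return lp, internal


def find_tic_reactions(model: MetabolicModel, tol: float = FLUX_TOL) -> frozenset[str]:
    """Parent ids of all reactions able to carry flux with exchanges closed."""
    dirs = find_tic_directions(model, tol=tol)
    return frozenset(parent for parent, _ in dirs)


def find_tic_directions(
    model: MetabolicModel, tol: float = FLUX_TOL
) -> frozenset[tuple[str, str]]:
    """Like :func:`find_tic_reactions` but at (parent, direction) granularity."""
    split, direction_of = _split_directions(model)
    lp, internal = _internal_unit_problem(split)
    hits: set[tuple[str, str]] = set()
    for rid in internal:
        if direction_of[rid] in hits:
            continue
        lp.set_objective({rid: 1.0}, direction="max")
        if lp.optimize() != STATUS_OPTIMAL:
            continue
        if lp.objective_value() > tol:
            # the whole support of this circulation is cycle-involved
            for other in internal:
                if lp.value(other) > tol:
                    hits.add(direction_of[other])
    return frozenset(hits)


def certify_tic_free(model: MetabolicModel, tol: float = FLUX_TOL) -> tuple[bool, float]:
    """True iff no internal direction can carry flux with exchanges closed.

    Returns (is_free, maximum internal flux found); the flux is a witness
    when the certificate fails.
    """
    split, _ = _split_directions(model)
    lp, internal = _internal_unit_problem(split)
    worst = 0.0
    for rid in internal:
        lp.set_objective({rid: 1.0}, direction="max")
        if lp.optimize() != STATUS_OPTIMAL:
            continue
        worst = max(worst, lp.objective_value())
        if worst > tol:
            return False, worst
    return True, worst


def apply_removal(
    model: MetabolicModel, removed: frozenset[tuple[str, str]]
) -> MetabolicModel:
    """Zero the removed directions: fwd removal sets ub=0, bwd removal lb=0."""
    out = model.copy()
    index = out._rxn_index()
    for parent, direction in removed:
        r = index[parent]
        if direction == FWD:
            r.ub = 0.0
            if r.lb > 0.0:
                r.lb = 0.0
        else:
            r.lb = 0.0
    return out


def minimal_tic_removal(
    model: MetabolicModel,
    biomass: str | None = None,
    eps: float = DEFAULT_EPS,
    big_m: float = DEFAULT_BIG_M,
    tol: float = FLUX_TOL,
    whole_reaction: bool = False,
    max_iterations: int = 200,
) -> TicReport:
    """Remove a minimum-cardinality set of directions so no TIC remains.

    ``biomass`` (default: the model objective) must stay feasible at flux >=
    eps after removal; if every hitting set kills biomass the report status
    is ``no_valid_removal`` with the accumulated cuts.  With
    ``whole_reaction=True`` removal decisions are taken per parent reaction
    instead of per direction.
    """
    biomass = biomass if biomass is not None else model.objective
    split, direction_of = _split_directions(model)
    tic_dirs = sorted(find_tic_directions(model, tol=tol))
    tic_parents = frozenset(p for p, _ in tic_dirs)
    if not tic_dirs:
        return TicReport(
            tic_reactions=frozenset(), removed=frozenset(), model=model.copy()
        )

    dir_to_split = {v: k for k, v in direction_of.items()}
    decision_units = (
        sorted(tic_parents) if whole_reaction else list(tic_dirs)
    )

    def unit_of(direction: tuple[str, str]):
        return direction[0] if whole_reaction else direction

    cuts: list[frozenset[tuple[str, str]]] = []

    z_name = {u: f"z{k}" for k, u in enumerate(decision_units)}

    def solve_master(current_cuts) -> tuple[str, frozenset[tuple[str, str]]]:
        lp = LinearProblem()
        for u in decision_units:
            lp.add_binary(z_name[u])
        # biomass-survival flux block on the split model
        for r in split.reactions:
            lp.add_var(f"w_{r.id}", r.lb, r.ub)
        balance: dict[str, dict[str, float]] = {}
        for r in split.reactions:
            for met, coeff in r.stoich.items():
                balance.setdefault(met, {})[f"w_{r.id}"] = coeff
        for met, coeffs in balance.items():
            lp.add_constraint(coeffs, lb=0.0, ub=0.0)
        if biomass is not None:
            if split.has_reaction(biomass):
                lp.add_constraint({f"w_{biomass}": 1.0}, lb=eps)
            else:  # biomass was reversible and got split
                fid = dir_to_split[(biomass, FWD)]
                bid = dir_to_split[(biomass, BWD)]
                lp.add_constraint({f"w_{fid}": 1.0, f"w_{bid}": -1.0}, lb=eps)
        for d in tic_dirs:
            sid = dir_to_split[d]
            lp.add_constraint(
                {f"w_{sid}": 1.0, z_name[unit_of(d)]: big_m}, ub=big_m
            )
        for cut in current_cuts:
            lp.add_constraint(
                {z_name[unit_of(d)]: 1.0 for d in cut if d in set(tic_dirs)}, lb=1.0
            )
        n = max(len(decision_units), 1)
        lp.set_objective(
            {z_name[u]: 1.0 + 1e-6 * (k / n) for k, u in enumerate(decision_units)},
            direction="min",
        )
        status = lp.optimize()
        if status != STATUS_OPTIMAL:
            return status, frozenset()
        chosen_units = {u for u in decision_units if lp.value(z_name[u]) > 0.5}
        removed = frozenset(
            d for d in tic_dirs if unit_of(d) in chosen_units
        )
        return status, removed

    def find_cycle(removed: frozenset[tuple[str, str]]):
        lp, internal = _internal_unit_problem(split)
        for d in removed:
            lp.set_bounds(dir_to_split[d], 0.0, 0.0)
        for rid in internal:
            d = direction_of[rid]
            if d in removed or d not in set(tic_dirs):
                continue
            lp.set_objective({rid: 1.0}, direction="max")
            if lp.optimize() != STATUS_OPTIMAL:
                continue
            if lp.objective_value() > tol:
                support = frozenset(
                    direction_of[o] for o in internal if lp.value(o) > tol
                )
                return support
        return None

    removed: frozenset[tuple[str, str]] = frozenset()
    iterations = 0
    while iterations < max_iterations:
        iterations += 1
        cycle = find_cycle(removed)
        if cycle is None:
            result_model = apply_removal(model, removed)
            return TicReport(
                tic_reactions=tic_parents,
                removed=removed,
                certificates=cuts,
                status=STATUS_OPTIMAL,
                iterations=iterations,
                model=result_model,
            )
        cuts.append(cycle)
        status, removed = solve_master(cuts)
        if status != STATUS_OPTIMAL:
            return TicReport(
                tic_reactions=tic_parents,
                removed=frozenset(),
                certificates=cuts,
                status="no_valid_removal",
                iterations=iterations,
            )
    raise RuntimeError("TIC removal did not converge within max_iterations")
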