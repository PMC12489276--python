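"""Thin LP/MILP layer over optlang's GLPK interface.

All structural optimization problems in this package (flux balance solves,
the compartmentalization and loop-removal MILPs, gap-filling) are built on
this layer.  Two GLPK-specific pitfalls are handled centrally:

* big-M formulations with a small flux floor (eps/M ~ 1e-6) fall inside
  GLPK's default integrality tolerance (1e-5), so the LP relaxation can be
  accepted as "integer feasible" and a wrong optimum returned; the MIP
  tolerance is therefore tightened to 1e-9 before every integer solve;
* optlang's ``.primal`` reports the last simplex (relaxation) values for
  integer problems, so MIP column values are read via swiglpk directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import swiglpk as glp
from optlang.glpk_interface import Constraint, Model as OptModel, Objective, Variable

from .model import MetabolicModel

STATUS_OPTIMAL = "optimal"
STATUS_INFEASIBLE = "infeasible"

#: absolute tolerance on LP optima used throughout
LP_TOL = 1e-9


@dataclass
class FluxResult:
    """Outcome of a flux optimization.

    ``objective`` is in h^-1 when the objective is a biomass reaction, else
    mmol gDW^-1 h^-1.  ``fluxes`` maps reaction id to flux.
    """

    objective: float
    fluxes: dict[str, float]
    status: str

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OPTIMAL


class LinearProblem:
    """A named-variable LP/MILP wrapper.

    Continuous variables are created with :meth:`add_var`, binaries with
    :meth:`add_binary`; constraints take ``{var_name: coeff}`` mappings so
    callers never touch sympy expressions directly.
    """

    def __init__(self) -> None:
        self._opt = OptModel()
        self._vars: dict[str, Variable] = {}
        self._has_binary = False
        self._n_con = 0
        self._pending: list[Constraint] = []

    # -- construction ----------------------------------------------------
    def add_var(self, name: str, lb: float | None, ub: float | None) -> None:
        v = Variable(name, lb=lb, ub=ub)
        self._vars[name] = v

    def add_binary(self, name: str) -> None:
        v = Variable(name, type="binary")
        self._vars[name] = v
        self._has_binary = True

    def add_constraint(
        self, coeffs: dict[str, float], lb: float | None = None, ub: float | None = None
    ) -> None:
        expr = sum(c * self._vars[n] for n, c in coeffs.items() if c != 0.0)
        self._n_con += 1
        self._pending.append(Constraint(expr, lb=lb, ub=ub, name=f"c{self._n_con}"))

    def flush(self) -> None:
        if self._pending:
            self._opt.add(self._pending)
            self._opt.update()
            self._pending = []

    def set_objective(self, coeffs: dict[str, float], direction: str = "max") -> None:
        self.flush()
        expr = sum(c * self._vars[n] for n, c in coeffs.items() if c != 0.0)
        self._opt.objective = Objective(expr, direction=direction)

    def set_bounds(self, name: str, lb: float | None, ub: float | None) -> None:
        v = self._vars[name]
        # clear first so lb<=ub ordering never trips optlang's setter
        v.lb = None
        v.ub = ub
        v.lb = lb

    def bounds(self, name: str) -> tuple[float | None, float | None]:
        v = self._vars[name]
        return v.lb, v.ub

    # -- solving ---------------------------------------------------------
    _GLP_STATUS = {
        glp.GLP_OPT: STATUS_OPTIMAL,
        glp.GLP_FEAS: "feasible",
        glp.GLP_INFEAS: STATUS_INFEASIBLE,
        glp.GLP_NOFEAS: STATUS_INFEASIBLE,
        glp.GLP_UNBND: "unbounded",
        glp.GLP_UNDEF: "undefined",
    }

    def optimize(self) -> str:
        """Solve via GLPK directly (optlang builds the problem only).

        optlang's own optimize() is bypassed: its scaling/retry sequence can
        re-run simplex from a stale basis after an infeasible result and
        report a spurious optimum, and its MIP defaults accept big-M
        relaxations as integral (see module docstring).
        """
        self.flush()
        self._opt.update()
        prob = self._opt.problem
        parm = glp.glp_smcp()
        glp.glp_init_smcp(parm)
        parm.msg_lev = glp.GLP_MSG_OFF
        glp.glp_std_basis(prob)
        glp.glp_simplex(prob, parm)
        self._status = self._GLP_STATUS.get(glp.glp_get_status(prob), "undefined")
        if self._has_binary and self._status == STATUS_OPTIMAL:
            iocp = glp.glp_iocp()
            glp.glp_init_iocp(iocp)
            iocp.msg_lev = glp.GLP_MSG_OFF
            iocp.tol_int = 1e-9
            iocp.tol_obj = 1e-9
            glp.glp_intopt(prob, iocp)
            self._status = self._GLP_STATUS.get(glp.glp_mip_status(prob), "undefined")
        return self._status

    @property
    def status(self) -> str:
        return getattr(self, "_status", "undefined")

    def objective_value(self) -> float:
        prob = self._opt.problem
        if self._has_binary:
            return float(glp.glp_mip_obj_val(prob))
        return float(glp.glp_get_obj_val(prob))

    def value(self, name: str) -> float:
        prob = self._opt.problem
        j = self._col_index(name)
        if self._has_binary:
            return float(glp.glp_mip_col_val(prob, j))
        return float(glp.glp_get_col_prim(prob, j))

    def values(self, names) -> dict[str, float]:
        return {n: self.value(n) for n in names}

    def _col_index(self, name: str) -> int:
        prob = self._opt.problem
        cols = getattr(self, "_col_cache", None)
        ncols = glp.glp_get_num_cols(prob)
        if cols is None or len(cols) != ncols:
            cols = {
                glp.glp_get_col_name(prob, j): j for j in range(1, ncols + 1)
            }
            self._col_cache = cols
        return cols[name]


def build_flux_problem(model: MetabolicModel) -> LinearProblem:
    """Build the steady-state LP: variables per reaction, S v = 0 rows."""
    lp = LinearProblem()
    for r in model.reactions:
        lp.add_var(r.id, r.lb, r.ub)
    balance: dict[str, dict[str, float]] = {}
    for r in model.reactions:
        for met, coeff in r.stoich.items():
            balance.setdefault(met, {})[r.id] = balance.setdefault(met, {}).get(r.id, 0.0) + coeff
    for met, coeffs in balance.items():
        lp.add_constraint(coeffs, lb=0.0, ub=0.0)
    return lp


def optimize_flux(
    model: MetabolicModel,
    objective: str | dict[str, float] | None = None,
    direction: str = "max",
) -> FluxResult:
    """Solve an FBA-style LP on the model and return fluxes for all reactions."""
    if objective is None:
        objective = model.objective
    if objective is None:
        raise ValueError("no objective reaction set")
    if isinstance(objective, str):
        objective = {objective: 1.0}
    lp = build_flux_problem(model)
    lp.set_objective(objective, direction=direction)
    status = lp.optimize()
    if status != STATUS_OPTIMAL:
        return FluxResult(objective=0.0, fluxes={}, status=status)
    fluxes = {r.id: lp.value(r.id) for r in model.reactions}
    return FluxResult(objective=lp.objective_value(), fluxes=fluxes, status=status)
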