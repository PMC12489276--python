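"""Flux analyses: FBA, pFBA, FVA, active-reaction calling, essentiality,
growth-correlation target screening, and homolog flux comparison.

All solves run on the native LP layer; growth conditions are applied with
:func:`algaegem.model.apply_condition` before building the problem.  pFBA
minimizes total absolute flux at fixed optimal growth on an internally split
model; FVA reports per-reaction flux ranges at a given fraction of the
optimum.  The screening procedure fixes growth at each of ``n_increments``
uniform fractions of the maximum, computes the parsimonious flux
distribution, and selects reactions whose flux correlates with growth
(Pearson r above a threshold at an adjusted p-value), mapping them to genes
through the GPR rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import GrowthCondition, MetabolicModel, apply_condition, split_reversible
from .solve import (
    STATUS_OPTIMAL,
    FluxResult,
    LinearProblem,
    build_flux_problem,
    optimize_flux,
)

FLUX_TOL = 1e-6


def _prepare(model: MetabolicModel, cond: GrowthCondition | None) -> MetabolicModel:
    return apply_condition(model, cond) if cond is not None else model


def fba(model: MetabolicModel, cond: GrowthCondition | None = None) -> FluxResult:
    """Maximize the (condition's) objective; growth objectives are in h^-1."""
    return optimize_flux(_prepare(model, cond))


def pfba(
    model: MetabolicModel,
    cond: GrowthCondition | None = None,
    fraction: float = 1.0,
) -> FluxResult:
    """Parsimonious FBA: minimize total |v| at growth = fraction x optimum."""
    prepared = _prepare(model, cond)
    best = optimize_flux(prepared)
    if not best.ok:
        return best
    split, mapping = split_reversible(prepared)
    lp = build_flux_problem(split)
    lp.add_constraint({split.objective: 1.0}, lb=fraction * best.objective,
                      ub=fraction * best.objective)
    lp.set_objective({r.id: 1.0 for r in split.reactions}, direction="min")
    status = lp.optimize()
    if status != STATUS_OPTIMAL:
        return FluxResult(objective=0.0, fluxes={}, status=status)
    fluxes: dict[str, float] = {}
    split_ids = {fid for pair in mapping.values() for fid in pair}
    for r in prepared.reactions:
        if r.id in mapping:
            fid, bid = mapping[r.id]
            fluxes[r.id] = lp.value(fid) - lp.value(bid)
        else:
            fluxes[r.id] = lp.value(r.id)
    growth = fluxes[prepared.objective] if prepared.objective in fluxes else 0.0
    return FluxResult(objective=growth, fluxes=fluxes, status=status)


def fva(
    model: MetabolicModel,
    cond: GrowthCondition | None = None,
    fraction_of_optimum: float = 1.0,
    reactions: list[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-reaction (min, max) flux with growth held >= fraction x optimum."""
    prepared = _prepare(model, cond)
    lp = build_flux_problem(prepared)
    if fraction_of_optimum > 0.0:
        best = optimize_flux(prepared)
        if not best.ok:
            raise RuntimeError(f"FBA not optimal ({best.status}); cannot run FVA")
        lp.add_constraint({prepared.objective: 1.0},
                          lb=fraction_of_optimum * best.objective)
    targets = reactions if reactions is not None else [r.id for r in prepared.reactions]
    ranges: dict[str, tuple[float, float]] = {}
    for rid in targets:
        lo = hi = 0.0
        lp.set_objective({rid: 1.0}, direction="min")
        if lp.optimize() == STATUS_OPTIMAL:
            lo = lp.objective_value()
        lp.set_objective({rid: 1.0}, direction="max")
        if lp.optimize() == STATUS_OPTIMAL:
            hi = lp.objective_value()
        ranges[rid] = (lo, hi)
    return ranges


def call_active_reactions(
    model: MetabolicModel,
    cond: GrowthCondition | None = None,
    fraction_of_optimum: float = 1.0,
    tol: float = FLUX_TOL,
) -> frozenset[str]:
    """Parent reactions with positive flux range, after split-pair exclusion.

    The model is split into irreversible directions; a direction is active
    when its FVA maximum exceeds ``tol``.  Split pairs whose forward and
    backward maxima agree within tolerance are excluded (both directions):
    such pairs indicate a cycle rather than genuine condition-specific
    activity.  Results are reported at parent-reaction level.
    """
    prepared = _prepare(model, cond)
    split, mapping = split_reversible(prepared)
    ranges = fva(split, None, fraction_of_optimum=fraction_of_optimum)
    active: set[str] = set()
    split_children = {fid: parent for parent, pair in mapping.items() for fid in pair}
    for parent, (fid, bid) in mapping.items():
        fmax, bmax = ranges[fid][1], ranges[bid][1]
        if abs(fmax - bmax) <= tol * max(1.0, abs(fmax), abs(bmax)):
            continue  # same maximum both ways: exclude as a false positive
        if max(fmax, bmax) > tol:
            active.add(parent)
    for rid, (_, hi) in ranges.items():
        if rid in split_children:
            continue
        if hi > tol:
            active.add(rid)
    return frozenset(active)


def condition_partition(
    auto: frozenset[str], mixo: frozenset[str], hetero: frozenset[str]
) -> dict[str, frozenset[str]]:
    """Exclusive-intersection classes of three active-reaction sets.

    Pairwise classes exclude the third set, matching UpSet-diagram semantics
    (e.g. ``mixo_hetero`` is active in both mixotrophic and heterotrophic
    growth but blocked photoautotrophically).
    """
    return {
        "auto_only": frozenset(auto - mixo - hetero),
        "mixo_only": frozenset(mixo - auto - hetero),
        "hetero_only": frozenset(hetero - auto - mixo),
        "auto_mixo": frozenset((auto & mixo) - hetero),
        "auto_hetero": frozenset((auto & hetero) - mixo),
        "mixo_hetero": frozenset((mixo & hetero) - auto),
        "all": frozenset(auto & mixo & hetero),
    }


def essentiality(
    model: MetabolicModel,
    cond: GrowthCondition | None = None,
    target: str = "gene",
    threshold_frac: float = 0.01,
) -> frozenset[str]:
    """Genes or reactions whose single knockout drops growth below
    threshold_frac x wild-type.

    A gene knockout disables every reaction whose GPR evaluates false with
    that gene absent; reaction knockouts zero the reaction bounds directly.
    """
    if target not in ("gene", "reaction"):
        raise ValueError("target must be 'gene' or 'reaction'")
    prepared = _prepare(model, cond)
    wild_type = optimize_flux(prepared)
    if not wild_type.ok:
        raise RuntimeError("wild-type FBA infeasible; cannot assess essentiality")
    cutoff = threshold_frac * wild_type.objective

    lp = build_flux_problem(prepared)
    lp.set_objective({prepared.objective: 1.0}, direction="max")
    essential: set[str] = set()

    def knockout_growth(disabled: list[str]) -> float:
        saved = {rid: lp.bounds(rid) for rid in disabled}
        for rid in disabled:
            lp.set_bounds(rid, 0.0, 0.0)
        growth = lp.objective_value() if lp.optimize() == STATUS_OPTIMAL else 0.0
        for rid, (lb, ub) in saved.items():
            lp.set_bounds(rid, lb, ub)
        return growth

    if target == "reaction":
        for r in prepared.reactions:
            if knockout_growth([r.id]) < cutoff:
                essential.add(r.id)
    else:
        for gene in sorted(prepared.genes):
            disabled = [
                r.id for r in prepared.reactions
                if not r.gpr.is_empty and not r.gpr.evaluate({gene})
            ]
            if disabled and knockout_growth(disabled) < cutoff:
                essential.add(gene)
    return frozenset(essential)


@dataclass
class TargetScreenResult:
    genes: frozenset[str]
    table: pd.DataFrame  # reaction_id, r, p, p_adj, selected
    skipped: frozenset[str]  # zero-variance flux series


def growth_correlated_targets(
    model: MetabolicModel,
    cond: GrowthCondition | None = None,
    n_increments: int = 100,
    r_min: float = 0.8,
    alpha: float = 0.01,
    mtc: str = "fdr_bh",
) -> TargetScreenResult:
    """Screen for genes whose reaction fluxes scale with growth rate.

    The maximum growth rate is divided into ``n_increments`` uniform steps;
    at each step growth is fixed and the pFBA flux distribution computed.
    Reactions with Pearson r > r_min and multiplicity-adjusted p < alpha
    (method ``mtc``: 'fdr_bh' or 'bonferroni') are mapped to the unique set
    of associated genes.
    """
    prepared = _prepare(model, cond)
    best = optimize_flux(prepared)
    if not best.ok or best.objective <= 0:
        raise RuntimeError("growth optimum must be positive for target screening")
    mu_max = best.objective
    growth_grid = np.array([(k / n_increments) * mu_max for k in range(1, n_increments + 1)])
    rxn_ids = [r.id for r in prepared.reactions]
    flux_matrix = np.empty((n_increments, len(rxn_ids)))
    for i, mu in enumerate(growth_grid):
        # fix growth by bounding the objective reaction at mu
        fixed = prepared.copy()
        obj = fixed.reaction(fixed.objective)
        obj.lb, obj.ub = mu, mu
        sol = pfba(fixed, None, fraction=1.0)
        if not sol.ok:
            raise RuntimeError(f"pFBA infeasible at growth {mu:.6g}")
        flux_matrix[i] = [sol.fluxes[rid] for rid in rxn_ids]

    rows = []
    skipped = set()
    for j, rid in enumerate(rxn_ids):
        series = flux_matrix[:, j]
        if np.ptp(series) < 1e-12:
            skipped.add(rid)
            continue
        r, p = stats.pearsonr(series, growth_grid)
        rows.append((rid, r, p))
    table = pd.DataFrame(rows, columns=["reaction_id", "r", "p"])
    if len(table):
        table["p_adj"] = multipletests(table["p"].to_numpy(), method=mtc)[1]
    else:
        table["p_adj"] = []
    table["selected"] = (table["r"] > r_min) & (table["p_adj"] < alpha)

    genes: set[str] = set()
    index = prepared._rxn_index()
    for rid in table.loc[table["selected"], "reaction_id"]:
        genes |= index[rid].genes
    return TargetScreenResult(
        genes=frozenset(genes), table=table, skipped=frozenset(skipped)
    )


def compare_homolog_fluxes(
    samples_a, samples_b, pairs: list[tuple[str, str]], alpha: float = 0.05
) -> pd.DataFrame:
    """Welch t-test per homolog reaction pair with Bonferroni correction.

    ``samples_a``/``samples_b`` are FluxSample objects from the two models.
    Returns a table (pair, means, t, p, p_bonf, significant, higher_in);
    pairs with zero variance on both sides are flagged undefined.
    """
    m = len(pairs)
    rows = []
    for rid_a, rid_b in pairs:
        xa = samples_a.column(rid_a)
        xb = samples_b.column(rid_b)
        if xa.std() == 0.0 and xb.std() == 0.0:
            rows.append((rid_a, rid_b, xa.mean(), xb.mean(), np.nan, np.nan,
                         np.nan, False, "undefined"))
            continue
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
        p_bonf = min(p * m, 1.0)
        significant = bool(p_bonf < alpha)
        higher = "a" if xa.mean() > xb.mean() else "b"
        rows.append((rid_a, rid_b, xa.mean(), xb.mean(), t, p, p_bonf,
                     significant, higher if significant else "none"))
    return pd.DataFrame(
        rows,
        columns=["reaction_a", "reaction_b", "mean_a", "mean_b", "t", "p",
                 "p_bonf", "significant", "higher_in"],
    )
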