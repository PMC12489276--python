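"""Artificial-centering hit-and-run sampling of the steady-state flux polytope.

The feasible set {v : S v = 0, lb <= v <= ub} is an H-polytope inside the
null space of S.  The chain walks in null-space coordinates so every iterate
satisfies the steady-state equalities to numerical precision; directions are
drawn ACHR-style as (random stored point - running center), which adapts
step geometry to elongated polytopes.  Every ``thinning``-th state is kept.
The chain is a pure function of the seed: fixed seed gives a bit-identical
sample matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

from .model import MetabolicModel
from .solve import STATUS_OPTIMAL, LinearProblem

_BOUND_TOL = 1e-9


class SamplingError(RuntimeError):
    pass


@dataclass
class FluxSample:
    """n_samples x n_reactions matrix of feasible flux vectors."""

    samples: np.ndarray
    reaction_ids: list[str]
    seed: int
    thinning: int

    def mean(self) -> dict[str, float]:
        mu = self.samples.mean(axis=0)
        return dict(zip(self.reaction_ids, mu.tolist()))

    def column(self, rxn_id: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(rxn_id)]


def _stoichiometric_matrix(model: MetabolicModel) -> tuple[np.ndarray, list[str]]:
    rxn_ids = [r.id for r in model.reactions]
    met_ids = [m.id for m in model.metabolites]
    met_pos = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, r in enumerate(model.reactions):
        for met, coeff in r.stoich.items():
            S[met_pos[met], j] += coeff
    return S, rxn_ids


def _warm_points(model: MetabolicModel, basis: np.ndarray, rng: np.random.Generator,
                 n_points: int) -> np.ndarray:
    """Feasible vertices from LPs with random null-space objectives."""
    lp = LinearProblem()
    for r in model.reactions:
        lp.add_var(r.id, r.lb, r.ub)
    balance: dict[str, dict[str, float]] = {}
    for r in model.reactions:
        for met, coeff in r.stoich.items():
            balance.setdefault(met, {})[r.id] = coeff
    for met, coeffs in balance.items():
        lp.add_constraint(coeffs, lb=0.0, ub=0.0)
    rxn_ids = [r.id for r in model.reactions]
    points = []
    for _ in range(n_points):
        direction = basis @ rng.standard_normal(basis.shape[1])
        norm = np.linalg.norm(direction)
        if norm < 1e-12:
            continue
        lp.set_objective(dict(zip(rxn_ids, (direction / norm).tolist())), direction="max")
        if lp.optimize() != STATUS_OPTIMAL:
            raise SamplingError(
                "flux polytope is unbounded along a null-space direction; "
                "tighten reaction bounds before sampling"
            )
        points.append(np.array([lp.value(rid) for rid in rxn_ids]))
    if not points:
        raise SamplingError("could not generate feasible warm-up points")
    return np.array(points)


def sample_fluxes(
    model: MetabolicModel,
    n: int = 5000,
    thinning: int = 1000,
    seed: int = 0,
    warmup_per_dim: int = 100,
) -> FluxSample:
    """Draw ``n`` feasible flux vectors, keeping every ``thinning``-th state.

    Warm-up runs ``warmup_per_dim`` x (null-space dimension) burn-in steps
    before the first kept state.  Raises SamplingError when the polytope is
    unbounded (the chord would be infinite) or empty.
    """
    S, rxn_ids = _stoichiometric_matrix(model)
    n_rxns = len(rxn_ids)
    if S.shape[0]:
        basis = null_space(S)
    else:
        basis = np.eye(n_rxns)
    dim = basis.shape[1]
    if dim == 0:
        raise SamplingError("flux polytope is a single point; nothing to sample")

    lb = np.array([r.lb for r in model.reactions], dtype=float)
    ub = np.array([r.ub for r in model.reactions], dtype=float)
    rng = np.random.default_rng(seed)

    vertices = _warm_points(model, basis, rng, n_points=min(2 * dim + 4, 30))
    center = vertices.mean(axis=0)
    stored = [v for v in vertices]
    point = center.copy()

    def step(x: np.ndarray) -> np.ndarray:
        # ACHR direction: stored point minus current center
        pick = stored[int(rng.integers(len(stored)))]
        d = pick - center
        nrm = (d @ d) ** 0.5
        if nrm < 1e-12:
            d = basis @ rng.standard_normal(dim)
            nrm = (d @ d) ** 0.5
            if nrm < 1e-12:
                return x
        d = d / nrm
        # chord extent: division only on coordinates that actually move
        moving = np.abs(d) > _BOUND_TOL
        dm = d[moving]
        xm = x[moving]
        to_ub = (ub[moving] - xm) / dm
        to_lb = (lb[moving] - xm) / dm
        hi = np.where(dm > 0, to_ub, to_lb)
        lo = np.where(dm > 0, to_lb, to_ub)
        if hi.size == 0:
            return x
        tmax = hi.min()
        tmin = lo.max()
        if not np.isfinite(tmin) or not np.isfinite(tmax):
            raise SamplingError("flux polytope is unbounded; tighten bounds")
        if tmax < tmin:
            return x
        t = tmin + (tmax - tmin) * rng.random()
        out = x + t * d
        np.clip(out, lb, ub, out=out)
        return out

    for _ in range(warmup_per_dim * dim):
        point = step(point)

    samples = np.empty((n, n_rxns))
    count = 0
    total = 0
    while count < n:
        point = step(point)
        total += 1
        if total % thinning == 0:
            samples[count] = point
            count += 1
            stored.append(point.copy())
            if len(stored) > 200:
                stored.pop(0)
            center = center + (point - center) / (len(stored) + 1)

    return FluxSample(samples=samples, reaction_ids=rxn_ids, seed=seed, thinning=thinning)


def validate_sample(model: MetabolicModel, sample: FluxSample, tol: float = 1e-6) -> bool:
    """Every row satisfies S v = 0 and the bounds within tolerance."""
    S, rxn_ids = _stoichiometric_matrix(model)
    assert rxn_ids == sample.reaction_ids
    lb = np.array([r.lb for r in model.reactions]) - tol
    ub = np.array([r.ub for r in model.reactions]) + tol
    X = sample.samples
    if S.shape[0] and np.abs(S @ X.T).max() > tol:
        return False
    return bool((X >= lb).all() and (X <= ub).all())
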