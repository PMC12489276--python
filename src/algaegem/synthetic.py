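"""Synthetic fixtures: toy networks with planted, verifiable structure.

Everything downstream is testable without downloads: the compartmentalization
demonstration network (two reactions replicated over three compartments with
five shared metabolites), noisy localization profiles with known ground
truth, and seeded random chain models with planted thermodynamically
infeasible cycles, gaps, and compartment assignments.  All generators are
pure functions of their arguments (and seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enzymes import UniversalPool
from .localization import LocalizationProfile
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction
from .gpr import parse_gpr


@dataclass
class ToySpec:
    """Parameters for :func:`make_random_model`."""

    n_reactions: int = 8
    n_tics: int = 0
    tic_length: int = 3
    n_gaps: int = 0
    uptake: float = 10.0
    biomass_yield: float = 0.5  # growth per unit substrate
    seed: int = 0


def make_fig2_toy() -> tuple[MetabolicModel, dict[str, frozenset[str]], list[tuple[str, str]]]:
    """Two-reaction, three-compartment compartmentalization demonstration.

    R1: A -> B + D and R2: B -> C + E over shared metabolites A..E, with A
    sourced in C1 and per-compartment precursor demands chosen so that the
    unique optimal pruning (verified by exhaustive enumeration of MILP
    optima) keeps R1 in {C1, C2} and R2 in {C1, C3}: one R2 instance is
    removed from C2 and one R1 instance from C3, and redundant transports
    are pruned.  Replication yields 6 instances and 15 transport candidates
    (5 metabolites x C(3,2) pairs).
    """
    model = MetabolicModel(id="fig2_toy", compartments=["C1", "C2", "C3"])
    for met in "ABCDE":
        model.add_metabolite(Metabolite(met, compartment="C1"))
    model.add_reaction(Reaction("R1", {"A": -1.0, "B": 1.0, "D": 1.0}))
    model.add_reaction(Reaction("R2", {"B": -1.0, "C": 1.0, "E": 1.0}))
    model.add_reaction(Reaction("SRC_A", {"A": 1.0}, kind="exchange"))
    assignment = {
        "R1": frozenset({"C1", "C2", "C3"}),
        "R2": frozenset({"C1", "C2", "C3"}),
        "SRC_A": frozenset({"C1"}),
    }
    precursors = [
        ("C", "C1"), ("D", "C1"), ("E", "C1"),
        ("A", "C2"), ("B", "C2"), ("D", "C2"),
        ("B", "C3"), ("C", "C3"), ("E", "C3"),
    ]
    return model, assignment, precursors

#: instances the demonstration toy's optimal pruning removes
FIG2_EXPECTED_REMOVED = frozenset({"R2__C2", "R1__C3"})


def simulate_localization_profiles(
    true_assignment: dict[str, str],
    n_tools: int = 5,
    noise: float = 0.2,
    seed: int = 0,
    compartments: list[str] | None = None,
    jitter: float = 0.0,
) -> LocalizationProfile:
    """Per-tool probability vectors around a planted true compartment.

    Each tool gives the true compartment probability 1 - noise and spreads
    the remaining mass uniformly over the other compartments.  With
    ``jitter`` > 0 a seeded perturbation of that magnitude is added per
    tool/protein before renormalization (independent across tools and
    proteins).  noise = 0 reproduces the truth exactly.
    """
    if not 0.0 <= noise < 1.0:
        raise ValueError("noise must be in [0, 1)")
    comps = compartments or sorted(set(true_assignment.values()))
    rng = np.random.default_rng(seed)
    profile = LocalizationProfile()
    for protein in sorted(true_assignment):
        truth = true_assignment[protein]
        if truth not in comps:
            raise ValueError(f"true compartment {truth!r} not in compartment list")
        others = [c for c in comps if c != truth]
        for t in range(n_tools):
            probs = {truth: 1.0 - noise}
            for c in others:
                probs[c] = noise / len(others) if others else 0.0
            if jitter > 0.0:
                for c in comps:
                    probs[c] = max(probs.get(c, 0.0) + jitter * rng.random(), 0.0)
                total = sum(probs.values())
                probs = {c: p / total for c, p in probs.items()}
            profile.set(protein, f"tool{t + 1}", {c: p for c, p in probs.items() if p > 0})
    return profile


def make_tca_like_block(
    n_reactions: int = 9, genes_per_reaction: int = 3
) -> tuple[MetabolicModel, dict[str, str]]:
    """A cycle of mitochondrial reactions with multi-gene GPRs.

    Emulates a TCA-cycle validation case: every associated gene is truly
    mitochondrial, so consensus voting should place the whole block in the
    mitochondrion.  Returns the model and the gene -> compartment truth.
    """
    model = MetabolicModel(id="tca_like", compartments=["c", "m"])
    truth: dict[str, str] = {}
    for i in range(n_reactions):
        model.add_metabolite(Metabolite(f"t{i}", compartment="m"))
    for i in range(n_reactions):
        genes = [f"tca_g{i}_{k}" for k in range(genes_per_reaction)]
        for g in genes:
            truth[g] = "m"
        model.add_reaction(
            Reaction(
                f"TCA{i + 1}",
                {f"t{i}": -1.0, f"t{(i + 1) % n_reactions}": 1.0},
                gpr=parse_gpr(" or ".join(genes)),
            )
        )
    return model, truth


def make_random_model(spec: ToySpec) -> tuple[MetabolicModel, dict]:
    """Seeded chain model with planted cycles and gaps.

    The backbone is EX_S -> S0 -> S1 -> ... -> biomass with known optimum
    uptake x yield.  Each planted cycle of length L adds L reactions that
    circulate through one backbone metabolite (a thermodynamically
    infeasible cycle disjoint from the biomass route).  Gaps remove backbone
    reactions into a universal pool.  Returns the model and a record of the
    planted structure: ``tic_reactions`` (list of id lists), ``gap_pool``
    (UniversalPool), ``expected_growth``.
    """
    rng = np.random.default_rng(spec.seed)
    n = max(spec.n_reactions, 2)
    model = MetabolicModel(id=f"chain{spec.seed}", compartments=["c", "e"])
    model.add_metabolite(Metabolite("S_e", compartment="e"))
    for i in range(n):
        model.add_metabolite(Metabolite(f"S{i}", compartment="c"))
    model.add_reaction(
        Reaction("EX_S", {"S_e": -1.0}, lb=-spec.uptake, ub=DEFAULT_BOUND, kind="exchange")
    )
    model.add_reaction(Reaction("UPT", {"S_e": -1.0, "S0": 1.0}, gpr=parse_gpr("g_upt"),
                                kind="transport"))
    for i in range(n - 1):
        model.add_reaction(
            Reaction(f"R{i + 1}", {f"S{i}": -1.0, f"S{i + 1}": 1.0},
                     gpr=parse_gpr(f"g{i + 1}"))
        )
    model.add_reaction(
        Reaction("biomass", {f"S{n - 1}": -1.0 / spec.biomass_yield}, kind="biomass")
    )
    model.objective = "biomass"

    tic_records: list[list[str]] = []
    for j in range(spec.n_tics):
        anchor = f"S{int(rng.integers(0, n - 1))}"
        length = max(spec.tic_length, 2)
        ids = []
        prev = anchor
        for k in range(length - 1):
            xm = f"X{j}_{k}"
            model.add_metabolite(Metabolite(xm, compartment="c"))
            rid = f"TIC{j}_{k}"
            model.add_reaction(Reaction(rid, {prev: -1.0, xm: 1.0}))
            ids.append(rid)
            prev = xm
        rid = f"TIC{j}_{length - 1}"
        model.add_reaction(Reaction(rid, {prev: -1.0, anchor: 1.0}))
        ids.append(rid)
        tic_records.append(ids)

    pool = UniversalPool()
    if spec.n_gaps:
        candidates = [f"R{i + 1}" for i in range(n - 1)]
        gaps = rng.choice(candidates, size=min(spec.n_gaps, len(candidates)),
                          replace=False)
        index = model._rxn_index()
        for rid in sorted(gaps):
            r = index[rid]
            pool.reactions.append(
                Reaction(f"U_{rid}", dict(r.stoich), lb=r.lb, ub=r.ub)
            )
            pool.source[f"U_{rid}"] = "universal"
        model.remove_reactions(sorted(gaps))

    records = {
        "tic_reactions": tic_records,
        "gap_pool": pool,
        "expected_growth": spec.uptake * spec.biomass_yield,
    }
    return model, records


def make_random_compartment_case(
    seed: int, n_comps: int = 2, chain_length: int = 3
) -> tuple[MetabolicModel, dict[str, frozenset[str]], list[tuple[str, str]]]:
    """Random small compartmentalization instance for brute-force comparison.

    A linear chain M0 -> M1 -> ... with a source of M0, each reaction
    randomly assigned to 1-2 of ``n_comps`` compartments, and 1-3 random
    precursor demands drawn from producible (metabolite, compartment) pairs.
    Kept small so exhaustive enumeration over keep/remove subsets is cheap.
    """
    rng = np.random.default_rng(seed)
    comps = [f"C{i + 1}" for i in range(n_comps)]
    model = MetabolicModel(id=f"case{seed}", compartments=list(comps))
    for i in range(chain_length + 1):
        model.add_metabolite(Metabolite(f"M{i}", compartment=comps[0]))
    model.add_reaction(Reaction("SRC", {"M0": 1.0}, kind="exchange"))
    assignment: dict[str, frozenset[str]] = {"SRC": frozenset({comps[0]})}
    for i in range(chain_length):
        rid = f"R{i + 1}"
        model.add_reaction(Reaction(rid, {f"M{i}": -1.0, f"M{i + 1}": 1.0}))
        k = int(rng.integers(1, n_comps + 1))
        chosen = rng.choice(comps, size=k, replace=False)
        assignment[rid] = frozenset(str(c) for c in chosen)
    # pools that exist after replication: producer and consumer compartments
    pool_comps: dict[str, set[str]] = {}
    for i in range(1, chain_length + 1):
        met = f"M{i}"
        pool_comps[met] = set(assignment[f"R{i}"])
        if i < chain_length:
            pool_comps[met] |= set(assignment[f"R{i + 1}"])
    n_prec = int(rng.integers(1, 4))
    precursors = []
    for _ in range(n_prec):
        met = f"M{int(rng.integers(1, chain_length + 1))}"
        comp = str(rng.choice(sorted(pool_comps[met])))
        if (met, comp) not in precursors:
            precursors.append((met, comp))
    return model, assignment, precursors
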