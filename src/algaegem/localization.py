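"""Consensus protein localization and reaction compartment voting.

Several subcellular-localization predictors each emit a per-protein
probability vector over compartments.  The consensus is the renormalized
arithmetic mean across tools ("wisdom of the crowd" with equal weights).
Reactions inherit compartment votes from their genes through the GPR rule:
the vote of reaction r for compartment c is the average consensus probability
of its genes, so per-reaction votes sum to one.  A reaction is retained in
every compartment whose vote strictly exceeds the retention threshold
(default 25%); reactions whose votes all fall below the threshold fall back
to their highest-vote compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model import ConfigurationError, MetabolicModel

#: common synonyms seen in predictor output files
DEFAULT_COMPARTMENT_ALIASES = {
    "cytoplasm": "c",
    "cytosol": "c",
    "chloroplast": "h",
    "plastid": "p",
    "thylakoid": "p",
    "mitochondrion": "m",
    "mitochondria": "m",
    "vacuole": "l",
    "lysosome": "l",
    "lysosome/vacuole": "l",
    "peroxisome": "x",
    "endoplasmic reticulum": "r",
    "er": "r",
    "extracellular": "e",
    "secreted": "e",
}


@dataclass
class LocalizationProfile:
    """Per-tool localization probabilities: protein -> tool -> {comp: p}."""

    data: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)

    def proteins(self) -> list[str]:
        return sorted(self.data)

    def tools(self) -> list[str]:
        return sorted({t for tools in self.data.values() for t in tools})

    def set(self, protein: str, tool: str, probs: dict[str, float]) -> None:
        for comp, p in probs.items():
            if not 0.0 <= p <= 1.0 + 1e-12:
                raise ValueError(
                    f"probability {p} for {protein}/{tool}/{comp} outside [0, 1]"
                )
        self.data.setdefault(protein, {})[tool] = dict(probs)


@dataclass
class ConsensusLocalization:
    """Aggregated probabilities: protein -> {comp: p}, summing to 1."""

    probabilities: dict[str, dict[str, float]] = field(default_factory=dict)
    unlocalized: frozenset[str] = frozenset()

    def get(self, protein: str) -> dict[str, float]:
        return self.probabilities.get(protein, {})


#: reaction -> {comp: normalized vote}
CompartmentVote = dict[str, dict[str, float]]
#: reaction -> non-empty set of compartments
CompartmentAssignment = dict[str, frozenset[str]]


def read_predictions_tsv(path, aliases: dict[str, str] | None = None) -> LocalizationProfile:
    """Read a predictor table with columns protein_id, tool, compartment, probability."""
    table = pd.read_csv(Path(path), sep="\t")
    required = {"protein_id", "tool", "compartment", "probability"}
    if not required <= set(table.columns):
        raise ValueError(f"prediction table must have columns {sorted(required)}")
    alias = dict(DEFAULT_COMPARTMENT_ALIASES)
    alias.update(aliases or {})
    profile = LocalizationProfile()
    for (protein, tool), group in table.groupby(["protein_id", "tool"]):
        probs: dict[str, float] = {}
        for _, row in group.iterrows():
            comp = str(row["compartment"]).strip().lower()
            comp = alias.get(comp, comp)
            probs[comp] = probs.get(comp, 0.0) + float(row["probability"])
        profile.set(str(protein), str(tool), probs)
    return profile


def aggregate_tool_predictions(
    profile: LocalizationProfile, tools: list[str] | None = None
) -> ConsensusLocalization:
    """Average per-tool probability vectors into a consensus per protein.

    Each tool's vector is renormalized to sum to one first; tools that omit a
    compartment contribute probability zero for it.  Proteins whose every
    tool reports an all-zero vector are flagged unlocalized and excluded from
    the consensus (and hence from voting).
    """
    consensus: dict[str, dict[str, float]] = {}
    unlocalized: set[str] = set()
    for protein, per_tool in profile.data.items():
        selected = {t: v for t, v in per_tool.items() if tools is None or t in tools}
        if not selected:
            raise ValueError(f"protein {protein} has no predictions from requested tools")
        compartments = sorted({c for v in selected.values() for c in v})
        sums = {c: 0.0 for c in compartments}
        n_informative = 0
        for vec in selected.values():
            total = sum(vec.values())
            if total <= 0.0:
                continue
            n_informative += 1
            for c in compartments:
                sums[c] += vec.get(c, 0.0) / total
        if n_informative == 0:
            unlocalized.add(protein)
            continue
        mean = {c: s / len(selected) for c, s in sums.items()}
        total = sum(mean.values())
        consensus[protein] = {c: p / total for c, p in mean.items() if p > 0.0}
    return ConsensusLocalization(
        probabilities=consensus, unlocalized=frozenset(unlocalized)
    )


def vote_reactions(
    model: MetabolicModel, consensus: ConsensusLocalization
) -> CompartmentVote:
    """Vote each GPR-carrying reaction into compartments via its genes.

    vote(r, c) = (1/|genes(r)|) * sum_g consensus(g, c).  Reactions without a
    GPR rule receive no vote record.  Genes missing from both the consensus
    and the unlocalized set raise a ValueError.
    """
    known = set(consensus.probabilities) | set(consensus.unlocalized)
    votes: CompartmentVote = {}
    for r in model.reactions:
        genes = sorted(r.genes)
        if not genes:
            continue
        unknown = [g for g in genes if g not in known]
        if unknown:
            raise ValueError(
                f"reaction {r.id}: genes {unknown} have no localization prediction"
            )
        acc: dict[str, float] = {}
        for g in genes:
            for c, p in consensus.get(g).items():
                acc[c] = acc.get(c, 0.0) + p
        votes[r.id] = {c: p / len(genes) for c, p in acc.items()}
    return votes


def assign_reaction_compartments(
    votes: CompartmentVote,
    threshold: float = 0.25,
    fixed: dict[str, frozenset[str]] | None = None,
    default: str = "c",
    model: MetabolicModel | None = None,
) -> CompartmentAssignment:
    """Threshold votes into compartment assignments.

    A reaction is retained in every compartment with vote strictly above the
    threshold; if none qualifies it falls back to the argmax compartment
    (lexicographic tie-break).  Reactions listed in ``fixed`` (predefined
    pathway compartments that curation must respect) get exactly their fixed
    set.  If a model is supplied, its non-exchange reactions without a GPR
    are assigned ``{default}``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    fixed = fixed or {}
    if model is not None:
        comps = set(model.compartments)
        for rid, comp_set in fixed.items():
            bad = set(comp_set) - comps
            if bad:
                raise ConfigurationError(
                    f"fixed compartments {sorted(bad)} for {rid} not in model"
                )

    assignment: CompartmentAssignment = {}
    for rid, vote in votes.items():
        if rid in fixed:
            assignment[rid] = frozenset(fixed[rid])
            continue
        kept = {c for c, p in vote.items() if p > threshold}
        if not kept:
            best = min(vote.items(), key=lambda cp: (-cp[1], cp[0]))[0]
            kept = {best}
        assignment[rid] = frozenset(kept)
    for rid, comp_set in fixed.items():
        assignment[rid] = frozenset(comp_set)
    if model is not None:
        for r in model.reactions:
            if r.id in assignment or r.kind == "exchange":
                continue
            if r.gpr.is_empty:
                assignment[r.id] = frozenset([default])
    return assignment
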