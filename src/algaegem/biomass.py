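"""Condition-specific biomass reactions and media exchanges.

The cell's dry weight is partitioned into six macromolecular classes
(protein, DNA, RNA, carbohydrate, chlorophyll, lipid) whose mass fractions
(g gDW^-1) are rescaled to sum to exactly 1.  Polymer classes are expanded
into monomer precursors using molar fractions computed from the organism's
genome and proteome; the stoichiometric coefficient of monomer m in class K
with class fraction f_K and molar fraction x_m is

    coeff_m = 1000 * f_K * x_m / sum_k x_k * (MW_k - MW_water)   [mmol/gDW]

where the water of polymerization (18.02 g/mol) is subtracted from each
monomer's molecular weight.  Non-polymer classes supply explicit precursor
metabolites with their own within-class mass shares and full molecular
weights.  By construction the residue-mass-weighted coefficient sum closes
at 1000 mg gDW^-1, which keeps predicted specific growth rates comparable
across models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .model import (
    DEFAULT_BOUND,
    MEDIA_EXCHANGES,
    MetabolicModel,
    Metabolite,
    Reaction,
)

MW_WATER = 18.02

#: average molecular weights of free amino acids, g/mol
AMINO_ACID_MW = {
    "G": 75.07, "A": 89.09, "S": 105.09, "P": 115.13, "V": 117.15,
    "T": 119.12, "C": 121.16, "L": 131.17, "I": 131.17, "N": 132.12,
    "D": 133.10, "Q": 146.15, "K": 146.19, "E": 147.13, "M": 149.21,
    "H": 155.15, "F": 165.19, "R": 174.20, "Y": 181.19, "W": 204.23,
}

DNTP_MW = {"dATP": 491.18, "dCTP": 467.16, "dGTP": 507.18, "dTTP": 482.17}
NTP_MW = {"ATP": 507.18, "CTP": 483.16, "GTP": 523.18, "UTP": 484.14}

POLYMER_CLASSES = ("protein", "dna", "rna")
BIOMASS_CLASSES = POLYMER_CLASSES + ("carbohydrate", "chlorophyll", "lipid")

DEFAULT_MONOMER_MW = {**AMINO_ACID_MW, **DNTP_MW, **NTP_MW}


class BiomassError(ValueError):
    pass


@dataclass
class MonomerFractions:
    """Per-class molar fractions; each class sums to 1."""

    protein: dict[str, float] = field(default_factory=dict)
    dna: dict[str, float] = field(default_factory=dict)
    rna: dict[str, float] = field(default_factory=dict)

    def for_class(self, name: str) -> dict[str, float]:
        return getattr(self, name)

    def validate(self, tol: float = 1e-9) -> None:
        for name in POLYMER_CLASSES:
            frac = self.for_class(name)
            if frac and abs(sum(frac.values()) - 1.0) > tol:
                raise BiomassError(f"{name} monomer fractions do not sum to 1")


@dataclass
class BiomassComposition:
    """Class mass fractions (g gDW^-1) for one growth condition.

    ``precursor_masses`` carries explicit within-class mass shares for the
    non-polymer classes, e.g. ``{"carbohydrate": {"starch": 0.6, "sucrose":
    0.4}}``; shares are renormalized within each class.
    """

    condition: str
    class_fractions: dict[str, float] = field(default_factory=dict)
    precursor_masses: dict[str, dict[str, float]] = field(default_factory=dict)

    def rescaled_fractions(self) -> dict[str, float]:
        """Class fractions rescaled so they sum to exactly 1 g/gDW."""
        for name, f in self.class_fractions.items():
            if name not in BIOMASS_CLASSES:
                raise BiomassError(f"unknown biomass class {name!r}")
            if f < 0:
                raise BiomassError(f"negative class fraction for {name}")
        total = sum(self.class_fractions.values())
        if total <= 0:
            raise BiomassError("class fractions sum to zero")
        return {k: v / total for k, v in self.class_fractions.items()}


@dataclass
class BiomassReaction:
    """Precursor coefficients in mmol gDW^-1 plus polymerization byproducts."""

    id: str
    condition: str
    precursor_coefficients: dict[str, float]  # consumed, positive numbers
    byproducts: dict[str, float] = field(default_factory=dict)  # produced
    residue_mw: dict[str, float] = field(default_factory=dict)  # mg/mmol basis
    gam: float = 0.0  # mmol ATP hydrolyzed per gDW; carries no dry mass

    def mass_mg(self) -> float:
        """Residue-mass-weighted coefficient sum; 1000 mg/gDW by construction."""
        return sum(
            coeff * self.residue_mw[met]
            for met, coeff in self.precursor_coefficients.items()
        )

    def to_reaction(self, ub: float = DEFAULT_BOUND) -> Reaction:
        stoich = {m: -c for m, c in self.precursor_coefficients.items()}
        if self.gam > 0.0:
            for m, c in (("ATP", -self.gam), ("h2o", -self.gam)):
                stoich[m] = stoich.get(m, 0.0) + c
        for m, c in self.byproducts.items():
            stoich[m] = stoich.get(m, 0.0) + c
        return Reaction(self.id, stoich, lb=0.0, ub=ub, kind="biomass")


# ---------------------------------------------------------------------------
# genome-derived monomer fractions
# ---------------------------------------------------------------------------

def _read_fasta(path) -> list[str]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise BiomassError(f"empty FASTA file: {path}")
    return [str(rec.seq).upper() for rec in records]


def monomer_fractions_from_genome(genome_fasta, proteome_fasta) -> MonomerFractions:
    """Molar monomer fractions from genome and proteome FASTA files.

    Amino-acid fractions are residue frequencies over all protein sequences.
    dNTP fractions come from double-stranded base counts: complementarity
    forces dATP=dTTP=(A+T)/2N and dGTP=dCTP=(G+C)/2N.  NTP fractions use the
    coding-strand composition with T read as U.  Line wrapping and case have
    no effect.
    """
    genome = _read_fasta(genome_fasta)
    proteome = _read_fasta(proteome_fasta)

    aa_counts = {aa: 0 for aa in AMINO_ACID_MW}
    for seq in proteome:
        for ch in seq:
            if ch in aa_counts:
                aa_counts[ch] += 1
    total_aa = sum(aa_counts.values())
    if total_aa == 0:
        raise BiomassError("proteome contains no standard amino acids")
    protein = {aa: n / total_aa for aa, n in aa_counts.items() if n > 0}

    base_counts = {b: 0 for b in "ATGC"}
    for seq in genome:
        for ch in seq:
            if ch in base_counts:
                base_counts[ch] += 1
    total_b = sum(base_counts.values())
    if total_b == 0:
        raise BiomassError("genome contains no A/T/G/C bases")
    at = (base_counts["A"] + base_counts["T"]) / total_b
    gc = (base_counts["G"] + base_counts["C"]) / total_b
    dna = {
        name: frac
        for name, frac in (
            ("dATP", at / 2), ("dTTP", at / 2), ("dGTP", gc / 2), ("dCTP", gc / 2)
        )
        if frac > 0
    }
    rna = {
        name: base_counts[b] / total_b
        for name, b in (("ATP", "A"), ("UTP", "T"), ("GTP", "G"), ("CTP", "C"))
        if base_counts[b] > 0
    }
    fractions = MonomerFractions(protein=protein, dna=dna, rna=rna)
    fractions.validate(tol=1e-9)
    return fractions


# ---------------------------------------------------------------------------
# biomass reaction construction
# ---------------------------------------------------------------------------

def build_biomass_reaction(
    comp: BiomassComposition,
    mono: MonomerFractions,
    mw_table: dict[str, float] | None = None,
    reaction_id: str | None = None,
    gam: float = 0.0,
) -> BiomassReaction:
    """Convert class fractions + monomer fractions into one biomass reaction.

    ``mw_table`` maps monomer/precursor name to molecular weight in g/mol
    (defaults cover amino acids and (d)NTPs).  ``gam`` adds a
    growth-associated maintenance term of that many mmol ATP hydrolyzed per
    gDW.  Polymerization water is released stoichiometrically.
    """
    mw = dict(DEFAULT_MONOMER_MW)
    mw.update(mw_table or {})
    fractions = comp.rescaled_fractions()

    coefficients: dict[str, float] = {}
    residue_mw: dict[str, float] = {}
    water_released = 0.0

    for cls, f_class in fractions.items():
        if f_class == 0.0:
            continue
        if cls in POLYMER_CLASSES:
            monomers = mono.for_class(cls)
            if not monomers:
                raise BiomassError(f"no monomer fractions for class {cls!r}")
            denom = 0.0
            for m, x in monomers.items():
                if m not in mw:
                    raise BiomassError(f"missing molecular weight for {m!r}")
                denom += x * (mw[m] - MW_WATER)
            for m, x in monomers.items():
                coeff = 1000.0 * f_class * x / denom
                if coeff == 0.0:
                    continue
                coefficients[m] = coefficients.get(m, 0.0) + coeff
                residue_mw[m] = mw[m] - MW_WATER
                water_released += coeff
        else:
            shares = comp.precursor_masses.get(cls)
            if not shares:
                raise BiomassError(f"class {cls!r} needs explicit precursor masses")
            total_share = sum(shares.values())
            for met, share in shares.items():
                if met not in mw:
                    raise BiomassError(f"missing molecular weight for {met!r}")
                mass_mg = 1000.0 * f_class * share / total_share
                coeff = mass_mg / mw[met]
                coefficients[met] = coefficients.get(met, 0.0) + coeff
                residue_mw[met] = mw[met]

    byproducts = {}
    if water_released > 0.0:
        byproducts["h2o"] = water_released
    if gam > 0.0:
        # maintenance ATP hydrolysis moves phosphate, not dry mass
        byproducts["ADP"] = byproducts.get("ADP", 0.0) + gam
        byproducts["pi"] = byproducts.get("pi", 0.0) + gam

    rid = reaction_id or f"biomass_{comp.condition}"
    return BiomassReaction(
        id=rid,
        condition=comp.condition,
        precursor_coefficients=coefficients,
        byproducts=byproducts,
        residue_mw=residue_mw,
        gam=gam,
    )


def mass_closure_mg(reaction: BiomassReaction) -> float:
    """Residue-weighted precursor mass in mg/gDW (1000 for a closed reaction)."""
    return reaction.mass_mg()


# ---------------------------------------------------------------------------
# media
# ---------------------------------------------------------------------------

def attach_media(model: MetabolicModel, extracellular: str = "e") -> MetabolicModel:
    """Ensure the 11 media exchange reactions exist (8 nutrients + light,
    acetate, CO2).

    Existing exchanges for the same metabolite are reused; the call is
    idempotent.  Bounds are left closed (0) until a growth condition is
    applied.
    """
    out = model.copy()
    if extracellular not in out.compartments:
        out.compartments.append(extracellular)
    met_index = out._met_index()
    exchanged_mets = {
        next(iter(r.stoich)): r.id for r in out.reactions if r.kind == "exchange"
    }
    for key, (ex_id, met_id) in MEDIA_EXCHANGES.items():
        if met_id not in met_index:
            out.add_metabolite(Metabolite(met_id, name=key, compartment=extracellular))
            met_index = out._met_index()
        if met_id in exchanged_mets or out.has_reaction(ex_id):
            continue
        out.add_reaction(Reaction(ex_id, {met_id: -1.0}, lb=0.0, ub=DEFAULT_BOUND,
                                  kind="exchange"))
    return out
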