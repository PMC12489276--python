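"""Build a biomass reaction from class fractions and check mass closure.

Derives monomer fractions from tiny genome/proteome FASTA files, converts a
class composition (g/gDW) into stoichiometric coefficients (mmol/gDW), and
verifies the 1000 mg/gDW closure that makes growth rates comparable across
models.
"""

import tempfile
from pathlib import Path

from algaegem import build_biomass_reaction, mass_closure_mg, monomer_fractions_from_genome
from algaegem.biomass import BiomassComposition

with tempfile.TemporaryDirectory() as tmp:
    genome = Path(tmp) / "genome.fa"
    proteome = Path(tmp) / "proteome.fa"
    genome.write_text(">scaffold1\nATGGCCAAATTTGGGCCCATCGATTAG\n")
    proteome.write_text(">prot1\nMAKFGPID\n>prot2\nGGLLKKAA\n")
    mono = monomer_fractions_from_genome(genome, proteome)

print("amino-acid fractions :", {k: round(v, 3) for k, v in sorted(mono.protein.items())})
print("dNTP fractions       :", {k: round(v, 3) for k, v in sorted(mono.dna.items())})

comp = BiomassComposition(
    "auto_100",
    {"protein": 0.55, "dna": 0.03, "rna": 0.08, "carbohydrate": 0.34},
    precursor_masses={"carbohydrate": {"starch_unit": 1.0}},
)
rxn = build_biomass_reaction(comp, mono, mw_table={"starch_unit": 162.14})

print(f"reaction id          : {rxn.id}")
print(f"precursors           : {len(rxn.precursor_coefficients)}")
print(f"mass closure         : {mass_closure_mg(rxn):.6f} mg/gDW")

# Class fractions are rescaled to sum to exactly 1 g/gDW, so the
# residue-mass-weighted coefficient sum lands on 1000 mg by construction.
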