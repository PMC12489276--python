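# algaegem

**De novo refinement of genome-scale metabolic models (GEMs) for green
algae** — from an uncompartmentalized draft network to a functional,
compartmentalized, loop-free, enzyme-constrained model, plus the flux
analyses used to nominate gene targets for growth improvement.

GEM reconstruction pipelines can assemble a draft reaction network from
databases, but two refinement steps have traditionally required heavy manual
curation in eukaryotes: placing every reaction into the right organelle, and
removing internal flux loops that violate thermodynamics. This package
implements both as exact mixed-integer programs, together with the
surrounding machinery a modeler needs: consensus protein localization,
condition-specific biomass reactions, GECKO-style enzyme constraints,
gap-filling, and a comparative flux-analysis suite (FBA, pFBA, FVA,
essentiality, hit-and-run sampling, flux–growth correlation screening).

## The core methods

**Compartmentalization by minimal additions.** Localization predictors give
each protein a probability vector over ≤8 compartments; the consensus is the
renormalized mean across tools, and a reaction's vote for compartment *c* is
the mean consensus of its GPR genes. The reaction is *replicated* into every
compartment with vote > 25%. All possible 1:1 transports between
compartment pools of shared metabolites are then added as candidates, and a
MILP retains the smallest set of replicated copies and transports,

```
min Σᵢ yᵢ   s.t.   S v = 0,  −M·yᵢ ≤ vᵢ ≤ M·yᵢ,
                   v_demand ≥ ε for every designated precursor,
                   ≥1 copy per parent reaction,  y fixed for curated pathways,
```

so protein localization is respected while parsimony prunes redundancy.

**Thermodynamically infeasible cycle (TIC) removal.** TICs are sets of
internal reactions that can carry flux with every exchange closed. Detection
is a per-direction LP sweep with unit caps; removal is a lazy hitting-set
MILP: each discovered cycle support adds a covering cut, and an embedded
flux block (`S w = 0`, `w_biomass ≥ ε`, `wᵢ ≤ M(1−zᵢ)`) guarantees biomass
survives. The removal set is provably minimum-cardinality; removing one
direction of a reversible reaction just makes it irreversible.

**Biomass and enzyme constraints.** Class mass fractions (g gDW⁻¹) are
rescaled to sum to 1; polymer classes expand to monomers via genome-derived
molar fractions with coefficients `1000·f_K·x_m / Σ x_k(MW_k − MW_w)`
(mmol gDW⁻¹), so coefficients always close at 1000 mg gDW⁻¹. Enzyme
constraints follow GECKO: `v ≤ 3600·kcat·e`, isozymes become parallel
copies, complex subunits each draw enzyme, and `Σ MW·e ≤ P` caps the total
protein pool.

## Worked example

`python examples/01_compartmentalize_toy.py` builds a two-reaction network
(R1: A→B+D, R2: B→C+E) replicated over three compartments with 15 candidate
transports and compartment-specific precursor demands, then prunes it:

```
replicated instances : 6
transport candidates : 15
solver status        : optimal
retained additions   : 6
removed instances    : ['R1__C3', 'R2__C2']
kept transports      : ['T_A_C1_C2', 'T_B_C1_C3']
```

Of 21 removable additions the MILP keeps 6: four reaction copies (one R2
copy is dropped from compartment C2 and one R1 copy from C3) and the two
transports that carry A into C2 and B into C3 — the smallest network that
still produces every demanded precursor in its compartment.

`python examples/05_enzyme_constraints.py` shows the enzyme pool capping a
single catalyzed flux:

```
unconstrained optimum : 1000.0 mmol/gDW/h
enzyme-limited optimum: 43.200 mmol/gDW/h
closed form 3600*k*P/MW: 43.200 mmol/gDW/h
pool -> infinity      : 1000.0 mmol/gDW/h
```

With kcat = 2 s⁻¹, MW = 50 kDa and a 0.3 g gDW⁻¹ protein budget the optimum
equals the closed form 3600·kcat·P/MW exactly; an unlimited pool recovers
the unconstrained LP optimum.

The other examples cover loop removal, localization voting, biomass
construction, and target screening; each prints what it computes and what
the numbers mean. A thin CLI (`algaegem localize|compartmentalize|detic|
biomass|gapfill|ecmodel|fba|pfba|fva|active|essential|targets|sample|
compare|synth`) wraps the same entry points for shell pipelines.

## Model files

SBML Level 3 + FBC is the interchange format (via cobrapy). A plain JSON
dialect serves as a text-fixture format: top-level keys `id`,
`compartments`, `objective`, `metabolites` (id, name, compartment, formula,
mw) and `reactions` (id, stoich map, lb, ub, gpr string, subsystem, kind ∈
{enzymatic, transport, exchange, biomass, demand}). `algaegem.read_model` /
`write_model` infer the dialect from the extension.

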