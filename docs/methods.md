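# Methods

This note documents the models and procedures implemented in `algaegem`,
their assumptions, the parameters that matter, and the numerical choices —
in the spirit of the model documentation shipped by constraint-based
modeling packages.

## Scope and model container

The package operates on stoichiometric metabolic networks at steady state:
metabolites with compartments, reactions as signed stoichiometries with flux
bounds (mmol gDW⁻¹ h⁻¹), boolean gene–protein–reaction (GPR) rules, and one
linear objective. Exchange reactions are written `met ↔ ∅` with uptake as
negative flux, so a printed uptake capacity of 10 becomes a lower bound of
−10. Up to eight compartments are supported (cytoplasm, chloroplast,
lysosome/vacuole, mitochondrion, thylakoid/plastid, peroxisome, ER,
extracellular). SBML L3+FBC is read and written through cobrapy; a JSON
dialect serves as a plain-text fixture format.

## Growth conditions

Four named conditions drive all comparative analyses:

| condition  | light bound | acetate uptake | CO₂      |
|------------|-------------|----------------|----------|
| auto_100   | 100         | 0              | open     |
| auto_3k    | 3000        | 0              | open     |
| mixo       | 100         | 2              | open     |
| hetero     | 0           | 2              | closed   |

plus the eight nutrient uptakes (H₂O, H⁺, Pi, NH₄, SO₄, Fe²⁺, Mg²⁺, O₂) at
10 mmol gDW⁻¹ h⁻¹ each. The photon intensity number is used directly as the
uptake-bound magnitude; no unit conversion from μmol photons m⁻² s⁻¹ to
flux is applied, because the condition definitions treat the intensity as a
bound. CO₂ has no published bound; it is opened (default bound magnitude
1000) for conditions with inorganic carbon and closed heterotrophically,
overridable per condition. Applying a condition only touches exchanges
present in the model (`strict=True` demands all eleven), is idempotent, and
sets the objective to the condition's biomass reaction
(`biomass_auto_100` … `biomass_hetero`; all four coexist in one model).

## Consensus localization and voting

Each predictor tool yields a per-protein probability vector over
compartments. Tool vectors are renormalized individually (tools that do not
sum to 1 are common), then averaged with equal weights — no reliability
weighting, since none is published — and renormalized again. Proteins whose
every tool reports all-zero mass are flagged *unlocalized* and excluded
from voting. A reaction's vote for compartment c is the mean consensus of
its GPR genes, `vote(r,c) = |genes(r)|⁻¹ Σ_g consensus(g,c)`, so votes sum
to 1 whenever all genes are localized. The reaction is retained in every
compartment with vote strictly above the threshold (default 0.25, "above"
read as strict); if none qualifies, the argmax compartment is used with a
lexicographic tie-break; reactions without GPR default to the cytoplasm
(transporters typically lack gene support). Curated pathway assignments
(`fixed`) override votes entirely.

At 20% per-tool noise with five tools the expected vote for the true
compartment is 0.8, far above the threshold, which is why recovery of
planted single-gene assignments is complete in the validation suite; real
predictor errors are correlated across tools, which this generator does not
emulate (see *Synthetic data* below).

## Compartmentalization MILP

Replication instantiates each reaction once per assigned compartment over
compartment-specific metabolite pools (`met__comp`); exchanges follow their
assignment or attach extracellularly. For every metabolite present in k ≥ 2
compartments, C(k,2) reversible 1:1 carrier candidates are added (no
mechanism, charge or proton balancing — a stated non-goal). The pruning
MILP uses one binary y per replicated instance and per transport (1 =
retained), big-M flux coupling `−M·y ≤ v ≤ M·y`, steady state, and a demand
flux ≥ ε for every designated precursor *simultaneously* (a per-precursor
mode with separate flux blocks is available; the joint mode is the default
because functionality means producing all precursors at once). Constraints
force ≥ 1 instance per parent reaction — the optimization chooses *where*
content lives, not *whether* (a switch disables this), and forces y = 1 for
curated `fixed_keep` sets. The objective minimizes retained additions with
equal weights for instances and transports, perturbed by 1e-6·rank/n so
alternate optima resolve to the lexicographically smallest retained set
deterministically across runs.

Defaults: ε = 1e-3 mmol gDW⁻¹ h⁻¹ (no published floor; small enough not to
distort optima, large enough for LP tolerances), M = 1000 (exceeds any flux
reachable under uptake bounds of 10). Feasibility with all candidates
retained is checked by LP first; on failure each precursor is probed
individually and the unproducible ones reported. After the solve, the
pruned model is re-certified feasible by an independent LP.

On 50 random instances with ≤ 12 removable elements the MILP optimum equals
exhaustive enumeration (ascending-cardinality subset search with early
stop); the bundled two-reaction demonstration network has a provably unique
optimal instance pattern, verified by enumerating all MILP optima with
no-good cuts during development.

## Loop (TIC) elimination

A thermodynamically infeasible cycle is internal flux feasible with all
exchanges closed. Detection: reversible reactions are split internally into
directions, exchanges and demands are fixed to zero, internal directions are
capped at 1, and each direction's maximum flux is solved; any direction
above tolerance (1e-6) — and the whole support of its circulation — is
cycle-involved. This per-direction sweep is solver-independent and
equivalent in detection power to a single aggregate LP.

Removal is a lazy hitting-set MILP over the cycle-involved directions: an
inner LP exhibits a circulation among retained directions; its support adds
a covering cut `Σ_{d∈C} z_d ≥ 1`; the master minimizes `Σ z_d` subject to
all cuts plus an embedded flux block (`S w = 0`, `w_biomass ≥ ε`,
`w_d ≤ ub·(1−z_d)`) so biomass survives every candidate removal. The loop
terminates because cycle supports are finite; the result is
minimum-cardinality over all constraints (verified against brute force on
all test instances). Removal is direction-level by default — zeroing one
direction of a reversible reaction converts it to irreversible, consistent
with curated models showing far fewer reversible reactions after this stage
— with a `whole_reaction` switch. If every hitting set kills biomass the
status `no_valid_removal` is returned with the accumulated cuts.

## Biomass construction

Dry mass is partitioned into protein, DNA, RNA, carbohydrate, chlorophyll
and lipid fractions (g gDW⁻¹), rescaled to sum to exactly 1. Monomer molar
fractions come from sequence: amino-acid frequencies over the proteome;
dNTPs from double-stranded base counts (complementarity forces
dATP = dTTP); NTPs from coding-strand composition. Polymer coefficients are
`1000·f_K·x_m / Σ_k x_k(MW_k − MW_w)` mmol gDW⁻¹ with 18.02 g mol⁻¹ of
water subtracted per residue — applied uniformly to protein, DNA and RNA as
the residue-mass convention, which makes the 1000 mg gDW⁻¹ closure exact by
construction (chemically, NTP polymerization releases PPi rather than
water; the closure identity is defined on these residue masses and is
self-consistent). Non-polymer classes take explicit precursor mass shares
at full molecular weight (lipid coefficients are an input table, not
re-derived). Polymerization water is released stoichiometrically. A
growth-associated maintenance term (mmol ATP gDW⁻¹, default 0 — no
published value) hydrolyzes ATP without moving dry mass. `attach_media`
idempotently ensures the 11 media exchanges, reusing any existing exchange
for the same metabolite.

## Gap-filling and enzyme constraints

Gap-filling selects a minimum-cardinality subset of a universal candidate
pool restoring biomass flux ≥ ε (binary per candidate, big-M coupling,
optional per-candidate penalties for database preference, lexicographic
tie-break). Infeasibility even with the full pool raises a structured error
listing unproducible biomass precursors (per-precursor demand probes). The
added set is re-verified by LP.

Enzyme constraints follow the GECKO formulation on an irreversible model:
kcat (s⁻¹) × 3600 gives h⁻¹; each isozyme module (OR branch of the GPR,
expanded to disjunctive normal form) becomes a parallel reaction copy; each
complex subunit with a kcat is consumed at flux/kcat (subunits without a
kcat are unconstrained — the documented convention); enzyme draw reactions
consume MW (kDa = g mmol⁻¹) grams of a single protein pool whose exchange
is bounded by P (g protein gDW⁻¹). Saturation and mass-fraction factors are
collapsed into P, which is the one measured quantity. The single-reaction
closed form `v_max = 3600·kcat·P/MW` and the pool→∞ limit are exact and
tested to 1e-9 relative.

## Flux analyses

FBA, pFBA (minimize Σ|v| on an internally split model at growth fixed to a
fraction of the optimum, default 1.0) and FVA (per-reaction min/max at
growth ≥ fraction × optimum) run on the native LP layer; cobrapy serves as
an independent FBA oracle in the tests, never as the implementation.
Active-reaction calling splits reversibles, computes FVA maxima per
direction, excludes split pairs whose forward and backward maxima agree
within 1e-6 relative (cycle signatures, not genuine activity; the tolerance
is this package's choice), and reports parents with any remaining maximum
above tolerance. Condition comparison uses exclusive-intersection classes
(UpSet semantics: a pairwise class excludes the third set). Essentiality
knocks out single genes (disabling reactions whose GPR evaluates false) or
single reactions; essential means growth < 1% of wild type (threshold
exposed). The target screen fixes growth at k/n of the optimum for
k = 1..n (default n = 100), computes pFBA fluxes, and selects reactions
with Pearson r > 0.8 and adjusted p < 0.01 (Benjamini–Hochberg by default,
Bonferroni switch; Pearson p from the t transform with n−2 df), mapping
them to the unique gene set via GPRs; zero-variance flux series are skipped
and reported. Anticorrelated series (e.g. uptake exchanges, negative by
sign convention) do not pass an `r > r_min` screen.

Flux sampling is artificial-centering hit-and-run in null-space
coordinates: every iterate satisfies S v = 0 to machine precision;
directions are (random stored point − running center); chord endpoints come
from the bounds; warm-up is 100 × (null-space dimension) steps from the
average of random-objective LP vertices; every `thinning`-th state is kept.
The chain is a pure function of the seed (bit-identical matrices). The
default run of 5000 samples at thinning 1000 walks 5×10⁶ steps and takes
on the order of two minutes on one core for small models; the test suite
uses shorter chains except for the headline uniform-segment check.
Homolog comparison applies Welch's t-test per reaction pair with Bonferroni
correction over the pairs at α = 0.05, reporting direction; the
high-vs-low-light analysis is the same operation with identity pairing of
one model sampled under two bound settings. pFBA alternate optima exist in
principle; tests assert objective-level quantities except on toys with
unique optima.

## Synthetic data

The fixture generators are first-class, tested code. They emulate: the
two-reaction/three-compartment compartmentalization network (5 shared
metabolites, 15 transport candidates, per-compartment precursor demands
chosen so the optimal pruning pattern is unique at the instance level);
noisy localization profiles (truth gets 1−η per tool, remainder uniform,
optional seeded jitter — with jitter 0 the profiles are deterministic and
the seed is inert); seeded chain models with planted internal cycles
(records name the cycle members), removable "gap" reactions paired with a
universal pool, and known optimal growth (uptake × yield); random small
compartmentalization cases sized for exhaustive enumeration; and a
mitochondrial reaction block with multi-gene GPRs for the
pathway-assignment validation. What passing these tests shows: the
optimization machinery is exact and the statistical procedures behave as
specified on networks whose ground truth is known. What they do not show:
robustness to correlated predictor errors, missing annotations, thermodynamically
inconsistent stoichiometry, or genome-scale degeneracy — those require the
published models, which the benchmark script consumes from local files.

## Numerical choices

GLPK (via optlang/swiglpk) solves all LPs and MILPs. Two GLPK behaviors
required central handling: the default integrality tolerance (1e-5)
accepts LP relaxations of big-M models with ε/M ≈ 1e-6 as integral, so MIP
solves run at tol_int = 1e-9; and the high-level retry path can re-run
simplex from a stale basis after an infeasible result and report a spurious
optimum, so the solver layer drives `glp_simplex`/`glp_intopt` directly
from a fresh standard basis and reads statuses and column values from GLPK
itself. LP optima below 1e-9 are treated as zero; flux-activity calls use
1e-6; steady-state audits accept 1e-6 residuals. Degenerate inputs:
empty GPRs evaluate true under any knockout; zero-dimensional sampling
polytopes raise; all-zero localization vectors are excluded rather than
renormalized.

## Problem sizes

The default verification suite runs 50 random compartmentalization
instances (≤ 12 binary decisions each, checked against exhaustive
enumeration), 50 planted-cycle instances (each well under a second), a
50-protein recovery panel, and one 5000-sample chain at thinning 1000.
These sizes were chosen so every exactness claim is backed by an
independent enumeration or closed form while the whole suite completes in a
few minutes on a single core.

## Known limitations

Transport candidates are unbalanced 1:1 carriers; localization tools are
equally weighted; the consensus-merge of per-condition loop-removal
solutions (union of retained directions with per-condition bound masks) is
an assumption where no merge rule is published; GLPK limits MILP scale
compared to commercial solvers, though genome-scale pruning instances
remain tractable because binaries attach only to replicated copies and
candidate transports; and the acceptance surface is synthetic — benchmark
reproduction against the published genome-scale models requires their files
locally (`scripts/benchmark_published.py`).
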