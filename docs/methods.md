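# Methods

## Model structure

The tissue model is a single stoichiometric network assembled from a core
cell model of plant central metabolism. Four cell types are represented —
mesophyll (MC), companion cell (CC), leaf sieve element (SE), petiolar
sieve element (pSE) — each as two steady-state replicas, one per diel phase
(light `l`, dark `d`). All fluxes are on a leaf-area basis
(µmol m⁻² s⁻¹); "unbounded" is encoded as ±1000 per COBRA convention.

Cell customizations follow phloem anatomy: sieve elements have no vacuole
and no mRNA-turnover reaction; only MC and CC exchange sugars and amino
acids with the apoplast; the plasma-membrane H⁺-PPiase (and H⁺-ATPase) sit
on the companion cell; pSE additionally carries the sap-export reaction and
a sucrose leak/retrieval pair against a petiole apoplast, with its own
plasma-membrane H⁺-ATPase returning the retrieval protons.

Phase replicas of one cell are joined by reversible accumulation reactions
for starch (plastid) and, where a vacuole exists, sucrose, nitrate, malate
and amino acids. Sieve elements therefore accumulate only plastidial
starch. The dark replica has no photon uptake.

Inter-cell connectivity:

- **Apoplast** (per phase, shared by MC and CC): passive, outward-only
  efflux of sucrose/hexoses from MC; proton-coupled symport (default 1 H⁺
  per molecule) into CC; amino acids strictly MC → apoplast → CC. CC pumps
  protons back with the H⁺-ATPase and H⁺-PPiase. Gases, nitrate and photons
  enter each cell through its own boundary exchanges. Companion-cell uptake
  is symport-only because it is concentrative; a reversible passive carrier
  would let the cell import against zero proton cost and void the very
  energetics under study.
- **Symplast** (CC↔SE, SE↔pSE, per phase): zero-cost reversible transfers
  of all cytosolic species except an exclusion list (protons, polymers:
  starch/cellulose/callose/heteroglycan, lipids, superoxide, iron);
  nucleotides and nicotinamide cofactors move downstream only, preventing
  unrealistic energy export from sieve elements back to companion cells.
- **Phloem export** (pSE, per phase): a fixed-stoichiometry sink consuming
  sap species in molar ratio (default 9 sucrose : 0.5 glutamate :
  0.25 histidine : 0.25 lysine — a synthetic 9:1 sugar:amino-acid profile;
  a measured composition can be supplied in the run config). An equality
  row couples the phases: `v_dark = dark_fraction · v_light`,
  `dark_fraction = 1/3` by default.

## Quantitative constraints

Applied in a fixed order by `apply_standard_constraints`:

1. **Cell-ratio scaling** (MC:CC:SE:pSE = 20:1:5:6). Maintenance, protein-
   and RNA-turnover and carbon-uptake bounds in phloem cells are multiplied
   by `r_cell / r_MC`; every other phloem-cell bound is capped at the
   largest finite mesophyll bound (the photon uptake, 200 by default). A
   mesophyll reaction bounded at 20 is thus bounded at 1, 5 and 6 in CC, SE
   and pSE.
2. **Photon capture.** CC light-phase photon uptake ≤ 20% of the mesophyll
   bound per cell, i.e. 1% on a leaf basis at 20:1; SE/pSE capture none.
3. **Carbon assimilation.** The mesophyll carboxylation upper bounds sum to
   the target assimilation rate (default 5 µmol CO₂ m⁻² s⁻¹, a typical
   mature-rosette value). The synthetic core's lumped Calvin-cycle reaction
   fixes exactly one CO₂ per unit flux so the bound is also the carbon rate.
4. **Maintenance and turnover lower bounds.** ATP maintenance is linear in
   the light intensity (`slope·I + intercept`, defaults 0.05 and 1.0,
   chosen so mesophyll light maintenance ≈ 5% of the photon bound — a
   placeholder in the published-coefficient's absence); the dark phase pays
   the intercept. Protein turnover is the measured leaf-area flux

       (15 mg protein/gFW ÷ 118.9 g/mol) × 10⁻⁶ s⁻¹ × 50 gFW/gDW × 15 gDW/m²
       = 9.45×10⁻² µmol AA m⁻² s⁻¹,

   scaled per cell by `r_cell/r_MC`. RNA turnover: the same chain with
   600 µg RNA/gFW, a 107-min half-life (decay ≈ 10⁻⁴ s⁻¹) and 500 Da per
   ribonucleotide yields 0.09 µmol m⁻² s⁻¹, but the source estimate prints
   0.9; both values are exposed (`compute_rna_turnover_flux` vs
   `RNA_TURNOVER_REPORTED_FLUX`) and the printed 0.9 is the shipped default
   constraint. Neither is silently corrected.

## Optimization

All solves are LPs over split variables `v = f − r`, `f, r ≥ 0`, assembled
sparse and handed to HiGHS (`scipy.optimize.linprog`). Lexicographic stages
fix prior optima as rows: the parsimonious solve fixes the maximized phloem
rate as an equality before minimizing `Σ(f+r)`; the weighted solve floors
the phloem rate at `(1 − gap)` times the parsimonious reference (exactly),
minimizes the transcript distance H, caps H at `H* + 10⁻⁶·max(1, H*)` and
minimizes the flux sum G. Feasibility is the solver's default (~10⁻⁹);
FVA flags a flux as non-unique when its interval exceeds 10⁻⁶. Variable
ordering follows model insertion order, so reruns are bit-stable.

**Sign handling in H.** The distance compares `r_cell · d_i` with the
reaction's *directional activity* `f + r`, summed over the light and dark
phases (transcript data carry no phase information) and, for the CC data
column, over the CC/SE/pSE complex (companion cells make the transcripts
for enucleate sieve elements). For loop-free fluxes activity equals `|v|`;
where a transcript target exceeds the reachable net flux the optimizer may
hold activity above `|v|`, which is the linear-programming relaxation of an
otherwise non-convex (mixed-integer) distance. `FluxSolution.activity`
exposes these totals so the distance is auditable; the final flux-sum stage
penalizes any surplus activity at the same rate as real flux.

**Transcript mapping.** Gene-association trees aggregate isoforms by sum
(OR) and complex subunits by minimum (AND), both configurable. A reaction
enters the data set D only if a value is computable in every profiled cell
type. Abundances are max-normalized to a configurable flux scale (default
1.0); the published data's normalization is unstated, so max-normalization
is the shipped default.

## Synthetic data

`make_toy_core_model` emulates the structural features the pipeline
assumes, not any real reaction inventory: split photosystems (PSII, b6f,
PSI, FNR) plus a ferredoxin–plastoquinone cyclic route so PSII removal
still allows photophosphorylation but eliminates NADPH; a lumped Calvin
cycle; triose-phosphate shuttles that export plastid ATP/NADPH as cytosolic
ATP/NADH; glycolysis with both ATP- and PPi-dependent
phosphofructokinases; a reversible non-oxidative pentose phosphate lump
(so ribose-5-phosphate for RNA turnover does not force NADPH production);
invertase and sucrose-synthase degradation routes; mitochondrial
respiration with phosphate and adenine carriers; vacuolar V-ATPase/V-PPiase
with proton-coupled storage; protein/RNA turnover pseudo-reactions
consuming ATP and amino acids/ribose-phosphate and releasing AMP and PPi;
per-compartment adenylate kinases (AMP can be rephosphorylated in the
cytosol, the mitochondrion via carriers, or the plastid in the light — so
the cytosolic+mitochondrial double knockout is lethal in the dark while
single knockouts reroute); and three amino-acid pathways with contrasting
by-products (histidine releases PPi and NADH, glutamate is cheap and also
catabolizable, lysine consumes ATP and NADPH). Every reaction is
phosphorus-balanced; P is a conserved moiety with no boundary source.
Carbon formulas are consistent so atom-count accounting is exact.

Generated models are deterministic for a given spec; the seed is recorded
and drives transcript generation. Synthetic transcripts are lognormal
draws, or, given a ground-truth flux vector, the group-summed diel activity
divided by the cell ratio — so a noiseless profile is exactly recoverable
(distance 0), with multiplicative lognormal noise and dropout as options.

What the fixture does **not** emulate: the real core model's ~hundreds of
reactions and full amino-acid complement, measured sap composition, real
transcriptome normalization and sparsity, or thermodynamics. Passing tests
demonstrate that the machinery (assembly, constraints, hierarchical solve,
analyses) is correct, not that any particular published flux value is
reproduced; the published headline fluxes additionally depend on the
published core network and transcriptome and on alternate-optima
selection.

## Numerical and design choices

- LP backend: HiGHS through scipy — deterministic, no licensing, sparse.
- Knockouts zero bounds rather than deleting reactions, keeping indices
  stable; scenario edits are bound edits, saved and restored (audited by a
  hash test).
- The H⁺-PPiase cap scenario limits the pump to 10% of its flux in a
  baseline solve of the same pipeline, matching "10% of its previous flux"
  semantics rather than 10% of an arbitrary bound.
- "Per cell basis" report columns divide leaf-area fluxes by the cell
  ratio. Energy budgets count the named currency species only (no
  ATP-equivalents); reactions that merely move a currency between
  compartments are listed as transfers, excluded from shares.
- Report tables drop fluxes below 0.005 µmol m⁻² s⁻¹ by default.
- FVA fixes the phloem rate and H (not G) by default; fixing G is possible
  through the ledger argument.
- Petiole leak and retrieval default to 0.005 µmol m⁻² s⁻¹ each (a
  placeholder magnitude, ~5% of the fixture's light-phase sucrose export).

## Problem sizes

The default fixture tissue has ~710 reactions (~1,400 LP columns plus
distance slacks); a full parsimonious or weighted solve takes well under a
second, the acceptance script a few seconds, and the complete test suite
(188 tests, including exhaustive vertex-enumeration oracles on ≤8-reaction
toys) about ten seconds on one CPU.

## Known limitations

- The LP relaxation of the transcript distance can leave surplus
  directional activity on under-target reactions (see above); net fluxes
  and mass balances are unaffected.
- Maintenance coefficients, petiole leak magnitudes and the synthetic sap
  composition are placeholders where no measured value is printed; all are
  config-exposed.
- No thermodynamic or kinetic constraints; no xylem, bundle sheath or
  sub-diel time resolution.
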