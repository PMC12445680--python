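# Methods

`pbem` computes protonation and one-electron redox equilibria of membrane
proteins with continuum electrostatics, maps the transmembrane electric
field, and estimates hole-hopping kinetics along residue chains. This note
documents the models, the numerical choices behind them, and what the
synthetic fixtures do and do not establish.

## Continuum model and the finite-difference LPB solver

The electrostatic free energies come from the linearized
Poisson–Boltzmann (LPB) equation

∇·(ε(r)∇φ) − ε_w κ² φ = −4π ρ,

discretized with the standard 7-point stencil on regular cubic grids.
Conventions and defaults:

- **Dielectric**: ε = 4 inside the van der Waals union of the atoms, 80
  outside. No solvent-excluded-surface construction is attempted; the
  vdW union is the boundary. Face dielectrics are harmonic means of
  ε_in/ε_out weighted by the fraction of each grid edge inside the
  protein, estimated from the edge's two end nodes and its midpoint.
  This edge-fraction homogenization is what brings the Born energy within
  ~0.6% of the closed form at 0.3 Å spacing; a plain node-pair harmonic
  mean is noticeably worse.
- **Screening**: ionic strength 100 mM at 300 K gives a Debye length of
  ~9.7 Å (computed from first principles, not hard-coded); κ² is zeroed
  inside the vdW union plus a 2.0 Å Stern shell. Both the ionic strength
  and the Stern width are parameters of `PBParams`.
- **Charges** are assigned to nodes by trilinear (cloud-in-cell)
  spreading. Grid self-energies are never reported raw: every reported
  quantity is a difference in which the self term cancels (heterogeneous
  minus homogeneous solve on the *same* grid with the *same* spreading,
  or protein minus model compound on identical grids).
- **Boundary conditions**: the coarsest grid uses summed per-atom
  Debye–Hückel monopoles; each finer focusing level takes Dirichlet
  values interpolated from its parent. Default focusing cascade
  2.5 → 1.0 → 0.3 Å, with the fine cubic grid centered on the site of
  interest (region of interest + 3 Å, intermediate level + 8 Å).
- **Solver**: Jacobi-preconditioned conjugate gradients on the symmetric
  positive-definite system, relative residual 1e−6, iteration cap 10⁴;
  non-convergence raises an error carrying the residual.
- **Units**: lengths Å, charges e; internally potentials are kept in a
  Gaussian-style unit where E[kcal/mol] = 332.064·q·φ. Fixed
  conversions: 1 kcal/mol = 43.364 mV per electron (0.0230605 kcal/mol
  per meV), RT ln10 at 300 K = 1.3727 kcal/mol = 59.5 meV, kT = 0.02585 eV.

Accuracy anchors (all recomputed in the test suite): Born ion (q = 1 e,
a = 2 Å, ε 1→80) −82.46 vs −81.98 kcal/mol analytic (0.6%); Kirkwood
off-center charge (1 Å off-center in a 5 Å ε = 4 sphere) within 0.1% of
the truncated series; half-voxel translation of the whole system changes
the Born energy by < 1%; refining the finest level 0.3 → 0.2 Å moves it
by ≪ 1 kcal/mol.

## Thermodynamic cycle and microstate model

Each titratable site carries explicit charge-state vectors over its member
atoms; state 0 is the reference (deprotonated for acids/bases, reduced for
redox couples, the cation for His). For every non-reference state the
state-difference charges are solved in two environments — the full protein
and the model compound (member atoms alone in water) — and the shift

ΔΔG = Δ(reaction field) + Δ(background interaction)

is added to the aqueous reference value:

- pKa_intr = pKa_ref ∓ ΔΔG / RT ln10 (protonation/deprotonation),
- Em_intr = Em_ref + ΔΔG × 43.364 mV/(kcal/mol), with Em_ref(Trp/Trp•+)
  = 1070 mV.

Background = all non-site partial charges plus every *other* site frozen
in its reference state; a site's own member atoms never enter its
background (they are fully described by the reaction-field cycle).
Couplings W_ij between state-difference charge sets are computed from the
already-solved potentials and symmetrized; the raw asymmetry (a grid
discretization diagnostic) is retained in the details.

A microstate s has energy G(s) = Σᵢ gᵢ(sᵢ; pH, E) + ½ Σᵢ≠ⱼ W_ij(sᵢ,sⱼ)
with g = RT ln10 (pH − pKa_intr) per bound proton and g = F(Em_intr − E)
per removed electron, E being the applied bias potential. His is one
three-state site (cation, Nδ-H, Nε-H; the doubly deprotonated state is
excluded) with the two tautomer reference pKa values 7.0 and 6.6.

Isolated-site closure is exact by construction: for a site alone in water
the two environments coincide, so the computed Em/pKa equals the
reference value to solver precision regardless of grid placement.

## Equilibrium sampling

- **Exact enumeration** (the oracle): full Boltzmann sum over all
  microstates, feasible to 2²⁰ states; used whenever the free-site count
  allows, including inside the bias-potential bisection.
- **Metropolis Monte Carlo**: single-site moves each sweep plus paired
  moves for site pairs with max|W| > 2.5 kcal/mol; defaults 10³ burn-in
  and 10⁵ production sweeps; occupancy standard errors from 20 batch
  means; fully reproducible per seed. Against exact enumeration the
  maximum occupancy deviation on 12–15-site clusters is ≲ 0.002 at 10⁵
  sweeps (the suite enforces ≤ 0.01).
- **pKa**: Henderson–Hasselbalch read-out — the pH where the protonated
  fraction crosses ½, interpolated on the logit scale (exactly linear for
  an isolated site); the Hill coefficient is the logit slope at the
  midpoint.
- **Em**: a bias potential is bisected until the oxidized fraction is
  within 0.005 of ½ *and* the bracket is below 0.01 mV (the exact backend
  makes the tighter bracket essentially free and keeps slope fits clean);
  all other sites re-equilibrate at every bias.

## Em decomposition and profiles

For each redox site, Em − Em_ref is split exactly into

- **solvation shift**: the reaction-field (protein-minus-model) term —
  the "solvation loss" of burying the nascent cation, always ≥ 0 for
  deeper burial;
- **charge shift**: interaction of the ox-minus-red charges with the
  background charges plus the equilibrium-average charges of the other
  titratable sites (evaluated at the site's own midpoint bias);
- **residual**: whatever is left; it reports the nonlinearity of coupled
  titration and is < 0.01 mV on weakly coupled fixtures.

The per-residue table redistributes the charge shift over residues
(per-atom background terms grouped by residue; equilibrium-average W for
titratable neighbours) and sums back to it identically. Site z
coordinates are |Δq|-weighted centroids. Conformer-ensemble spreads are
reported as mean ± max signed deviation over the conformer list.

## Field maps

The transmembrane potential map solves the plain Poisson equation
(κ = 0) in a fixed 120 Å cube of 76³ ≈ 4.39×10⁵ nodes, with every atomic
charge smeared into a σ = 1 Å Gaussian renormalized to its exact charge,
ε = 4 inside the protein and an optional membrane slab between the
user-declared interface planes, and Dirichlet 0 V on the z = ±60 Å
planes. The lateral faces are also grounded (a symmetric closure; the
paper-style specification fixes only the z planes). This makes the
field *direction* robust but depresses absolute values near the lateral
walls — the capacitor test therefore checks against the grounded-box
closed form E = (4πσ/ε)(L−a)/L, which wide plates reproduce within 3%.
E = −∇φ by central differences; exports are OpenDX scalar fields and CSV
slices.

## Hole hopping

Rates come from the Moser–Dutton ruler log₁₀k = 15 − 0.6R −
3.1(ΔG°+λ)²/λ (coefficients configurable; the packing-factor variant is
not implemented). For a donor→acceptor hole hop ΔG° = Em(acceptor) −
Em(donor) in eV: holes run downhill toward lower Em. Backward rates
enforce exact detailed balance k_b = k_f·exp(ΔG°/kT) so chain occupancies
relax to Boltzmann; note the empirical quadratic coefficient 3.1 does not
itself encode a 300 K Boltzmann factor, so applying the ruler with
sign-flipped ΔG° would violate detailed balance by 10^(4.4·ΔG°) — the
explicit Boltzmann construction is the consistent choice for kinetics.
The chain transfer time is the mean first-passage time to the absorbing
terminal sink, from the closed-form birth–death nested sum; the suite
checks it to 0.1% against an independent matrix-exponential
master-equation integral, and a +0.2 eV uphill intermediate costs the
expected ~10^(0.2/0.0596) Boltzmann factor.

## Synthetic fixtures: what they emulate, and what they do not

- **Born/Kirkwood ions** give analytic anchors for the solver.
- **Layered membrane mimic**: a 40 Å slab of cubic-packed 2 Å
  pseudo-atoms with ionized groups in 5 Å slabs (negative toward −z,
  positive toward +z by default) and nine-atom pseudo-indole redox probes
  on the membrane normal. It reproduces the qualitative signature of
  type-II reaction centers — Em of buried probes rises monotonically
  toward the positive (cytoplasmic) layer, and the interior field points
  from the positive to the negative layer.
- **Coupled redox–proton pair**: a probe and a sulfonate-like strong acid
  (reference pKa −1) buried 4 Å apart in an ε = 4 blob. Burial raises the
  acid's intrinsic pKa to ~11 and the ~10 kcal/mol coupling pulls it to
  ~4 upon oxidation, so oxidation releases exactly one proton across
  pH 6–9: Em(pH) is Nernstian, −59.4 mV/pH fitted vs −59.5 theoretical at
  300 K. The strong-acid reference is what makes strict coupling
  attainable: with a carboxylate reference (4.0) burial overshoots the pKa
  beyond the reach of any realistic coupling.
- **Site clusters**: single-atom pseudo-acids in water with the nearest
  pair pinned at the distance that yields the target coupling (the
  distance→W law is a fixed table calibrated once against the PB solver,
  since cavity overlap boosts couplings up to 6× below 4 Å separation).

The probes are synthetic stand-ins: their oxidized-state charge
distribution sums to +1 over the ring but is not a fitted radical-cation
charge set, and the bundled amino-acid library carries charges only on
backbone amides and charged side-chain groups. Passing fixtures therefore
establish the correctness of the machinery (cycle closure, coupling,
decomposition, sampling, kinetics) under controlled conditions — not the
absolute Em values of real reaction centers, which additionally depend on
fitted charge sets, hydrogen placement and structure preparation.

## Problem sizes and runtimes

Defaults are chosen so a full fixture-suite pipeline runs on one CPU in a
few minutes: focused fine grids are 41–51³ nodes, the field box 76³, MC
production 10⁵ sweeps, enumeration capped at 2²⁰ states. The layered
profile (3 probes, ~3600 atoms) completes in ~5 s; the field map in ~4 s;
the coupled-fixture Em(pH) scan in ~3 s.

## Known limitations

- vdW-union dielectric boundary (no SES probe): systematically smaller
  low-dielectric volume than MEAD-style molecular surfaces; documented
  divergence source for absolute shifts.
- The bundled charge library is minimal and synthetic; real applications
  should supply PQR files with fitted charges.
- No conformational sampling inside titration; conformers enter only
  through the ensemble-Em average.
- Nonlinear PB, explicit membrane slabs in Em calculations, and hydrogen
  placement are out of scope.
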