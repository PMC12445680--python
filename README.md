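# pbem

Continuum-electrostatics calculations of protonation states (pKa) and
one-electron redox midpoint potentials (Em) in membrane proteins, with
transmembrane electric-field maps and hole-hopping kinetics along residue
chains. The package targets questions like those raised by tryptophan
redox chemistry in type-II photosynthetic reaction centers: how far does
the protein environment push Em(Trp/Trp•+) above its 1070 mV aqueous
value, which charges are responsible, and how fast can an electron hole
hop along a tryptophan chain toward a carotenoid sink?

It is written for structural bioinformaticians and computational
biophysicists who have a charged structure (PQR, or PDB plus the bundled
minimal charge library) and want site energetics, titration curves, Em
profiles along the membrane normal, and kinetic estimates — all from one
config-driven pipeline or from the library API.

## The model

Site energetics come from the linearized Poisson–Boltzmann equation
∇·(ε∇φ) − ε_w κ²φ = −4πρ, solved by finite differences with a
2.5 → 1.0 → 0.3 Å grid-focusing cascade (ε = 4 protein / 80 water, 100 mM,
300 K). For each titratable site the thermodynamic cycle

pKa_intr = pKa_ref ∓ ΔΔG/RT ln10,  Em_intr = Em_ref + ΔΔG·(43.364 mV per kcal/mol)

converts the protein-vs-model-compound charging-energy difference ΔΔG
(solvation loss + background charges) into intrinsic values; site–site
couplings W_ij complete the microstate energy
G(s) = Σᵢ gᵢ(sᵢ; pH, E) + ½Σᵢ≠ⱼ W_ij(sᵢ,sⱼ). Equilibria come from exact
microstate enumeration (≤ 2²⁰ states) or Metropolis Monte Carlo; pKa is
read at half-protonation (Henderson–Hasselbalch) and Em as the bias
potential equalizing oxidized and reduced populations (Nernst midpoint).
Em shifts decompose exactly into solvation-loss and protein-charge terms.
Hole-hopping rates use the Moser–Dutton ruler
log₁₀k = 15 − 0.6R − 3.1(ΔG°+λ)²/λ with exact detailed balance, and chain
transfer times are mean first-passage times to an absorbing sink.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

A redox probe strictly coupled to a proton-release site: oxidation ejects
one proton, so the midpoint potential must fall 59.5 mV per pH unit at
300 K (RT ln10/F).

```python
import numpy as np
from pbem import PBParams, TitrationConditions, compute_site_energetics, em_midpoint
from pbem.synth import make_coupled_redox_proton

structure, sites = make_coupled_redox_proton(seed=1)
energetics = compute_site_energetics(structure, sites, PBParams())
print("W =", round(float(energetics.W[0, 1, 1, 1]), 2), "kcal/mol")
for ph in (6, 7, 8, 9):
    em = em_midpoint(energetics, "TRX-P:2", cond=TitrationConditions(pH=ph))
    print(f"pH {ph}: Em = {em:7.1f} mV")
```

prints

```
W = 9.83 kcal/mol
pH 6: Em =  1369.8 mV
pH 7: Em =  1310.6 mV
pH 8: Em =  1251.1 mV
pH 9: Em =  1191.7 mV
```

The coupling (9.8 kcal/mol, far above the ~1.4 kcal/mol of a pH-unit) and
the buried acid's intrinsic pKa (~11.2) keep the proton release strict
over the whole window, and the fitted slope, −59.4 mV/pH, is the
Nernstian signature of one-proton-per-electron coupling. The same
machinery produces Em-vs-z profiles with per-residue shift decompositions
(`pbem.redox.em_profile`), field maps (`pbem.field.solve_field`) and
chain kinetics (`pbem.hopping.lambda_sweep`).

The CLI drives the same stages from a YAML config:

```sh
pbem all --config run.yaml --out runs/demo
```

writing PQR/CSV/OpenDX outputs plus a plain-text manifest with seeds and
per-stage timings.

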