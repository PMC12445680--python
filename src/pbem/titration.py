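"""Thermodynamic-cycle intrinsic pKa/Em values and equilibrium titration.

The microstate model assigns each titratable site a discrete state label;
state 0 is the reference (deprotonated for acids/bases, reduced for redox
couples, the cation for His).  A microstate ``s`` has free energy

    G(s) = sum_i g_i(s_i; pH, E) + 1/2 sum_{i != j} W_ij(s_i, s_j)

with, per non-reference state,

* protonation  (acids, bases):   g = RT ln10 (pH - pKa_intr)
* deprotonation (His tautomers): g = RT ln10 (pKa_intr - pH)
* one-electron oxidation:        g = F (Em_intr - E)

where ``E`` is the applied solution (bias) potential in mV.  Equilibrium
populations come from exact enumeration of all microstates (the oracle,
feasible up to 2^20 states) or from Metropolis Monte Carlo sampling with
single-site moves plus paired moves for strongly coupled site pairs.
pKa values are read off the Henderson-Hasselbalch half-protonation point of
the titration curve; Em values are found by bisecting the bias potential
until oxidized and reduced populations are equal (the Nernst midpoint).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .constants import (COULOMB_KCAL, KCAL_PER_MEV, MV_PER_KCAL, R_KCAL,
                        T_DEFAULT, rt_ln10)
from .pb import PBParams, FocusedPotential, focus_solve, \
    homogeneous_reference, ChargingEnergy


@dataclass
class TitrationConditions:
    """Solution conditions of a titration run."""

    pH: float = 7.0
    bias_mv: float = 0.0           # applied solution redox potential, mV
    temperature: float = T_DEFAULT
    ionic_strength: float = 0.1

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


# state-descriptor tags used in SiteEnergetics
PROTONATE, DEPROTONATE, OXIDIZE = "protonate", "deprotonate", "oxidize"


@dataclass
class SiteEnergetics:
    """Intrinsic site values plus the pairwise interaction tensor.

    ``state_kinds[i][k]`` describes the reference->k transition of site i
    as ``(tag, value)`` with tag ``protonate``/``deprotonate`` (value an
    intrinsic pKa) or ``oxidize`` (value an intrinsic Em in mV).
    ``W[i, j, k, l]`` is the coupling (kcal/mol) between state k of site i
    and state l of site j, zero whenever either index is the reference.
    """

    site_ids: list
    kinds: list                    # acid | base | his_tautomer | redox
    n_states: np.ndarray
    state_kinds: list              # per site: list of (tag, value), [0]=None
    state_charges_total: np.ndarray   # (n, smax) total charge per state
    W: np.ndarray                  # (n, n, smax, smax), kcal/mol
    fixed_states: np.ndarray | None = None     # -1 = free
    details: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.site_ids)
        self.n_states = np.asarray(self.n_states, dtype=int)
        self.W = np.asarray(self.W, dtype=float)
        if self.fixed_states is None:
            self.fixed_states = np.full(n, -1, dtype=int)
        if not np.allclose(self.W, np.swapaxes(self.W, 0, 1
                                               ).swapaxes(2, 3), atol=1e-9):
            raise ValueError("interaction tensor must be symmetric")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("interaction tensor must be finite")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def smax(self) -> int:
        return int(self.n_states.max())

    def index(self, site_id: str) -> int:
        return self.site_ids.index(site_id)

    @property
    def free(self) -> np.ndarray:
        return np.flatnonzero(self.fixed_states < 0)

    def g_matrix(self, cond: TitrationConditions) -> np.ndarray:
        """Per-site per-state intrinsic energies (kcal/mol) at the given
        conditions, including couplings to fixed sites; +inf pads states
        that do not exist."""
        n, smax = self.n_sites, self.smax
        rtl = rt_ln10(cond.temperature)
        g = np.full((n, smax), np.inf)
        for i in range(n):
            g[i, 0] = 0.0
            for k in range(1, self.n_states[i]):
                tag, value = self.state_kinds[i][k]
                if tag == PROTONATE:
                    g[i, k] = rtl * (cond.pH - value)
                elif tag == DEPROTONATE:
                    g[i, k] = rtl * (value - cond.pH)
                elif tag == OXIDIZE:
                    g[i, k] = (value - cond.bias_mv) * KCAL_PER_MEV
                else:
                    raise ValueError(f"unknown state tag {tag!r}")
        for j in np.flatnonzero(self.fixed_states >= 0):
            sj = self.fixed_states[j]
            for i in range(n):
                if i != j:
                    g[i, :] += self.W[i, j, :, sj]
        valid = np.arange(smax)[None, :] < self.n_states[:, None]
        if not np.all(np.isfinite(g[valid])):
            raise ValueError("non-finite site energetics")
        return g

    # -- convenience constructor for synthetic binary systems ------------
    @classmethod
    def from_scalars(cls, site_ids, kinds, values, W_scalar,
                     fixed_states=None, charges=None):
        """Build binary-site energetics from scalar values.

        ``values`` are intrinsic pKa (acid/base) or Em in mV (redox);
        ``W_scalar`` is the (n, n) coupling between the two non-reference
        states, kcal/mol.  ``charges`` optionally gives the total charge of
        the non-reference state (defaults: acid/base +1 relative to
        deprotonated, redox +1 relative to reduced, with the conventional
        absolute charges -1/0 for deprotonated acid/base and 0/+1 for
        red/ox).
        """
        n = len(site_ids)
        W_scalar = np.asarray(W_scalar, dtype=float)
        W = np.zeros((n, n, 2, 2))
        W[:, :, 1, 1] = W_scalar
        state_kinds, totals = [], np.zeros((n, 2))
        for i, (kind, value) in enumerate(zip(kinds, values)):
            if kind in ("acid", "base"):
                state_kinds.append([None, (PROTONATE, float(value))])
                totals[i] = (-1.0, 0.0) if kind == "acid" else (0.0, 1.0)
            elif kind == "redox":
                state_kinds.append([None, (OXIDIZE, float(value))])
                totals[i] = (0.0, 1.0)
            else:
                raise ValueError("from_scalars supports acid/base/redox")
        if charges is not None:
            totals = np.asarray(charges, dtype=float)
        fixed = None
        if fixed_states is not None:
            fixed = np.asarray(fixed_states, dtype=int)
        return cls(list(site_ids), list(kinds), np.full(n, 2), state_kinds,
                   totals, W, fixed)


@dataclass
class Populations:
    """Equilibrium state occupancies per site."""

    site_ids: list
    state_labels: list             # per site list of labels
    occupancies: np.ndarray        # (n, smax)
    mc_error: np.ndarray           # (n, smax) standard errors (0 for exact)
    meta: dict = field(default_factory=dict)

    def occupancy(self, site_id: str, state: int) -> float:
        return float(self.occupancies[self.site_ids.index(site_id), state])

    def mean_charges(self, energetics: SiteEnergetics) -> np.ndarray:
        """Equilibrium-average total charge per site."""
        return (self.occupancies
                * energetics.state_charges_total).sum(axis=1)


# ---------------------------------------------------------------------------
# PB-backed intrinsic energetics


def compute_site_energetics(structure, sites, params: PBParams,
                            background_charges=None) -> SiteEnergetics:
    """Intrinsic pKa/Em values and couplings from the PB thermodynamic cycle.

    For every site and non-reference state the state-difference charges are
    solved in the protein dielectric environment (all structure atoms) and
    in the model-compound environment (the site's member atoms alone in
    water); the reaction-field difference plus the interaction with
    background charges gives the intrinsic-value shift:

        pKa_intr = pKa_ref -/+ ddG / (RT ln10)      (protonation/deprot.)
        Em_intr  = Em_ref + ddG * (43.364 mV per kcal/mol)

    Background charges are all structure charges outside any site's member
    atoms plus every other site frozen in its reference state.  Couplings
    ``W`` are the symmetrized cross-interactions of the state-difference
    potentials.  Per-background-atom interaction terms are retained in
    ``details`` for the per-residue contribution tables.
    """
    n = len(sites)
    member_of = np.full(structure.n_atoms, -1, dtype=int)
    for i, s in enumerate(sites):
        member_of[s.member_atoms] = i
    if background_charges is None:
        background_charges = structure.charges.copy()
    bg_q = np.array(background_charges, dtype=float)
    bg_q[member_of >= 0] = 0.0      # site atoms are described by state charges
    # other sites' reference-state charges join the background
    for s in sites:
        bg_q[s.member_atoms] += s.state_charges[0]

    smax = max(s.n_states for s in sites)
    W = np.zeros((n, n, smax, smax))
    state_kinds, totals = [], np.zeros((n, smax))
    fixed = np.full(n, -1, dtype=int)
    details = {"per_state": {}, "background_q": bg_q}
    potentials = {}

    for i, s in enumerate(sites):
        if s.fixed_state is not None:
            fixed[i] = s.state_labels.index(s.fixed_state)
        kinds_i = [None]
        for k in range(s.n_states):
            totals[i, k] = s.state_total_charge(k)
        pos = structure.positions[s.member_atoms]
        rad = structure.radii[s.member_atoms]
        for k in range(1, s.n_states):
            dq = s.diff_charges(k)
            foc_prot = focus_solve(structure.positions, structure.radii,
                                   pos, dq, params)
            foc_model = focus_solve(
                pos, rad, pos, dq, params,
                coarse_grid=foc_prot.levels[0].grid)
            hom = homogeneous_reference(foc_prot.finest.grid, pos, dq,
                                        params, params.eps_in)
            phih = hom.evaluate(pos)
            qsum = s.state_charges[k] + s.state_charges[0]
            rf_prot = 0.5 * COULOMB_KCAL * np.dot(
                qsum, foc_prot.finest.evaluate(pos) - phih)
            rf_model = 0.5 * COULOMB_KCAL * np.dot(
                qsum, foc_model.finest.evaluate(pos) - phih)
            # own member atoms are fully described by the reaction-field
            # cycle; they must not re-enter through the background
            bg_q_i = bg_q.copy()
            bg_q_i[s.member_atoms] = 0.0
            bg_idx = np.flatnonzero(bg_q_i != 0)
            back_by_atom = np.zeros(structure.n_atoms)
            if len(bg_idx):
                phi_bg = foc_prot.evaluate(structure.positions[bg_idx])
                back_by_atom[bg_idx] = COULOMB_KCAL * bg_q_i[bg_idx] * phi_bg
            back = float(back_by_atom.sum())
            ddg = (rf_prot - rf_model) + back
            tag_value = s.reference[s.state_labels[k]]
            dn = s.state_charges[k].sum() - s.state_charges[0].sum()
            if s.kind == "redox":
                kinds_i.append((OXIDIZE, tag_value + ddg * MV_PER_KCAL))
            elif s.kind == "his_tautomer":
                # reference is the cation; k is a deprotonation
                kinds_i.append((DEPROTONATE,
                                tag_value + ddg / rt_ln10(params.temperature)))
            else:
                # reference deprotonated; k is a protonation
                kinds_i.append((PROTONATE,
                                tag_value - ddg / rt_ln10(params.temperature)))
            potentials[(i, k)] = foc_prot
            details["per_state"][(s.site_id, s.state_labels[k])] = {
                "rf_protein": rf_prot, "rf_model": rf_model,
                "solvation_kcal": rf_prot - rf_model,
                "background_kcal": back, "back_by_atom": back_by_atom,
                "ddg_kcal": ddg, "dn": dn,
            }
        state_kinds.append(kinds_i)

    for i, si in enumerate(sites):
        for j, sj in enumerate(sites):
            if j <= i:
                continue
            for k in range(1, si.n_states):
                for l in range(1, sj.n_states):
                    pij = COULOMB_KCAL * np.dot(
                        sj.diff_charges(l),
                        potentials[(i, k)].evaluate(
                            structure.positions[sj.member_atoms]))
                    pji = COULOMB_KCAL * np.dot(
                        si.diff_charges(k),
                        potentials[(j, l)].evaluate(
                            structure.positions[si.member_atoms]))
                    w = 0.5 * (pij + pji)
                    W[i, j, k, l] = W[j, i, l, k] = w
                    details.setdefault("w_asymmetry", {})[
                        (si.site_id, sj.site_id, k, l)] = abs(pij - pji)

    eng = SiteEnergetics([s.site_id for s in sites],
                         [s.kind for s in sites],
                         np.array([s.n_states for s in sites]),
                         state_kinds, totals, W, fixed, details)
    eng.details["state_labels"] = [list(s.state_labels) for s in sites]
    return eng


def interaction_energy(structure, site_a, site_b, params: PBParams,
                       state_a: int = 1, state_b: int = 1) -> float:
    """Symmetrized coupling W_AB (kcal/mol) between two sites' state
    changes, from the protein-environment potentials of their
    state-difference charges."""
    if np.intersect1d(site_a.member_atoms, site_b.member_atoms).size:
        raise ValueError("sites share atoms")
    vals = []
    for s1, s2 in ((site_a, site_b), (site_b, site_a)):
        k1 = state_a if s1 is site_a else state_b
        k2 = state_b if s2 is site_b else state_a
        foc = focus_solve(structure.positions, structure.radii,
                          structure.positions[s1.member_atoms],
                          s1.diff_charges(k1), params)
        vals.append(COULOMB_KCAL * np.dot(
            s2.diff_charges(k2),
            foc.evaluate(structure.positions[s2.member_atoms])))
    return float(0.5 * (vals[0] + vals[1]))


# ---------------------------------------------------------------------------
# Equilibrium populations


def enumerate_exact(energetics: SiteEnergetics,
                    cond: TitrationConditions) -> Populations:
    """Boltzmann-exact occupancies from the full microstate sum."""
    free = energetics.free
    n_states = energetics.n_states[free]
    total = int(np.prod(n_states, dtype=np.float64)) if len(free) else 1
    if np.prod(n_states, dtype=np.float64) > 2 ** 20:
        raise ValueError("state space exceeds 2^20; use mc_titrate")
    g = energetics.g_matrix(cond)
    rt = R_KCAL * cond.temperature

    n, smax = energetics.n_sites, energetics.smax
    occ = np.zeros((n, smax))
    for j in np.flatnonzero(energetics.fixed_states >= 0):
        occ[j, energetics.fixed_states[j]] = 1.0
    if len(free) == 0:
        return Populations(energetics.site_ids, _labels(energetics), occ,
                           np.zeros_like(occ), {"backend": "exact"})

    states = np.array(list(itertools.product(
        *[range(k) for k in n_states])), dtype=int)      # (M, nf)
    G = np.zeros(len(states))
    for a, i in enumerate(free):
        G += g[i, states[:, a]]
    for a in range(len(free)):
        for b in range(a + 1, len(free)):
            G += energetics.W[free[a], free[b], states[:, a], states[:, b]]
    G -= G.min()
    w = np.exp(-G / rt)
    w /= w.sum()
    for a, i in enumerate(free):
        for k in range(n_states[a]):
            occ[i, k] = w[states[:, a] == k].sum()
    return Populations(energetics.site_ids, _labels(energetics), occ,
                       np.zeros_like(occ),
                       {"backend": "exact", "n_microstates": total})


def _labels(energetics: SiteEnergetics):
    labels = energetics.details.get("state_labels")
    if labels is None:
        labels = [[f"s{k}" for k in range(ns)]
                  for ns in energetics.n_states]
    return labels


def mc_titrate(energetics: SiteEnergetics, cond: TitrationConditions,
               n_sweeps: int = 100_000, burn_in: int = 1000,
               seed: int | None = None,
               pair_threshold: float = 2.5) -> Populations:
    """Metropolis Monte Carlo titration.

    Single-site state moves every sweep, plus paired moves for site pairs
    whose maximum |W| exceeds ``pair_threshold`` kcal/mol (strongly coupled
    pairs equilibrate poorly under single flips).  Occupancies are averaged
    over production sweeps; standard errors come from 20 batch means.
    Fully reproducible for a given seed.
    """
    if seed is None:
        raise ValueError("mc_titrate requires an explicit seed")
    g = energetics.g_matrix(cond)
    if not np.all(np.isfinite(g[g < np.inf])):
        raise ValueError("non-finite site energetics")
    rng = np.random.default_rng(seed)
    rt = R_KCAL * cond.temperature
    n, smax = energetics.n_sites, energetics.smax
    W = energetics.W
    free = energetics.free
    ns = energetics.n_states

    s = np.zeros(n, dtype=int)
    for j in np.flatnonzero(energetics.fixed_states >= 0):
        s[j] = energetics.fixed_states[j]

    wmax = np.abs(W).max(axis=(2, 3))
    pairs = [(int(i), int(j)) for a, i in enumerate(free)
             for j in free[a + 1:] if wmax[i, j] > pair_threshold]

    counts = np.zeros((n, smax))
    n_batch = 20
    batch_len = max(n_sweeps // n_batch, 1)
    batch_occ = np.zeros((n_batch, n, smax))
    arange_n = np.arange(n)

    def delta(i, new):
        d = g[i, new] - g[i, s[i]]
        d += (W[i, arange_n, new, s] - W[i, arange_n, s[i], s]).sum()
        return d

    for sweep in range(n_sweeps + burn_in):
        for i in free:
            if ns[i] == 2:
                new = 1 - s[i]
            else:
                new = int(rng.integers(ns[i] - 1))
                if new >= s[i]:
                    new += 1
            d = delta(i, new)
            if d <= 0 or rng.random() < np.exp(-d / rt):
                s[i] = new
        for (i, j) in pairs:
            ni = int(rng.integers(ns[i] - 1))
            if ni >= s[i]:
                ni += 1
            nj = int(rng.integers(ns[j] - 1))
            if nj >= s[j]:
                nj += 1
            d = delta(i, ni) + delta(j, nj) \
                + (W[i, j, ni, nj] - W[i, j, ni, s[j]]
                   - W[i, j, s[i], nj] + W[i, j, s[i], s[j]])
            if d <= 0 or rng.random() < np.exp(-d / rt):
                s[i], s[j] = ni, nj
        if sweep >= burn_in:
            counts[arange_n, s] += 1.0
            b = min((sweep - burn_in) // batch_len, n_batch - 1)
            batch_occ[b, arange_n, s] += 1.0

    occ = counts / n_sweeps
    batch_means = batch_occ / batch_len
    err = batch_means.std(axis=0, ddof=1) / np.sqrt(n_batch)
    return Populations(energetics.site_ids, _labels(energetics), occ, err,
                       {"backend": "mc", "seed": seed, "sweeps": n_sweeps,
                        "burn_in": burn_in, "pairs": pairs,
                        "temperature": cond.temperature})


# ---------------------------------------------------------------------------
# pKa and Em extraction


def _protonated_fraction(energetics, pops, i):
    kind = energetics.kinds[i]
    if kind in ("acid", "base"):
        return pops.occupancies[i, 1]
    if kind == "his_tautomer":
        return pops.occupancies[i, 0]
    raise ValueError("site is not a protonatable site")


@dataclass
class PkaResult:
    pka: float
    hill: float
    ph_grid: np.ndarray
    protonated: np.ndarray


def pka_curve(energetics: SiteEnergetics, site_id: str, ph_grid,
              cond: TitrationConditions | None = None,
              backend: str = "exact", **mc_kwargs) -> PkaResult:
    """Titration curve and Henderson-Hasselbalch pKa of one site.

    The pKa is the pH at half-protonation, found by monotone interpolation
    of the computed curve; the Hill coefficient is the logit slope at the
    midpoint (1 for a non-interacting site).
    """
    cond = cond or TitrationConditions()
    i = energetics.index(site_id)
    ph_grid = np.asarray(ph_grid, dtype=float)
    prot = np.empty_like(ph_grid)
    for k, ph in enumerate(ph_grid):
        c = TitrationConditions(ph, cond.bias_mv, cond.temperature,
                                cond.ionic_strength)
        pops = enumerate_exact(energetics, c) if backend == "exact" \
            else mc_titrate(energetics, c, **mc_kwargs)
        prot[k] = _protonated_fraction(energetics, pops, i)
    if not (prot.max() >= 0.5 >= prot.min()):
        raise ValueError("titration curve does not cross 0.5 in this pH "
                         "range; widen the grid")
    eps = 1e-12
    logit = np.log10((prot + eps) / (1 - prot + eps))
    order = np.argsort(logit)
    pka = float(np.interp(0.0, logit[order], ph_grid[order]))
    k0 = int(np.argmin(np.abs(ph_grid - pka)))
    lo, hi = max(k0 - 1, 0), min(k0 + 2, len(ph_grid))
    slope = np.polyfit(ph_grid[lo:hi], logit[lo:hi], 1)[0]
    return PkaResult(pka, float(-slope), ph_grid, prot)


def em_midpoint(energetics: SiteEnergetics, site_id: str,
                bounds=(-2000.0, 4000.0),
                cond: TitrationConditions | None = None,
                backend: str = "exact", occ_tol: float = 0.005,
                e_tol: float = 0.01, **mc_kwargs) -> float:
    """Redox midpoint potential (mV) by bias-potential bisection.

    All other titratable sites re-equilibrate at every bias potential.  The
    bisection runs until the oxidized fraction is within ``occ_tol`` of 0.5
    and the bracket is narrower than ``e_tol`` mV.
    """
    cond = cond or TitrationConditions()
    i = energetics.index(site_id)
    if energetics.kinds[i] != "redox":
        raise ValueError(f"{site_id} is not a redox site")

    def ox_fraction(e_mv):
        c = TitrationConditions(cond.pH, e_mv, cond.temperature,
                                cond.ionic_strength)
        pops = enumerate_exact(energetics, c) if backend == "exact" \
            else mc_titrate(energetics, c, **mc_kwargs)
        return pops.occupancies[i, 1] - 0.5

    lo, hi = bounds
    flo, fhi = ox_fraction(lo), ox_fraction(hi)
    if flo > 0 or fhi < 0:
        raise ValueError("bias bounds do not bracket the midpoint")
    while True:
        mid = 0.5 * (lo + hi)
        fm = ox_fraction(mid)
        if abs(fm) <= occ_tol and (hi - lo) <= e_tol:
            return mid
        if fm < 0:
            lo = mid
        else:
            hi = mid
        if (hi - lo) < 1e-9:
            return 0.5 * (lo + hi)
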