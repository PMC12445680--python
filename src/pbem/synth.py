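"""Synthetic fixtures: analytic ions, layered membrane mimics, site
clusters, coupled redox-proton pairs and conformer ensembles.

Every generator is pure: the same parameters and seed yield bitwise
identical structures.  The layered "membrane protein" mimics the charge
architecture of type-II reaction centers: a low-dielectric body spanning a
40 Å membrane with ionized groups arranged in 5 Å slabs and buried
Trp-like redox probes along the membrane normal (+z).  Probes are
nine-atom pseudo-indole rings whose oxidized-minus-reduced charge
difference sums to +1 e, spread over the ring.
"""

from __future__ import annotations

import numpy as np

from .structure import AtomRecord, Structure, TitratableSite

#: oxidized-state charge distribution of the pseudo-indole probe (sums to 1)
PROBE_OX_CHARGES = np.array([0.10, 0.12, 0.10, 0.28, 0.14, 0.06, 0.08,
                             0.06, 0.06])
PROBE_ATOM_NAMES = ["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3",
                    "CH2"]


def make_born_ion(q: float = 1.0, a: float = 2.0) -> Structure:
    """Single pseudo-atom Born ion: charge ``q`` e, cavity radius ``a`` Å."""
    if a <= 0:
        raise ValueError("Born radius must be positive")
    atom = AtomRecord(1, "ION", "ION", "X", 1, np.zeros(3), q, a)
    return Structure([atom])


def make_kirkwood_sphere(a: float = 5.0, offset: float = 1.0,
                         q: float = 1.0) -> Structure:
    """Dielectric sphere of radius ``a`` with a unit charge ``offset`` Å
    off-center (the charge atom has zero radius; the sphere atom zero
    charge)."""
    if not 0 <= offset < a:
        raise ValueError("offset must lie inside the sphere")
    sphere = AtomRecord(1, "SPH", "SPH", "X", 1, np.zeros(3), 0.0, a)
    charge = AtomRecord(2, "Q", "CHG", "X", 2,
                        np.array([offset, 0.0, 0.0]), q, 0.0)
    return Structure([sphere, charge])


def _probe_atoms(center, serial0, resnum, chain="P"):
    """Nine-atom pseudo-indole ring in the xy plane, radius 1.4 Å."""
    atoms = []
    for k, name in enumerate(PROBE_ATOM_NAMES):
        ang = 2.0 * np.pi * k / 9.0
        pos = np.asarray(center) + np.array([1.4 * np.cos(ang),
                                             1.4 * np.sin(ang), 0.0])
        atoms.append(AtomRecord(serial0 + k, name, "TRX", chain, resnum,
                                pos, 0.0, 1.7))
    return atoms


def _probe_site(structure, chain, resnum):
    idx = structure.residue_atom_indices(chain, resnum)
    charges = np.vstack([np.zeros(9), PROBE_OX_CHARGES])
    return TitratableSite(f"TRX-{chain}:{resnum}", "redox", idx,
                          ["reduced", "oxidized"], charges,
                          {"oxidized": 1070.0})


def make_layered_protein(seed: int = 0,
                         slab_charges=(-4, -3, 0, 0, 0, 0, 3, 4),
                         probe_z=(-10.0, 0.0, 10.0),
                         half_width: float = 12.0,
                         half_height: float = 20.0):
    """Layered membrane-protein mimic.

    A neutral low-dielectric body of cubic-packed 2 Å pseudo-atoms spans
    ``z in [-half_height, half_height]`` (a 40 Å membrane by default).
    ``slab_charges`` gives the net number of unit charges in each 5 Å slab
    from the bottom (periplasmic, -z) to the top (cytoplasmic, +z)
    interface; charged groups are single +-1 e pseudo-atoms placed at
    seeded random lateral positions inside the slab.  Redox probe rings sit
    on the z-axis at ``probe_z`` depths.

    Returns ``(structure, sites)``; the structure carries the membrane
    interface planes.
    """
    rng = np.random.default_rng(seed)
    atoms = []
    serial = 1
    grid = np.arange(-half_width, half_width + 1e-9, 2.0)
    zgrid = np.arange(-half_height, half_height + 1e-9, 2.0)
    for x in grid:
        for y in grid:
            for z in zgrid:
                atoms.append(AtomRecord(serial, "C", "BDY", "B", 1,
                                        np.array([x, y, z]), 0.0, 2.0))
                serial += 1

    n_slabs = len(slab_charges)
    slab_h = 2.0 * half_height / n_slabs
    resnum = 1
    for region, net in enumerate(slab_charges):
        z_lo = -half_height + region * slab_h
        for _ in range(abs(int(net))):
            xy = rng.uniform(-half_width + 2.0, half_width - 2.0, size=2)
            z = rng.uniform(z_lo + 1.0, z_lo + slab_h - 1.0)
            sign = 1.0 if net > 0 else -1.0
            resnum += 1
            atoms.append(AtomRecord(serial, "Q", "CAT" if net > 0 else "ANI",
                                    "I", resnum,
                                    np.array([xy[0], xy[1], z]), sign, 2.0))
            serial += 1

    probes = []
    for z in probe_z:
        if abs(z) > half_height:
            raise ValueError(f"probe at z={z} lies outside the body")
        resnum += 1
        atoms.extend(_probe_atoms((0.0, 0.0, z), serial, resnum))
        probes.append(resnum)
        serial += 9

    st = Structure(atoms, interfaces=(-half_height, half_height))
    sites = [_probe_site(st, "P", rn) for rn in probes]
    return st, sites


def make_site_cluster(n: int, coupling: float = 1.4, seed: int = 0,
                      pka_range=(4.0, 10.0)):
    """Cluster of ``n`` single-atom acid pseudo-sites in water.

    Positions are seeded uniform points in a cube scaled so that computed
    nearest-neighbour couplings reach the ``coupling`` target scale
    (kcal/mol) under screened-Coulomb interaction at 100 mM.  Feasible up
    to n = 20 (exact-enumeration oracle limit).

    Returns ``(structure, sites)``.
    """
    if n > 20:
        raise ValueError("site clusters are limited to 20 sites "
                         "(enumeration oracle)")
    rng = np.random.default_rng(seed)
    # distance -> coupling law for two radius-1.7 Å sites in water at
    # 100 mM (PB-calibrated once; cavity overlap dominates below ~4 Å,
    # screened Coulomb with a ~1.14 cavity factor beyond)
    r_tab = np.array([2.2, 3.0, 3.5, 4.0, 5.0, 6.0, 8.0, 12.0, 20.0])
    w_tab = np.array([9.40, 3.06, 1.63, 0.80, 0.57, 0.42, 0.26,
                      0.104, 0.0266])
    logw = np.log(w_tab)[::-1]
    r = float(np.interp(np.log(coupling), logw, r_tab[::-1]))
    # pin the first pair at exactly the target distance; everyone else
    # keeps a wider berth so the nearest pair sets the coupling scale
    side = max(r * 1.8 * n ** (1.0 / 3.0), 2.0 * r)
    pos = np.empty((n, 3))
    pos[0] = 0.0
    if n > 1:
        u = rng.normal(size=3)
        pos[1] = r * u / np.linalg.norm(u)
    count = 2 if n > 1 else 1
    while count < n:
        cand = rng.uniform(-side / 2, side / 2, size=3)
        if np.linalg.norm(pos[:count] - cand, axis=1).min() >= 1.1 * r:
            pos[count] = cand
            count += 1
    atoms, sites_spec = [], []
    for i in range(n):
        atoms.append(AtomRecord(i + 1, "O", "PSA", "S", i + 1, pos[i],
                                0.0, 1.7))
    st = Structure(atoms)
    pkas = rng.uniform(*pka_range, size=n)
    sites = []
    for i in range(n):
        sites.append(TitratableSite(
            f"PSA-S:{i + 1}", "acid", [i], ["deprotonated", "protonated"],
            np.array([[-1.0], [0.0]]), {"protonated": float(pkas[i])}))
    return st, sites


def make_coupled_redox_proton(seed: int = 0, probe_x: float = -1.5,
                              acid_x: float = 2.5,
                              body_radius: float = 6.0,
                              acid_pka_ref: float = -1.0):
    """A redox probe strictly coupled to a proton-release site.

    A pseudo-indole probe and a single-atom strong acid (sulfonate-like
    model compound, reference pKa -1) sit ~4 Å apart inside a
    low-dielectric spherical blob of packed pseudo-atoms.  Burial raises
    the acid's intrinsic pKa to ~11 and the strong coupling
    (W ~ 10 kcal/mol, well above 4) pulls it to ~4 upon probe oxidation,
    so oxidation releases exactly one proton across pH 6-9 and the Em-vs-pH
    slope is Nernstian (-59.5 mV/pH at 300 K).

    Returns ``(structure, sites)``.
    """
    rng = np.random.default_rng(seed)   # reserved: geometry is deterministic
    del rng
    atoms = []
    serial = 1
    grid = np.arange(-body_radius, body_radius + 1e-9, 2.0)
    for x in grid:
        for y in grid:
            for z in grid:
                if x * x + y * y + z * z <= body_radius ** 2:
                    atoms.append(AtomRecord(serial, "C", "BDY", "B", 1,
                                            np.array([x, y, z]), 0.0, 2.0))
                    serial += 1
    atoms.extend(_probe_atoms((probe_x, 0.0, 0.0), serial, 2))
    serial += 9
    atoms.append(AtomRecord(serial, "O", "PSA", "P", 3,
                            np.array([acid_x, 0.0, 0.0]), 0.0, 1.7))
    st = Structure(atoms)
    probe = _probe_site(st, "P", 2)
    acid_idx = st.residue_atom_indices("P", 3)
    acid = TitratableSite("PSA-P:3", "acid", acid_idx,
                          ["deprotonated", "protonated"],
                          np.array([[-1.0], [0.0]]),
                          {"protonated": acid_pka_ref})
    return st, [probe, acid]


def make_conformer_ensemble(structure: Structure, n_conformers: int = 10,
                            sigma: float = 0.3, seed: int = 0) -> Structure:
    """Copy of ``structure`` with ``n_conformers`` jittered coordinate sets
    (isotropic Gaussian displacement of standard deviation ``sigma`` Å)."""
    rng = np.random.default_rng(seed)
    confs = [structure.positions
             + rng.normal(0.0, sigma, structure.positions.shape)
             for _ in range(n_conformers)]
    return Structure(list(structure.atoms()), conformers=confs,
                     interfaces=structure.interfaces)
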