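"""Charged molecular structures, titratable sites and membrane-slab tallies.

The central container is :class:`Structure`: parallel numpy arrays of atom
metadata, coordinates (Å), partial charges (e) and van der Waals radii (Å),
optionally with alternative conformer coordinate sets sharing the same atom
ordering.  Structures are read from PQR files (whitespace dialect, charges
and radii in the file) or from plain PDB files with charges/radii assigned
from the bundled minimal model-compound library.

Titratable sites (Asp/Glu/Cys/Tyr acids, Lys/Arg bases, His three-state
tautomer sites, and user-flagged Trp redox couples) are defined on top of a
structure; each site carries per-state charge vectors over its member atoms
and the reference pKa/Em of its model compound in water.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.spatial.distance import cdist

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "HN", "HA", "HA1", "HA2",
                  "H1", "H2", "H3"}

WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SOL"}


class ParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


class ChargeAssignmentError(KeyError):
    """Raised when a residue has no entry in the charge library."""


def load_charge_library() -> dict:
    """Load the bundled minimal charge/radius library (parsed YAML)."""
    ref = importlib.resources.files("pbem.data").joinpath("charges.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


@dataclass
class AtomRecord:
    """One atom: identity, position (Å), partial charge (e), radius (Å)."""

    atom_id: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray
    charge: float
    radius: float

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position components must be finite")
        if not np.isfinite(self.charge):
            raise ValueError("charge must be finite")
        if not (np.isfinite(self.radius) and self.radius >= 0):
            raise ValueError("radius must be finite and non-negative")


class Structure:
    """Ordered collection of atoms with optional conformer coordinate sets.

    Parameters
    ----------
    atoms
        Sequence of :class:`AtomRecord`, kept in file order.
    conformers
        Optional list of alternative ``(n_atoms, 3)`` coordinate arrays with
        the same atom ordering as the base coordinates.
    interfaces
        Optional ``(z_lo, z_hi)`` membrane interface planes in Å; the
        membrane normal is the +z axis by convention.
    """

    def __init__(self, atoms, conformers=None, interfaces=None):
        atoms = list(atoms)
        n = len(atoms)
        self.atom_id = np.array([a.atom_id for a in atoms], dtype=int)
        self.atom_name = [a.atom_name for a in atoms]
        self.residue_name = [a.residue_name for a in atoms]
        self.chain_id = [a.chain_id for a in atoms]
        self.residue_number = np.array([a.residue_number for a in atoms],
                                       dtype=int)
        self.positions = np.array([a.position for a in atoms], dtype=float) \
            if n else np.zeros((0, 3))
        self.charges = np.array([a.charge for a in atoms], dtype=float)
        self.radii = np.array([a.radius for a in atoms], dtype=float)
        self.conformers = []
        for c in (conformers or []):
            c = np.asarray(c, dtype=float)
            if c.shape != self.positions.shape:
                raise ValueError("conformer must match base atom count and "
                                 "ordering")
            self.conformers.append(c)
        self.interfaces = tuple(interfaces) if interfaces is not None else None

    @property
    def n_atoms(self) -> int:
        return len(self.charges)

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def atoms(self):
        """Iterate atoms as :class:`AtomRecord` views."""
        for i in range(self.n_atoms):
            yield AtomRecord(int(self.atom_id[i]), self.atom_name[i],
                             self.residue_name[i], self.chain_id[i],
                             int(self.residue_number[i]),
                             self.positions[i].copy(),
                             float(self.charges[i]), float(self.radii[i]))

    def residue_keys(self):
        """Ordered unique (chain, resnum, resname) keys."""
        seen, out = set(), []
        for i in range(self.n_atoms):
            key = (self.chain_id[i], int(self.residue_number[i]),
                   self.residue_name[i])
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def residue_atom_indices(self, chain_id: str, residue_number: int):
        """Indices of all atoms of one residue, in file order."""
        idx = [i for i in range(self.n_atoms)
               if self.chain_id[i] == chain_id
               and self.residue_number[i] == residue_number]
        return np.array(idx, dtype=int)

    def atom_index(self, chain_id, residue_number, atom_name):
        for i in self.residue_atom_indices(chain_id, residue_number):
            if self.atom_name[i] == atom_name:
                return int(i)
        raise KeyError(f"atom {atom_name} not found in "
                       f"{chain_id}:{residue_number}")

    def with_positions(self, positions: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates (same atoms)."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != self.positions.shape:
            raise ValueError("coordinate array shape mismatch")
        out = Structure([], interfaces=self.interfaces)
        for name in ("atom_id", "atom_name", "residue_name", "chain_id",
                     "residue_number", "charges", "radii"):
            setattr(out, name, getattr(self, name))
        out.positions = positions.copy()
        out.conformers = []
        return out

    def subset(self, indices) -> "Structure":
        """New structure containing only the given atoms (order preserved)."""
        indices = np.asarray(indices, dtype=int)
        out = Structure([], interfaces=self.interfaces)
        out.atom_id = self.atom_id[indices]
        out.atom_name = [self.atom_name[i] for i in indices]
        out.residue_name = [self.residue_name[i] for i in indices]
        out.chain_id = [self.chain_id[i] for i in indices]
        out.residue_number = self.residue_number[indices]
        out.positions = self.positions[indices]
        out.charges = self.charges[indices]
        out.radii = self.radii[indices]
        out.conformers = [c[indices] for c in self.conformers]
        return out


@dataclass
class TitratableSite:
    """A residue's titratable group with its charge states.

    ``state_labels[0]`` is the reference state of the microstate model:
    deprotonated for acids and bases, reduced for redox couples, the
    doubly-protonated cation for His.  ``reference`` maps every
    non-reference state label to the model-compound value governing the
    reference->state transition (a pKa, or an Em in mV for redox sites).
    """

    site_id: str
    kind: str                      # acid | base | his_tautomer | redox
    member_atoms: np.ndarray       # atom indices into the parent structure
    state_labels: list
    state_charges: np.ndarray      # (n_states, n_members) charge vectors
    reference: dict
    fixed_state: str | None = None

    def __post_init__(self):
        self.member_atoms = np.asarray(self.member_atoms, dtype=int)
        self.state_charges = np.asarray(self.state_charges, dtype=float)
        if len(self.state_labels) < 2:
            raise ValueError("a titratable site needs at least two states")
        if self.state_charges.shape != (len(self.state_labels),
                                        len(self.member_atoms)):
            raise ValueError("state_charges shape mismatch")
        for k, label in enumerate(self.state_labels[1:], start=1):
            dq = self.state_charges[k].sum() - self.state_charges[0].sum()
            if abs(abs(dq) - 1.0) > 1e-6:
                raise ValueError(
                    f"state {label} of {self.site_id} differs from the "
                    f"reference by {dq:+.3f} e, expected +-1 e")
            if label not in self.reference:
                raise ValueError(f"state {label} of {self.site_id} has no "
                                 "reference value")
        if self.fixed_state is not None \
                and self.fixed_state not in self.state_labels:
            raise ValueError(f"unknown fixed state {self.fixed_state!r}")

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def diff_charges(self, state: int) -> np.ndarray:
        """Charge vector of ``state`` minus the reference state."""
        return self.state_charges[state] - self.state_charges[0]

    def state_total_charge(self, state: int) -> float:
        return float(self.state_charges[state].sum())


@dataclass
class RegionTally:
    """Counts of ionized groups per membrane slab (unit-charge picture)."""

    edges: np.ndarray              # region boundaries along z, Å
    n_positive: np.ndarray         # per-region positive-group counts
    n_negative: np.ndarray
    net: np.ndarray

    def __post_init__(self):
        if np.any(self.n_positive < 0) or np.any(self.n_negative < 0):
            raise ValueError("group counts must be non-negative")


# ---------------------------------------------------------------------------
# PQR / PDB input and output


def read_pqr(path) -> Structure:
    """Read a whitespace-delimited PQR file.

    Expected per-atom fields: record name, serial, atom name, residue name,
    optional chain id, residue number, x, y, z, charge, radius.  Numeric
    fields that fail to parse raise :class:`ParseError` naming the line.
    """
    atoms = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            fields = line.split()
            if len(fields) == 11:
                (_, serial, name, resname, chain, resnum,
                 x, y, z, q, r) = fields
            elif len(fields) == 10:
                (_, serial, name, resname, resnum, x, y, z, q, r) = fields
                chain = ""
            else:
                raise ParseError(f"line {lineno}: expected 10 or 11 fields, "
                                 f"got {len(fields)}")
            try:
                atoms.append(AtomRecord(int(serial), name, resname, chain,
                                        int(resnum),
                                        np.array([float(x), float(y),
                                                  float(z)]),
                                        float(q), float(r)))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return Structure(atoms)


def write_pqr(structure: Structure, path) -> None:
    """Write a whitespace-delimited PQR file (round-trips with read_pqr)."""
    with open(path, "w") as fh:
        for a in structure.atoms():
            chain = a.chain_id if a.chain_id else ""
            fields = ["ATOM", str(a.atom_id), a.atom_name, a.residue_name]
            if chain:
                fields.append(chain)
            fields.append(str(a.residue_number))
            fields += [f"{v:.4f}" for v in a.position]
            fields += [f"{a.charge:.4f}", f"{a.radius:.4f}"]
            fh.write(" ".join(fields) + "\n")


def read_pdb(path, charge_library: dict | None = None,
             retain_waters=(), zero_charge_fallback: bool = False
             ) -> Structure:
    """Read a PDB file and assign charges/radii from the bundled library.

    Crystallographic waters are removed unless named in ``retain_waters``
    (``"chain:resnum"`` strings).  Residues absent from the library raise
    :class:`ChargeAssignmentError` unless ``zero_charge_fallback`` is set,
    in which case their atoms get zero charge and element radii.
    """
    import gemmi

    lib = charge_library or load_charge_library()
    radii = lib["radii"]
    backbone = lib["backbone"]
    sidechain = lib["sidechain"]
    retain = set(retain_waters)

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    atoms = []
    serial = 0
    model = st[0]
    for chain in model:
        for res in chain:
            key = f"{chain.name}:{res.seqid.num}"
            if res.name in WATER_RESNAMES and key not in retain:
                continue
            known = res.name in sidechain or res.name in WATER_RESNAMES
            if not known and not zero_charge_fallback:
                raise ChargeAssignmentError(
                    f"residue {res.name} ({key}) not in charge library and "
                    "zero-charge fallback is disabled")
            for at in res:
                serial += 1
                elem = at.element.name.upper()
                r = radii.get(elem, radii["default"])
                q = 0.0
                if res.name in sidechain:
                    q = backbone.get(at.name,
                                     sidechain[res.name].get(at.name, 0.0))
                atoms.append(AtomRecord(serial, at.name, res.name, chain.name,
                                        res.seqid.num,
                                        np.array([at.pos.x, at.pos.y,
                                                  at.pos.z]),
                                        q, r))
    return Structure(atoms)


# ---------------------------------------------------------------------------
# Titratable-site definition


def define_sites(structure: Structure, redox_residues=(),
                 fixed_states: dict | None = None,
                 charge_library: dict | None = None):
    """Identify titratable sites in a structure.

    Asp/Glu/Cys/Tyr, Lys/Arg and His residues become titratable sites
    automatically; Trp residues become one-electron redox sites only when
    listed in ``redox_residues`` (``"chain:resnum"`` strings).
    ``fixed_states`` maps site ids to state labels that are held fixed
    (for example ligating His residues kept neutral).

    Returns a list of :class:`TitratableSite`.
    """
    lib = charge_library or load_charge_library()
    site_defs = lib["sites"]
    fixed_states = fixed_states or {}
    redox = set(redox_residues)
    sites = []
    for chain, resnum, resname in structure.residue_keys():
        key = f"{chain}:{resnum}"
        if resname not in site_defs:
            continue
        sdef = site_defs[resname]
        if sdef["kind"] == "redox" and key not in redox:
            continue
        res_idx = structure.residue_atom_indices(chain, resnum)
        name_to_idx = {structure.atom_name[i]: int(i) for i in res_idx}
        members = [m for m in sdef["members"] if m in name_to_idx]
        needed = set()
        for st_charges in sdef["states"].values():
            needed |= set(st_charges)
        missing = needed - set(members)
        if missing:
            raise ValueError(
                f"site {resname} {key}: member atoms {sorted(missing)} "
                "required by its state charge sets are missing")
        member_idx = np.array([name_to_idx[m] for m in members], dtype=int)
        labels = list(sdef["states"])
        state_charges = np.array(
            [[sdef["states"][lab].get(m, 0.0) for m in members]
             for lab in labels])
        if sdef["kind"] == "redox":
            reference = {lab: float(sdef["em_ref_mv"]) for lab in labels[1:]}
        elif sdef["kind"] == "his_tautomer":
            reference = {"delta_protonated": float(sdef["pka_ref_epsilon"]),
                         "epsilon_protonated": float(sdef["pka_ref_delta"])}
        else:
            reference = {labels[1]: float(sdef["pka_ref"])}
        site_id = f"{resname}-{key}"
        sites.append(TitratableSite(site_id, sdef["kind"], member_idx,
                                    labels, state_charges, reference,
                                    fixed_state=fixed_states.get(site_id)))
    return sites


# ---------------------------------------------------------------------------
# Membrane-slab charge tallies and edge-to-edge distances


def region_charge_tally(structure: Structure, sites, site_states: dict,
                        layer_thickness: float = 5.0,
                        interfaces=None) -> RegionTally:
    """Tally ionized groups in membrane slabs along z.

    Each ionized group is approximated as one unit charge located at the
    centroid of its member atoms.  ``site_states`` maps site ids to the
    equilibrium state label of each site; groups whose state carries zero
    total charge are not counted.  Slabs of ``layer_thickness`` Å span the
    membrane between the two ``interfaces`` z-planes (defaults to the
    structure's own ``interfaces``).
    """
    if interfaces is None:
        interfaces = structure.interfaces
    if interfaces is None:
        raise ValueError("membrane interface planes are required")
    z_lo, z_hi = sorted(interfaces)
    zmin, zmax = structure.positions[:, 2].min(), structure.positions[:, 2].max()
    # sanity check: reject interface planes far away from all coordinates
    if z_lo < zmin - 40.0 or z_hi > zmax + 40.0:
        raise ValueError("interface planes lie outside the coordinate range")
    edges = np.arange(z_lo, z_hi + 0.5 * layer_thickness, layer_thickness)
    if edges[-1] < z_hi - 1e-9:
        edges = np.append(edges, z_hi)
    n_regions = len(edges) - 1
    n_pos = np.zeros(n_regions, dtype=int)
    n_neg = np.zeros(n_regions, dtype=int)
    for site in sites:
        label = site_states.get(site.site_id, site.state_labels[0])
        state = site.state_labels.index(label)
        q = site.state_total_charge(state)
        if abs(q) < 0.5:
            continue
        z = structure.positions[site.member_atoms, 2].mean()
        if z < edges[0] or z > edges[-1]:
            continue
        region = min(int((z - edges[0]) // layer_thickness), n_regions - 1)
        if q > 0:
            n_pos[region] += 1
        else:
            n_neg[region] += 1
    return RegionTally(edges, n_pos, n_neg, n_pos - n_neg)


def edge_to_edge_distance(structure: Structure, res_a, res_b) -> float:
    """Minimum heavy-atom side-chain distance between two residues, Å.

    ``res_a``/``res_b`` are ``(chain, resnum)`` pairs.  Backbone atoms and
    hydrogens are excluded; this is the edge-to-edge convention used with
    the Moser-Dutton ruler.
    """
    def sidechain_coords(res):
        chain, num = res
        idx = structure.residue_atom_indices(chain, num)
        if len(idx) == 0:
            raise KeyError(f"residue {chain}:{num} not found")
        keep = [i for i in idx
                if structure.atom_name[i] not in BACKBONE_ATOMS
                and not structure.atom_name[i].startswith("H")]
        if not keep:
            raise ValueError(f"residue {chain}:{num} has no side-chain "
                             "heavy atoms")
        return structure.positions[keep]

    a = sidechain_coords(res_a)
    b = sidechain_coords(res_b)
    return float(cdist(a, b).min())
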