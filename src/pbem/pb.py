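"""Finite-difference linearized Poisson-Boltzmann solver with grid focusing.

The discretization is the standard 7-point stencil on a regular cubic grid:

    sum_faces eps_face (phi_nbr - phi_p) / h^2  -  eps_w kappa^2 phi_p
        = -4 pi rho_p

with face dielectrics obtained by harmonic-mean homogenization of the
protein (``eps_in``) and water (``eps_out``) values along each grid edge,
ionic screening ``kappa^2`` masked to zero inside the van der Waals union
of the atoms plus a Stern layer, and Debye-Hueckel monopole boundary
conditions on the coarsest grid.  Finer grids of a focusing cascade take
Dirichlet boundary values interpolated from their parent.

Potentials are kept in a Gaussian-style internal unit in which the energy
of a charge ``q`` (e) at potential ``phi`` is ``332.064 * q * phi``
kcal/mol; multiply by :data:`pbem.constants.VOLT_PER_PHI` for volts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import cg

from .constants import COULOMB_KCAL, T_DEFAULT, debye_length


class ConvergenceError(RuntimeError):
    """Linear solver failed to reach the requested residual."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class GridSpec:
    """Regular cubic grid: origin (Å), spacing (Å), node counts per axis."""

    origin: tuple
    spacing: float
    shape: tuple

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if min(self.shape) < 8:
            raise ValueError("grids need at least 8 nodes per axis")

    @property
    def extent(self):
        """(min, max) corner coordinates of the grid."""
        o = np.asarray(self.origin)
        return o, o + (np.asarray(self.shape) - 1) * self.spacing

    def axes(self):
        o = np.asarray(self.origin)
        return [o[d] + self.spacing * np.arange(self.shape[d])
                for d in range(3)]

    def contains(self, points, margin: float = 0.0) -> np.ndarray:
        """Boolean mask: points at least ``margin`` inside the grid box."""
        lo, hi = self.extent
        p = np.atleast_2d(points)
        return np.all((p >= lo + margin) & (p <= hi - margin), axis=1)


def grid_enclosing(points, radii=None, margin: float = 10.0,
                   spacing: float = 2.5) -> GridSpec:
    """Smallest grid covering the given atoms plus a margin."""
    points = np.atleast_2d(points)
    pad = margin + (np.max(radii) if radii is not None and len(radii) else 0)
    lo = points.min(axis=0) - pad
    hi = points.max(axis=0) + pad
    shape = tuple(max(8, int(np.ceil((hi[d] - lo[d]) / spacing)) + 1)
                  for d in range(3))
    return GridSpec(tuple(lo), spacing, shape)


def grid_centered(center, half_extent: float, spacing: float) -> GridSpec:
    """Cubic grid of half-width ``half_extent`` centered on ``center``."""
    center = np.asarray(center, dtype=float)
    n = max(8, 2 * int(np.ceil(half_extent / spacing)) + 1)
    origin = center - 0.5 * (n - 1) * spacing
    return GridSpec(tuple(origin), spacing, (n, n, n))


@dataclass
class PBParams:
    """Continuum model parameters.

    eps_in/eps_out are the protein and water dielectric constants (4/80),
    ionic strength in mol/L at temperature T (K) sets the Debye screening,
    ``stern`` is the ion-exclusion shell width in Å, and ``levels`` the
    focusing resolutions (Å, coarse to fine).
    """

    eps_in: float = 4.0
    eps_out: float = 80.0
    ionic_strength: float = 0.1
    temperature: float = T_DEFAULT
    stern: float = 2.0
    levels: tuple = (2.5, 1.0, 0.3)
    roi_margin: float = 3.0
    mid_margin: float = 8.0
    coarse_margin: float = 15.0
    tol: float = 1e-6
    maxiter: int = 10000

    @property
    def kappa(self) -> float:
        """Inverse Debye length (1/Å) in the water phase; 0 at I = 0."""
        lam = debye_length(self.ionic_strength, self.temperature,
                           self.eps_out)
        return 0.0 if np.isinf(lam) else 1.0 / lam


@dataclass
class DielectricMap:
    """Face dielectrics plus the screening mask for one grid."""

    grid: GridSpec
    eps_x: np.ndarray          # (nx-1, ny, nz) face values along x
    eps_y: np.ndarray
    eps_z: np.ndarray
    kappa2_eps: np.ndarray     # eps_w * kappa^2 at ion-accessible nodes
    params: PBParams


def _inside_mask(origin, spacing, shape, pos, radii):
    """Stamp the van der Waals union onto a node lattice."""
    mask = np.zeros(shape, dtype=bool)
    if len(pos) == 0:
        return mask
    origin = np.asarray(origin, dtype=float)
    axes = [origin[d] + spacing[d] * np.arange(shape[d]) for d in range(3)]
    for p, r in zip(pos, radii):
        if r <= 0:
            continue
        sl, local = [], []
        for d in range(3):
            lo = int(np.ceil((p[d] - r - origin[d]) / spacing[d]))
            hi = int(np.floor((p[d] + r - origin[d]) / spacing[d]))
            lo, hi = max(lo, 0), min(hi, shape[d] - 1)
            if lo > hi:
                break
            sl.append(slice(lo, hi + 1))
            local.append(axes[d][lo:hi + 1] - p[d])
        else:
            d2 = (local[0][:, None, None] ** 2 + local[1][None, :, None] ** 2
                  + local[2][None, None, :] ** 2)
            mask[tuple(sl)] |= d2 <= r * r
    return mask


def build_dielectric_map(pos, radii, grid: GridSpec, params: PBParams,
                         uniform_eps: float | None = None,
                         check_coverage: bool = False) -> DielectricMap:
    """Build face dielectrics and the screening mask for one grid level.

    The protein interior is the van der Waals union of the atoms; each grid
    edge gets the harmonic mean of eps_in/eps_out weighted by the fraction
    of the edge inside the protein (estimated from its end nodes and
    midpoint).  ``uniform_eps`` short-circuits to a homogeneous medium.
    """
    h = grid.spacing
    nx, ny, nz = grid.shape
    if check_coverage and len(pos):
        lo, hi = grid.extent
        plo = (np.asarray(pos) - np.asarray(radii)[:, None]).min(axis=0)
        phi_ = (np.asarray(pos) + np.asarray(radii)[:, None]).max(axis=0)
        if np.any(plo < lo + 2.0) or np.any(phi_ > hi - 2.0):
            raise ValueError("grid does not cover the structure plus a "
                             "2 Å margin")
    if uniform_eps is not None:
        eps_x = np.full((nx - 1, ny, nz), uniform_eps)
        eps_y = np.full((nx, ny - 1, nz), uniform_eps)
        eps_z = np.full((nx, ny, nz - 1), uniform_eps)
        kap = np.zeros(grid.shape)
        return DielectricMap(grid, eps_x, eps_y, eps_z, kap, params)

    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    radii = np.asarray(radii, dtype=float)
    sp = (h, h, h)
    node_in = _inside_mask(grid.origin, sp, grid.shape, pos, radii)
    o = np.asarray(grid.origin)

    def face_eps(axis):
        off = np.zeros(3)
        off[axis] = 0.5 * h
        shape = list(grid.shape)
        shape[axis] -= 1
        mid_in = _inside_mask(o + off, sp, tuple(shape), pos, radii)
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        frac = (node_in[tuple(sl_a)].astype(float)
                + node_in[tuple(sl_b)] + 2.0 * mid_in) / 4.0
        return 1.0 / (frac / params.eps_in + (1.0 - frac) / params.eps_out)

    eps_x, eps_y, eps_z = face_eps(0), face_eps(1), face_eps(2)

    kap = np.zeros(grid.shape)
    if params.kappa > 0:
        excluded = _inside_mask(grid.origin, sp, grid.shape, pos,
                                radii + params.stern)
        kap[~excluded] = params.eps_out * params.kappa ** 2
    return DielectricMap(grid, eps_x, eps_y, eps_z, kap, params)


def spread_charges(grid: GridSpec, pos, q) -> np.ndarray:
    """Trilinear (cloud-in-cell) assignment of point charges to nodes (e)."""
    rho = np.zeros(grid.shape)
    if len(pos) == 0:
        return rho
    pos = np.atleast_2d(pos)
    q = np.atleast_1d(q)
    o = np.asarray(grid.origin)
    t = (pos - o) / grid.spacing
    i0 = np.floor(t).astype(int)
    if np.any(i0 < 0) or np.any(i0 + 1 >= np.asarray(grid.shape)):
        raise ValueError("charge outside grid")
    f = t - i0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (np.where(dx, f[:, 0], 1 - f[:, 0])
                     * np.where(dy, f[:, 1], 1 - f[:, 1])
                     * np.where(dz, f[:, 2], 1 - f[:, 2]))
                np.add.at(rho, (i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz),
                          w * q)
    return rho


@dataclass
class PotentialGrid:
    """Node potentials on one grid (internal unit; see module docstring)."""

    grid: GridSpec
    values: np.ndarray
    residual: float = 0.0
    provenance: dict = field(default_factory=dict)

    def evaluate(self, points) -> np.ndarray:
        """Trilinear interpolation of the potential at arbitrary points."""
        points = np.atleast_2d(points)
        o = np.asarray(self.grid.origin)
        t = (points - o) / self.grid.spacing
        i0 = np.clip(np.floor(t).astype(int), 0,
                     np.asarray(self.grid.shape) - 2)
        f = t - i0
        out = np.zeros(len(points))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (np.where(dx, f[:, 0], 1 - f[:, 0])
                         * np.where(dy, f[:, 1], 1 - f[:, 1])
                         * np.where(dz, f[:, 2], 1 - f[:, 2]))
                    out += w * self.values[i0[:, 0] + dx, i0[:, 1] + dy,
                                           i0[:, 2] + dz]
        return out

    def write_dx(self, path) -> None:
        """Export as an OpenDX scalar field."""
        nx, ny, nz = self.grid.shape
        o = self.grid.origin
        h = self.grid.spacing
        with open(path, "w") as fh:
            fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            fh.write(f"origin {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}\n")
            fh.write(f"delta {h:.6f} 0 0\ndelta 0 {h:.6f} 0\n"
                     f"delta 0 0 {h:.6f}\n")
            fh.write(f"object 2 class gridconnections counts {nx} {ny} "
                     f"{nz}\n")
            fh.write(f"object 3 class array type double rank 0 items "
                     f"{nx * ny * nz} data follows\n")
            flat = self.values.ravel()
            for i in range(0, len(flat), 3):
                fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
            fh.write('attribute "dep" string "positions"\n'
                     'object "potential" class field\n')


def _dh_boundary(grid: GridSpec, pos, q, eps_out, kappa):
    """Debye-Hueckel per-atom monopole potential on the grid boundary."""
    nx, ny, nz = grid.shape
    phi = np.zeros(grid.shape)
    if len(pos) == 0:
        return phi
    bmask = np.zeros(grid.shape, dtype=bool)
    bmask[0], bmask[-1] = True, True
    bmask[:, 0], bmask[:, -1] = True, True
    bmask[:, :, 0], bmask[:, :, -1] = True, True
    idx = np.argwhere(bmask)
    coords = np.asarray(grid.origin) + idx * grid.spacing
    pos = np.atleast_2d(pos)
    q = np.atleast_1d(q)
    vals = np.zeros(len(idx))
    chunk = 20000
    for s in range(0, len(idx), chunk):
        d = np.linalg.norm(coords[s:s + chunk, None, :] - pos[None], axis=2)
        d = np.maximum(d, 1e-6)
        vals[s:s + chunk] = (q[None] * np.exp(-kappa * d) / (eps_out * d)
                             ).sum(axis=1)
    phi[tuple(idx.T)] = vals
    return phi


def solve_lpb(pos, q, dmap: DielectricMap, boundary="dh",
              tol: float | None = None,
              maxiter: int | None = None,
              rho: np.ndarray | None = None) -> PotentialGrid:
    """Solve the linearized PB equation on one grid.

    ``boundary`` is ``"zero"``, ``"dh"`` (sum of per-atom Debye-Hueckel
    monopoles), an ndarray of boundary potentials, or a callable mapping an
    ``(m, 3)`` coordinate array to potentials (used for analytic Coulomb
    boundaries of homogeneous reference solves).
    """
    grid = dmap.grid
    p = dmap.params
    tol = p.tol if tol is None else tol
    maxiter = p.maxiter if maxiter is None else maxiter
    h = grid.spacing
    nx, ny, nz = grid.shape

    if rho is None:
        rho = spread_charges(grid, pos, q)

    if isinstance(boundary, np.ndarray):
        phi_b = boundary
    elif callable(boundary):
        phi_b = np.zeros(grid.shape)
        bmask = np.zeros(grid.shape, dtype=bool)
        bmask[0], bmask[-1] = True, True
        bmask[:, 0], bmask[:, -1] = True, True
        bmask[:, :, 0], bmask[:, :, -1] = True, True
        idx = np.argwhere(bmask)
        coords = np.asarray(grid.origin) + idx * grid.spacing
        phi_b[tuple(idx.T)] = boundary(coords)
    elif boundary == "zero":
        phi_b = np.zeros(grid.shape)
    elif boundary == "dh":
        phi_b = _dh_boundary(grid, pos, q, p.eps_out, p.kappa)
    else:
        raise ValueError(f"unknown boundary rule {boundary!r}")

    interior = np.zeros(grid.shape, dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    n_int = int(interior.sum())
    num = -np.ones(grid.shape, dtype=np.int64)
    num[interior] = np.arange(n_int)

    diag = np.zeros(grid.shape)
    b = 4.0 * np.pi * rho / h
    rows, cols, vals = [], [], []
    for axis, eps in ((0, dmap.eps_x), (1, dmap.eps_y), (2, dmap.eps_z)):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        sl_a, sl_b = tuple(sl_a), tuple(sl_b)
        # every face couples node a (low side) and node b (high side)
        diag[sl_a] += eps
        diag[sl_b] += eps
        a_int = interior[sl_a]
        b_int = interior[sl_b]
        both = a_int & b_int
        rows.append(num[sl_a][both])
        cols.append(num[sl_b][both])
        vals.append(-eps[both])
        # interior node next to a Dirichlet node: move to the RHS
        tmp = np.zeros(grid.shape)
        tmp[sl_a] += np.where(a_int & ~b_int, eps * phi_b[sl_b], 0.0)
        tmp[sl_b] += np.where(b_int & ~a_int, eps * phi_b[sl_a], 0.0)
        b += tmp
    diag += h * h * dmap.kappa2_eps

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    d_int = diag[interior]
    A = coo_matrix(
        (np.concatenate([vals, vals, d_int]),
         (np.concatenate([rows, cols, np.arange(n_int)]),
          np.concatenate([cols, rows, np.arange(n_int)]))),
        shape=(n_int, n_int)).tocsr()
    rhs = b[interior]

    from scipy.sparse import diags
    M = diags(1.0 / d_int)
    x, info = cg(A, rhs, rtol=tol, maxiter=maxiter, M=M)
    res = float(np.linalg.norm(A @ x - rhs)
                / max(np.linalg.norm(rhs), 1e-300))
    if info != 0:
        raise ConvergenceError(
            f"LPB solver did not converge (info={info}, residual={res:.2e})",
            residuals=[res])
    phi = phi_b.copy()
    phi[interior] = x
    return PotentialGrid(grid, phi, residual=res,
                         provenance={"tol": tol, "boundary": str(type(
                             boundary).__name__ if not isinstance(
                                 boundary, str) else boundary)})


class FocusedPotential:
    """Potential hierarchy from grid focusing; evaluates on the finest
    level containing each query point."""

    def __init__(self, levels):
        self.levels = list(levels)          # coarse -> fine

    @property
    def finest(self) -> PotentialGrid:
        return self.levels[-1]

    def evaluate(self, points) -> np.ndarray:
        points = np.atleast_2d(points)
        out = np.full(len(points), np.nan)
        done = np.zeros(len(points), dtype=bool)
        for pg in reversed(self.levels):
            inside = pg.grid.contains(points, margin=0.5 * pg.grid.spacing)
            todo = inside & ~done
            if np.any(todo):
                out[todo] = pg.evaluate(points[todo])
                done |= todo
        if not np.all(done):
            raise ValueError("points outside the coarsest grid")
        return out


def focus_solve(diel_pos, diel_radii, source_pos, source_q,
                params: PBParams, roi_center=None, roi_half=None,
                uniform_eps: float | None = None,
                coarse_grid: GridSpec | None = None) -> FocusedPotential:
    """Three-level (by default) focused LPB solve.

    The coarsest grid encloses the dielectric-defining atoms and the
    sources with Debye-Hueckel boundaries; each finer cubic grid centers on
    the region of interest and takes Dirichlet boundary values from its
    parent.  ``uniform_eps`` produces a homogeneous-medium solve (used for
    reaction-field references).
    """
    source_pos = np.atleast_2d(source_pos)
    if roi_center is None:
        roi_center = source_pos.mean(axis=0)
    if roi_half is None:
        half = np.max(np.abs(source_pos - roi_center)) if len(source_pos) \
            else 0.0
        roi_half = half + params.roi_margin

    levels = list(params.levels)
    if coarse_grid is None:
        all_pts = np.vstack([np.atleast_2d(diel_pos), source_pos]) \
            if len(np.atleast_2d(diel_pos)) else source_pos
        all_r = np.concatenate([np.asarray(diel_radii, dtype=float),
                                np.zeros(len(source_pos))]) \
            if len(np.atleast_2d(diel_pos)) else np.zeros(len(source_pos))
        coarse_grid = grid_enclosing(all_pts, all_r, params.coarse_margin,
                                     levels[0])

    margins = np.linspace(params.mid_margin, params.roi_margin,
                          max(len(levels) - 1, 1))
    grids = [coarse_grid]
    for lev, marg in zip(levels[1:], margins):
        g = grid_centered(roi_center, roi_half + marg, lev)
        lo_p, hi_p = grids[-1].extent
        lo, hi = g.extent
        if np.any(lo < lo_p) or np.any(hi > hi_p):
            raise ValueError("focused grid is clipped by its parent level")
        grids.append(g)

    out = []
    parent = None
    for g in grids:
        dmap = build_dielectric_map(diel_pos, diel_radii, g, params,
                                    uniform_eps=uniform_eps)
        if parent is None:
            bc = "dh" if uniform_eps is None else _coulomb_bc(
                source_pos, source_q, uniform_eps)
            pg = solve_lpb(source_pos, source_q, dmap, boundary=bc)
        else:
            bmask = np.zeros(g.shape, dtype=bool)
            bmask[0], bmask[-1] = True, True
            bmask[:, 0], bmask[:, -1] = True, True
            bmask[:, :, 0], bmask[:, :, -1] = True, True
            idx = np.argwhere(bmask)
            coords = np.asarray(g.origin) + idx * g.spacing
            phi_b = np.zeros(g.shape)
            phi_b[tuple(idx.T)] = parent.evaluate(coords)
            pg = solve_lpb(source_pos, source_q, dmap, boundary=phi_b)
        out.append(pg)
        parent = pg
    return FocusedPotential(out)


def _coulomb_bc(pos, q, eps):
    pos = np.atleast_2d(pos)
    q = np.atleast_1d(q)

    def bc(coords):
        d = np.linalg.norm(coords[:, None, :] - pos[None], axis=2)
        d = np.maximum(d, 1e-6)
        return (q[None] / (eps * d)).sum(axis=1)
    return bc


def homogeneous_reference(grid: GridSpec, source_pos, source_q,
                          params: PBParams, eps: float) -> PotentialGrid:
    """Uniform-dielectric solve on a given grid with analytic Coulomb
    boundary values; used to cancel the grid self-energy."""
    dmap = build_dielectric_map(np.zeros((0, 3)), np.zeros(0), grid, params,
                                uniform_eps=eps)
    return solve_lpb(source_pos, source_q, dmap,
                     boundary=_coulomb_bc(source_pos, source_q, eps))


@dataclass
class ChargingEnergy:
    """Reaction-field and background terms of a state change, kcal/mol."""

    reaction_field: float
    background: float
    back_by_atom: np.ndarray | None = None

    @property
    def total(self) -> float:
        return self.reaction_field + self.background

    @property
    def total_mev(self) -> float:
        from .constants import MV_PER_KCAL
        return self.total * MV_PER_KCAL


def charging_energy(structure, site, state: int = 1,
                    environment: str = "protein",
                    params: PBParams | None = None) -> ChargingEnergy:
    """Reaction-field and background energies of one site state change.

    ``environment="protein"`` uses the full structure as the dielectric
    body with all non-member partial charges as background;
    ``"model_compound"`` places the site's member atoms alone in water with
    no background.  The difference of the two environments feeds the
    thermodynamic cycle for intrinsic pKa/Em values.
    """
    params = params or PBParams()
    pos = structure.positions[site.member_atoms]
    rad = structure.radii[site.member_atoms]
    dq = site.diff_charges(state)
    if environment == "protein":
        diel_pos, diel_rad = structure.positions, structure.radii
    elif environment == "model_compound":
        diel_pos, diel_rad = pos, rad
    else:
        raise ValueError(f"unknown environment {environment!r}")
    foc = focus_solve(diel_pos, diel_rad, pos, dq, params)
    hom = homogeneous_reference(foc.finest.grid, pos, dq, params,
                                params.eps_in)
    qsum = site.state_charges[state] + site.state_charges[0]
    rf = float(0.5 * COULOMB_KCAL
               * np.dot(qsum, foc.finest.evaluate(pos) - hom.evaluate(pos)))
    back_by_atom = np.zeros(structure.n_atoms)
    if environment == "protein":
        bg_q = structure.charges.copy()
        bg_q[site.member_atoms] = 0.0
        bg_idx = np.flatnonzero(bg_q != 0)
        if len(bg_idx):
            back_by_atom[bg_idx] = COULOMB_KCAL * bg_q[bg_idx] \
                * foc.evaluate(structure.positions[bg_idx])
    return ChargingEnergy(rf, float(back_by_atom.sum()), back_by_atom)


def reaction_field_energy(source_pos, source_q, diel_pos, diel_radii,
                          params: PBParams,
                          eps_in: float | None = None) -> float:
    """Reaction-field (solvation) energy of a charge set, kcal/mol.

    ``0.5 * sum_i q_i (phi_het - phi_hom)(r_i)`` with the homogeneous
    reference at the interior dielectric on the same finest grid, so the
    grid self-energy cancels exactly.  For an isolated charge in water this
    is the (negative) Born energy.
    """
    eps_in = params.eps_in if eps_in is None else eps_in
    foc = focus_solve(diel_pos, diel_radii, source_pos, source_q, params)
    hom = homogeneous_reference(foc.finest.grid, source_pos, source_q,
                                params, eps_in)
    pts = np.atleast_2d(source_pos)
    dphi = foc.finest.evaluate(pts) - hom.evaluate(pts)
    return float(0.5 * COULOMB_KCAL
                 * np.dot(np.atleast_1d(source_q), dphi))
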