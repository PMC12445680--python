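"""Em profiles along the membrane normal, shift decompositions and
conformer-ensemble spreads.

Each tryptophan-like redox site gets one :class:`EmRecord`: its computed
midpoint potential, the z-coordinate of its state-difference charge
centroid, and an exact-by-construction decomposition

    Em - Em_ref = solvation_shift + charge_shift + residual

where the solvation shift is the reaction-field ("solvation loss") term
with all protein partial charges zeroed, the charge shift collects the
interaction of the site's ox-minus-red charges with the background charges
and the equilibrium-average charges of the other titratable sites, and the
residual reports whatever nonlinearity coupled titration introduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import MV_PER_KCAL
from .pb import PBParams
from .titration import (SiteEnergetics, TitrationConditions,
                        compute_site_energetics, em_midpoint,
                        enumerate_exact)


@dataclass
class EmRecord:
    """One redox site's midpoint potential and its decomposition (mV)."""

    site_id: str
    em_mv: float
    z: float
    em_ref_mv: float
    solvation_shift_mv: float
    charge_shift_mv: float
    residual_mv: float
    per_residue_mv: dict = field(default_factory=dict)
    ok: bool = True

    @property
    def total_shift_mv(self) -> float:
        return self.em_mv - self.em_ref_mv


@dataclass
class EnsembleEm:
    """Mean Em and maximum signed deviation over a conformer ensemble."""

    site_id: str
    mean_mv: float
    max_dev_mv: float
    n_conformers: int
    per_conformer_mv: np.ndarray = None

    def __post_init__(self):
        if self.max_dev_mv < 0:
            raise ValueError("deviation must be non-negative")

    def __str__(self):
        return f"{self.site_id}: {self.mean_mv:.0f} " \
               f"(±{self.max_dev_mv:.0f}) mV"


def _site_z(structure, site) -> float:
    """z of the |ox-minus-red|-charge-weighted site centroid."""
    dq = np.abs(site.diff_charges(1))
    z = structure.positions[site.member_atoms, 2]
    return float((dq * z).sum() / dq.sum()) if dq.sum() > 0 \
        else float(z.mean())


def decompose_shift(energetics: SiteEnergetics, site_id: str,
                    em_mv: float,
                    cond: TitrationConditions | None = None) -> dict:
    """Split one redox site's Em shift into solvation and charge terms.

    Populations of the other sites are evaluated with the bias potential
    set to the site's midpoint, so the charge term reflects the charge
    state of the protein in equilibrium with the half-oxidized site.
    """
    cond = cond or TitrationConditions()
    i = energetics.index(site_id)
    detail = energetics.details["per_state"][
        (site_id, energetics.details["state_labels"][i][1])]
    em_ref = _reference_em(energetics, i)
    solv_mv = detail["solvation_kcal"] * MV_PER_KCAL
    pops = enumerate_exact(
        energetics, TitrationConditions(cond.pH, em_mv, cond.temperature,
                                        cond.ionic_strength))
    w_term = 0.0
    for j in range(energetics.n_sites):
        if j == i:
            continue
        for l in range(energetics.n_states[j]):
            w_term += pops.occupancies[j, l] * energetics.W[i, j, 1, l]
    charge_mv = (detail["background_kcal"] + w_term) * MV_PER_KCAL
    residual = em_mv - em_ref - solv_mv - charge_mv
    return {"em_ref_mv": em_ref, "solvation_shift_mv": solv_mv,
            "charge_shift_mv": charge_mv, "residual_mv": residual,
            "populations": pops}


def _reference_em(energetics, i) -> float:
    detail = energetics.details["per_state"][
        (energetics.site_ids[i], energetics.details["state_labels"][i][1])]
    em_intr = energetics.state_kinds[i][1][1]
    return em_intr - detail["ddg_kcal"] * MV_PER_KCAL


def per_residue_contributions(structure, energetics: SiteEnergetics,
                              site_id: str, populations) -> dict:
    """Per-residue breakdown (mV) of one site's charge shift.

    Background (non-titrating) charges contribute through the stored
    per-atom interaction terms grouped by residue; titratable residues
    contribute their equilibrium-average coupling.  The values sum to the
    charge shift of :func:`decompose_shift` to within numerical precision.
    """
    i = energetics.index(site_id)
    detail = energetics.details["per_state"][
        (site_id, energetics.details["state_labels"][i][1])]
    out = {}
    back = detail["back_by_atom"]
    for a in np.flatnonzero(back != 0):
        key = (f"{structure.residue_name[a]}-{structure.chain_id[a]}:"
               f"{structure.residue_number[a]}")
        out[key] = out.get(key, 0.0) + back[a] * MV_PER_KCAL
    for j in range(energetics.n_sites):
        if j == i:
            continue
        w = sum(populations.occupancies[j, l] * energetics.W[i, j, 1, l]
                for l in range(energetics.n_states[j]))
        key = energetics.site_ids[j]
        out[key] = out.get(key, 0.0) + w * MV_PER_KCAL
    return out


def em_profile(structure, sites, params: PBParams | None = None,
               cond: TitrationConditions | None = None,
               energetics: SiteEnergetics | None = None) -> list:
    """Compute one :class:`EmRecord` per redox site, sorted by z.

    A site whose midpoint search fails is returned flagged (``ok=False``)
    with NaN values so the rest of the profile survives.
    """
    params = params or PBParams()
    cond = cond or TitrationConditions()
    if energetics is None:
        energetics = compute_site_energetics(structure, sites, params)
    records = []
    for site in sites:
        if site.kind != "redox":
            continue
        z = _site_z(structure, site)
        try:
            em = em_midpoint(energetics, site.site_id, cond=cond)
            d = decompose_shift(energetics, site.site_id, em, cond)
            pr = per_residue_contributions(structure, energetics,
                                           site.site_id, d["populations"])
            records.append(EmRecord(site.site_id, em, z, d["em_ref_mv"],
                                    d["solvation_shift_mv"],
                                    d["charge_shift_mv"], d["residual_mv"],
                                    pr))
        except ValueError:
            records.append(EmRecord(site.site_id, np.nan, z, np.nan,
                                    np.nan, np.nan, np.nan, {}, ok=False))
    records.sort(key=lambda r: r.z)
    return records


def profile_table(records) -> pd.DataFrame:
    """Plot-ready Em-vs-z table."""
    return pd.DataFrame(
        [{"site_id": r.site_id, "z": r.z, "em_mv": r.em_mv,
          "em_ref_mv": r.em_ref_mv,
          "solvation_shift_mv": r.solvation_shift_mv,
          "charge_shift_mv": r.charge_shift_mv,
          "residual_mv": r.residual_mv, "ok": r.ok}
         for r in records])


def ensemble_em(structure, sites, params: PBParams | None = None,
                cond: TitrationConditions | None = None) -> list:
    """Per-site mean Em and maximum signed deviation over conformers.

    The structure's conformer list (falling back to the base coordinates
    alone) is evaluated one conformation at a time; results are formatted
    "mean (±dev) mV".  All conformers share the base topology by
    construction of :class:`~pbem.structure.Structure`.
    """
    params = params or PBParams()
    cond = cond or TitrationConditions()
    coord_sets = structure.conformers or [structure.positions]
    ems = {s.site_id: [] for s in sites if s.kind == "redox"}
    for coords in coord_sets:
        st = structure.with_positions(coords)
        eng = compute_site_energetics(st, sites, params)
        for s in sites:
            if s.kind != "redox":
                continue
            ems[s.site_id].append(
                em_midpoint(eng, s.site_id, cond=cond))
    out = []
    for site_id, vals in ems.items():
        vals = np.asarray(vals)
        mean = float(vals.mean())
        dev = float(np.abs(vals - mean).max())
        out.append(EnsembleEm(site_id, mean, dev, len(vals), vals))
    return out
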