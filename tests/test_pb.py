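"""Finite-difference LPB solver against analytic electrostatics oracles."""

import numpy as np
import pytest

from pbem.constants import COULOMB_KCAL, debye_length
from pbem.pb import (ConvergenceError, GridSpec, PBParams, _coulomb_bc,
                     _inside_mask, build_dielectric_map, charging_energy,
                     focus_solve, grid_enclosing, reaction_field_energy,
                     solve_lpb, spread_charges)
from pbem.structure import AtomRecord, Structure, TitratableSite
from pbem.titration import interaction_energy

from conftest import BORN_ANALYTIC, kirkwood_series

ORIGIN = np.array([[0.0, 0.0, 0.0]])
UNIT_Q = np.array([1.0])


class TestDebye:
    def test_zero_ionic_strength_means_no_screening(self):
        assert debye_length(0.0) == np.inf
        assert PBParams(ionic_strength=0.0).kappa == 0.0

    def test_100mM_room_temperature_length(self):
        # closed form lambda_D(nm) = 0.304 / sqrt(I) for water at 298 K
        assert debye_length(0.1, 298.0, 80.0) == pytest.approx(9.6, rel=0.02)

    def test_inverse_sqrt_scaling(self):
        assert debye_length(0.4) == pytest.approx(debye_length(0.1) / 2.0)

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            debye_length(-0.1)


class TestGrid:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            GridSpec((0, 0, 0), -1.0, (10, 10, 10))
        with pytest.raises(ValueError):
            GridSpec((0, 0, 0), 1.0, (4, 10, 10))

    def test_charge_spreading_conserves_charge(self):
        g = GridSpec((-5, -5, -5), 1.0, (11, 11, 11))
        rho = spread_charges(g, np.array([[0.3, -0.2, 1.7]]), UNIT_Q)
        assert rho.sum() == pytest.approx(1.0)

    def test_inside_mask_volume_matches_analytic_sphere(self):
        # protein-node count of a Born sphere vs volume / voxel volume
        m = _inside_mask((-3, -3, -3), (0.3, 0.3, 0.3), (21, 21, 21),
                         ORIGIN, np.array([2.0]))
        expected = 4.0 / 3.0 * np.pi * 8.0 / 0.3 ** 3
        assert m.sum() == pytest.approx(expected, rel=0.05)


class TestSolver:
    def test_coulomb_potential_in_uniform_water(self):
        p = PBParams(eps_in=80.0, eps_out=80.0, ionic_strength=0.0)
        g = grid_enclosing(ORIGIN, np.array([0.0]), margin=20, spacing=1.0)
        dmap = build_dielectric_map(np.zeros((0, 3)), np.zeros(0), g, p,
                                    uniform_eps=80.0)
        pg = solve_lpb(ORIGIN, UNIT_Q, dmap,
                       boundary=_coulomb_bc(ORIGIN, UNIT_Q, 80.0))
        phi = pg.evaluate(np.array([[10.0, 0.0, 0.0]]))[0] * COULOMB_KCAL
        assert phi == pytest.approx(332.064 / (80.0 * 10.0), rel=0.02)

    def test_potential_linear_in_charges(self):
        p = PBParams(ionic_strength=0.1)
        g = GridSpec((-10, -10, -10), 2.0, (11, 11, 11))
        dmap = build_dielectric_map(ORIGIN, np.array([2.0]), g, p)
        pg1 = solve_lpb(ORIGIN, UNIT_Q, dmap, boundary="dh")
        pg2 = solve_lpb(ORIGIN, 2.0 * UNIT_Q, dmap, boundary="dh")
        assert np.allclose(pg2.values, 2.0 * pg1.values, rtol=1e-5,
                           atol=1e-12)

    def test_convergence_error_carries_residual(self):
        p = PBParams()
        g = GridSpec((-10, -10, -10), 2.0, (11, 11, 11))
        dmap = build_dielectric_map(ORIGIN, np.array([2.0]), g, p)
        with pytest.raises(ConvergenceError) as exc:
            solve_lpb(ORIGIN, UNIT_Q, dmap, boundary="dh", maxiter=2)
        assert exc.value.residuals

    def test_coverage_check(self):
        p = PBParams()
        g = GridSpec((-3, -3, -3), 1.0, (8, 8, 8))
        with pytest.raises(ValueError, match="cover"):
            build_dielectric_map(ORIGIN, np.array([5.0]), g, p,
                                 check_coverage=True)


class TestDxExport:
    def test_written_grid_round_trips(self, tmp_path):
        from pbem.pb import PotentialGrid
        g = GridSpec((-2.0, -2.0, -2.0), 0.5, (9, 9, 9))
        values = np.arange(9 ** 3, dtype=float).reshape(9, 9, 9) / 100.0
        path = tmp_path / "phi.dx"
        PotentialGrid(g, values).write_dx(path)
        text = path.read_text()
        assert "object 1 class gridpositions counts 9 9 9" in text
        assert f"items {9 ** 3} data follows" in text
        data = []
        for line in text.splitlines():
            parts = line.split()
            if parts and all(_is_float(p) for p in parts) \
                    and not line.startswith(("origin", "delta")):
                data.extend(float(p) for p in parts)
        assert np.allclose(np.array(data).reshape(9, 9, 9), values)


def _is_float(tok):
    try:
        float(tok)
        return True
    except ValueError:
        return False


class TestDielectricMap:
    def test_probe_far_from_atoms_is_water_and_accessible(self):
        p = PBParams(ionic_strength=0.1)
        g = GridSpec((-40, -40, -40), 2.5, (33, 33, 33))
        dmap = build_dielectric_map(ORIGIN, np.array([2.0]), g, p)
        # corner node, 30+ Å from the atom
        assert dmap.eps_x[0, 0, 0] == pytest.approx(80.0)
        assert dmap.kappa2_eps[0, 0, 0] > 0

    def test_center_of_large_atom_is_protein_and_excluded(self):
        p = PBParams(ionic_strength=0.1)
        g = GridSpec((-20, -20, -20), 1.0, (41, 41, 41))
        dmap = build_dielectric_map(ORIGIN, np.array([10.0]), g, p)
        c = 20
        assert dmap.eps_x[c, c, c] == pytest.approx(4.0)
        assert dmap.kappa2_eps[c, c, c] == 0.0

    def test_stern_layer_extends_ion_exclusion(self):
        p = PBParams(ionic_strength=0.1, stern=2.0)
        g = GridSpec((-10, -10, -10), 1.0, (21, 21, 21))
        dmap = build_dielectric_map(ORIGIN, np.array([2.0]), g, p)
        # node at 3 Å: outside the 2 Å atom, inside atom+stern
        assert dmap.kappa2_eps[13, 10, 10] == 0.0
        assert dmap.kappa2_eps[17, 10, 10] > 0


class TestBornKirkwood:
    def test_born_reaction_field_within_2pct(self, born_energy):
        assert born_energy == pytest.approx(BORN_ANALYTIC, rel=0.02)

    def test_kirkwood_off_center_within_3pct(self, kirkwood_energy):
        expected = kirkwood_series(1.0, 5.0, 1.0, 4.0, 80.0)
        assert kirkwood_energy == pytest.approx(expected, rel=0.03)

    def test_sign_symmetric_in_charge(self):
        p = PBParams(eps_in=1.0, eps_out=80.0, ionic_strength=0.0,
                     levels=(2.5, 1.0))
        em = reaction_field_energy(ORIGIN, -UNIT_Q, ORIGIN,
                                   np.array([2.0]), p, eps_in=1.0)
        ep = reaction_field_energy(ORIGIN, UNIT_Q, ORIGIN,
                                   np.array([2.0]), p, eps_in=1.0)
        assert em == pytest.approx(ep, rel=1e-6)

    def test_grid_translation_robustness(self):
        # shifting the whole system by half a coarse voxel: < 1% change
        p = PBParams(eps_in=1.0, eps_out=80.0, ionic_strength=0.0)
        shift = np.array([[1.25, 1.25, 1.25]])
        e0 = reaction_field_energy(ORIGIN, UNIT_Q, ORIGIN,
                                   np.array([2.0]), p, eps_in=1.0)
        e1 = reaction_field_energy(ORIGIN + shift, UNIT_Q, ORIGIN + shift,
                                   np.array([2.0]), p, eps_in=1.0)
        assert abs(e1 - e0) / abs(e0) < 0.01

    def test_refining_finest_level_changes_little(self):
        p2 = PBParams(eps_in=1.0, eps_out=80.0, ionic_strength=0.0,
                      levels=(2.5, 1.0, 0.2))
        e02 = reaction_field_energy(ORIGIN, UNIT_Q, ORIGIN,
                                    np.array([2.0]), p2, eps_in=1.0)
        p3 = PBParams(eps_in=1.0, eps_out=80.0, ionic_strength=0.0)
        e03 = reaction_field_energy(ORIGIN, UNIT_Q, ORIGIN,
                                    np.array([2.0]), p3, eps_in=1.0)
        assert abs(e02 - e03) < 1.0

    def test_solvation_loss_sign(self):
        # creating a charge is more favourable in water than in a cavity
        p = PBParams(ionic_strength=0.0, levels=(2.5, 1.0))
        water = reaction_field_energy(ORIGIN, UNIT_Q, ORIGIN,
                                      np.array([2.0]), p)
        blob = np.vstack([ORIGIN[0] + d for d in
                          [(0, 0, 0), (3, 0, 0), (-3, 0, 0), (0, 3, 0),
                           (0, -3, 0), (0, 0, 3), (0, 0, -3)]])
        cavity = reaction_field_energy(ORIGIN, UNIT_Q, blob,
                                       np.full(7, 3.0), p)
        assert water < cavity < 0


class TestFocusing:
    def test_uniform_dielectric_focusing_is_self_consistent(self):
        # focused potential equals the analytic Coulomb limit within 1%
        p = PBParams(eps_in=80.0, eps_out=80.0, ionic_strength=0.0)
        foc = focus_solve(ORIGIN, np.array([0.0]), ORIGIN, UNIT_Q, p,
                          uniform_eps=80.0)
        probe = np.array([[4.0, 0.0, 0.0]])
        phi = foc.evaluate(probe)[0]
        assert phi == pytest.approx(1.0 / (80.0 * 4.0), rel=0.01)

    def test_clipped_roi_rejected(self):
        p = PBParams(coarse_margin=2.0, mid_margin=40.0)
        with pytest.raises(ValueError, match="clipped"):
            focus_solve(ORIGIN, np.array([2.0]), ORIGIN, UNIT_Q, p)


def _two_site_structure(separation, radius=0.0):
    atoms = [AtomRecord(1, "O", "PSA", "A", 1, np.zeros(3), 0.0, radius),
             AtomRecord(2, "O", "PSA", "A", 2,
                        np.array([separation, 0.0, 0.0]), 0.0, radius)]
    st = Structure(atoms)
    mk = lambda i: TitratableSite(f"S{i}", "base", [i - 1],
                                  ["deprotonated", "protonated"],
                                  np.array([[0.0], [1.0]]),
                                  {"protonated": 7.0})
    return st, mk(1), mk(2)


class TestInteraction:
    def test_unscreened_coulomb_at_5A(self):
        st, a, b = _two_site_structure(5.0)
        p = PBParams(ionic_strength=0.0, levels=(2.5, 1.0, 0.3))
        w = interaction_energy(st, a, b, p)
        assert w == pytest.approx(332.064 / (80.0 * 5.0), rel=0.02)

    def test_reciprocity_before_symmetrization(self):
        st, a, b = _two_site_structure(6.0, radius=1.5)
        p = PBParams(ionic_strength=0.0, levels=(2.5, 1.0))
        vals = []
        for s1, s2 in ((a, b), (b, a)):
            foc = focus_solve(st.positions, st.radii,
                              st.positions[s1.member_atoms],
                              s1.diff_charges(1), p)
            vals.append(COULOMB_KCAL * float(
                foc.evaluate(st.positions[s2.member_atoms])[0]))
        assert abs(vals[0] - vals[1]) / abs(np.mean(vals)) < 0.05

    def test_screened_to_negligible_at_60A(self):
        st, a, b = _two_site_structure(60.0)
        p = PBParams(ionic_strength=0.1, levels=(2.5,))
        w = interaction_energy(st, a, b, p)
        assert abs(w) < 0.01

    def test_shared_atoms_rejected(self):
        st, a, _ = _two_site_structure(5.0)
        with pytest.raises(ValueError, match="share"):
            interaction_energy(st, a, a, PBParams())


class TestChargingEnergy:
    def test_cycle_closure_for_lone_site(self):
        # "protein" consisting of the site alone: both environments agree
        st, a, _ = _two_site_structure(50.0, radius=1.7)
        st1 = st.subset([0])
        site = TitratableSite("S1", "base", [0],
                              ["deprotonated", "protonated"],
                              np.array([[0.0], [1.0]]), {"protonated": 7.0})
        p = PBParams(ionic_strength=0.0, levels=(2.5, 1.0))
        prot = charging_energy(st1, site, environment="protein", params=p)
        model = charging_energy(st1, site, environment="model_compound",
                                params=p)
        assert prot.reaction_field == pytest.approx(model.reaction_field,
                                                    abs=1e-9)
        assert prot.background == 0.0 == model.background

    def test_background_coulomb_at_10A(self):
        atoms = [AtomRecord(1, "O", "PSA", "A", 1, np.zeros(3), 0.0, 0.0),
                 AtomRecord(2, "Q", "BGC", "A", 2,
                            np.array([10.0, 0.0, 0.0]), 1.0, 0.0)]
        st = Structure(atoms)
        site = TitratableSite("S1", "base", [0],
                              ["deprotonated", "protonated"],
                              np.array([[0.0], [1.0]]), {"protonated": 7.0})
        p = PBParams(ionic_strength=0.0, levels=(2.5, 1.0, 0.3))
        ce = charging_energy(st, site, environment="protein", params=p)
        assert ce.background == pytest.approx(332.064 / (80.0 * 10.0),
                                              rel=0.02)
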