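"""Shared fixtures.  Expensive PB computations are session-scoped so the
unit and acceptance layers share one solve."""

import numpy as np
import pytest

from pbem.pb import PBParams, reaction_field_energy
from pbem.redox import em_profile
from pbem.structure import AtomRecord, Structure, TitratableSite
from pbem.synth import make_coupled_redox_proton, make_layered_protein
from pbem.titration import (TitrationConditions, compute_site_energetics,
                            em_midpoint)

BORN_ANALYTIC = -0.5 * 332.064 / 2.0 * (1.0 - 1.0 / 80.0)   # q=1, a=2 Å


def kirkwood_series(q, a, r, eps_in, eps_out, lmax=80):
    """Reaction-field energy of a charge r off-center in a sphere of
    radius a (kcal/mol), truncated Kirkwood expansion."""
    s = 0.0
    for l in range(lmax + 1):
        s += ((eps_out - eps_in) * (l + 1)
              / (eps_in * ((l + 1) * eps_out + l * eps_in))) * (r / a) ** (2 * l)
    return -0.5 * 332.064 * q * q / a * s


@pytest.fixture(scope="session")
def born_energy():
    """PB reaction-field energy of the q=1, a=2 Å Born ion (eps 1->80)."""
    p = PBParams(eps_in=1.0, eps_out=80.0, ionic_strength=0.0)
    pos = np.array([[0.0, 0.0, 0.0]])
    return reaction_field_energy(pos, np.array([1.0]), pos,
                                 np.array([2.0]), p, eps_in=1.0)


@pytest.fixture(scope="session")
def kirkwood_energy():
    """PB reaction-field energy, charge 1 Å off-center in a 5 Å eps=4
    sphere in water."""
    p = PBParams(eps_in=4.0, eps_out=80.0, ionic_strength=0.0)
    return reaction_field_energy(np.array([[1.0, 0.0, 0.0]]),
                                 np.array([1.0]),
                                 np.array([[0.0, 0.0, 0.0]]),
                                 np.array([5.0]), p)


def single_acid_structure(pka_ref=4.4):
    """One Glu-like acid model compound alone in water."""
    atom = AtomRecord(1, "O", "PSA", "A", 1, np.zeros(3), 0.0, 1.7)
    st = Structure([atom])
    site = TitratableSite("PSA-A:1", "acid", [0],
                          ["deprotonated", "protonated"],
                          np.array([[-1.0], [0.0]]),
                          {"protonated": pka_ref})
    return st, [site]


def lone_probe_structure():
    """A single pseudo-indole redox probe alone in water."""
    from pbem.synth import _probe_atoms, _probe_site
    atoms = _probe_atoms((0.0, 0.0, 0.0), 1, 1)
    st = Structure(atoms)
    return st, [_probe_site(st, "P", 1)]


@pytest.fixture(scope="session")
def coupled():
    """Coupled redox-proton fixture with PB energetics."""
    st, sites = make_coupled_redox_proton(seed=0)
    eng = compute_site_energetics(st, sites, PBParams())
    return st, sites, eng


@pytest.fixture(scope="session")
def coupled_ems(coupled):
    """Em of the coupled fixture's probe at pH 6, 7, 8, 9."""
    _, _, eng = coupled
    return {ph: em_midpoint(eng, "TRX-P:2",
                            cond=TitrationConditions(pH=ph))
            for ph in (6.0, 7.0, 8.0, 9.0)}


@pytest.fixture(scope="session")
def layered():
    """Layered membrane fixture with PB energetics."""
    st, sites = make_layered_protein(seed=1)
    eng = compute_site_energetics(st, sites, PBParams())
    return st, sites, eng


@pytest.fixture(scope="session")
def layered_records(layered):
    st, sites, eng = layered
    return em_profile(st, sites, PBParams(), energetics=eng)


@pytest.fixture(scope="session")
def lone_probe_record():
    """Em profile of the solvent-exposed probe with no environment."""
    st, sites = lone_probe_structure()
    return em_profile(st, sites, PBParams())[0]
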