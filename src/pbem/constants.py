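"""Physical constants and unit conversions.

Internal conventions
--------------------
* lengths in Å, charges in elementary charges (e)
* electrostatic potentials ``phi`` solve ``div(eps grad phi) = -4 pi rho``
  with ``rho`` in e/Å^3, so that the energy of a charge ``q`` at potential
  ``phi`` is ``COULOMB_KCAL * q * phi`` in kcal/mol
* free energies in kcal/mol; midpoint potentials in mV vs NHE
"""

import numpy as np

#: Coulomb constant e^2/(4 pi eps0) expressed in kcal·Å/(mol·e^2).
COULOMB_KCAL = 332.064

#: kcal/mol per meV for a one-electron process (1 eV = 23.0605 kcal/mol).
KCAL_PER_MEV = 0.0230605

#: mV shift per kcal/mol for a one-electron process.
MV_PER_KCAL = 1.0 / KCAL_PER_MEV  # 43.364

#: Gas constant in kcal/(mol·K).
R_KCAL = 1.9872041e-3

#: Default temperature (K).
T_DEFAULT = 300.0

#: RT·ln10 at 300 K (kcal/mol); 1.377 kcal/mol = 59.5 meV.
RT_LN10_300 = R_KCAL * T_DEFAULT * np.log(10.0)

#: Boltzmann constant in eV/K.
KB_EV = 8.617333e-5

#: kT at 300 K in eV.
KT_EV_300 = KB_EV * 300.0  # 0.02585

#: Conversion from the internal potential unit (e/Å, Gaussian-style) to volts.
VOLT_PER_PHI = 14.39964

#: Vacuum permittivity route to the Debye length: lambda_D in Å for
#: ionic strength I (mol/L), temperature T (K) and relative dielectric eps.
def debye_length(ionic_strength: float, temperature: float = T_DEFAULT,
                 eps: float = 80.0) -> float:
    """Debye screening length in Å; infinite at zero ionic strength."""
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    if ionic_strength == 0:
        return np.inf
    # lambda_D = sqrt(eps0 eps kB T / (2 NA e^2 I)) with I in mol/m^3
    eps0 = 8.8541878128e-12
    kb = 1.380649e-23
    na = 6.02214076e23
    e = 1.602176634e-19
    i_si = ionic_strength * 1000.0
    lam_m = np.sqrt(eps0 * eps * kb * temperature / (2.0 * na * e * e * i_si))
    return lam_m * 1e10


def rt_ln10(temperature: float = T_DEFAULT) -> float:
    """RT ln 10 in kcal/mol at the given temperature."""
    return R_KCAL * temperature * np.log(10.0)


def nernst_slope_mv(temperature: float = T_DEFAULT) -> float:
    """RT ln10 / F in mV: the Nernstian Em-vs-pH slope magnitude."""
    return rt_ln10(temperature) * MV_PER_KCAL
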