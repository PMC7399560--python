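"""Physical constants and unit conversions used throughout the package.

Internal unit policy: lengths in nm, energies in kT, angles in radians.
Outputs follow liquid-crystal conventions: twist densities in turns/um,
writhe densities in 1/mm, pitches in um, mass concentrations in g/L.
"""

#: oxDNA length unit in nm (applied exactly once, on file read/write).
OXDNA_LENGTH_NM = 0.8518

#: Rise per base pair of B-DNA, nm.
RISE_NM = 0.34

#: Equilibrium helical repeat of unconfined B-DNA, bp per turn.
BP_PER_TURN = 10.5

#: Reference duplex twist density Tw0 = 1/(10.5 bp * 0.34 nm/bp), turns/nm.
TW0_TURNS_PER_NM = 1.0 / (BP_PER_TURN * RISE_NM)

#: Molar mass of one base pair, Da (g/mol).
BP_MASS_DA = 650.0

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Elementary charge, C.
E_CHARGE = 1.602176634e-19

#: Boltzmann constant, J/K.
K_BOLTZMANN = 1.380649e-23

#: Vacuum permittivity, F/m.
EPSILON_0 = 8.8541878128e-12

#: Relative permittivity of water near room temperature.
WATER_EPS_R = 80.1

# Unit conversions
TURNS_PER_NM_TO_TURNS_PER_UM = 1.0e3
PER_NM_TO_PER_MM = 1.0e6
#: rho [1/nm^3] * M [Da] * DA_PER_NM3_TO_G_PER_L = c [g/L]
DA_PER_NM3_TO_G_PER_L = 1.66053906660


def bjerrum_length_nm(temperature_k: float = 293.0,
                      eps_r: float = WATER_EPS_R) -> float:
    """Bjerrum length e^2 / (4 pi eps0 eps_r kT) in nm."""
    import math
    lb_m = E_CHARGE ** 2 / (
        4.0 * math.pi * EPSILON_0 * eps_r * K_BOLTZMANN * temperature_k)
    return lb_m * 1e9
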