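"""Physical constants pinned to CODATA 2018 exact values.

All quantities surfaced by this package use a single unit convention:
distances in nm, energies in kJ/mol, charges in units of the elementary
charge e, temperatures in K, concentrations in mol/L at the interface.
"""

#: elementary charge, C
E_CHARGE = 1.602176634e-19
#: Boltzmann constant, J/K
K_B = 1.380649e-23
#: Avogadro constant, 1/mol
N_A = 6.02214076e23
#: vacuum permittivity, F/m
EPS_0 = 8.8541878128e-12
#: molar gas constant, kJ/(mol K)
R_GAS = K_B * N_A * 1e-3  # 8.31446261815324e-3

#: default simulation temperature, K
T_DEFAULT = 300.0


def kt_kj_mol(temperature: float) -> float:
    """Thermal energy RT in kJ/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return R_GAS * temperature
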