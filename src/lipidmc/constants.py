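"""Physical constants and unit conversions.

Internal units: length in nm, charge in elementary charges e, energy in
units of kB*T at the configured temperature.  This makes the Metropolis
exponent exp(-dE) parameter-free.
"""

#: e^2 / (4 pi eps0) in eV * nm
COULOMB_EV_NM = 1.4399645

#: Boltzmann constant in eV / K
KB_EV_PER_K = 8.617333262e-5

#: 1 gauss in mT
GAUSS_TO_MT = 0.1


def coulomb_prefactor_kT_nm(temperature_K: float) -> float:
    """e^2/(4 pi eps0) expressed in kB*T * nm at the given temperature.

    At 295 K this is ~56.6 kBT*nm, so two unit charges 1 nm apart in a
    medium with relative permittivity 80 interact with ~0.71 kBT.
    """
    if temperature_K <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_K}")
    return COULOMB_EV_NM / (KB_EV_PER_K * temperature_K)
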