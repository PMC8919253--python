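"""Project-wide unit system: Å, fs, eV, u, elementary charge.

Conversion factors live here and nowhere else; all dynamics code works in
these units internally.
"""

#: 1 u·Å²/fs² in eV (kinetic-energy conversion).
EV_PER_U_A2_FS2 = 103.642696562

#: Acceleration conversion: a [Å/fs²] = F [eV/Å] / m [u] * ACC_CONV.
ACC_CONV = 1.0 / EV_PER_U_A2_FS2

#: Boltzmann constant, eV/K.
KB = 8.617333262e-5

#: Coulomb constant, eV·Å/e².
COULOMB_K = 14.3996


def kinetic_energy(masses, velocities) -> float:
    """Kinetic energy in eV from masses (u) and velocities (Å/fs)."""
    return 0.5 * float((masses * (velocities**2).sum(axis=-1)).sum()) * EV_PER_U_A2_FS2


def kinetic_temperature(masses, velocities) -> float:
    """Instantaneous kinetic temperature (K), 3N degrees of freedom."""
    n = len(masses)
    return 2.0 * kinetic_energy(masses, velocities) / (3.0 * n * KB)
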