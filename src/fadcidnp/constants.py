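"""Physical constants and unit conversions.

All spin Hamiltonian terms are handled internally in angular frequency
units (rad s^-1).  Couplings quoted in millitesla -- the conventional unit
for hyperfine and exchange couplings in spin chemistry -- are converted via
the free-electron gyromagnetic ratio.
"""

# Bohr magneton over hbar, rad s^-1 T^-1
MU_B_OVER_HBAR = 9.2740100783e-24 / 1.054571817e-34

# free-electron g factor, used for the mT -> rad/s coupling conversion
G_E = 2.00231930436

# electron gyromagnetic ratio (magnitude), rad s^-1 T^-1
GAMMA_E = G_E * MU_B_OVER_HBAR

# proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA_H = 2.6752218744e8

# nm^2 per cm^2 (diffusion coefficients are quoted in cm^2/s, distances in nm)
NM2_PER_CM2 = 1.0e14


def mT_to_angular(x_mT: float) -> float:
    """Convert a coupling quoted in mT to angular frequency (rad/s)."""
    return GAMMA_E * x_mT * 1.0e-3


def angular_to_mT(w: float) -> float:
    """Inverse of :func:`mT_to_angular`."""
    return w / (GAMMA_E * 1.0e-3)
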