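"""Independent dense brute-force resolvent oracle.

Rebuilds the full stochastic-Liouville generator on a 2-node radial grid
from first principles, without any of the package's superoperator
machinery: individual product-state nuclei instead of collective bath
sectors, no zero-quantum reduction, and the generator realized column by
column by applying the equation of motion to basis matrices.  Used to
validate the production solver to high accuracy.
"""

import numpy as np

from fadcidnp.constants import GAMMA_E, MU_B_OVER_HBAR, NM2_PER_CM2, mT_to_angular
from fadcidnp.spin_sim import BiradicalModel, exchange_coupling

_s = {
    "x": np.array([[0, 0.5], [0.5, 0]], dtype=complex),
    "y": np.array([[0, -0.5j], [0.5j, 0]], dtype=complex),
    "z": np.array([[0.5, 0], [0, -0.5]], dtype=complex),
}
_i2 = np.eye(2, dtype=complex)


def _op(which, slot, n_slots):
    mats = [_i2] * n_slots
    mats[slot] = _s[which]
    out = mats[0]
    for m in mats[1:]:
        out = np.kron(out, m)
    return out


def dense_oracle_polarization(B, model: BiradicalModel, r_nodes, weights):
    """(geminate, escape) polarization on a 2-node grid, dense resolvent.

    The additional nuclei are individual spins-1/2 in the product basis
    (n_add <= 2 keeps the dense solve small).
    """
    spins, exch, kin = model.spins, model.exchange, model.kinetics
    n_add = int(spins.n_add)
    n_slots = 3 + n_add  # electron a, electron b, observed nucleus, bath spins
    d = 2**n_slots
    SA = [_op(k, 0, n_slots) for k in "xyz"]
    SB = [_op(k, 1, n_slots) for k in "xyz"]
    IN = [_op(k, 2, n_slots) for k in "xyz"]
    baths = [[_op(k, 3 + j, n_slots) for k in "xyz"] for j in range(n_add)]
    E = np.eye(d, dtype=complex)
    SASB = sum(SA[i] @ SB[i] for i in range(3))
    Qs = 0.25 * E - SASB
    a = mT_to_angular(spins.A)
    a_add = mT_to_angular(spins.A_add)

    def hamiltonian(r):
        J = mT_to_angular(float(exchange_coupling(r, exch)))
        H = (
            spins.ga * MU_B_OVER_HBAR * B * SA[2]
            + spins.gb * MU_B_OVER_HBAR * B * SB[2]
            + a * sum(SA[i] @ IN[i] for i in range(3))
            - J * (0.5 * E + 2.0 * SASB)
        )
        for bath in baths:
            H = H + a_add * sum(SB[i] @ bath[i] for i in range(3))
        return H

    H0, H1 = hamiltonian(r_nodes[0]), hamiltonian(r_nodes[1])
    # relaxation rates: bi-Lorentzian local-field spectral density
    w_e = GAMMA_E * B
    k1 = sum(
        (kin.G / 3.0) * tau / (1.0 + (w_e * tau) ** 2) for tau in (kin.tau_u, kin.tau_rot)
    )
    kz = sum((kin.G / 3.0) * tau for tau in (kin.tau_u, kin.tau_rot))
    lind_ops = []
    for S3 in (SA, SB):
        Sp, Sm = S3[0] + 1j * S3[1], S3[0] - 1j * S3[1]
        lind_ops += [(Sp, k1), (Sm, k1), (S3[2], 2.0 * kz)]
    # detailed-balance diffusion rates between the two nodes
    h = r_nodes[1] - r_nodes[0]
    k0 = kin.D * NM2_PER_CM2 / h**2
    w01 = k0 * np.sqrt(weights[0] / weights[1])  # node1 -> node0
    w10 = k0 * np.sqrt(weights[1] / weights[0])  # node0 -> node1

    def rhs(rho0, rho1):
        out0 = -1j * (H0 @ rho0 - rho0 @ H0)
        out1 = -1j * (H1 @ rho1 - rho1 @ H1)
        for L, rate in lind_ops:
            Ld = L.conj().T
            out0 += rate * (L @ rho0 @ Ld - 0.5 * (Ld @ L @ rho0 + rho0 @ Ld @ L))
            out1 += rate * (L @ rho1 @ Ld - 0.5 * (Ld @ L @ rho1 + rho1 @ Ld @ L))
        out0 += w01 * rho1 - w10 * rho0
        out1 += w10 * rho0 - w01 * rho1
        out0 -= 0.5 * kin.kp * (Qs @ rho0 + rho0 @ Qs)  # contact recombination
        out0 -= kin.ks * rho0
        out1 -= kin.ks * rho1
        return out0, out1

    N = 2 * d * d
    Lmat = np.zeros((N, N), dtype=complex)
    for node in range(2):
        for i in range(d):
            for j in range(d):
                basis = np.zeros((d, d), dtype=complex)
                basis[i, j] = 1.0
                args = (basis, np.zeros((d, d), dtype=complex))
                if node == 1:
                    args = args[::-1]
                o0, o1 = rhs(*args)
                Lmat[:, node * d * d + i * d + j] = np.concatenate(
                    [o0.reshape(-1), o1.reshape(-1)]
                )
    rho_spin = (E - Qs) / (3.0 * 2 ** (n_add + 1))  # triplet x mixed nucleus+bath
    rhs_vec = -np.concatenate(
        [weights[0] * rho_spin.reshape(-1), weights[1] * rho_spin.reshape(-1)]
    )
    x = np.linalg.solve(Lmat, rhs_vec)
    X0 = x[: d * d].reshape(d, d)
    X1 = x[d * d :].reshape(d, d)
    obs = 2.0 * IN[2]
    p_gem = kin.kp * float(np.real(np.trace(obs @ (Qs @ X0))))
    p_esc = kin.ks * float(np.real(np.trace(obs @ (X0 + X1))))
    return p_gem, p_esc
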