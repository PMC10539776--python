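import numpy as np
import pytest

import fadcidnp.spin_sim as ss
from fadcidnp.constants import GAMMA_E, MU_B_OVER_HBAR, mT_to_angular
from fadcidnp.distributions import RadialGrid
from fadcidnp.spin_sim import (
    QS,
    BiradicalModel,
    BiradicalSpinParams,
    CIDNPCurve,
    ExchangeModel,
    KineticsRelaxationParams,
    bath_sectors,
    build_diffusion_operator,
    build_hamiltonian,
    build_relaxation,
    curve_features,
    exchange_coupling,
    field_sweep,
    geminate_polarization,
    semiclassical_projections,
)

# ---------------------------------------------------------------------------
# exchange law
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "conv", ["decay_length_nm", "inverse_length_per_nm", "decay_length_from_contact"]
)
def test_exchange_monotone_and_signed(conv):
    m = ExchangeModel(J0=-2.3e8, alpha=0.214, convention=conv)
    r = np.linspace(0.0, 2.0, 50)
    J = exchange_coupling(r, m)
    assert np.all(J < 0)  # sign of J0 everywhere
    assert np.all(np.diff(np.abs(J)) <= 1e-9 * np.abs(J[:-1]))  # |J| non-increasing


def test_exchange_amplitude_at_zero_distance():
    for conv in ("decay_length_nm", "inverse_length_per_nm"):
        m = ExchangeModel(J0=-2.3e8, alpha=0.214, convention=conv)
        assert exchange_coupling(0.0, m) == pytest.approx(-2.3e8)


def test_exchange_half_decay_point():
    m = ExchangeModel(J0=-4.0, alpha=0.2, convention="decay_length_nm")
    assert exchange_coupling(0.2 * np.log(2), m) == pytest.approx(-2.0, rel=1e-12)


def test_exchange_contact_offset_capped_inside_contact():
    m = ExchangeModel(J0=-10.0, alpha=0.214, convention="decay_length_from_contact")
    assert exchange_coupling(0.2, m) == pytest.approx(-10.0)
    assert exchange_coupling(m.r_contact, m) == pytest.approx(-10.0)


def test_exchange_negative_distance_rejected():
    with pytest.raises(ValueError, match="non-negative"):
        exchange_coupling(-0.1, ExchangeModel())


# ---------------------------------------------------------------------------
# Hamiltonian
# ---------------------------------------------------------------------------


def test_hamiltonian_self_adjoint():
    H = build_hamiltonian(0.01, 0.7, BiradicalSpinParams(), ExchangeModel(), m_add=1.0)
    assert np.max(np.abs(H - H.conj().T)) < 1e-12 * np.max(np.abs(H))


def test_hamiltonian_degenerate_limit():
    spins = BiradicalSpinParams(A=0.0, A_add=0.0)
    H = build_hamiltonian(0.0, 50.0, spins, ExchangeModel())  # B=0, J(r) ~ 0
    assert np.max(np.abs(H)) < 1e-3  # rad/s; all eigenvalues degenerate at 0


def test_zeeman_limit_st0_gap_proportional_to_delta_g():
    # A = 0, J = 0: product states; the S-T0 splitting per unit field is
    # the electron Zeeman difference (ga - gb) muB/hbar
    spins = BiradicalSpinParams(ga=2.004, gb=2.001, A=0.0, A_add=0.0)
    exch = ExchangeModel(J0=0.0)
    B = 0.5
    H = build_hamiltonian(B, 0.9, spins, exch)
    # |alpha beta> and |beta alpha> energies differ by (ga-gb) muB B
    e_ab = np.real(H[2, 2])  # a=alpha, b=beta, nucleus alpha
    e_ba = np.real(H[4, 4])
    expected = (spins.ga - spins.gb) * MU_B_OVER_HBAR * B
    assert e_ab - e_ba == pytest.approx(expected, rel=1e-12)


def test_singlet_tminus_crossing_at_twice_J():
    # fixed negative J, A = 0, equal g: the nuclear-doubled S and T- levels
    # cross where the electron Zeeman energy equals 2|J|; the numerical
    # eigenvalue scan must agree with that closed form
    J_mT = -3.0
    spins = BiradicalSpinParams(ga=2.0, gb=2.0, A=0.0, A_add=0.0)
    exch = ExchangeModel(J0=J_mT, alpha=1e6, convention="decay_length_nm")  # flat J(r)

    def st_gap(B):
        ev = np.linalg.eigvalsh(build_hamiltonian(B, 0.9, spins, exch))
        return ev[2] - ev[1]  # gap between the S doublet and the T- doublet

    B_c_expected = 2 * abs(J_mT) * mT_to_angular(1.0) / (2.0 * MU_B_OVER_HBAR)
    Bs = np.linspace(0.8 * B_c_expected, 1.2 * B_c_expected, 401)
    B_c = Bs[int(np.argmin([st_gap(B) for B in Bs]))]
    assert B_c == pytest.approx(B_c_expected, rel=0.01)


# ---------------------------------------------------------------------------
# relaxation generator
# ---------------------------------------------------------------------------


def test_relaxation_zero_G_gives_zero_generator():
    R = build_relaxation(0.1, KineticsRelaxationParams(G=0.0))
    assert np.all(R == 0)


def test_relaxation_rates_scale_with_G_at_zero_field():
    kin1 = KineticsRelaxationParams(G=1e17)
    kin2 = KineticsRelaxationParams(G=2e17)
    R1 = build_relaxation(0.0, kin1)
    R2 = build_relaxation(0.0, kin2)
    assert np.allclose(R2, 2.0 * R1, rtol=1e-12)


def test_relaxation_lorentzian_tail_falls_as_inverse_square_field():
    kin = KineticsRelaxationParams()
    # far above both dispersion knees the flip rate falls as 1/omega^2
    k1_a, _ = ss._relaxation_rates(40.0, kin)
    k1_b, _ = ss._relaxation_rates(80.0, kin)
    assert k1_a / k1_b == pytest.approx(4.0, rel=0.02)


def test_relaxation_trace_preserving_and_rates_nonnegative():
    R = build_relaxation(0.004, KineticsRelaxationParams())
    # trace preservation: vec(I)^T R = 0 (Lindblad form)
    tr = np.eye(8).reshape(-1) @ R
    assert np.max(np.abs(tr)) < 1e-10 * np.max(np.abs(R))
    k1, kz = ss._relaxation_rates(0.004, KineticsRelaxationParams())
    assert k1 >= 0 and kz >= 0


# ---------------------------------------------------------------------------
# diffusion operator
# ---------------------------------------------------------------------------


def test_diffusion_columns_conserve_probability(sim1_weights, grid):
    L = build_diffusion_operator(grid, sim1_weights, 2e-7)
    scale = np.max(np.abs(L))
    assert np.max(np.abs(L.sum(axis=0))) < 1e-12 * scale


def test_diffusion_equilibrium_is_stationary(sim1_weights, grid):
    L = build_diffusion_operator(grid, sim1_weights, 2e-7)
    scale = np.max(np.abs(L))
    assert np.max(np.abs(L @ sim1_weights)) < 1e-10 * scale


def test_diffusion_zero_weight_nodes_disconnected(grid):
    w = np.zeros(grid.n_points)
    w[:10] = 0.1
    L = build_diffusion_operator(grid, w, 2e-7)
    assert np.all(L[10:, :] == 0) and np.all(L[:, 10:] == 0)


def test_diffusion_all_zero_distribution_rejected(grid):
    with pytest.raises(ValueError, match="zero"):
        build_diffusion_operator(grid, np.zeros(grid.n_points), 2e-7)


def test_diffusion_slowest_mode_flat_distribution():
    # cell-centred grid spanning [0, L]: slowest relaxation rate -> pi^2 D/L^2
    n = 201
    L_nm = 1.0
    h = L_nm / n
    grid = RadialGrid(h / 2, L_nm - h / 2, n)
    D = 2e-7  # cm^2/s
    Lop = build_diffusion_operator(grid, np.full(n, 1.0 / n), D)
    ev = np.linalg.eigvals(Lop)
    rates = np.sort(-np.real(ev))
    assert rates[0] == pytest.approx(0.0, abs=1e-4 * rates[1])
    expected = np.pi**2 * D * 1e14 / L_nm**2
    assert rates[1] == pytest.approx(expected, rel=0.02)


# ---------------------------------------------------------------------------
# channel bookkeeping
# ---------------------------------------------------------------------------


def test_bath_sector_weights_sum_to_one():
    for n in (0, 1, 2, 3, 4, 5):
        sectors = bath_sectors(n)
        assert sum(w for _, w in sectors) == pytest.approx(1.0, rel=1e-12)
    assert dict((I, round(w * 16)) for I, w in bath_sectors(4)) == {2.0: 5, 1.0: 9, 0.0: 2}


def test_semiclassical_projection_weights():
    ws = dict(semiclassical_projections(BiradicalSpinParams(n_add=4)))
    assert ws == {
        -2.0: 1 / 16, -1.0: 4 / 16, 0.0: 6 / 16, 1.0: 4 / 16, 2.0: 1 / 16,
    }


def test_quantum_and_semiclassical_agree_without_additional_nuclei(grid, sim1_weights):
    m = BiradicalModel(spins=BiradicalSpinParams(n_add=0))
    q = geminate_polarization(4e-3, m, grid, sim1_weights, method="quantum")
    s = geminate_polarization(4e-3, m, grid, sim1_weights, method="semiclassical")
    assert q == pytest.approx(s, rel=1e-12)


# ---------------------------------------------------------------------------
# polarization physics
# ---------------------------------------------------------------------------


def test_no_sink_rejected(grid, sim1_weights):
    m = BiradicalModel(kinetics=KineticsRelaxationParams(kp=0.0, ks=0.0))
    with pytest.raises(ValueError, match="sink"):
        geminate_polarization(4e-3, m, grid, sim1_weights)


def test_zero_mechanism_gives_zero_polarization(grid, sim1_weights):
    m = BiradicalModel(spins=BiradicalSpinParams(ga=2.0034, gb=2.0034, A=0.0, A_add=0.0))
    for B in (4e-3, 0.1):
        assert abs(geminate_polarization(B, m, grid, sim1_weights)) < 1e-12


def test_probability_conserved_without_sinks():
    # kp = ks = 0: propagate rho for a while; total trace over nodes stays 1
    from scipy.linalg import expm

    from fadcidnp.spin_sim import _channel_ops, _relaxation_rates

    m = BiradicalModel(
        spins=BiradicalSpinParams(n_add=0),
        kinetics=KineticsRelaxationParams(kp=0.0, ks=0.0),
    )
    grid = RadialGrid(0.8, 0.9, 3)
    w = np.array([0.5, 0.3, 0.2])
    ops = _channel_ops(1)
    B = 2e-3
    k1, kz = _relaxation_rates(B, m.kinetics)
    a = mT_to_angular(m.spins.A)
    base = (
        m.spins.ga * MU_B_OVER_HBAR * B * ops.C_za
        + m.spins.gb * MU_B_OVER_HBAR * B * ops.C_zb
        + a * ops.C_hfc
        + k1 * ops.R_flip
        + kz * ops.R_deph
    )
    Jw = mT_to_angular(1.0) * np.asarray(exchange_coupling(grid.nodes, m.exchange))
    Ld = build_diffusion_operator(grid, w, m.kinetics.D)
    n, nk = 3, ops.nk
    L = np.kron(Ld, np.eye(nk)).astype(complex)
    for i in range(n):
        L[i * nk : (i + 1) * nk, i * nk : (i + 1) * nk] += base - Jw[i] * ops.C_ex
    x0 = (w[:, None] * ops.rho0[None, :]).reshape(-1)
    # trace functional on the reduced space
    tr_vec = np.tile(np.eye(8).reshape(-1)[ops.keep], n)
    for t in (1e-9, 1e-7):
        xt = expm(L * t) @ x0
        assert np.real(tr_vec @ xt) == pytest.approx(1.0, abs=1e-10)


def test_lac_extremum_scales_linearly_with_exchange():
    # delta distribution at a fixed distance, diffusion-inactive, weak sinks:
    # the emissive extremum tracks 2|J| over a decade (slope 2 +- 10%)
    r0, lam = 0.8, 0.214
    ratios = []
    for J_mT in (3.0, 10.0, 30.0):
        m = BiradicalModel(
            spins=BiradicalSpinParams(n_add=0, A=-0.2),
            exchange=ExchangeModel(J0=-J_mT * np.exp(r0 / lam)),
            kinetics=KineticsRelaxationParams(G=0.0, kp=1e7, ks=1e4),
        )
        grid = RadialGrid(r0, r0 + 0.02, 3)
        w = np.array([1.0, 0.0, 0.0])
        fields = np.geomspace(1.0e-3 * J_mT, 4.4e-3 * J_mT, 21)
        feat = curve_features(field_sweep(fields, m, grid, w))
        assert feat.sign == "emissive"
        ratios.append(feat.extremum_field * 1e3 / J_mT)
    assert np.all(np.abs(np.array(ratios) - 2.0) < 0.2)
    # linearity across the decade
    assert max(ratios) / min(ratios) < 1.1


def test_low_field_sign_invariant_under_hfc_sign_flip(grid, sim1_weights):
    vals = {}
    for A in (-0.7, +0.7):
        m = BiradicalModel(spins=BiradicalSpinParams(A=A))
        vals[A] = geminate_polarization(4e-3, m, grid, sim1_weights)
    assert vals[-0.7] < 0 and vals[+0.7] < 0  # emissive either way (T- - S)


# ---------------------------------------------------------------------------
# curve features
# ---------------------------------------------------------------------------


def test_triangle_extremum_and_fwhm_linear_axis():
    B = np.linspace(0.5, 8.5, 161)
    y = np.maximum(1.0 - np.abs(B - 4.0) / 5.0, 0.0)
    feat = curve_features(CIDNPCurve(B, y), axis="linear")
    assert feat.extremum_field == pytest.approx(4.0, abs=0.05)
    assert feat.fwhm == pytest.approx(5.0, abs=0.05)
    assert feat.sign == "absorptive"


def test_mirrored_curve_flips_sign_only():
    B = np.linspace(0.5, 8.5, 161)
    y = np.maximum(1.0 - np.abs(B - 4.0) / 5.0, 0.0)
    up = curve_features(CIDNPCurve(B, y), axis="linear")
    dn = curve_features(CIDNPCurve(B, -y), axis="linear")
    assert dn.extremum_field == pytest.approx(up.extremum_field, rel=1e-12)
    assert dn.fwhm == pytest.approx(up.fwhm, rel=1e-12)
    assert dn.sign == "emissive" and dn.extremum_amplitude == pytest.approx(
        -up.extremum_amplitude
    )


def test_gaussian_fwhm_closed_form():
    B = np.geomspace(1e-4, 1e-1, 301)
    x = np.log10(B)
    sigma = 0.35
    y = -np.exp(-0.5 * ((x + 2.5) / sigma) ** 2)
    feat = curve_features(CIDNPCurve(B, y), axis="log")
    # closed form in the log coordinate where the curve is Gaussian
    left = 10 ** (-2.5 - 2.3548 * sigma / 2)
    right = 10 ** (-2.5 + 2.3548 * sigma / 2)
    assert feat.extremum_field == pytest.approx(10**-2.5, rel=1e-3)
    assert feat.fwhm == pytest.approx(right - left, rel=1e-2)


def test_monotone_curve_rejected():
    B = np.linspace(1, 2, 10)
    with pytest.raises(ValueError, match="monotone|interior"):
        curve_features(CIDNPCurve(B, B**2), axis="linear")


def test_curve_validation():
    with pytest.raises(ValueError, match="increasing"):
        CIDNPCurve(np.array([1.0, 1.0, 2.0]), np.zeros(3))
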