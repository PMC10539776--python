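import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from fadcidnp.nmrd_fit import NMRDCurve, NMRDModelParams, eq1_rate
from fadcidnp.shuttle_deconv import (
    TransferProfile,
    attenuation_factor,
    deconvolve_curve,
    interpolate_rate,
)
from fadcidnp.spin_sim import CIDNPCurve

TRUTH = NMRDModelParams(R1=9.0, R1_inf=0.55, tau_c=0.95e-9)


def _profile(B_start=4e-3, B0=9.4, T=0.1, n=201):
    u = np.linspace(0, 1, n)
    s = 0.5 * (1 - np.cos(np.pi * u))
    z0 = 0.35
    z = z0 * np.log(B0 / B_start) * (1 - s)
    return TransferProfile(u * T, B0 * np.exp(-z / z0))


# -- rate interpolation -------------------------------------------------------


def test_spline_passes_through_knots_exactly():
    B = np.geomspace(1e-3, 16.44, 12)
    curve = NMRDCurve("A8", B, 1.0 / eq1_rate(B, TRUTH))
    for b, r in zip(B, curve.rate):
        assert interpolate_rate(curve, b) == pytest.approx(r, rel=1e-12)


def test_spline_tracks_closed_form_between_knots():
    B = np.geomspace(1e-4, 16.44, 40)  # dense knots spanning the field range
    curve = NMRDCurve("A8", B, 1.0 / eq1_rate(B, TRUTH))
    Bq = np.geomspace(1.2e-4, 15.0, 300)
    spl = interpolate_rate(curve, Bq)
    ref = eq1_rate(Bq, TRUTH)
    assert np.max(np.abs(spl - ref) / ref) < 5e-3


def test_out_of_range_clamped_with_warning():
    B = np.geomspace(1e-3, 10.0, 10)
    curve = NMRDCurve("A8", B, 1.0 / eq1_rate(B, TRUTH))
    with pytest.warns(UserWarning, match="clamped"):
        lo = interpolate_rate(curve, 1e-5)
    assert lo == pytest.approx(curve.rate[0])


def test_model_params_rate_source_is_closed_form():
    assert interpolate_rate(TRUTH, 0.25) == pytest.approx(eq1_rate(0.25, TRUTH))


# -- attenuation factor -------------------------------------------------------


def test_zero_rates_give_unit_factor():
    assert attenuation_factor(_profile(), lambda B: 0.0) == pytest.approx(1.0)


def test_constant_rate_closed_form():
    prof = _profile(T=0.1)
    f = attenuation_factor(prof, lambda B: 3.0)
    assert f == pytest.approx(np.exp(3.0 * 0.1), rel=1e-12)


def test_500_interval_product_matches_fine_quadrature():
    prof = _profile()
    f = attenuation_factor(prof, TRUTH, n_intervals=500)
    integral, _ = quad(
        lambda t: eq1_rate(float(prof.field_at(t)), TRUTH), 0.0, prof.duration,
        limit=400,
    )
    assert f == pytest.approx(np.exp(integral), rel=1e-3)


def test_factor_converges_beyond_500_intervals():
    prof = _profile()
    f500 = attenuation_factor(prof, TRUTH, 500)
    f4000 = attenuation_factor(prof, TRUTH, 4000)
    assert abs(f500 - f4000) / f4000 < 1e-3


def test_negative_rates_rejected():
    with pytest.raises(ValueError, match="negative"):
        attenuation_factor(_profile(), lambda B: -1.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(B_start=st.floats(1e-4, 5.0), T=st.floats(0.01, 1.0))
def test_attenuation_factor_at_least_one(B_start, T):
    assert attenuation_factor(_profile(B_start=B_start, T=T), TRUTH) >= 1.0


# -- deconvolution ------------------------------------------------------------


def _observed_curve():
    B = np.geomspace(1e-4, 9.4, 15)
    amp = -np.exp(-0.5 * ((np.log10(B) + 2.35) / 0.35) ** 2)
    return CIDNPCurve(B, amp, uncertainty=0.02 * np.abs(amp))


def test_unit_factors_identity():
    obs = _observed_curve()
    out = deconvolve_curve(obs, lambda B: _profile(B_start=B), lambda B: 0.0)
    assert np.allclose(out.amplitude, obs.amplitude, rtol=1e-14)


def test_attenuate_then_deconvolve_roundtrip():
    true = _observed_curve()
    factors = np.array(
        [attenuation_factor(_profile(B_start=b), TRUTH) for b in true.field_T]
    )
    observed = CIDNPCurve(true.field_T, true.amplitude / factors)
    rec = deconvolve_curve(observed, lambda B: _profile(B_start=B), TRUTH)
    assert np.max(np.abs(rec.amplitude - true.amplitude) / np.abs(true.amplitude)) < 1e-6


def test_deconvolve_then_reattenuate_identity():
    obs = _observed_curve()
    rec = deconvolve_curve(obs, lambda B: _profile(B_start=B), TRUTH)
    factors = rec.amplitude / obs.amplitude
    back = rec.amplitude / factors
    assert np.allclose(back, obs.amplitude, rtol=1e-12)
    assert np.all(factors >= 1.0)
    # uncertainties scale by the same factor
    assert np.allclose(rec.uncertainty / obs.uncertainty, factors, rtol=1e-12)


def test_missing_profile_names_field():
    obs = _observed_curve()
    profiles = {}  # none available
    with pytest.raises(KeyError, match="no transfer profile"):
        deconvolve_curve(obs, profiles, TRUTH)


def test_profile_validation():
    with pytest.raises(ValueError, match="start at 0"):
        TransferProfile(np.array([0.1, 0.2]), np.array([1.0, 2.0]))
    with pytest.raises(ValueError, match="positive"):
        TransferProfile(np.array([0.0, 0.2]), np.array([-1.0, 2.0]))
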