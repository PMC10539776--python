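"""Synthetic data generators emulating the experimental data streams.

The generators replace the spectrometer side of the study so that every
analysis stage (T1 extraction, dispersion fitting, shuttle deconvolution,
model ranking) can be exercised and tested end to end:

* inversion-recovery decay series whose T1 obey the two-contribution
  dispersion model, per proton;
* monotone shuttle field-time profiles from a parametric fringe-field
  (exponential stray field along the magnet bore) plus a smooth
  constant-acceleration-like motion law;
* noisy "observed" CIDNP field dependences obtained by attenuating a true
  curve with the transfer losses the deconvolution stage must undo.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .nmrd_fit import NMRDModelParams, RelaxationDecaySeries
from .shuttle_deconv import RateSource, TransferProfile, attenuation_factor
from .spin_sim import CIDNPCurve

__all__ = [
    "SyntheticStudyConfig",
    "DEFAULT_PROTON_TRUTHS",
    "gen_nmrd_decays",
    "gen_transfer_profile",
    "gen_observed_cidnp",
]

#: Representative dispersion-model truths for the proton set of the study
#: (adenine A8/A2, flavin F6/F9 and the ribityl F5',5'' pair).  Correlation
#: times are of order 1 ns and distinct per site so that site-specificity is
#: meaningful; A8 carries the fastest low-field relaxation (its transfer
#: losses at a few mT are of order one half).
DEFAULT_PROTON_TRUTHS: dict[str, NMRDModelParams] = {
    "A8": NMRDModelParams(R1=9.0, R1_inf=0.55, tau_c=0.95e-9, proton="A8"),
    "A2": NMRDModelParams(R1=4.0, R1_inf=0.25, tau_c=0.90e-9, proton="A2"),
    "F6": NMRDModelParams(R1=5.0, R1_inf=0.40, tau_c=1.00e-9, proton="F6"),
    "F9": NMRDModelParams(R1=6.0, R1_inf=0.50, tau_c=0.85e-9, proton="F9"),
    "F5p": NMRDModelParams(R1=7.0, R1_inf=0.60, tau_c=0.70e-9, proton="F5p"),
}


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study conditions for the synthetic generators.

    decay_noise / cidnp_noise : relative (multiplicative Gaussian) noise.
    detection_field : T (high-field NMR detection position).
    transfer_duration : s (sample shuttle travel time; the default 0.1 s is
        comparable with the low-field T1 of the fastest proton, A8, which
        is what makes deconvolution matter: about one-half of the A8 signal
        polarized at a few mT is lost on the way to detection).
    fringe_length : dimensionless shape parameter of the stray field decay
        along the bore, B(z) = B0 exp(-z / fringe_length) with z in metres.
    n_delays : inversion-recovery delays per decay series.
    seed : base seed; all generators derive child streams from it.
    """

    proton_truths: dict[str, NMRDModelParams] = field(
        default_factory=lambda: dict(DEFAULT_PROTON_TRUTHS)
    )
    decay_noise: float = 0.03
    cidnp_noise: float = 0.02
    detection_field: float = 9.4
    transfer_duration: float = 0.1
    fringe_length: float = 0.35
    n_delays: int = 12
    n_profile_points: int = 201
    seed: int = 0

    def __post_init__(self):
        if self.decay_noise < 0 or self.cidnp_noise < 0:
            raise ValueError("noise levels must be non-negative")
        if self.transfer_duration <= 0:
            raise ValueError("transfer duration must be positive")

    def rng(self, *key: object) -> np.random.Generator:
        # stable across processes (unlike hash() on strings)
        digest = zlib.crc32(repr(key).encode()) % 2**31
        ss = np.random.SeedSequence([self.seed % 2**31, digest])
        return np.random.default_rng(ss)


def gen_nmrd_decays(
    cfg: SyntheticStudyConfig, fields, protons: list[str] | None = None
) -> dict[str, list[RelaxationDecaySeries]]:
    """Inversion-recovery series per proton per field.

    T1(B) = 1 / R1_tot(B) from the proton's dispersion truth; intensities
    follow I(tau) = 1 - 2 exp(-tau/T1) (ideal inversion, unit equilibrium)
    with multiplicative Gaussian noise.  Deterministic per (config, seed).
    """
    from .nmrd_fit import eq1_rate

    fields = np.asarray(fields, dtype=float)
    protons = protons or list(cfg.proton_truths)
    out: dict[str, list[RelaxationDecaySeries]] = {}
    for proton in protons:
        truth = cfg.proton_truths[proton]
        series = []
        for B in fields:
            T1 = 1.0 / eq1_rate(float(B), truth)
            tau = np.linspace(0.0, 3.5 * T1, cfg.n_delays)
            I = 1.0 - 2.0 * np.exp(-tau / T1)
            if cfg.decay_noise > 0:
                g = cfg.rng("decay", proton, float(B)).standard_normal(tau.size)
                I = I * (1.0 + cfg.decay_noise * g)
            series.append(RelaxationDecaySeries(proton, float(B), tau, I))
        out[proton] = series
    return out


def gen_transfer_profile(cfg: SyntheticStudyConfig, B_start: float) -> TransferProfile:
    """Field-versus-time profile of one shuttle transfer, B_start -> B0.

    The sample sits at bore position z_start where the stray field
    B(z) = B0 exp(-z/z0) equals B_start and moves to the magnet centre with
    a smooth raised-cosine displacement law (zero velocity at both ends),
    completing in ``transfer_duration``.  The resulting B(t) is monotone
    non-decreasing with exact endpoints.
    """
    B0 = cfg.detection_field
    if not (0 < B_start <= B0):
        raise ValueError("need 0 < B_start <= detection field")
    z0 = cfg.fringe_length
    z_start = z0 * np.log(B0 / B_start)
    u = np.linspace(0.0, 1.0, cfg.n_profile_points)
    s = 0.5 * (1.0 - np.cos(np.pi * u))  # smooth 0 -> 1
    z = z_start * (1.0 - s)
    B = B0 * np.exp(-z / z0)
    B[0], B[-1] = B_start, B0  # exact endpoints
    return TransferProfile(u * cfg.transfer_duration, B)


def gen_observed_cidnp(
    true_curve: CIDNPCurve,
    cfg: SyntheticStudyConfig,
    rates: RateSource,
    n_intervals: int = 500,
) -> CIDNPCurve:
    """Attenuate a true CIDNP curve by the transfer losses and add noise.

    observed(i) = true(i) / attenuation(B_i) * (1 + noise),
    the exact inverse of the deconvolution stage at zero noise.
    """
    factors = np.array(
        [
            attenuation_factor(gen_transfer_profile(cfg, float(B)), rates, n_intervals)
            for B in true_curve.field_T
        ]
    )
    obs = true_curve.amplitude / factors
    if cfg.cidnp_noise > 0:
        g = cfg.rng("cidnp", true_curve.nucleus).standard_normal(obs.size)
        obs = obs * (1.0 + cfg.cidnp_noise * g)
    unc = cfg.cidnp_noise * np.abs(obs) if cfg.cidnp_noise > 0 else None
    meta = dict(true_curve.meta)
    meta.update(source="synthetic-observed", seed=cfg.seed)
    return CIDNPCurve(
        true_curve.field_T.copy(), obs, uncertainty=unc, nucleus=true_curve.nucleus, meta=meta
    )
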