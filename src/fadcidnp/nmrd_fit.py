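"""Site-specific NMRD analysis: T1 extraction and dispersion fitting.

Fast-field-cycling inversion-recovery series give, per proton and per
relaxation field B_L, a decay of signal intensity with the variable delay
tau_vd.  Fitting each decay yields T1(B_L); the resulting relaxation
dispersion (NMRD) curve is then fitted with a two-contribution model,

    R1_tot(B) = R1 / (1 + (gamma_H * B * tau_c)^2) + R1_inf,

whose Lorentzian part carries a site-specific local-field correlation time
tau_c (the transition between motional regimes, gamma_H*B*tau_c ~ 1, falls
at a few tesla for a molecule like FAD in water) and whose constant part
absorbs field-independent relaxation.  Only the high-field branch of the
dispersion identifies tau_c site-specifically; the strong-coupling
low-field region is excluded by the fit window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

from .constants import GAMMA_H

__all__ = [
    "RelaxationDecaySeries",
    "NMRDCurve",
    "NMRDModelParams",
    "DecayFitResult",
    "eq1_rate",
    "fit_decay",
    "fit_dispersion",
]


@dataclass
class RelaxationDecaySeries:
    """Inversion-recovery intensities versus variable delay at one field."""

    proton: str
    B_L: float  # relaxation field, T
    tau_vd: np.ndarray  # s
    intensity: np.ndarray

    def __post_init__(self):
        self.tau_vd = np.asarray(self.tau_vd, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.tau_vd.shape != self.intensity.shape or self.tau_vd.ndim != 1:
            raise ValueError("tau_vd and intensity must be 1-D arrays of equal length")
        if np.any(self.tau_vd < 0) or np.any(np.diff(self.tau_vd) <= 0):
            raise ValueError("tau_vd must be non-negative and strictly increasing")


@dataclass
class NMRDCurve:
    """T1 versus relaxation field for one proton."""

    proton: str
    B: np.ndarray  # T
    T1: np.ndarray  # s
    T1_err: np.ndarray | None = None

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        self.T1 = np.asarray(self.T1, dtype=float)
        if self.B.shape != self.T1.shape or self.B.ndim != 1:
            raise ValueError("B and T1 must be 1-D arrays of equal length")
        if np.any(np.diff(self.B) <= 0):
            raise ValueError("fields must be strictly increasing")
        if np.any(self.T1 <= 0):
            raise ValueError("T1 must be positive")
        if self.T1_err is not None:
            self.T1_err = np.asarray(self.T1_err, dtype=float)
            if self.T1_err.shape != self.B.shape:
                raise ValueError("T1_err must match B in shape")

    @property
    def rate(self) -> np.ndarray:
        return 1.0 / self.T1

    @property
    def rate_err(self) -> np.ndarray | None:
        if self.T1_err is None:
            return None
        return self.T1_err / self.T1**2


@dataclass(frozen=True)
class NMRDModelParams:
    """Dispersion-model parameters for one proton.

    R1 : low-field local-field relaxation rate (s^-1).
    R1_inf : field-independent rate (s^-1).
    tau_c : local-field correlation time (s).
    """

    R1: float
    R1_inf: float
    tau_c: float
    R1_err: float | None = None
    R1_inf_err: float | None = None
    tau_c_err: float | None = None
    residual_norm: float | None = None
    proton: str = ""

    def __post_init__(self):
        if self.R1 < 0 or self.R1_inf < 0:
            raise ValueError("rates must be non-negative")
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")


@dataclass(frozen=True)
class DecayFitResult:
    T1: float
    T1_err: float
    I0: float
    I_inf: float
    flagged: bool = False
    message: str = ""


def eq1_rate(B, p: NMRDModelParams):
    """Total relaxation rate (s^-1) of the two-contribution dispersion model."""
    B = np.asarray(B, dtype=float)
    if np.any(B < 0):
        raise ValueError("field must be non-negative")
    out = p.R1 / (1.0 + (GAMMA_H * B * p.tau_c) ** 2) + p.R1_inf
    return out if out.ndim else float(out)


def fit_decay(series: RelaxationDecaySeries) -> DecayFitResult:
    """Three-parameter exponential fit I(tau) = I_inf + (I0 - I_inf) e^(-tau/T1).

    The free plateau I_inf absorbs incomplete inversion.  A fit that does
    not converge or pins T1 at a bound is returned flagged rather than
    raised, so batch pipelines can skip bad series.
    """
    tau, I = series.tau_vd, series.intensity
    if len(tau) < 4:
        raise ValueError("need at least 4 distinct delays")
    span = tau[-1] - tau[0]
    pars = Parameters()
    pars.add("I_inf", value=float(I[-1]))
    pars.add("I0", value=float(I[0]))
    pars.add("T1", value=float(max(span / 3.0, 1e-6)), min=1e-6 * span + 1e-12, max=100.0 * span)

    def resid(p):
        return p["I_inf"] + (p["I0"] - p["I_inf"]) * np.exp(-tau / p["T1"]) - I

    out = minimize(resid, pars)
    T1 = float(out.params["T1"].value)
    T1_err = float(out.params["T1"].stderr or np.nan)
    at_bound = (
        T1 <= out.params["T1"].min * 1.001 or T1 >= out.params["T1"].max * 0.999
    )
    flagged = (not out.success) or at_bound or not np.isfinite(T1_err)
    msg = "" if not flagged else ("T1 at bound" if at_bound else out.message)
    return DecayFitResult(
        T1=T1,
        T1_err=T1_err,
        I0=float(out.params["I0"].value),
        I_inf=float(out.params["I_inf"].value),
        flagged=flagged,
        message=msg,
    )


def fit_dispersion(
    curve: NMRDCurve, B_min: float = 0.56, B_max: float = 16.44
) -> NMRDModelParams:
    """Weighted nonlinear least squares of the dispersion model in rate space.

    Only points with B_min <= B <= B_max enter the residuals (the published
    analysis used 0.56-16.44 T, and 1.77-16.44 T for the A8 proton whose
    low-field points are affected by strong coupling).  Weights are
    propagated T1 uncertainties when present, unit weights otherwise.
    """
    mask = (curve.B >= B_min) & (curve.B <= B_max)
    B = curve.B[mask]
    R = curve.rate[mask]
    if B.size < 4:
        raise ValueError(
            f"need at least 4 points in the window [{B_min}, {B_max}] T, have {B.size}"
        )
    w = None
    if curve.rate_err is not None:
        sig = curve.rate_err[mask]
        if np.all(sig > 0):
            w = 1.0 / sig
    R_lo, R_hi = float(R.max()), float(R.min())
    if R_lo - R_hi <= 0:
        raise ValueError("flat dispersion data: tau_c not identifiable")
    # initial tau_c from the field of the half-amplitude point
    R_half = R_hi + 0.5 * (R_lo - R_hi)
    B_half = float(np.interp(-R_half, -R, B))  # R decreases with B
    tau0 = 1.0 / (GAMMA_H * max(B_half, 1e-3))
    pars = Parameters()
    pars.add("R1", value=R_lo - R_hi, min=0.0)
    pars.add("R1_inf", value=max(R_hi, 1e-12), min=0.0)
    pars.add("tau_c", value=float(np.clip(tau0, 1e-12, 1e-7)), min=1e-12, max=1e-7)

    def resid(p):
        model = p["R1"] / (1.0 + (GAMMA_H * B * p["tau_c"]) ** 2) + p["R1_inf"]
        r = model - R
        return r * w if w is not None else r

    out = minimize(resid, pars)
    g = lambda name: float(out.params[name].value)
    ge = lambda name: (
        float(out.params[name].stderr) if out.params[name].stderr is not None else None
    )
    return NMRDModelParams(
        R1=g("R1"),
        R1_inf=g("R1_inf"),
        tau_c=g("tau_c"),
        R1_err=ge("R1"),
        R1_inf_err=ge("R1_inf"),
        tau_c_err=ge("tau_c"),
        residual_norm=float(np.sqrt(np.sum(np.asarray(out.residual) ** 2))),
        proton=curve.proton,
    )
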