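"""Relaxation deconvolution of shuttled CIDNP field dependences.

Between polarization in the low field B_i and detection at high field, the
sample travels through the fringe field of the magnet; during the transfer
the hyperpolarization relaxes with the field-dependent rate R1(B).  The
true polarization generated at B_i is reconstructed from the observed one
by multiplying with the accumulated attenuation

    P_true(i) = P_obs(i) * prod_n exp(R_n * dt_n),

where the transfer's field-versus-time profile is split into equal time
intervals (500 by default), the field is held constant within each
interval, and R_n is the relaxation rate interpolated from the NMRD data
at that field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy.interpolate import CubicSpline

from .nmrd_fit import NMRDCurve, NMRDModelParams, eq1_rate
from .spin_sim import CIDNPCurve

__all__ = [
    "TransferProfile",
    "interpolate_rate",
    "attenuation_factor",
    "deconvolve_curve",
]


@dataclass
class TransferProfile:
    """Magnetic field experienced by the sample versus time since transfer start."""

    t: np.ndarray  # s, strictly increasing from 0
    B: np.ndarray  # T

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.t.shape != self.B.shape or self.t.ndim != 1 or self.t.size < 2:
            raise ValueError("t and B must be 1-D arrays of equal length >= 2")
        if self.t[0] != 0.0 or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must start at 0 and be strictly increasing")
        if np.any(self.B <= 0):
            raise ValueError("fields must be positive")

    @property
    def duration(self) -> float:
        return float(self.t[-1])

    def field_at(self, times) -> np.ndarray:
        return np.interp(times, self.t, self.B)


RateSource = NMRDCurve | NMRDModelParams | Callable[[float], float]


def _spline_for(curve: NMRDCurve) -> CubicSpline:
    # spline on log10(B): the knots span several decades of field
    return CubicSpline(np.log10(curve.B), curve.rate)


def interpolate_rate(source: RateSource, B) -> np.ndarray | float:
    """R1(B) in s^-1 from an NMRD curve (cubic spline through the knots),
    dispersion-model parameters (closed form) or a user callable.

    Spline evaluation outside the measured field range is clamped to the
    nearest knot, with a warning.
    """
    B_arr = np.atleast_1d(np.asarray(B, dtype=float))
    if isinstance(source, NMRDModelParams):
        out = eq1_rate(B_arr, source)
    elif isinstance(source, NMRDCurve):
        lo, hi = source.B[0], source.B[-1]
        if np.any(B_arr < lo) or np.any(B_arr > hi):
            warnings.warn(
                "field outside the NMRD data range; rate clamped to the nearest knot",
                stacklevel=2,
            )
        out = _spline_for(source)(np.log10(np.clip(B_arr, lo, hi)))
    elif callable(source):
        out = np.array([float(source(b)) for b in B_arr])
    else:
        raise TypeError(f"unsupported rate source {type(source)!r}")
    out = np.asarray(out, dtype=float)
    return out if np.ndim(B) else float(out[0])


def attenuation_factor(
    profile: TransferProfile, rates: RateSource, n_intervals: int = 500
) -> float:
    """Multiplicative relaxation-loss factor (>= 1) for one transfer.

    The profile is split into ``n_intervals`` equal time intervals; within
    each the field is held constant (evaluated at the interval midpoint)
    and the rate contributes exp(R_n * dt_n); the product over intervals is
    returned.  Interval order is immaterial since the factors commute.
    """
    if profile.duration <= 0:
        raise ValueError("profile duration must be positive")
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    dt = profile.duration / n_intervals
    t_mid = (np.arange(n_intervals) + 0.5) * dt
    R = np.asarray(interpolate_rate(rates, profile.field_at(t_mid)), dtype=float)
    if np.any(R < 0):
        raise ValueError("negative relaxation rate encountered")
    return float(np.exp(np.sum(R) * dt))


def deconvolve_curve(
    observed: CIDNPCurve,
    profiles: Mapping[float, TransferProfile] | Callable[[float], TransferProfile],
    rates: RateSource,
    n_intervals: int = 500,
) -> CIDNPCurve:
    """Reconstruct the true CIDNP field dependence from an observed one.

    ``profiles`` maps each polarization field B_i to its transfer profile
    (or generates one on demand).  Each point and its uncertainty are
    multiplied by the attenuation factor of its transfer.
    """
    factors = np.empty(len(observed))
    for k, B in enumerate(observed.field_T):
        if callable(profiles):
            prof = profiles(B)
        else:
            try:
                prof = profiles[B]
            except KeyError:
                raise KeyError(
                    f"no transfer profile for polarization field {B:.6g} T"
                ) from None
        factors[k] = attenuation_factor(prof, rates, n_intervals)
    meta = dict(observed.meta)
    meta["relaxation_corrected"] = True
    return CIDNPCurve(
        observed.field_T.copy(),
        observed.amplitude * factors,
        uncertainty=None if observed.uncertainty is None else observed.uncertainty * factors,
        nucleus=observed.nucleus,
        meta=meta,
    )
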