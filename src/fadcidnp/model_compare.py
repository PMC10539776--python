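"""Scoring of simulated CIDNP field dependences against observed data.

CIDNP amplitudes are in arbitrary units, so the comparison normalizes the
observed (relaxation-corrected) curve to unit extremum magnitude, scales
each simulated curve by a free positive amplitude factor (least squares),
and reports q = sum of squared deviations.  Candidate end-to-end distance
distributions are ranked by ascending q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .distributions import DistanceDistribution, RadialGrid
from .spin_sim import BiradicalModel, CIDNPCurve, field_sweep

__all__ = ["QScore", "QReport", "q_statistic", "rank_curves", "rank_models"]


@dataclass(frozen=True)
class QScore:
    model: str
    q: float
    scale: float
    sign_mismatch: bool = False


@dataclass
class QReport:
    """Per-model q scores, sorted ascending (best fit first)."""

    scores: list[QScore] = field(default_factory=list)

    @property
    def ranking(self) -> list[str]:
        return [s.model for s in self.scores]

    @property
    def best(self) -> QScore:
        return self.scores[0]

    def sort(self):
        self.scores.sort(key=lambda s: s.q)
        return self


def _interp_onto(sim: CIDNPCurve, fields: np.ndarray) -> np.ndarray:
    if fields[0] < sim.field_T[0] * (1 - 1e-9) or fields[-1] > sim.field_T[-1] * (1 + 1e-9):
        raise ValueError(
            "simulated curve does not cover the observed field range "
            f"[{fields[0]:.4g}, {fields[-1]:.4g}] T"
        )
    # monotone cubic on log-field: no spurious overshoot between grid points
    return PchipInterpolator(np.log10(sim.field_T), sim.amplitude)(np.log10(fields))


def q_statistic(sim: CIDNPCurve, obs: CIDNPCurve, name: str = "") -> QScore:
    """q = sum of squared deviations after normalization and amplitude fit.

    The observed curve is normalized so its extremum magnitude is 1 (sign
    preserved; an emissive curve stays negative).  The simulated curve is
    interpolated onto the observed fields and given one free positive scale
    factor.  A best-fit scale that would have to be negative flags a sign
    mismatch and is scored with the scale forced to zero from above
    (q = sum of obs^2, the worst admissible value).
    """
    peak = float(np.max(np.abs(obs.amplitude)))
    if peak == 0:
        raise ValueError("observed curve is identically zero")
    y = obs.amplitude / peak
    s = _interp_onto(sim, obs.field_T)
    ss = float(s @ s)
    if ss == 0:
        return QScore(name or sim.meta.get("distribution", "sim"), float(y @ y), 0.0, True)
    scale = float(s @ y) / ss
    if scale <= 0:
        return QScore(name or sim.meta.get("distribution", "sim"), float(y @ y), 0.0, True)
    q = float(np.sum((scale * s - y) ** 2))
    return QScore(name or sim.meta.get("distribution", "sim"), q, scale, False)


def rank_curves(obs: CIDNPCurve, sims: dict[str, CIDNPCurve]) -> QReport:
    """Score pre-computed simulated curves against the observed one."""
    if not sims:
        raise ValueError("need at least one simulated curve")
    rep = QReport([q_statistic(c, obs, name=n) for n, c in sims.items()])
    return rep.sort()


def rank_models(
    obs: CIDNPCurve,
    models: list[DistanceDistribution],
    params: BiradicalModel,
    grid: RadialGrid,
    fields: np.ndarray | None = None,
) -> QReport:
    """Simulate each candidate distance distribution and rank by q.

    ``fields`` defaults to a logarithmic grid covering the observed range.
    """
    if not models:
        raise ValueError("need at least one candidate distribution")
    if fields is None:
        fields = np.geomspace(obs.field_T[0], obs.field_T[-1], 41)
    sims = {}
    for k, dist in enumerate(models):
        name = dist.name or f"model{k + 1}"
        sims[name] = field_sweep(fields, params, grid, dist)
    return rank_curves(obs, sims)
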