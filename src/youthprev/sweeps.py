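"""Sensitivity surfaces: (phi, theta) grids and effect-size curves.

Every cell of a grid and every point of a curve is recalibrated to the same
pre-intervention prevalence target, so differences across cells are pure
intervention effects — the comparability construction that makes the
surfaces interpretable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .calibration import CalibrationInfeasibleError, calibrate
from .equilibrium import equilibrium
from .interventions import KINDS, InterventionSpec, post_intervention_prevalence
from .params import AUSTRALIA_DEFAULTS, CalibrationTargets

__all__ = ["phi_theta_grid", "effect_curves", "DEFAULT_PHI_GRID",
           "DEFAULT_THETA_GRID", "DEFAULT_EFFECT_GRID"]

logger = logging.getLogger(__name__)

DEFAULT_PHI_GRID = np.round(np.arange(0.05, 0.951, 0.05), 10)
DEFAULT_THETA_GRID = np.round(np.arange(1.0, 6.001, 0.25), 10)
DEFAULT_EFFECT_GRID = np.round(np.arange(0.0, 1.001, 0.02), 10)


def _rates(rates: dict[str, float] | None) -> dict[str, float]:
    merged = dict(AUSTRALIA_DEFAULTS)
    if rates:
        merged.update(rates)
    return merged


def phi_theta_grid(
    phi_values=DEFAULT_PHI_GRID,
    theta_values=DEFAULT_THETA_GRID,
    h_post: float = 0.5,
    targets: CalibrationTargets | None = None,
    rates: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Post-intervention equilibrium prevalence over a (phi, theta) grid.

    For each (phi, theta) the onset rate u is recalibrated at h = 1 to the
    baseline disorder-prevalence target; the selective intervention then
    sets h to ``h_post`` and the equilibrium prevalence is re-evaluated.
    With the default ``h_post = 0.5`` the intervention halves the fraction
    of the vulnerable population at increased risk.

    Returns a long-format frame with columns ``phi``, ``theta``, ``h_post``,
    ``prevalence`` (NaN for cells whose baseline target is infeasible, which
    are reported, never clamped).
    """
    if targets is None:
        targets = CalibrationTargets()
    r = _rates(rates)
    rows = []
    for theta in np.asarray(theta_values, dtype=float):
        for phi in np.asarray(phi_values, dtype=float):
            try:
                report = calibrate(phi, theta, targets, **r)
                prev = equilibrium(report.params.replace(h=h_post)).prevalence_D
            except CalibrationInfeasibleError as exc:
                logger.warning("cell (phi=%g, theta=%g) infeasible: %s",
                               phi, theta, exc)
                prev = float("nan")
            rows.append({"phi": phi, "theta": theta, "h_post": h_post,
                         "prevalence": prev})
    return pd.DataFrame(rows)


def effect_curves(
    phi: float,
    theta: float,
    effects=DEFAULT_EFFECT_GRID,
    targets: CalibrationTargets | None = None,
    rates: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Post-intervention prevalence vs individual-level effect, per intervention type.

    One calibrated baseline per (phi, theta); the universal, selective and
    indicated mechanisms are each swept over ``effects``. All three curves
    start at the baseline prevalence at effect 0 and are monotone
    non-increasing; the selective curve is bounded below by the h = 0
    (theta_eff = 1) limit.

    Returns a long-format frame with columns ``kind``, ``effect``,
    ``prevalence``.
    """
    if targets is None:
        targets = CalibrationTargets()
    baseline = calibrate(phi, theta, targets, **_rates(rates)).params
    rows = []
    for kind in KINDS:
        for effect in np.asarray(effects, dtype=float):
            prev = post_intervention_prevalence(
                baseline, InterventionSpec(kind=kind, effect=effect)
            )
            rows.append({"kind": kind, "effect": effect, "prevalence": prev})
    return pd.DataFrame(rows)
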