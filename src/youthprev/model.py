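"""High-level modelling interface: `PreventionModel` and `PreventionResults`.

A :class:`PreventionModel` is built from a vulnerability scenario
(phi, theta), fixed demographic/clinical rates and the empirical prevalence
targets; ``fit()`` calibrates the free rates (i from the prevalence-target
ratio unless fixed, u by root-finding, g by linear scaling) and returns a
:class:`PreventionResults` carrying the calibrated parameter vector, the
equilibrium, diagnostics and a ``summary()`` table. Intervention
comparison, transient simulation and sensitivity sweeps hang off the
results object.

Example
-------
>>> from youthprev import PreventionModel, InterventionSpec
>>> res = PreventionModel(phi=0.4, theta=2.0).fit()
>>> round(100 * res.prevalence_D, 2)
7.8
>>> spec = InterventionSpec("universal", 0.21)
>>> round(100 * res.intervene(spec), 2)
6.55
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import dynamics, sweeps
from .calibration import CalibrationReport, calibrate
from .equilibrium import equilibrium
from .interventions import (
    InterventionSpec,
    apply_intervention,
    compare_interventions,
)
from .params import (
    AUSTRALIA_DEFAULTS,
    CalibrationTargets,
    EquilibriumResult,
    ModelParameters,
    StockState,
)

__all__ = ["PreventionModel", "PreventionResults"]


class PreventionModel:
    """Four-compartment youth mental-disorder model for one vulnerability scenario.

    Parameters
    ----------
    phi : float
        Proportion of adolescents turning 12 who are vulnerable.
    theta : float
        Symptom-onset hazard ratio of the at-risk vulnerable population.
    targets : CalibrationTargets, optional
        Empirical equilibrium targets (defaults: 18.6% subthreshold, 7.80%
        full-threshold, population one million).
    i : float, optional
        Fix the progression rate instead of deriving it from the
        prevalence-target ratio.
    lam, mu, alpha, beta, gamma : float, optional
        Demographic rates and mortality hazard ratios; default to the
        Australian youth values.
    """

    def __init__(
        self,
        phi: float,
        theta: float,
        targets: CalibrationTargets | None = None,
        *,
        i: float | None = None,
        lam: float | None = None,
        mu: float | None = None,
        alpha: float | None = None,
        beta: float | None = None,
        gamma: float | None = None,
    ) -> None:
        self.phi = float(phi)
        self.theta = float(theta)
        self.targets = targets if targets is not None else CalibrationTargets()
        d = AUSTRALIA_DEFAULTS
        self.rates = {
            "lam": d["lam"] if lam is None else float(lam),
            "mu": d["mu"] if mu is None else float(mu),
            "alpha": d["alpha"] if alpha is None else float(alpha),
            "beta": d["beta"] if beta is None else float(beta),
            "gamma": d["gamma"] if gamma is None else float(gamma),
        }
        self.fixed_i = None if i is None else float(i)

    @classmethod
    def from_config(cls, config: dict) -> "PreventionModel":
        """Build a model from a parsed scenario-configuration mapping."""
        targets_cfg = config.get("targets", {})
        targets = CalibrationTargets(
            target_prev_D=float(targets_cfg.get("target_prev_D", 0.0780)),
            target_prev_S=float(targets_cfg.get("target_prev_S", 0.186)),
            target_population=float(targets_cfg.get("target_population", 1_000_000)),
        )
        p = config.get("parameters", {})
        return cls(
            phi=float(p["phi"]),
            theta=float(p["theta"]),
            targets=targets,
            i=float(p["i"]) if "i" in p else None,
            lam=float(p["lam"]) if "lam" in p else None,
            mu=float(p["mu"]) if "mu" in p else None,
            alpha=float(p["alpha"]) if "alpha" in p else None,
            beta=float(p["beta"]) if "beta" in p else None,
            gamma=float(p["gamma"]) if "gamma" in p else None,
        )

    def fit(self) -> "PreventionResults":
        """Calibrate i (unless fixed), u and g to the targets."""
        report = calibrate(
            self.phi, self.theta, self.targets, i=self.fixed_i, **self.rates
        )
        return PreventionResults(model=self, report=report)


@dataclass
class PreventionResults:
    """Calibrated scenario: parameter estimates, equilibrium and diagnostics."""

    model: PreventionModel
    report: CalibrationReport
    _equilibrium: EquilibriumResult = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._equilibrium = equilibrium(self.report.params)

    # -- estimates ---------------------------------------------------------

    @property
    def params(self) -> ModelParameters:
        """Calibrated pre-intervention parameter vector (h = 1)."""
        return self.report.params

    @property
    def equilibrium(self) -> EquilibriumResult:
        return self._equilibrium

    @property
    def prevalence_D(self) -> float:
        return self._equilibrium.prevalence_D

    @property
    def prevalence_S(self) -> float:
        return self._equilibrium.prevalence_S

    # -- interventions -----------------------------------------------------

    def intervene(self, spec: InterventionSpec) -> float:
        """Equilibrium disorder prevalence after permanently applying ``spec``."""
        return equilibrium(apply_intervention(self.params, spec)).prevalence_D

    def compare(self, specs: Sequence[InterventionSpec]) -> pd.DataFrame:
        """Comparison table of several interventions on this baseline."""
        return compare_interventions(self.params, specs)

    # -- dynamics ----------------------------------------------------------

    def simulate(
        self,
        t_end: float,
        switch: tuple[float, InterventionSpec] | None = None,
        initial: StockState | None = None,
        *,
        step: float = 0.1,
    ) -> dynamics.Trajectory:
        """Integrate a transient scenario; starts at equilibrium by default."""
        if initial is None:
            initial = self._equilibrium.stocks
        return dynamics.integrate(self.params, initial, t_end, switch, step=step)

    # -- sweeps ------------------------------------------------------------

    def effect_curves(self, effects=sweeps.DEFAULT_EFFECT_GRID) -> pd.DataFrame:
        """Prevalence-vs-effect curves for all three intervention types."""
        return sweeps.effect_curves(
            self.model.phi, self.model.theta, effects, self.model.targets,
            rates={**self.model.rates, "i": self.report.i},
        )

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Human-readable calibration and equilibrium summary."""
        p = self.params
        eq = self._equilibrium
        eigs = ", ".join(f"{e:.5f}" for e in eq.eigenvalues)
        lines = [
            "Youth mental-disorder stock-flow model — calibrated scenario",
            "=" * 62,
            f"Scenario           phi = {p.phi:g}, theta = {p.theta:g}, h = {p.h:g}",
            f"Fixed rates        lam = {p.lam:g}, mu = {p.mu:g}, "
            f"alpha/beta/gamma = {p.alpha:g}/{p.beta:g}/{p.gamma:g}",
            f"Calibrated rates   u = {self.report.u:.6g}, i = {self.report.i:.6g}, "
            f"g = {self.report.g:.6g}",
            "-" * 62,
            f"Equilibrium stocks N = {eq.stocks.N:,.0f}  V = {eq.stocks.V:,.0f}  "
            f"S = {eq.stocks.S:,.0f}  D = {eq.stocks.D:,.0f}",
            f"Total population   {eq.stocks.total:,.0f}",
            f"Prevalence         subthreshold = {100 * eq.prevalence_S:.2f}%   "
            f"full-threshold = {100 * eq.prevalence_D:.2f}%",
            f"Eigenvalues (1/yr) {eigs}   stable: {eq.stable}",
            f"Slowest timescale  {-1.0 / max(eq.eigenvalues):.1f} years",
        ]
        return "\n".join(lines)
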