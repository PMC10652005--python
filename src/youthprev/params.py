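"""Core domain types for the four-compartment youth mental-health model.

The model tracks a population of adolescents and young adults (12-24 years)
through four stocks: not-vulnerable (``N``), vulnerable (``V``), experiencing
subthreshold symptoms (``S``) and full-threshold mental disorder (``D``).
Adolescents enter at rate ``g`` per year, a fraction ``phi`` of them
vulnerable; symptom onset occurs at per capita rate ``u`` for the
non-vulnerable and ``[1 + h*(theta - 1)] * u`` for the vulnerable; progression
from subthreshold symptoms to full-threshold disorder occurs at per capita
rate ``i``; ageing (``lam``) and mortality (``mu`` scaled by hazard ratios
``alpha``, ``beta``, ``gamma``) remove people from every stock.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = [
    "ModelParameters",
    "StockState",
    "EquilibriumResult",
    "CalibrationTargets",
    "DomainViolationError",
    "DegenerateModelError",
    "effective_onset_multiplier",
]


class DomainViolationError(ValueError):
    """A parameter or argument lies outside its scientific domain."""


class DegenerateModelError(ValueError):
    """The model cannot be evaluated (e.g. all removal rates zero)."""


def effective_onset_multiplier(h: float, theta: float) -> float:
    """Multiplier applied to the onset rate ``u`` for the vulnerable stock.

    The vulnerable population develops symptoms at per capita rate
    ``[1 + h*(theta - 1)] * u``: ``theta`` is the symptom-onset hazard ratio
    of the (at-risk) vulnerable population relative to the non-vulnerable
    population, and ``h`` is the fraction of the vulnerable stock still at
    increased risk (1 before any selective prevention; selective
    interventions reduce it).

    Parameters
    ----------
    h : float
        Fraction of the vulnerable stock at increased risk, in [0, 1].
    theta : float
        Symptom-onset hazard ratio, >= 1.

    Returns
    -------
    float
        ``1 + h*(theta - 1)``, which lies in ``[1, theta]``.
    """
    if not 0.0 <= h <= 1.0:
        raise DomainViolationError(f"h must lie in [0, 1], got {h!r}")
    if theta < 1.0:
        raise DomainViolationError(f"theta must be >= 1, got {theta!r}")
    return 1.0 + h * (theta - 1.0)


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter vector of the stock-flow system.

    Attributes
    ----------
    phi : float
        Proportion of adolescents turning 12 who are vulnerable, in [0, 1].
    theta : float
        Symptom-onset hazard ratio, vulnerable vs non-vulnerable; >= 1.
    u : float
        Per capita symptom-onset rate of the non-vulnerable population
        (per person-year); >= 0.
    h : float
        Fraction of the vulnerable population at increased risk, in [0, 1];
        equal to 1 before any selective intervention.
    i : float
        Per capita disease-progression rate from subthreshold symptoms to
        full-threshold disorder (per person-year); >= 0.
    lam : float
        Ageing-out rate: reciprocal of the number of years spent in the
        youth population (per person-year); >= 0.
    mu : float
        Per capita mortality rate of the non-vulnerable population
        (per person-year); >= 0.
    alpha, beta, gamma : float
        Mortality hazard ratios of the vulnerable, subthreshold and
        full-threshold stocks relative to the non-vulnerable stock;
        must satisfy ``1 <= alpha < beta < gamma``.
    g : float
        Yearly inflow of adolescents turning 12 (persons per year); >= 0.
    """

    phi: float
    theta: float
    u: float
    h: float = 1.0
    i: float = 0.0
    lam: float = 0.0
    mu: float = 0.0
    alpha: float = 1.0
    beta: float = 1.2
    gamma: float = 1.673
    g: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise DomainViolationError(f"phi must lie in [0, 1], got {self.phi!r}")
        if self.theta < 1.0:
            raise DomainViolationError(f"theta must be >= 1, got {self.theta!r}")
        if not 0.0 <= self.h <= 1.0:
            raise DomainViolationError(f"h must lie in [0, 1], got {self.h!r}")
        for name in ("u", "i", "lam", "mu", "g"):
            value = getattr(self, name)
            if value < 0.0 or not np.isfinite(value):
                raise DomainViolationError(
                    f"{name} must be a finite non-negative rate, got {value!r}"
                )
        if not (1.0 <= self.alpha < self.beta < self.gamma):
            raise DomainViolationError(
                "mortality hazard ratios must satisfy 1 <= alpha < beta < gamma, "
                f"got alpha={self.alpha!r}, beta={self.beta!r}, gamma={self.gamma!r}"
            )

    @property
    def theta_eff(self) -> float:
        """Effective onset multiplier ``1 + h*(theta - 1)`` (recomputed on access)."""
        return effective_onset_multiplier(self.h, self.theta)

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced (validation re-runs)."""
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {
            "phi": self.phi,
            "theta": self.theta,
            "u": self.u,
            "h": self.h,
            "i": self.i,
            "lam": self.lam,
            "mu": self.mu,
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "g": self.g,
        }

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParameters":
        return cls(**{k: float(v) for k, v in d.items()})


# Table of literature-sourced defaults for the Australian youth population:
# progression rate i derived from the 18.6%/7.80% prevalence targets, ageing
# over a 13-year window (1/13 = 0.07692), mortality and its hazard ratios
# from national statistics.
AUSTRALIA_DEFAULTS: dict[str, float] = {
    "i": 0.03251,
    "lam": 0.07692,
    "mu": 0.0003343,
    "alpha": 1.0,
    "beta": 1.2,
    "gamma": 1.673,
}


@dataclass(frozen=True)
class StockState:
    """Compartment levels at one time point (persons)."""

    N: float
    V: float
    S: float
    D: float
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("N", "V", "S", "D"):
            value = getattr(self, name)
            if value < 0.0 or not np.isfinite(value):
                raise DomainViolationError(
                    f"stock {name} must be finite and non-negative, got {value!r}"
                )

    @property
    def total(self) -> float:
        return self.N + self.V + self.S + self.D

    def as_array(self) -> np.ndarray:
        return np.array([self.N, self.V, self.S, self.D], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray, t: float = 0.0) -> "StockState":
        return cls(N=float(y[0]), V=float(y[1]), S=float(y[2]), D=float(y[3]), t=t)

    def __iter__(self) -> Iterator[float]:
        return iter((self.N, self.V, self.S, self.D))

    def to_dict(self) -> dict[str, float]:
        return {"t": self.t, "N": self.N, "V": self.V, "S": self.S, "D": self.D}


@dataclass(frozen=True)
class EquilibriumResult:
    """Closed-form equilibrium of the system with its stability diagnostics.

    ``prevalence_S`` and ``prevalence_D`` are proportions of the total
    population (S/total, D/total). When the inflow ``g`` is zero the
    equilibrium is the empty population and prevalences are undefined
    (``nan`` with ``prevalence_defined`` False) rather than an error.
    """

    stocks: StockState
    prevalence_S: float
    prevalence_D: float
    eigenvalues: tuple[float, float, float, float]
    stable: bool
    prevalence_defined: bool = True

    def to_dict(self) -> dict[str, float]:
        d = {"N": self.stocks.N, "V": self.stocks.V, "S": self.stocks.S,
             "D": self.stocks.D}
        d["prevalence_S"] = self.prevalence_S
        d["prevalence_D"] = self.prevalence_D
        return d


@dataclass(frozen=True)
class CalibrationTargets:
    """Empirical targets the pre-intervention equilibrium must reproduce.

    Defaults are the Australian youth estimates: 18.6% with subthreshold
    symptoms, 7.80% with full-threshold disorders, in a constant population
    of one million.
    """

    target_prev_D: float = 0.0780
    target_prev_S: float = 0.186
    target_population: float = 1_000_000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_prev_D < 1.0:
            raise DomainViolationError(
                f"target_prev_D must lie in (0, 1), got {self.target_prev_D!r}"
            )
        if not 0.0 < self.target_prev_S < 1.0:
            raise DomainViolationError(
                f"target_prev_S must lie in (0, 1), got {self.target_prev_S!r}"
            )
        if self.target_prev_D + self.target_prev_S >= 1.0:
            raise DomainViolationError(
                "target prevalences must sum to less than 1"
            )
        if self.target_population <= 0.0:
            raise DomainViolationError(
                f"target_population must be positive, got {self.target_population!r}"
            )
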