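"""Prevention mechanisms and their population-level equilibrium effects.

Three intervention types are modelled through the parameter they touch:

* universal — delivered population-wide; proportionally reduces the per
  capita symptom-onset rate u (individual-level effect = -du/u0);
* selective — targets the vulnerable (risk-factor-exposed) population;
  reduces h, the fraction of the vulnerable stock at increased risk
  (effect = -dh, an absolute decrement which equals the proportional one
  when the pre-intervention h is 1);
* indicated — targets those with subthreshold symptoms; proportionally
  reduces the progression rate i (effect = -di/i0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .equilibrium import equilibrium
from .params import DomainViolationError, ModelParameters

__all__ = [
    "InterventionSpec",
    "apply_intervention",
    "post_intervention_prevalence",
    "compare_interventions",
]

logger = logging.getLogger(__name__)

KINDS = ("universal", "selective", "indicated")


@dataclass(frozen=True)
class InterventionSpec:
    """One preventive intervention: its type and individual-level effect.

    ``effect`` in [0, 1] is the proportional reduction of u (universal) or
    i (indicated), or the absolute reduction of h (selective).
    """

    kind: str
    effect: float

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise DomainViolationError(
                f"kind must be one of {KINDS}, got {self.kind!r}"
            )
        if not 0.0 <= self.effect <= 1.0:
            raise DomainViolationError(
                f"effect must lie in [0, 1], got {self.effect!r}"
            )

    @classmethod
    def parse(cls, text: str) -> "InterventionSpec":
        """Parse a ``kind:effect`` string, e.g. ``universal:0.21``."""
        kind, _, effect = text.partition(":")
        if not effect:
            raise DomainViolationError(
                f"expected 'kind:effect' (e.g. 'universal:0.21'), got {text!r}"
            )
        return cls(kind=kind.strip(), effect=float(effect))


def apply_intervention(
    params: ModelParameters, spec: InterventionSpec
) -> ModelParameters:
    """Return a parameter vector with the intervention's effect applied.

    universal: u' = (1 - effect) * u; indicated: i' = (1 - effect) * i;
    selective: h' = h - effect, clamped at 0 (with a warning) if the
    decrement exceeds the remaining h. The input is never mutated, so
    stacked interventions compose by sequential application; effects on
    disjoint parameters are order-independent.
    """
    if spec.kind == "universal":
        return params.replace(u=(1.0 - spec.effect) * params.u)
    if spec.kind == "indicated":
        return params.replace(i=(1.0 - spec.effect) * params.i)
    h_new = params.h - spec.effect
    if h_new < 0.0:
        logger.warning(
            "selective effect %.3g exceeds current h=%.3g; clamping h to 0",
            spec.effect, params.h,
        )
        h_new = 0.0
    return params.replace(h=h_new)


def post_intervention_prevalence(
    baseline: ModelParameters, spec: InterventionSpec
) -> float:
    """Equilibrium disorder prevalence after permanently applying one intervention.

    ``baseline`` should be a calibrated pre-intervention scenario (h = 1);
    the result never exceeds the baseline prevalence and equals it at
    effect 0.
    """
    return equilibrium(apply_intervention(baseline, spec)).prevalence_D


def compare_interventions(
    baseline: ModelParameters, specs: Sequence[InterventionSpec] | Iterable[InterventionSpec]
) -> pd.DataFrame:
    """Side-by-side equilibrium comparison of interventions on one calibrated baseline.

    Returns one row per spec, in the supplied order, with columns ``kind``,
    ``effect``, ``prevalence`` (proportion), ``prevalence_pct``,
    ``abs_reduction_pct_points`` and ``rel_reduction``.
    """
    specs = list(specs)
    if not specs:
        raise DomainViolationError("at least one intervention spec is required")
    base_prev = equilibrium(baseline).prevalence_D
    rows = []
    for spec in specs:
        prev = post_intervention_prevalence(baseline, spec)
        rows.append(
            {
                "kind": spec.kind,
                "effect": spec.effect,
                "prevalence": prev,
                "prevalence_pct": 100.0 * prev,
                "abs_reduction_pct_points": 100.0 * (base_prev - prev),
                "rel_reduction": (base_prev - prev) / base_prev,
            }
        )
    return pd.DataFrame(rows)
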