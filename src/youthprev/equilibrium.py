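"""Flow equations, closed-form equilibrium and stability analysis.

The system is linear with constant coefficients:

    dN/dt = (1 - phi) g - u N - (lam + mu) N
    dV/dt = phi g - theta_eff u V - (lam + alpha mu) V
    dS/dt = u N + theta_eff u V - i S - (lam + beta mu) S
    dD/dt = i S - (lam + gamma mu) D

with ``theta_eff = 1 + h (theta - 1)``. Setting the derivatives to zero and
solving sequentially (the coupling is strictly feed-forward N,V -> S -> D)
gives the closed-form equilibrium used throughout the package; the Jacobian
is lower-triangular in the ordering (N, V, S, D), so the eigenvalues are the
negated diagonal removal rates and the equilibrium is always locally stable
when all removal rates are positive.
"""

from __future__ import annotations

import numpy as np

from .params import (
    DegenerateModelError,
    EquilibriumResult,
    ModelParameters,
    StockState,
)

__all__ = ["flow_derivatives", "jacobian", "stability_eigenvalues", "equilibrium"]


def flow_derivatives(state: StockState, params: ModelParameters) -> np.ndarray:
    """Time-derivatives (dN/dt, dV/dt, dS/dt, dD/dt) in persons per year.

    Flows are conservative: the four derivatives sum to the inflow ``g``
    minus total removals by ageing and mortality.
    """
    p = params
    te = p.theta_eff
    N, V, S, D = state.N, state.V, state.S, state.D
    dN = (1.0 - p.phi) * p.g - p.u * N - (p.lam + p.mu) * N
    dV = p.phi * p.g - te * p.u * V - (p.lam + p.alpha * p.mu) * V
    dS = p.u * N + te * p.u * V - p.i * S - (p.lam + p.beta * p.mu) * S
    dD = p.i * S - (p.lam + p.gamma * p.mu) * D
    return np.array([dN, dV, dS, dD], dtype=float)


def jacobian(params: ModelParameters) -> np.ndarray:
    """4x4 Jacobian of the flow field in the stock ordering (N, V, S, D).

    Lower-triangular: onset feeds N and V forward into S, progression feeds
    S into D, and nothing feeds back.
    """
    p = params
    te = p.theta_eff
    return np.array(
        [
            [-(p.u + p.lam + p.mu), 0.0, 0.0, 0.0],
            [0.0, -(te * p.u + p.lam + p.alpha * p.mu), 0.0, 0.0],
            [p.u, te * p.u, -(p.i + p.lam + p.beta * p.mu), 0.0],
            [0.0, 0.0, p.i, -(p.lam + p.gamma * p.mu)],
        ],
        dtype=float,
    )


def stability_eigenvalues(
    params: ModelParameters,
) -> tuple[tuple[float, float, float, float], bool]:
    """Analytic eigenvalues (per year) of the Jacobian and a stability flag.

    Because the Jacobian is lower-triangular, the eigenvalues are its
    diagonal entries: the negated per capita removal rates of the four
    stocks. The slowest (least negative) eigenvalue sets the convergence
    time scale of any transient; with the default rates it is
    ``-(lam + gamma*mu)``, the removal rate of the disorder stock.
    """
    p = params
    te = p.theta_eff
    eigs = (
        -(p.u + p.lam + p.mu),
        -(te * p.u + p.lam + p.alpha * p.mu),
        -(p.i + p.lam + p.beta * p.mu),
        -(p.lam + p.gamma * p.mu),
    )
    return eigs, all(e < 0.0 for e in eigs)


def equilibrium(params: ModelParameters) -> EquilibriumResult:
    """Closed-form equilibrium stocks, prevalences and stability.

    Solves the steady-state equations sequentially:

        N* = (1 - phi) g / (u + lam + mu)
        V* = phi g / (theta_eff u + lam + alpha mu)
        S* = (u N* + theta_eff u V*) / (i + lam + beta mu)
        D* = i S* / (lam + gamma mu)

    Raises
    ------
    DegenerateModelError
        If any removal-rate denominator is zero (the corresponding stock
        would grow without bound and no equilibrium exists).

    Notes
    -----
    With ``g = 0`` the equilibrium is the empty population; prevalences are
    then reported as ``nan`` and flagged undefined rather than raising, so
    that parameter sweeps remain robust.
    """
    p = params
    te = p.theta_eff
    denom_N = p.u + p.lam + p.mu
    denom_V = te * p.u + p.lam + p.alpha * p.mu
    denom_S = p.i + p.lam + p.beta * p.mu
    denom_D = p.lam + p.gamma * p.mu
    for name, d in (("N", denom_N), ("V", denom_V), ("S", denom_S), ("D", denom_D)):
        if d <= 0.0:
            raise DegenerateModelError(
                f"removal rate of stock {name} is zero; no equilibrium exists"
            )
    N = (1.0 - p.phi) * p.g / denom_N
    V = p.phi * p.g / denom_V
    S = (p.u * N + te * p.u * V) / denom_S
    D = p.i * S / denom_D
    total = N + V + S + D
    if total > 0.0:
        prev_S, prev_D, defined = S / total, D / total, True
    else:
        prev_S, prev_D, defined = float("nan"), float("nan"), False
    eigs, stable = stability_eigenvalues(p)
    return EquilibriumResult(
        stocks=StockState(N=N, V=V, S=S, D=D),
        prevalence_S=prev_S,
        prevalence_D=prev_D,
        eigenvalues=eigs,
        stable=stable,
        prevalence_defined=defined,
    )
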