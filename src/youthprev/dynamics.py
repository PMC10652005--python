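"""Transient trajectories and convergence-time diagnostics.

The flow field is linear and non-stiff at the default rates (all removal
rates well below 1 per year), so a fixed-step classical Runge-Kutta scheme
is accurate, deterministic and trivially reproducible. An intervention
switch, if given, is forced onto the time grid and the parameters change
exactly once there, remaining in place for the rest of the integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equilibrium import flow_derivatives
from .interventions import InterventionSpec, apply_intervention
from .params import DomainViolationError, ModelParameters, StockState

__all__ = ["Trajectory", "integrate", "time_to_equilibrium", "NOT_REACHED"]

#: Sentinel returned by time_to_equilibrium when the band is never entered
#: (or not held through the end of the trajectory).
NOT_REACHED = float("nan")


@dataclass(frozen=True)
class Trajectory:
    """Integrated trajectory: times, stock matrix and derived prevalence series."""

    times: np.ndarray            # (n,), strictly increasing, years
    stocks: np.ndarray           # (n, 4) columns N, V, S, D
    switch_time: float | None = None

    def __post_init__(self) -> None:
        if len(self.times) == 0:
            raise DomainViolationError("trajectory must contain at least one point")
        if len(self.times) != len(self.stocks):
            raise DomainViolationError("times and states must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise DomainViolationError("times must be strictly increasing")

    @property
    def totals(self) -> np.ndarray:
        return self.stocks.sum(axis=1)

    @property
    def prevalence_D_series(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.totals > 0, self.stocks[:, 3] / self.totals, np.nan)

    @property
    def states(self) -> list[StockState]:
        return [
            StockState.from_array(row, t=float(t))
            for t, row in zip(self.times, self.stocks)
        ]

    def final_state(self) -> StockState:
        return StockState.from_array(self.stocks[-1], t=float(self.times[-1]))

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame with columns time, N, V, S, D, prevalence_D."""
        return pd.DataFrame(
            {
                "time": self.times,
                "N": self.stocks[:, 0],
                "V": self.stocks[:, 1],
                "S": self.stocks[:, 2],
                "D": self.stocks[:, 3],
                "prevalence_D": self.prevalence_D_series,
            }
        )


def _rk4_segment(
    params: ModelParameters, y0: np.ndarray, t0: float, t1: float, step: float
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one constant-parameter segment; returns (times, stocks).

    The segment is divided into equal steps no larger than ``step`` so the
    endpoint lands exactly on ``t1``.
    """
    n_steps = max(1, int(np.ceil((t1 - t0) / step - 1e-12)))
    dt = (t1 - t0) / n_steps
    times = t0 + dt * np.arange(n_steps + 1)
    times[-1] = t1
    out = np.empty((n_steps + 1, 4))
    out[0] = y0
    y = y0.copy()

    def f(y: np.ndarray) -> np.ndarray:
        # evaluate the flow field on a raw array (negative transients from
        # round-off are tolerated here; the result is validated at the end)
        state = StockState.__new__(StockState)
        object.__setattr__(state, "N", y[0])
        object.__setattr__(state, "V", y[1])
        object.__setattr__(state, "S", y[2])
        object.__setattr__(state, "D", y[3])
        object.__setattr__(state, "t", 0.0)
        return flow_derivatives(state, params)

    for k in range(n_steps):
        k1 = f(y)
        k2 = f(y + 0.5 * dt * k1)
        k3 = f(y + 0.5 * dt * k2)
        k4 = f(y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[k + 1] = y
    return times, out


def integrate(
    params: ModelParameters,
    initial: StockState,
    t_end: float,
    switch: tuple[float, InterventionSpec] | None = None,
    *,
    step: float = 0.1,
) -> Trajectory:
    """Integrate the stock-flow system forward from ``initial`` until ``t_end``.

    Parameters
    ----------
    params : ModelParameters
        Pre-switch parameters.
    initial : StockState
        Starting stocks; ``initial.t`` is the start time.
    t_end : float
        End time (years), must exceed the start time.
    switch : (time, InterventionSpec), optional
        A single permanent parameter change: at the switch time the
        intervention is applied via :func:`apply_intervention` and the new
        parameters remain in place indefinitely. The switch time is always
        a grid point.
    step : float
        Maximum Runge-Kutta step (years). The default 0.1 resolves rates of
        order 0.1/year to ~1e-10 relative accuracy.

    Raises
    ------
    DomainViolationError
        For a non-positive time span or a switch time outside (t0, t_end).
    RuntimeError
        If the integration produces non-finite values.
    """
    t0 = initial.t
    if t_end <= t0:
        raise DomainViolationError(f"t_end={t_end!r} must exceed start time {t0!r}")
    if step <= 0.0:
        raise DomainViolationError("step must be positive")
    y0 = initial.as_array()

    if switch is None:
        times, stocks = _rk4_segment(params, y0, t0, t_end, step)
        switch_time = None
    else:
        switch_time, spec = switch
        if not t0 < switch_time < t_end:
            raise DomainViolationError(
                f"switch time {switch_time!r} must lie strictly between "
                f"{t0!r} and {t_end!r}"
            )
        t_pre, y_pre = _rk4_segment(params, y0, t0, switch_time, step)
        post_params = apply_intervention(params, spec)
        t_post, y_post = _rk4_segment(post_params, y_pre[-1], switch_time, t_end, step)
        times = np.concatenate([t_pre, t_post[1:]])
        stocks = np.concatenate([y_pre, y_post[1:]])

    if not np.all(np.isfinite(stocks)):
        raise RuntimeError("integration failed: non-finite stocks encountered")
    # round-off can leave tiny negative values near zero stocks
    stocks = np.clip(stocks, 0.0, None)
    return Trajectory(times=times, stocks=stocks, switch_time=switch_time)


def time_to_equilibrium(
    traj: Trajectory, target: float, epsilon: float
) -> float:
    """Years after the switch until prevalence settles within ``epsilon`` of ``target``.

    Scans the trajectory after its switch time (or from its start when no
    switch was recorded) for the first time at which
    ``|prevalence_D - target| < epsilon`` holds and continues to hold
    through the end of the trajectory. Returns :data:`NOT_REACHED`
    (``nan``) if the band is never entered for good; smaller ``epsilon``
    can only increase the returned time.
    """
    if epsilon <= 0.0:
        raise DomainViolationError("epsilon must be positive")
    t_ref = traj.switch_time if traj.switch_time is not None else traj.times[0]
    prev = traj.prevalence_D_series
    inside = np.abs(prev - target) < epsilon
    after = traj.times >= t_ref
    # first index from which `inside` holds at every later point after t_ref
    holds_to_end = np.logical_and.accumulate(inside[::-1])[::-1]
    candidates = np.flatnonzero(holds_to_end & after)
    if candidates.size == 0:
        return NOT_REACHED
    return float(traj.times[candidates[0]] - t_ref)
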