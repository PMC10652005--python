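"""Transient integration against the closed-form equilibria."""

import numpy as np
import pytest

from youthprev import (
    DomainViolationError,
    InterventionSpec,
    apply_intervention,
    equilibrium,
    integrate,
    stability_eigenvalues,
    time_to_equilibrium,
)
from youthprev.dynamics import NOT_REACHED, Trajectory

SPECS = [InterventionSpec("universal", 0.21),
         InterventionSpec("selective", 0.44),
         InterventionSpec("indicated", 0.31)]


def test_starting_at_equilibrium_stays_there(table1_params):
    eq = equilibrium(table1_params)
    traj = integrate(table1_params, eq.stocks, t_end=100.0)
    assert np.all(np.abs(traj.prevalence_D_series - 0.0780) < 1e-8)


@pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.kind)
def test_switch_converges_to_post_intervention_equilibrium(table1_params, spec):
    """A permanent switch at t=1000 relaxes onto the new closed-form equilibrium."""
    eq = equilibrium(table1_params)
    traj = integrate(table1_params, eq.stocks, t_end=1300.0, switch=(1000.0, spec))
    target = equilibrium(apply_intervention(table1_params, spec))
    final = traj.final_state()
    np.testing.assert_allclose(
        final.as_array(), target.stocks.as_array(), rtol=1e-6
    )
    assert traj.prevalence_D_series[-1] == pytest.approx(
        target.prevalence_D, rel=1e-6
    )


def test_universal_terminal_prevalence_matches_headline(table1_params):
    eq = equilibrium(table1_params)
    traj = integrate(table1_params, eq.stocks, t_end=1200.0,
                     switch=(1000.0, InterventionSpec("universal", 0.21)))
    assert traj.prevalence_D_series[-1] == pytest.approx(0.0655, abs=1e-4)


def test_step_halving_leaves_prevalence_unchanged(table1_params):
    """The integrator is converged: halving the step moves nothing by > 1e-8."""
    eq = equilibrium(table1_params)
    kw = dict(t_end=1050.0, switch=(1000.0, InterventionSpec("selective", 0.5)))
    coarse = integrate(table1_params, eq.stocks, step=0.1, **kw)
    fine = integrate(table1_params, eq.stocks, step=0.05, **kw)
    shared = np.isin(np.round(fine.times, 9), np.round(coarse.times, 9))
    assert np.max(np.abs(
        fine.prevalence_D_series[shared] - coarse.prevalence_D_series
    )) < 1e-8


def test_switch_time_lands_on_grid(table1_params):
    eq = equilibrium(table1_params)
    traj = integrate(table1_params, eq.stocks, t_end=1100.0,
                     switch=(1000.0, InterventionSpec("universal", 0.21)),
                     step=0.3)
    assert np.any(traj.times == 1000.0)


def test_monotone_approach_after_switch(table1_params):
    """Real negative eigenvalues: prevalence moves to the new level without overshoot."""
    eq = equilibrium(table1_params)
    traj = integrate(table1_params, eq.stocks, t_end=1300.0,
                     switch=(1000.0, InterventionSpec("universal", 0.21)))
    post = traj.prevalence_D_series[traj.times >= 1000.0]
    assert np.all(np.diff(post) <= 1e-12)


def test_population_conserved_along_trajectory(table1_params):
    eq = equilibrium(table1_params)
    traj = integrate(table1_params, eq.stocks, t_end=1000.0)
    assert np.max(np.abs(traj.totals / 1_000_000 - 1.0)) < 1e-9


def test_population_shift_after_switch_is_tiny(table1_params):
    """An intervention redistributes people toward lower-mortality stocks, so the
    total drifts off 1,000,000 — but only by the mortality differentials,
    a few parts in 10^5 here."""
    eq = equilibrium(table1_params)
    traj = integrate(table1_params, eq.stocks, t_end=1300.0,
                     switch=(1000.0, InterventionSpec("selective", 0.5)))
    drift = np.abs(traj.totals / 1_000_000 - 1.0)
    assert drift[-1] > 0.0  # the shift is real ...
    assert np.max(drift) < 1e-4  # ... and bounded by the mortality differentials


def test_invalid_time_spans_rejected(table1_params):
    eq = equilibrium(table1_params)
    with pytest.raises(DomainViolationError):
        integrate(table1_params, eq.stocks, t_end=0.0)
    with pytest.raises(DomainViolationError):
        integrate(table1_params, eq.stocks, t_end=10.0,
                  switch=(20.0, SPECS[0]))


def test_trajectory_frame_is_tidy(table1_params):
    eq = equilibrium(table1_params)
    frame = integrate(table1_params, eq.stocks, t_end=5.0).to_frame()
    assert list(frame.columns) == ["time", "N", "V", "S", "D", "prevalence_D"]
    assert len(frame) == 51


class TestTimeToEquilibrium:
    def test_already_at_target_returns_zero(self, table1_params):
        eq = equilibrium(table1_params)
        traj = integrate(table1_params, eq.stocks, t_end=50.0)
        assert time_to_equilibrium(traj, 0.0780, 1e-6) == 0.0

    def test_relaxation_time_tracks_dominant_eigenvalue(self, table1_params):
        """Covering 90% of the prevalence change takes ~ln(10)/|slowest eigenvalue|,
        about 30 years at the reference rates."""
        spec = InterventionSpec("universal", 0.21)
        eq = equilibrium(table1_params)
        traj = integrate(table1_params, eq.stocks, t_end=1400.0,
                         switch=(1000.0, spec))
        target = equilibrium(apply_intervention(table1_params, spec)).prevalence_D
        eps = 0.1 * abs(0.0780 - target)
        t90 = time_to_equilibrium(traj, target, eps)
        slowest = max(stability_eigenvalues(table1_params)[0])
        bound = np.log(10.0) / abs(slowest)  # single-exponential estimate, ~30 y
        assert 0.5 * bound < t90 < 1.5 * bound

    def test_monotone_in_epsilon(self, table1_params):
        spec = InterventionSpec("universal", 0.21)
        eq = equilibrium(table1_params)
        traj = integrate(table1_params, eq.stocks, t_end=1400.0,
                         switch=(1000.0, spec))
        target = equilibrium(apply_intervention(table1_params, spec)).prevalence_D
        delta = abs(0.0780 - target)
        times = [time_to_equilibrium(traj, target, f * delta)
                 for f in (0.2, 0.1, 0.05, 0.01)]
        assert np.all(np.diff(times) >= 0)

    def test_band_never_held_returns_flag(self, table1_params):
        eq = equilibrium(table1_params)
        traj = integrate(table1_params, eq.stocks, t_end=20.0,
                         switch=(10.0, InterventionSpec("universal", 0.21)))
        # 20 years is far too short to settle within a hair of the new level
        result = time_to_equilibrium(traj, 0.0655, 1e-7)
        assert np.isnan(result) and np.isnan(NOT_REACHED)

    def test_requires_positive_epsilon(self, table1_params):
        eq = equilibrium(table1_params)
        traj = integrate(table1_params, eq.stocks, t_end=5.0)
        with pytest.raises(DomainViolationError):
            time_to_equilibrium(traj, 0.078, 0.0)


def test_trajectory_invariants_enforced():
    with pytest.raises(DomainViolationError):
        Trajectory(times=np.array([0.0, 1.0, 1.0]), stocks=np.zeros((3, 4)))
    with pytest.raises(DomainViolationError):
        Trajectory(times=np.array([0.0]), stocks=np.zeros((2, 4)))
    with pytest.raises(DomainViolationError):
        Trajectory(times=np.array([]), stocks=np.zeros((0, 4)))
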