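"""Intervention mechanics and population-level equilibrium effects."""

import numpy as np
import pytest

from youthprev import (
    DomainViolationError,
    InterventionSpec,
    PreventionModel,
    apply_intervention,
    compare_interventions,
    equilibrium,
    post_intervention_prevalence,
)


class TestApplyIntervention:
    def test_universal_scales_onset_rate(self, table1_params):
        out = apply_intervention(table1_params, InterventionSpec("universal", 0.21))
        assert out.u == pytest.approx(0.79 * table1_params.u, rel=1e-15)
        assert out.i == table1_params.i and out.h == table1_params.h

    def test_selective_decrements_h(self, table1_params):
        out = apply_intervention(table1_params, InterventionSpec("selective", 0.5))
        assert out.h == 0.5
        assert out.u == table1_params.u and out.i == table1_params.i

    def test_indicated_scales_progression_rate(self, table1_params):
        out = apply_intervention(table1_params, InterventionSpec("indicated", 0.31))
        assert out.i == pytest.approx(0.69 * table1_params.i, rel=1e-15)

    def test_zero_effect_is_identity(self, table1_params):
        for kind in ("universal", "selective", "indicated"):
            assert apply_intervention(
                table1_params, InterventionSpec(kind, 0.0)
            ) == table1_params

    def test_input_not_mutated(self, table1_params):
        u0 = table1_params.u
        apply_intervention(table1_params, InterventionSpec("universal", 0.5))
        assert table1_params.u == u0

    def test_selective_overshoot_clamps_to_zero(self, table1_params, caplog):
        half = apply_intervention(table1_params, InterventionSpec("selective", 0.7))
        with caplog.at_level("WARNING"):
            out = apply_intervention(half, InterventionSpec("selective", 0.7))
        assert out.h == 0.0
        assert any("clamping" in r.message for r in caplog.records)

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_effect_out_of_range_rejected(self, bad):
        with pytest.raises(DomainViolationError):
            InterventionSpec("universal", bad)

    def test_unknown_kind_rejected(self):
        with pytest.raises(DomainViolationError):
            InterventionSpec("heroic", 0.1)

    def test_parse_kind_effect_strings(self):
        assert InterventionSpec.parse("universal:0.21") == InterventionSpec(
            "universal", 0.21
        )
        with pytest.raises(DomainViolationError):
            InterventionSpec.parse("universal")

    def test_stacked_effects_on_disjoint_parameters_commute(self, table1_params):
        a = InterventionSpec("universal", 0.2)
        b = InterventionSpec("indicated", 0.3)
        ab = apply_intervention(apply_intervention(table1_params, a), b)
        ba = apply_intervention(apply_intervention(table1_params, b), a)
        assert ab == ba


class TestPopulationLevelEffects:
    def test_headline_prevalences(self, table1_results):
        """Real-world effects 0.21/0.44/0.31 move 7.80% to 6.55/7.17/5.93%."""
        expected = {"universal": (0.21, 6.55), "selective": (0.44, 7.17),
                    "indicated": (0.31, 5.93)}
        for kind, (effect, pct) in expected.items():
            prev = table1_results.intervene(InterventionSpec(kind, effect))
            assert 100 * prev == pytest.approx(pct, abs=0.01)

    def test_prevalence_monotone_in_effect(self, table1_params):
        for kind in ("universal", "selective", "indicated"):
            prevs = [
                post_intervention_prevalence(table1_params,
                                             InterventionSpec(kind, e))
                for e in np.linspace(0.0, 1.0, 21)
            ]
            assert np.all(np.diff(prevs) <= 1e-15)
            assert prevs[0] == pytest.approx(0.0780, abs=1e-10)

    def test_universal_indicated_near_equivalence(self, table1_params):
        """At (phi=0.4, theta=2) the universal and indicated curves stay within
        0.2 percentage points of each other for effects up to 0.4."""
        for e in np.linspace(0.0, 0.4, 21):
            pu = post_intervention_prevalence(table1_params,
                                              InterventionSpec("universal", e))
            pi = post_intervention_prevalence(table1_params,
                                              InterventionSpec("indicated", e))
            assert abs(pu - pi) < 0.002

    def test_selective_cannot_beat_total_onset_removal(self):
        """Full selective coverage leaves non-vulnerable onset untouched."""
        for phi, theta in [(0.2, 2.0), (0.6, 4.0), (0.9, 1.5)]:
            params = PreventionModel(phi=phi, theta=theta).fit().params
            p_sel = post_intervention_prevalence(params,
                                                 InterventionSpec("selective", 1.0))
            p_uni = post_intervention_prevalence(params,
                                                 InterventionSpec("universal", 1.0))
            assert p_sel >= p_uni

    def test_selective_null_when_theta_is_one(self):
        """With theta=1 the vulnerable have no excess risk; h is irrelevant."""
        params = PreventionModel(phi=0.4, theta=1.0).fit().params
        base = equilibrium(params).prevalence_D
        for e in (0.2, 0.5, 1.0):
            assert post_intervention_prevalence(
                params, InterventionSpec("selective", e)
            ) == pytest.approx(base, rel=1e-12)


class TestComparisonTable:
    def test_rows_follow_input_order_and_values(self, table1_results):
        specs = [InterventionSpec("universal", 0.21),
                 InterventionSpec("selective", 0.44),
                 InterventionSpec("indicated", 0.31)]
        table = table1_results.compare(specs)
        assert list(table["kind"]) == ["universal", "selective", "indicated"]
        assert table["prevalence"].tolist() == pytest.approx(
            [0.0655, 0.0717, 0.0593], abs=1e-4
        )
        np.testing.assert_allclose(
            table["prevalence_pct"], 100 * table["prevalence"], rtol=1e-15
        )

    def test_zero_effects_show_baseline_and_no_reduction(self, table1_results):
        specs = [InterventionSpec(k, 0.0)
                 for k in ("universal", "selective", "indicated")]
        table = table1_results.compare(specs)
        assert table["prevalence"].tolist() == pytest.approx([0.0780] * 3,
                                                             abs=1e-10)
        assert table["abs_reduction_pct_points"].tolist() == pytest.approx(
            [0.0] * 3, abs=1e-8
        )

    def test_empty_spec_list_rejected(self, table1_params):
        with pytest.raises(DomainViolationError):
            compare_interventions(table1_params, [])
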