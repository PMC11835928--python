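"""Tests for the named restriction analyses on the bundled example plants.

Frozen expected values were computed with an independent scalar
implementation of the same equations (plain-Python loops over the
interpolated inputs) before the engine was written.
"""

import numpy as np
import pytest

from photorestrict import (
    Conductances,
    LightParams,
    NRHParams,
    OperationalPoint,
    control_analysis,
    diffusional_limitation,
    light_assimilation,
    light_limitation,
    light_nonlight,
    path_dependent_contributions,
    stomatal_limitation,
    stomatal_nonstomatal,
    treatment_contributions,
)
from photorestrict.analyses import scaled_light_params
from photorestrict.framework import State


class TestStomatalLimitation:
    def test_healthy_worked_example(self, healthy):
        table = stomatal_limitation(healthy.params_ci, healthy.operational)
        assert table.omega_start == pytest.approx(13.8566, abs=1e-3)
        assert table.omega_end == pytest.approx(20.7058, abs=1e-3)
        assert table.xi("c") == pytest.approx(6.8492, abs=1e-3)
        assert table.rho("c") == pytest.approx(1.0, abs=1e-12)
        assert table.meta["stomatal_limitation"] == pytest.approx(0.33079, abs=1e-4)

    def test_matches_closed_form(self, healthy):
        """L must equal (A(Ca) - A(Ci_op))/A(Ca) by telescoping."""
        from photorestrict import nrh_assimilation

        table = stomatal_limitation(healthy.params_ci, healthy.operational, K=17)
        a_op = nrh_assimilation(200, healthy.params_ci)
        a_ca = nrh_assimilation(420, healthy.params_ci)
        assert table.meta["stomatal_limitation"] == pytest.approx(
            (a_ca - a_op) / a_ca, abs=1e-10
        )

    def test_zero_when_already_at_ambient(self, healthy):
        op = OperationalPoint(a_op=20.7, ci_op=420, ca=420)
        table = stomatal_limitation(healthy.params_ci, op)
        assert table.meta["stomatal_limitation"] == 0.0

    def test_rejects_cm_basis(self, healthy):
        with pytest.raises(ValueError, match="Ci-based"):
            stomatal_limitation(healthy.params_cm, healthy.operational)


class TestDiffusionalLimitation:
    def test_healthy_worked_example(self, healthy, healthy_g):
        table = diffusional_limitation(healthy.params_cm, healthy_g, 420)
        assert table.omega_start == pytest.approx(13.799, abs=1e-3)
        assert table.omega_end == pytest.approx(21.4199, abs=1e-3)
        assert table.meta["diffusional_limitation"] == pytest.approx(0.3558, abs=1e-3)
        assert abs(table.closure_residual) < 1e-2 * abs(table.delta_omega)

    def test_matches_closed_form(self, healthy, healthy_g):
        from photorestrict import coupled_assimilation, nrh_assimilation

        table = diffusional_limitation(healthy.params_cm, healthy_g, 420)
        a_op = coupled_assimilation(420, healthy_g, healthy.params_cm)
        a_pot = nrh_assimilation(420, healthy.params_cm)
        expect = (a_pot - a_op) / a_pot
        assert table.meta["diffusional_limitation"] == pytest.approx(expect, abs=1e-3)

    def test_zero_when_conductances_already_high(self, healthy):
        g = Conductances(1e6, 1e6)
        table = diffusional_limitation(healthy.params_cm, g, 420)
        assert table.meta["diffusional_limitation"] == 0.0


class TestStomatalNonstomatal:
    def test_treated_worked_example(self, healthy, treated):
        table = stomatal_nonstomatal(healthy.params_ci, treated.operational)
        assert table.meta["intermediate_assimilation"] == pytest.approx(
            15.2428, abs=1e-3
        )
        assert table.meta["stomatal_limitation"] == pytest.approx(0.20491, abs=1e-4)
        assert table.meta["nonstomatal_limitation"] == pytest.approx(0.26380, abs=1e-4)
        assert table.meta["potential_assimilation"] == pytest.approx(20.7058, abs=1e-3)
        flat = table.meta["treated_params"]
        assert flat.ce == pytest.approx(0.0883, abs=5e-4)
        assert flat.a_sat == pytest.approx(19.14, abs=0.01)

    def test_single_variant_agrees_with_two_tier(self, healthy, treated):
        """The overall limitation is path-independent (both variants share
        the same end states, so it telescopes); the split between the
        stomatal and non-stomatal parts shifts by the usual interaction
        term, well under the ±20% scale of path-dependent alternatives."""
        two = stomatal_nonstomatal(healthy.params_ci, treated.operational,
                                   variant="two-tier")
        one = stomatal_nonstomatal(healthy.params_ci, treated.operational,
                                   variant="single")
        total_two = two.meta["stomatal_limitation"] + two.meta["nonstomatal_limitation"]
        total_one = one.meta["stomatal_limitation"] + one.meta["nonstomatal_limitation"]
        tol = (abs(two.closure_residual) + abs(one.closure_residual)) / abs(
            one.omega_end
        ) + 1e-9
        assert total_one == pytest.approx(total_two, abs=tol)
        for key in ("stomatal_limitation", "nonstomatal_limitation"):
            assert one.meta[key] == pytest.approx(two.meta[key], rel=0.2)

    def test_identical_plants_have_no_nonstomatal_part(self, healthy):
        from photorestrict import nrh_assimilation

        a_op = float(nrh_assimilation(200, healthy.params_ci))
        op = OperationalPoint(a_op=a_op, ci_op=200, ca=420)
        table = stomatal_nonstomatal(
            healthy.params_ci, op, treated=healthy.params_ci
        )
        assert table.meta["nonstomatal_limitation"] == pytest.approx(0.0, abs=1e-12)
        assert table.meta["stomatal_limitation"] == pytest.approx(0.33079, abs=1e-4)

    def test_mu_override_changes_flattening(self, healthy, treated):
        default = stomatal_nonstomatal(healthy.params_ci, treated.operational)
        forced = stomatal_nonstomatal(
            healthy.params_ci, treated.operational, mu=150.0
        )
        assert forced.meta["treated_params"].ce != pytest.approx(
            default.meta["treated_params"].ce
        )
        # both estimated curves still pass through the operational point
        from photorestrict import nrh_assimilation

        for t in (default, forced):
            p = t.meta["treated_params"]
            assert nrh_assimilation(220, p) == pytest.approx(11, abs=1e-6)


class TestTreatmentContributions:
    def test_fig_style_worked_example(self, healthy, treated, healthy_g, treated_g):
        table = treatment_contributions(
            healthy.params_cm, healthy_g, treated.params_cm, treated_g, 420
        )
        assert table.meta["stomatal"] == pytest.approx(-0.7490, abs=1e-3)
        assert table.meta["mesophyll"] == pytest.approx(-0.3644, abs=1e-3)
        assert table.meta["diffusional"] == pytest.approx(-1.1134, abs=1e-3)
        assert table.meta["non_diffusional"] == pytest.approx(-1.6250, abs=1e-3)
        # contributions reconcile with the direct start/end evaluations
        assert table.delta_omega == pytest.approx(11.0611 - 13.7990, abs=1e-3)
        assert abs(table.closure_residual) < 1e-2 * abs(table.delta_omega)

    def test_no_treatment_no_contributions(self, healthy, healthy_g):
        table = treatment_contributions(
            healthy.params_cm, healthy_g, healthy.params_cm, healthy_g, 420
        )
        assert table.contributions == {}
        assert table.delta_omega == 0.0

    def test_unknown_treated_gm_variant(self, healthy, treated, healthy_g):
        """With treated g_m unknown, both states use an arbitrarily high
        g_m and the analysis resolves only stomatal vs non-diffusional."""
        table = treatment_contributions(
            healthy.params_ci.__class__(
                healthy.params_ci.a_sat, healthy.params_ci.ce,
                healthy.params_ci.omega, healthy.params_ci.gamma, basis="Cm"
            ),
            Conductances(0.063, 1e6),
            NRHParams(19, 0.09, 0.7, 45, basis="Cm"),
            Conductances(0.055, 1e6),
            420,
        )
        assert "g_m" not in table.contributions
        assert table.meta["mesophyll"] == 0.0
        assert table.meta["stomatal"] < 0


class TestControlAnalysis:
    @pytest.fixture
    def healthy_state(self, healthy, healthy_g):
        p = healthy.params_cm
        return State(
            "healthy-operational",
            "coupled",
            {
                "ca": 420.0, "g_s": healthy_g.g_s, "g_m": healthy_g.g_m,
                "a_sat": p.a_sat, "ce": p.ce, "omega": p.omega, "gamma": p.gamma,
            },
        )

    def test_shares_sum_to_one(self, healthy_state):
        frame = control_analysis(healthy_state)
        assert frame["share"].sum() == pytest.approx(1.0, abs=1e-6)

    def test_elasticity_identity(self, healthy_state):
        """eta = S*a/f at the state, to 4 decimals at i = 1e-4."""
        frame = control_analysis(healthy_state, i=1e-4)
        f0 = healthy_state.evaluate()
        for name in frame.index:
            a = healthy_state.inputs[name]
            assert frame.loc[name, "elasticity"] == pytest.approx(
                frame.loc[name, "sensitivity"] * a / f0, abs=1e-4
            )

    def test_healthy_operational_control_pattern(self, healthy_state):
        """Stomata dominate marginal control at the healthy operational
        state, with elasticity near one half."""
        frame = control_analysis(healthy_state)
        assert frame["share"].idxmax() == "g_s"
        assert frame.loc["g_s", "elasticity"] == pytest.approx(0.48, abs=0.02)


class TestLightAnalyses:
    HEALTHY = LightParams(y_ll=0.05, ga_sat=25, m=0.7)

    def test_limitation_closed_form(self):
        table = light_limitation(self.HEALTHY, 400, 1800)
        ga = lambda q: float(light_assimilation(q, self.HEALTHY))
        assert table.meta["light_limitation"] == pytest.approx(
            (ga(1800) - ga(400)) / ga(1800), abs=1e-10
        )

    def test_trivial_cases(self):
        assert light_limitation(self.HEALTHY, 1200, 1200).meta[
            "light_limitation"
        ] == 0.0
        dark = light_limitation(self.HEALTHY, 0, 1800)
        assert dark.meta["light_limitation"] == pytest.approx(1.0, abs=1e-12)

    def test_scaled_params_pass_through_point(self):
        p = scaled_light_params(self.HEALTHY, 400, 9.0)
        assert light_assimilation(400, p) == pytest.approx(9.0, abs=1e-9)
        assert p.m == self.HEALTHY.m
        assert p.ga_sat / p.y_ll == pytest.approx(
            self.HEALTHY.ga_sat / self.HEALTHY.y_ll
        )

    def test_light_nonlight_variants_agree(self):
        """As for the CO2 analyses: totals agree to closure, the split
        agrees to the interaction-term scale."""
        kw = dict(ppfd_op=400, ppfd_max=1800, ga_op=9.0)
        two = light_nonlight(self.HEALTHY, variant="two-tier", **kw)
        one = light_nonlight(self.HEALTHY, variant="single", **kw)
        total_two = two.meta["light_limitation"] + two.meta["nonlight_limitation"]
        total_one = one.meta["light_limitation"] + one.meta["nonlight_limitation"]
        tol = (abs(two.closure_residual) + abs(one.closure_residual)) / abs(
            one.omega_end
        ) + 1e-9
        assert total_one == pytest.approx(total_two, abs=tol)
        for key in ("light_limitation", "nonlight_limitation"):
            assert one.meta[key] == pytest.approx(two.meta[key], rel=0.2)

    def test_identical_plant_has_no_nonlight_part(self):
        table = light_nonlight(
            self.HEALTHY, 400, 1800, treated=self.HEALTHY
        )
        assert table.meta["nonlight_limitation"] == pytest.approx(0.0, abs=1e-12)


class TestPathDependence:
    def test_each_order_total_reconciles_with_delta(self, healthy, treated,
                                                    healthy_g, treated_g):
        """Each leg still changes two inputs (the conductance pair or the
        biochemical pair), so the totals reconcile to closure, not to
        machine precision."""
        args = (healthy.params_cm, healthy_g, treated.params_cm, treated_g, 420)
        for order in ("stomata-first", "biochemistry-first"):
            table = path_dependent_contributions(*args, order=order)
            total = sum(c.xi_total for c in table.contributions.values())
            assert total == pytest.approx(
                table.delta_omega, abs=1e-3 * abs(table.delta_omega)
            )

    def test_orders_bracket_simultaneous_path(self, healthy, treated,
                                              healthy_g, treated_g):
        """The two sequential orders straddle the simultaneous path, with a
        spread of roughly a fifth of the independent-path value."""
        args = (healthy.params_cm, healthy_g, treated.params_cm, treated_g, 420)
        simul = treatment_contributions(*args)
        sf = path_dependent_contributions(*args, order="stomata-first")
        bf = path_dependent_contributions(*args, order="biochemistry-first")
        for key in ("diffusional", "non_diffusional"):
            lo = min(sf.meta[key], bf.meta[key])
            hi = max(sf.meta[key], bf.meta[key])
            assert lo - 1e-9 <= simul.meta[key] <= hi + 1e-9
            spread = hi - lo
            assert spread <= 0.5 * abs(simul.meta[key])

    def test_orders_agree_for_additive_model(self):
        """For a model additive in its inputs the path plays no role."""
        from photorestrict.framework import (
            MODELS, ModelSpec, State, Transition, run_transition,
        )

        MODELS["toy_add"] = ModelSpec(
            "toy_add", ("u", "v"), lambda d: 2.0 * d["u"] + 3.0 * d["v"]
        )
        try:
            s0 = State("a", "toy_add", {"u": 1.0, "v": 5.0})
            s_mid1 = State("m1", "toy_add", {"u": 4.0, "v": 5.0})
            s_mid2 = State("m2", "toy_add", {"u": 1.0, "v": 9.0})
            s1 = State("b", "toy_add", {"u": 4.0, "v": 9.0})
            t_uv = run_transition(Transition((s0, s_mid1, s1), K=8))
            t_vu = run_transition(Transition((s0, s_mid2, s1), K=8))
            for name in ("u", "v"):
                assert t_uv.contributions[name].xi_total == pytest.approx(
                    t_vu.contributions[name].xi_total, abs=1e-12
                )
        finally:
            del MODELS["toy_add"]
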