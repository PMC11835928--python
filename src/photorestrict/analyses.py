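"""Named restriction analyses composing the models with the engine.

Each function builds the states of one documented procedure, runs the
K-interval transition, and returns the :class:`~.framework.ContributionTable`
with the procedure's headline numbers in ``table.meta``.  The per-interval
control series stays attached as ``table.control``.
"""

from __future__ import annotations

import logging

import pandas as pd

from .framework import State, Transition, run_transition
from .models import (
    G_HIGH,
    Conductances,
    LightParams,
    NRHParams,
    OperationalPoint,
    flattened_ce,
    light_assimilation,
)

__all__ = [
    "stomatal_limitation",
    "diffusional_limitation",
    "stomatal_nonstomatal",
    "treatment_contributions",
    "control_analysis",
    "light_limitation",
    "light_nonlight",
    "path_dependent_contributions",
    "scaled_light_params",
]

logger = logging.getLogger(__name__)

DEFAULT_K = 1000


def _nrh_inputs(p: NRHParams, c: float) -> dict:
    return {"c": c, "a_sat": p.a_sat, "ce": p.ce, "omega": p.omega, "gamma": p.gamma}


def _coupled_inputs(p: NRHParams, g: Conductances, ca: float) -> dict:
    return {
        "ca": ca,
        "g_s": g.g_s,
        "g_m": g.g_m,
        "a_sat": p.a_sat,
        "ce": p.ce,
        "omega": p.omega,
        "gamma": p.gamma,
    }


def stomatal_limitation(fit: NRHParams, op: OperationalPoint, K: int = DEFAULT_K):
    """Limitation imposed by stomata on a single plant.

    One transition on the Ci-based hyperbola from the operational Ci to the
    hypothetical state where stomata impose no barrier and Ci equals the
    ambient Ca (equivalent to g_s made arbitrarily high, realised directly
    on the driver to avoid a sentinel conductance).  meta keys:
    ``stomatal_limitation``, ``potential_assimilation``,
    ``operational_assimilation``.
    """
    if fit.basis != "Ci":
        raise ValueError("stomatal_limitation needs a Ci-based fit")
    t = Transition(
        (
            State("operational", "nrh", _nrh_inputs(fit, op.ci_op)),
            State("ci-at-ambient", "nrh", _nrh_inputs(fit, op.ca)),
        ),
        K=K,
    )
    table = run_transition(t)
    table.meta.update(
        stomatal_limitation=table.limitation("c") if "c" in table.contributions else 0.0,
        potential_assimilation=table.omega_end,
        operational_assimilation=table.omega_start,
    )
    return table


def diffusional_limitation(
    fit: NRHParams,
    g: Conductances,
    ca: float,
    K: int = DEFAULT_K,
    g_high: float = G_HIGH,
):
    """Limitation imposed jointly by stomata and mesophyll.

    One transition on the coupled supply-demand model (Cm-based fit) from
    the operational conductances to both conductances arbitrarily high
    (Cm -> Ca).  The conductances travel linearly in resistance (see
    :class:`~.framework.Transition`), the sound coordinate for removing a
    series diffusion barrier.  meta keys: ``diffusional_limitation``,
    ``potential_assimilation``, ``operational_assimilation``.
    """
    if fit.basis != "Cm":
        raise ValueError("diffusional_limitation needs a Cm-based fit")
    t = Transition(
        (
            State("operational", "coupled", _coupled_inputs(fit, g, ca)),
            State(
                "no-diffusive-barrier",
                "coupled",
                _coupled_inputs(fit, Conductances(g_high, g_high), ca),
            ),
        ),
        K=K,
        reciprocal=("g_s", "g_m"),
    )
    table = run_transition(t)
    changed = [n for n in ("g_s", "g_m") if n in table.contributions]
    table.meta.update(
        diffusional_limitation=table.limitation(*changed) if changed else 0.0,
        potential_assimilation=table.omega_end,
        operational_assimilation=table.omega_start,
    )
    return table


def stomatal_nonstomatal(
    healthy: NRHParams,
    op: OperationalPoint,
    variant: str = "two-tier",
    mu: float | None = None,
    treated: NRHParams | None = None,
    K: int = DEFAULT_K,
):
    """Split a treated plant's shortfall into stomatal and non-stomatal parts.

    The treated plant's Ci-based hyperbola is estimated by flattening the
    healthy curve through the treated operational point (curvature, the
    compensation point and the ratio mu = A_SAT/CE held fixed) unless a
    fitted ``treated`` parameter set is supplied.  ``variant`` "two-tier"
    lifts the stomatal barrier first (Ci -> Ca on the treated curve), then
    drives A_SAT and CE to the healthy values; "single" does both in one
    leg.  meta keys: ``stomatal_limitation``, ``nonstomatal_limitation``,
    ``intermediate_assimilation`` (two-tier only),
    ``potential_assimilation``, ``treated_params``.
    """
    if healthy.basis != "Ci":
        raise ValueError("stomatal_nonstomatal needs a Ci-based healthy fit")
    if variant not in ("two-tier", "single"):
        raise ValueError(f"variant must be 'two-tier' or 'single', got {variant!r}")
    if treated is None:
        mu = healthy.mu if mu is None else mu
        ce_p, a_sat_p = flattened_ce(
            op.a_op, op.ci_op, mu, healthy.omega, healthy.gamma
        )
        treated = NRHParams(a_sat_p, ce_p, healthy.omega, healthy.gamma, basis="Ci")
    s_op = State("treated-operational", "nrh", _nrh_inputs(treated, op.ci_op))
    s_ca = State("treated-ci-at-ambient", "nrh", _nrh_inputs(treated, op.ca))
    s_pot = State("healthy-potential", "nrh", _nrh_inputs(healthy, op.ca))
    states = (s_op, s_ca, s_pot) if variant == "two-tier" else (s_op, s_pot)
    table = run_transition(Transition(states, K=K))
    nonstomatal_names = [
        n for n in table.contributions if n != "c"
    ]  # a_sat, ce (+ omega/gamma when a fitted treated curve moves them)
    table.meta.update(
        stomatal_limitation=table.limitation("c") if "c" in table.contributions else 0.0,
        nonstomatal_limitation=table.limitation(*nonstomatal_names)
        if nonstomatal_names
        else 0.0,
        potential_assimilation=table.omega_end,
        treated_params=treated,
    )
    if variant == "two-tier":
        table.meta["intermediate_assimilation"] = table.state_outputs[1]
    return table


def treatment_contributions(
    healthy_fit: NRHParams,
    healthy_g: Conductances,
    treated_fit: NRHParams,
    treated_g: Conductances,
    ca: float,
    K: int = DEFAULT_K,
):
    """Resolve a treatment's effect into stomatal, mesophyll and
    non-diffusional contributions in one transition.

    All inputs of the coupled model (g_s, g_m, A_SAT, CE, and omega/gamma
    if they differ between fits) move linearly from healthy to treated
    values; when the treated g_m is unknown pass a Conductances with an
    arbitrarily high g_m in both states.  meta keys: ``stomatal``,
    ``mesophyll``, ``diffusional``, ``non_diffusional`` (all total
    contributions Xi, umol m-2 s-1), ``delta_assimilation``.
    """
    for fit, who in ((healthy_fit, "healthy"), (treated_fit, "treated")):
        if fit.basis != "Cm":
            raise ValueError(f"treatment_contributions needs Cm-based fits ({who})")
    t = Transition(
        (
            State("healthy-operational", "coupled",
                  _coupled_inputs(healthy_fit, healthy_g, ca)),
            State("treated-operational", "coupled",
                  _coupled_inputs(treated_fit, treated_g, ca)),
        ),
        K=K,
    )
    table = run_transition(t)
    xi = {n: c.xi_total for n, c in table.contributions.items()}
    nondiff = [n for n in xi if n not in ("g_s", "g_m")]
    table.meta.update(
        stomatal=xi.get("g_s", 0.0),
        mesophyll=xi.get("g_m", 0.0),
        diffusional=xi.get("g_s", 0.0) + xi.get("g_m", 0.0),
        non_diffusional=sum(xi[n] for n in nondiff),
        delta_assimilation=table.delta_omega,
    )
    return table


def control_analysis(
    state: State, inputs: tuple[str, ...] | None = None, i: float = 1.0e-4
) -> pd.DataFrame:
    """Sensitivity, elasticity and marginal shares at a single state.

    Each listed input is multiplied by (1 + i) in turn; the response is
    reported as sensitivity S (output units per input units), elasticity
    eta (dimensionless), and the input's share of the summed marginal
    response (shares sum to 1 by construction).  Default inputs are the
    conductances and biochemical parameters of the coupled model.
    """
    from .framework import MODELS

    if inputs is None:
        if state.model == "coupled":
            inputs = ("g_s", "g_m", "a_sat", "ce")
        else:
            raise ValueError("specify the inputs to perturb for this model")
    if not i > 0:
        raise ValueError(f"relative increment i must be > 0, got {i}")
    spec = MODELS[state.model]
    f0 = state.evaluate()
    rows = []
    import numpy as np

    for name in inputs:
        a = state.inputs[name]
        pert = dict(state.inputs)
        pert[name] = a * (1.0 + i)
        f1 = float(spec.fn({k: np.asarray(v) for k, v in pert.items()}))
        xi = f1 - f0
        eta = (
            (np.log(f1) - np.log(f0)) / (np.log(a * (1 + i)) - np.log(a))
            if (a > 0 and f0 > 0 and f1 > 0)
            else float("nan")
        )
        rows.append(
            {"input": name, "xi": xi, "sensitivity": xi / (a * i), "elasticity": eta}
        )
    frame = pd.DataFrame(rows).set_index("input")
    total = frame["xi"].sum()
    frame["share"] = frame["xi"] / total if total != 0 else float("nan")
    return frame


def light_limitation(
    fit: LightParams, ppfd_op: float, ppfd_max: float, K: int = DEFAULT_K
):
    """Reduction of gross assimilation due to sub-maximal light.

    One transition in PPFD from the operational to the maximum intensity
    on the light-response hyperbola; with two real intensities the same
    run quantifies a light *contribution* between conditions.  meta keys:
    ``light_limitation``, ``potential_assimilation``,
    ``operational_assimilation``.
    """
    def inputs(ppfd):
        return {"ppfd": ppfd, "y_ll": fit.y_ll, "ga_sat": fit.ga_sat, "m": fit.m}

    t = Transition(
        (
            State("operational-light", "light", inputs(ppfd_op)),
            State("maximum-light", "light", inputs(ppfd_max)),
        ),
        K=K,
    )
    table = run_transition(t)
    if ppfd_op == ppfd_max:
        lim = 0.0
    else:
        lim = table.limitation("ppfd")
    table.meta.update(
        light_limitation=lim,
        potential_assimilation=table.omega_end,
        operational_assimilation=table.omega_start,
    )
    return table


def scaled_light_params(
    healthy: LightParams, ppfd_op: float, ga_op: float
) -> LightParams:
    """Estimate a treated plant's light-response parameters from one point.

    Scaling Y_LL and GA_SAT by a common factor scales the whole curve, so
    the factor through (ppfd_op, ga_op) has the closed form
    ga_op / GA_healthy(ppfd_op); the curvature m is held fixed.  This is
    the light-response analogue of flattening the A/Ci curve at fixed
    A_SAT/CE ratio.
    """
    if not ga_op > 0:
        raise ValueError(f"ga_op must be > 0, got {ga_op}")
    ref = float(light_assimilation(ppfd_op, healthy))
    if not ref > 0:
        raise ValueError("healthy curve is non-positive at ppfd_op")
    lam = ga_op / ref
    return LightParams(y_ll=lam * healthy.y_ll, ga_sat=lam * healthy.ga_sat, m=healthy.m)


def light_nonlight(
    healthy: LightParams,
    ppfd_op: float,
    ppfd_max: float,
    treated: LightParams | None = None,
    ga_op: float | None = None,
    variant: str = "two-tier",
    K: int = DEFAULT_K,
):
    """Split a shaded, treated plant's shortfall into light and non-light parts.

    Mirrors :func:`stomatal_nonstomatal` on the light response: lift the
    light limitation first (PPFD -> ppfd_max on the treated curve), then
    drive the parameters to the healthy values; or do both in one leg
    (``variant="single"``).  The treated curve is either supplied or
    estimated from the operational point via :func:`scaled_light_params`.
    meta keys: ``light_limitation``, ``nonlight_limitation``,
    ``potential_assimilation``.
    """
    if variant not in ("two-tier", "single"):
        raise ValueError(f"variant must be 'two-tier' or 'single', got {variant!r}")
    if treated is None:
        if ga_op is None:
            raise ValueError("supply either treated params or ga_op")
        treated = scaled_light_params(healthy, ppfd_op, ga_op)

    def inputs(p: LightParams, ppfd):
        return {"ppfd": ppfd, "y_ll": p.y_ll, "ga_sat": p.ga_sat, "m": p.m}

    s_op = State("treated-operational", "light", inputs(treated, ppfd_op))
    s_full = State("treated-full-light", "light", inputs(treated, ppfd_max))
    s_pot = State("healthy-potential", "light", inputs(healthy, ppfd_max))
    states = (s_op, s_full, s_pot) if variant == "two-tier" else (s_op, s_pot)
    table = run_transition(Transition(states, K=K))
    nonlight = [n for n in table.contributions if n != "ppfd"]
    table.meta.update(
        light_limitation=table.limitation("ppfd") if "ppfd" in table.contributions else 0.0,
        nonlight_limitation=table.limitation(*nonlight) if nonlight else 0.0,
        potential_assimilation=table.omega_end,
        treated_params=treated,
    )
    if variant == "two-tier":
        table.meta["intermediate_assimilation"] = table.state_outputs[1]
    return table


def path_dependent_contributions(
    healthy_fit: NRHParams,
    healthy_g: Conductances,
    treated_fit: NRHParams,
    treated_g: Conductances,
    ca: float,
    order: str = "stomata-first",
    K: int = DEFAULT_K,
):
    """Sequential (path-dependent) variant of :func:`treatment_contributions`.

    Changes the conductances in one leg and the biochemical parameters in
    the other, in the requested ``order``.  Provided for comparison with
    the simultaneous path only: sequential orderings assume stomata and
    biochemistry respond independently, which is generally invalid, and
    the two orders bracket the simultaneous result.  Not recommended for
    reporting.
    """
    if order not in ("stomata-first", "biochemistry-first"):
        raise ValueError(
            f"order must be 'stomata-first' or 'biochemistry-first', got {order!r}"
        )
    for fit, who in ((healthy_fit, "healthy"), (treated_fit, "treated")):
        if fit.basis != "Cm":
            raise ValueError(f"path_dependent_contributions needs Cm-based fits ({who})")
    start = State(
        "healthy-operational", "coupled", _coupled_inputs(healthy_fit, healthy_g, ca)
    )
    end = State(
        "treated-operational", "coupled", _coupled_inputs(treated_fit, treated_g, ca)
    )
    if order == "stomata-first":
        mid = State(
            "conductances-moved", "coupled", _coupled_inputs(healthy_fit, treated_g, ca)
        )
    else:
        mid = State(
            "biochemistry-moved", "coupled", _coupled_inputs(treated_fit, healthy_g, ca)
        )
    table = run_transition(Transition((start, mid, end), K=K))
    xi = {n: c.xi_total for n, c in table.contributions.items()}
    nondiff = [n for n in xi if n not in ("g_s", "g_m")]
    table.meta.update(
        order=order,
        stomatal=xi.get("g_s", 0.0),
        mesophyll=xi.get("g_m", 0.0),
        diffusional=xi.get("g_s", 0.0) + xi.get("g_m", 0.0),
        non_diffusional=sum(xi[n] for n in nondiff),
        delta_assimilation=table.delta_omega,
    )
    return table
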