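"""Empirical photosynthesis models and the CO2 diffusion supply chain.

The CO2 response of net assimilation A is described by a non-rectangular
hyperbola (NRH) in the CO2 mole fraction C (either substomatal, Ci, or at
the mesophyll carboxylation sites, Cm)::

    omega * A**2 - (CE*(C - Gamma) + A_SAT) * A + A_SAT * CE * (C - Gamma) = 0

whose *lower* root is the physical branch: A = 0 at C = Gamma (the
compensation point), the initial slope is CE, and A saturates at A_SAT.
The curvature omega in (0, 1] interpolates between the rectangular
hyperbola (omega -> 0) and the Blackman limit (omega = 1, two straight
lines).  The light response of gross assimilation has the same shape with
PPFD as driver, initial slope Y(CO2)_LL and asymptote GA_SAT.

CO2 reaches the carboxylation sites by diffusing through stomata
(conductance g_S) and the mesophyll (g_M) in series; coupling the linear
supply function Cm = Ca - A/g_tot with the Cm-based demand hyperbola gives
a quadratic in A solved by :func:`coupled_assimilation`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NRHParams",
    "LightParams",
    "Conductances",
    "OperationalPoint",
    "MechanisticInputs",
    "nrh_assimilation",
    "light_assimilation",
    "total_conductance",
    "cm_from_ci",
    "operational_gs",
    "coupled_assimilation",
    "flattened_ce",
    "mechanistic_to_empirical",
    "G_HIGH",
]

#: Default "arbitrarily high" conductance (mol m-2 s-1) used to lift a
#: diffusional barrier; large enough that the coupled and uncoupled models
#: agree to < 1e-6 umol m-2 s-1 at realistic parameter values.
G_HIGH = 1.0e6

# omega below this is treated as the rectangular-hyperbola limit to avoid
# catastrophic cancellation in the /(2*omega) form.
_OMEGA_TINY = 1.0e-10


def _lower_root(a2, a1, a0):
    """Lower root of a2*x**2 + a1*x + a0 = 0, vectorised.

    Falls back to the linear root -a0/a1 where a2 vanishes (the
    rectangular-hyperbola limit of the saturating models).
    """
    a2, a1, a0 = np.broadcast_arrays(
        np.asarray(a2, float), np.asarray(a1, float), np.asarray(a0, float)
    )
    disc = a1 * a1 - 4.0 * a2 * a0
    if np.any(disc < 0):
        raise ValueError(
            "negative discriminant in quadratic model: parameters are "
            "outside the valid domain (check signs and units)"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        quad = (-a1 - np.sqrt(disc)) / (2.0 * a2)
        lin = -a0 / a1
    out = np.where(np.abs(a2) > _OMEGA_TINY, quad, lin)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class NRHParams:
    """Fitted parameters of the A/C non-rectangular hyperbola.

    a_sat : CO2-saturated assimilation rate, umol m-2 s-1
    ce    : initial slope, mol m-2 s-1
    omega : curvature, dimensionless, in (0, 1]
    gamma : x-intercept (CO2 compensation point), umol mol-1
    basis : which CO2 driver the curve was fitted against, "Ci" or "Cm"
    """

    a_sat: float
    ce: float
    omega: float
    gamma: float
    basis: str = "Ci"

    def __post_init__(self) -> None:
        if not self.a_sat > 0:
            raise ValueError(f"a_sat must be > 0, got {self.a_sat}")
        if not self.ce > 0:
            raise ValueError(f"ce must be > 0, got {self.ce}")
        if not 0 < self.omega <= 1:
            raise ValueError(f"omega must be in (0, 1], got {self.omega}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.basis not in ("Ci", "Cm"):
            raise ValueError(f"basis must be 'Ci' or 'Cm', got {self.basis!r}")

    @property
    def mu(self) -> float:
        """Ratio A_SAT/CE (umol mol-1), held fixed when flattening."""
        return self.a_sat / self.ce


@dataclass(frozen=True)
class LightParams:
    """Fitted parameters of the gross-assimilation light response.

    y_ll   : initial quantum yield Y(CO2)_LL, umol CO2 umol photons-1
    ga_sat : light-saturated gross assimilation, umol m-2 s-1
    m      : curvature, dimensionless, in (0, 1]
    """

    y_ll: float
    ga_sat: float
    m: float

    def __post_init__(self) -> None:
        if not self.y_ll > 0:
            raise ValueError(f"y_ll must be > 0, got {self.y_ll}")
        if not self.ga_sat > 0:
            raise ValueError(f"ga_sat must be > 0, got {self.ga_sat}")
        if not 0 < self.m <= 1:
            raise ValueError(f"m must be in (0, 1], got {self.m}")


@dataclass(frozen=True)
class Conductances:
    """Stomatal and mesophyll conductances to CO2, mol m-2 s-1."""

    g_s: float
    g_m: float

    def __post_init__(self) -> None:
        if not self.g_s > 0:
            raise ValueError(f"g_s must be > 0, got {self.g_s}")
        if not self.g_m > 0:
            raise ValueError(f"g_m must be > 0, got {self.g_m}")

    @property
    def g_tot(self) -> float:
        return total_conductance(self)


@dataclass(frozen=True)
class OperationalPoint:
    """Gas-exchange condition a plant attains in its growth environment.

    a_op  : net assimilation, umol m-2 s-1
    ci_op : substomatal CO2 mole fraction, umol mol-1
    ca    : ambient CO2 mole fraction, umol mol-1
    cm_op : CO2 at the carboxylation sites, umol mol-1 (optional)
    """

    a_op: float
    ci_op: float
    ca: float
    cm_op: float | None = None

    def __post_init__(self) -> None:
        if self.a_op > 0 and self.ca < self.ci_op:
            raise ValueError(
                f"ca ({self.ca}) cannot be below ci_op ({self.ci_op}) when "
                "the leaf is a net CO2 sink"
            )
        if self.cm_op is not None and self.a_op > 0 and self.cm_op > self.ci_op:
            raise ValueError(
                f"cm_op ({self.cm_op}) cannot exceed ci_op ({self.ci_op}) "
                "when the leaf is a net CO2 sink"
            )


@dataclass(frozen=True)
class MechanisticInputs:
    """Mechanistic parameters to approximate as empirical NRH parameters.

    v_max      : Rubisco (C3) or PEP carboxylase (C4) maximum rate, umol m-2 s-1
    k          : Michaelis-Menten constant of that carboxylase (O2-adjusted
                 for Rubisco), umol mol-1
    j_or_jatp  : electron-transport rate J (C3) or ATP production rate
                 J_ATP (C4), umol m-2 s-1
    r_l        : light respiration, umol m-2 s-1
    pathway    : "C3" or "C4"
    """

    v_max: float
    k: float
    j_or_jatp: float
    r_l: float
    pathway: str = "C3"

    def __post_init__(self) -> None:
        for name in ("v_max", "j_or_jatp", "r_l"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.k > 0:
            raise ValueError(f"k must be > 0, got {self.k}")
        if self.pathway not in ("C3", "C4"):
            raise ValueError(f"pathway must be 'C3' or 'C4', got {self.pathway!r}")


# ---------------------------------------------------------------------------
# kernels: plain-float/ndarray forms used by the transition engine


def nrh(c, a_sat, ce, omega, gamma):
    """A/C non-rectangular hyperbola, lower root. Units as in NRHParams."""
    s = ce * (np.asarray(c, float) - gamma)
    return _lower_root(omega, -(s + a_sat), a_sat * s)


def light(ppfd, y_ll, ga_sat, m):
    """Gross-assimilation light response, lower root."""
    s = y_ll * np.asarray(ppfd, float)
    return _lower_root(m, -(s + ga_sat), ga_sat * s)


def coupled(ca, g_s, g_m, a_sat, ce, omega, gamma):
    """Supply-demand coupled assimilation at ambient CO2 ca.

    Substituting the mesophyll supply function Cm = Ca - A/g_tot into the
    Cm-based demand hyperbola gives, with r = 1/g_tot,

        (omega + CE*r)*A**2
        - [CE*(Ca - Gamma) + A_SAT*(1 + CE*r)]*A
        + A_SAT*CE*(Ca - Gamma) = 0

    of which the lower root is the physical branch.
    """
    g_s = np.asarray(g_s, float)
    g_m = np.asarray(g_m, float)
    if np.any(g_s <= 0) or np.any(g_m <= 0):
        raise ValueError("conductances must be > 0")
    r = 1.0 / g_s + 1.0 / g_m  # 1/g_tot, series resistances
    a2 = omega + ce * r
    a1 = -(ce * (np.asarray(ca, float) - gamma) + a_sat * (1.0 + ce * r))
    a0 = a_sat * ce * (np.asarray(ca, float) - gamma)
    return _lower_root(a2, a1, a0)


# ---------------------------------------------------------------------------
# public typed operations


def nrh_assimilation(c, p: NRHParams):
    """Net assimilation at CO2 mole fraction ``c`` on the hyperbola ``p``.

    ``c`` may be a scalar or array; values below ``p.gamma`` are permitted
    and yield negative A (respiration exceeding carboxylation).
    """
    return nrh(c, p.a_sat, p.ce, p.omega, p.gamma)


def light_assimilation(ppfd, p: LightParams):
    """Gross assimilation at light intensity ``ppfd`` (umol photons m-2 s-1)."""
    if np.any(np.asarray(ppfd) < 0):
        raise ValueError("ppfd must be >= 0")
    return light(ppfd, p.y_ll, p.ga_sat, p.m)


def total_conductance(g: Conductances) -> float:
    """Series (total) conductance g_S*g_M/(g_S+g_M), mol m-2 s-1."""
    return g.g_s * g.g_m / (g.g_s + g.g_m)


def cm_from_ci(ci, a, g_m):
    """CO2 at the carboxylation sites: Cm = Ci - A/g_M.

    Raises if the result is negative, which signals a wrong g_m or a unit
    mix-up rather than a physical state.
    """
    if not g_m > 0:
        raise ValueError(f"g_m must be > 0, got {g_m}")
    cm = np.asarray(ci, float) - np.asarray(a, float) / g_m
    if np.any(cm < 0):
        raise ValueError(
            "computed Cm < 0: assimilation/g_m draw-down exceeds Ci "
            "(check g_m value and units)"
        )
    if cm.ndim == 0:
        return float(cm)
    return cm


def operational_gs(op: OperationalPoint) -> float:
    """Operational stomatal conductance g_S = A_op/(Ca - Ci_op)."""
    if op.ca == op.ci_op:
        raise ValueError("ca equals ci_op: operational g_s is undefined")
    return op.a_op / (op.ca - op.ci_op)


def coupled_assimilation(ca, g: Conductances, p: NRHParams):
    """Assimilation with the diffusion supply chain coupled to demand.

    ``p`` must be Cm-based: the hyperbola describes demand at the
    carboxylation sites, and the supply chain drops Ca to Cm through g_S
    and g_M in series.  Reduces to ``nrh_assimilation(ca, p)`` as both
    conductances grow arbitrarily large.
    """
    if p.basis != "Cm":
        raise ValueError(
            "coupled_assimilation requires Cm-based parameters; got a "
            f"{p.basis}-based fit"
        )
    return coupled(ca, g.g_s, g.g_m, p.a_sat, p.ce, p.omega, p.gamma)


def flattened_ce(a, c, mu, omega, gamma):
    """Initial slope CE' of the flattened hyperbola through (c, a).

    Flattening estimates a treated plant's curve from a single measured
    operational point by holding the curvature ``omega``, the compensation
    point ``gamma`` and the ratio ``mu`` = A_SAT/CE fixed, and solving the
    hyperbola for CE (positive branch).  Returns ``(ce_prime,
    a_sat_prime)`` with A_SAT' = mu * CE'.
    """
    if not c > gamma:
        raise ValueError(f"need c > gamma to flatten, got c={c}, gamma={gamma}")
    if not a > 0:
        raise ValueError(f"need a > 0 to flatten, got {a}")
    if not mu > 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    radicand = (a * (gamma - c - mu)) ** 2 - 4.0 * omega * a * a * mu * (c - gamma)
    if radicand < 0:
        raise ValueError(
            f"operational point (c={c}, a={a}) is not reachable by any "
            f"hyperbola with mu={mu}, omega={omega}, gamma={gamma}"
        )
    ce_prime = (a * (mu + c - gamma) + math.sqrt(radicand)) / (2.0 * mu * (c - gamma))
    return ce_prime, mu * ce_prime


def mechanistic_to_empirical(
    m: MechanisticInputs, gamma: float, omega: float = 0.7, basis: str = "Cm"
) -> NRHParams:
    """Approximate mechanistic parameters as empirical NRH parameters.

    CE = V_MAX/K; A_SAT = J/4 - R_L for C3 or J_ATP/5.5 - R_L for C4.
    ``gamma`` comes from the literature (or from R_L and K via a
    mechanistic model); ``omega`` is conventionally 0.7.
    """
    ce = m.v_max / m.k
    divisor = 4.0 if m.pathway == "C3" else 5.5
    a_sat = m.j_or_jatp / divisor - m.r_l
    if a_sat <= 0:
        raise ValueError(
            f"A_SAT = {a_sat:.3g} <= 0: respiration exceeds the "
            "electron-transport-supported rate"
        )
    return NRHParams(a_sat=a_sat, ce=ce, omega=omega, gamma=gamma, basis=basis)
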