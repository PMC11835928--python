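"""Generalised restriction engine: states, transitions, and the metrics.

A *state* is a complete, named set of inputs to a photosynthesis model f
(an output Omega as a function of one input a and all others b).  A
*transition* is an ordered list of >= 2 states; between adjacent states
every input scales linearly over K equal intervals,

    a_{m,k} = a_m + (k/K) * (a_{m+1} - a_m).

Over the interval k -> k+1 the *marginal contribution* of input a is the
forward difference

    xi(a) = f(a at k+1, others at k) - f(all at k),

with an alternate form xi' that holds the others at k+1; the two converge
as K grows.  Summing xi over all intervals and legs gives the *total
contribution* Xi(a); normalising by the overall change in output gives the
*relative contribution* rho(a) = Xi/(Omega_end - Omega_start), and by the
final (potential) output the *limitation* L(a) = Xi/Omega_end.  Per
interval, the *sensitivity* S = xi/delta_a and *elasticity*
eta = delta ln f / delta ln a are finite-difference control coefficients.

When a single input changes, the forward differences telescope and Xi
equals the overall change exactly for any K; when several inputs change
the first-order decomposition leaves a closure residual
sum_a Xi(a) - (Omega_end - Omega_start) that vanishes as K grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import models

__all__ = [
    "MODELS",
    "ModelSpec",
    "State",
    "Transition",
    "InputContribution",
    "ContributionTable",
    "ControlSeries",
    "interpolate_inputs",
    "marginal_contribution",
    "run_transition",
    "sensitivity",
    "elasticity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """A photosynthesis model usable by the engine: name, required inputs,
    and a vectorised evaluator over a mapping of input arrays."""

    name: str
    required: tuple[str, ...]
    fn: Callable[[Mapping[str, np.ndarray]], np.ndarray]


def _eval_nrh(d):
    return models.nrh(d["c"], d["a_sat"], d["ce"], d["omega"], d["gamma"])


def _eval_coupled(d):
    return models.coupled(
        d["ca"], d["g_s"], d["g_m"], d["a_sat"], d["ce"], d["omega"], d["gamma"]
    )


def _eval_light(d):
    return models.light(d["ppfd"], d["y_ll"], d["ga_sat"], d["m"])


#: Registry of models the engine can drive.  "nrh" is the A/C hyperbola
#: with driver key "c" (Ci or Cm depending on the fitted basis); "coupled"
#: couples the Cm-based hyperbola to the diffusion supply chain; "light"
#: is the gross-assimilation light response with driver "ppfd".
MODELS: dict[str, ModelSpec] = {
    "nrh": ModelSpec("nrh", ("c", "a_sat", "ce", "omega", "gamma"), _eval_nrh),
    "coupled": ModelSpec(
        "coupled",
        ("ca", "g_s", "g_m", "a_sat", "ce", "omega", "gamma"),
        _eval_coupled,
    ),
    "light": ModelSpec("light", ("ppfd", "y_ll", "ga_sat", "m"), _eval_light),
}


@dataclass(frozen=True)
class State:
    """A named condition: model selector plus a complete input map."""

    name: str
    model: str
    inputs: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(
                f"unknown model {self.model!r}; available: {sorted(MODELS)}"
            )
        spec = MODELS[self.model]
        missing = set(spec.required) - set(self.inputs)
        if missing:
            raise ValueError(
                f"state {self.name!r} is missing required inputs for model "
                f"{self.model!r}: {sorted(missing)}"
            )
        unknown = set(self.inputs) - set(spec.required)
        if unknown:
            raise ValueError(
                f"state {self.name!r} has inputs not used by model "
                f"{self.model!r}: {sorted(unknown)}"
            )
        for k, v in self.inputs.items():
            if not np.isfinite(v):
                raise ValueError(f"state {self.name!r}: input {k!r} is not finite")
        object.__setattr__(self, "inputs", dict(self.inputs))
        self.evaluate()  # the model must be defined at the state

    def evaluate(self) -> float:
        """Model output Omega at this state."""
        spec = MODELS[self.model]
        return float(spec.fn({k: np.asarray(v, float) for k, v in self.inputs.items()}))


@dataclass(frozen=True)
class Transition:
    """An ordered list of >= 2 states sharing one model, with K intervals
    per leg.

    Inputs named in ``reciprocal`` are interpolated linearly in their
    reciprocal (e.g. a conductance moves linearly in resistance).  This is
    the numerically sound path when a conductance is driven to an
    effectively infinite value: a linear-in-conductance path concentrates
    the whole response into the first interval and leaves a closure error
    that no K can shrink, whereas the series-resistance coordinate spreads
    it evenly.  All other inputs scale linearly.
    """

    states: tuple[State, ...]
    K: int = 1000
    reciprocal: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        states = tuple(self.states)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "reciprocal", tuple(self.reciprocal))
        if len(states) < 2:
            raise ValueError("a transition needs at least two states")
        if not (isinstance(self.K, (int, np.integer)) and self.K >= 1):
            raise ValueError(f"K must be an integer >= 1, got {self.K!r}")
        for name in self.reciprocal:
            if name not in states[0].inputs:
                raise ValueError(f"reciprocal path names unknown input {name!r}")
            for s in states:
                if not s.inputs[name] > 0:
                    raise ValueError(
                        f"reciprocal path requires {name!r} > 0 in every state"
                    )
        first = states[0]
        for s in states[1:]:
            if s.model != first.model:
                raise ValueError(
                    f"states {first.name!r} and {s.name!r} use different models"
                )
            if set(s.inputs) != set(first.inputs):
                raise ValueError(
                    f"states {first.name!r} and {s.name!r} have different "
                    "input names"
                )

    @property
    def input_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.states[0].inputs))

    def changing_inputs(self) -> tuple[str, ...]:
        """Inputs whose value differs between any pair of adjacent states."""
        out = []
        for name in self.input_names:
            vals = [s.inputs[name] for s in self.states]
            if any(v != vals[0] for v in vals[1:]):
                out.append(name)
        return tuple(out)


def interpolate_inputs(state_a: State, state_b: State, k: int, K: int) -> dict:
    """Inputs at interval node k of the K-interval leg state_a -> state_b."""
    if not 0 <= k <= K:
        raise ValueError(f"k must be in [0, {K}], got {k}")
    return {
        name: state_a.inputs[name]
        + (k / K) * (state_b.inputs[name] - state_a.inputs[name])
        for name in state_a.inputs
    }


def marginal_contribution(
    t: Transition, name: str, m: int, k: int, variant: str = "forward"
) -> float:
    """Marginal contribution xi of input ``name`` over interval k -> k+1 of
    leg m (0-based).  ``variant`` selects xi (forward, others held at k) or
    xi' (alternate, others held at k+1)."""
    if variant not in ("forward", "alternate"):
        raise ValueError(f"variant must be 'forward' or 'alternate', got {variant!r}")
    spec = MODELS[t.states[0].model]
    sa, sb = t.states[m], t.states[m + 1]
    if not 0 <= k < t.K:
        raise ValueError(f"k must be in [0, {t.K - 1}], got {k}")
    paths = _leg_paths(sa, sb, t.K, t.reciprocal)
    lo = {n: float(p[k]) for n, p in paths.items()}
    hi = {n: float(p[k + 1]) for n, p in paths.items()}
    if variant == "forward":
        # f(a at k+1, others at k) - f(all at k)
        base = dict(lo)
        pert = dict(lo)
        pert[name] = hi[name]
    else:
        # xi': f(all at k+1) - f(a at k, others at k+1)
        pert = dict(hi)
        base = dict(hi)
        base[name] = lo[name]
    fa = spec.fn({k_: np.asarray(v) for k_, v in pert.items()})
    fb = spec.fn({k_: np.asarray(v) for k_, v in base.items()})
    return float(fa - fb)


@dataclass(frozen=True)
class InputContribution:
    """Per-input metrics over a whole transition.

    rho and limitation are None when undefined (zero overall change /
    zero final output, respectively) — never silent NaN.
    """

    name: str
    xi_total: float
    rho: float | None
    limitation: float | None


@dataclass
class ControlSeries:
    """Per-interval sensitivity and elasticity records.

    ``frame`` columns: leg, k, input, value (input at node k), delta
    (input change over the interval), xi, sensitivity, elasticity
    (NaN where the log-ratio is undefined).
    """

    frame: pd.DataFrame

    def for_input(self, name: str) -> pd.DataFrame:
        return self.frame[self.frame["input"] == name].reset_index(drop=True)


@dataclass
class ContributionTable:
    """Result of a transition: per-input Xi/rho/L plus closure diagnostics."""

    contributions: dict[str, InputContribution]
    omega_start: float
    omega_end: float
    state_outputs: list[float]
    closure_residual: float
    K: int
    variant: str
    rho_defined: bool
    limitation_defined: bool
    control: ControlSeries | None = None
    meta: dict = field(default_factory=dict)

    @property
    def delta_omega(self) -> float:
        return self.omega_end - self.omega_start

    def xi(self, *names: str) -> float:
        """Summed total contribution of the named inputs."""
        return sum(self.contributions[n].xi_total for n in names)

    def limitation(self, *names: str) -> float:
        """Summed limitation of the named inputs (requires Omega_end != 0)."""
        if not self.limitation_defined:
            raise ValueError("limitation undefined: final output is zero")
        return sum(self.contributions[n].limitation for n in names)

    def rho(self, *names: str) -> float:
        if not self.rho_defined:
            raise ValueError("rho undefined: overall output change is zero")
        return sum(self.contributions[n].rho for n in names)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "input": c.name,
                "xi_total": c.xi_total,
                "rho": c.rho,
                "limitation": c.limitation,
            }
            for c in self.contributions.values()
        ]
        return pd.DataFrame(rows, columns=["input", "xi_total", "rho", "limitation"])


def _leg_paths(
    sa: State, sb: State, K: int, reciprocal: tuple[str, ...] = ()
) -> dict[str, np.ndarray]:
    # np.linspace lands exactly on both endpoints, so state outputs and
    # telescoping sums are reproduced without rounding drift at k = K.
    paths = {}
    for name in sa.inputs:
        a0, a1 = sa.inputs[name], sb.inputs[name]
        if name in reciprocal and a0 != a1:
            p = 1.0 / np.linspace(1.0 / a0, 1.0 / a1, K + 1)
            p[0], p[-1] = a0, a1  # pin endpoints against reciprocal round-off
        else:
            p = np.linspace(a0, a1, K + 1)
        paths[name] = p
    return paths


def run_transition(
    t: Transition, variant: str = "forward", control: bool = True
) -> ContributionTable:
    """Run a K-interval transition and compute all restriction metrics.

    Returns a :class:`ContributionTable`; the per-interval
    :class:`ControlSeries` (sensitivity and elasticity of every changing
    input over every interval) is attached as ``table.control`` unless
    ``control=False``.
    """
    if variant not in ("forward", "alternate"):
        raise ValueError(f"variant must be 'forward' or 'alternate', got {variant!r}")
    spec = MODELS[t.states[0].model]
    changing = t.changing_inputs()
    xi_totals = {name: 0.0 for name in changing}
    records: list[pd.DataFrame] = []

    for leg in range(len(t.states) - 1):
        sa, sb = t.states[leg], t.states[leg + 1]
        paths = _leg_paths(sa, sb, t.K, t.reciprocal)
        f_nodes = spec.fn(paths)  # Omega at every node, length K+1
        lo = {n: v[:-1] for n, v in paths.items()}
        hi = {n: v[1:] for n, v in paths.items()}
        for name in changing:
            if sa.inputs[name] == sb.inputs[name]:
                continue  # xi = 0 on every interval of this leg
            if variant == "forward":
                pert = dict(lo)
                pert[name] = hi[name]
                xi = spec.fn(pert) - f_nodes[:-1]
            else:
                pert = dict(hi)
                pert[name] = lo[name]
                xi = f_nodes[1:] - spec.fn(pert)
            xi_totals[name] += float(xi.sum())
            if control:
                delta = hi[name] - lo[name]
                with np.errstate(divide="ignore", invalid="ignore"):
                    sens = xi / delta
                    f_lo, f_hi = f_nodes[:-1], f_nodes[:-1] + xi
                    ok = (lo[name] > 0) & (hi[name] > 0) & (f_lo > 0) & (f_hi > 0)
                    eta = np.where(
                        ok,
                        (np.log(np.where(ok, f_hi, 1.0)) - np.log(np.where(ok, f_lo, 1.0)))
                        / (np.log(np.where(ok, hi[name], 1.0)) - np.log(np.where(ok, lo[name], 1.0))),
                        np.nan,
                    )
                records.append(
                    pd.DataFrame(
                        {
                            "leg": leg,
                            "k": np.arange(t.K),
                            "input": name,
                            "value": lo[name],
                            "delta": delta,
                            "xi": xi,
                            "sensitivity": sens,
                            "elasticity": eta,
                        }
                    )
                )

    omega_start = t.states[0].evaluate()
    omega_end = t.states[-1].evaluate()
    state_outputs = [s.evaluate() for s in t.states]
    delta_omega = omega_end - omega_start
    closure = sum(xi_totals.values()) - delta_omega
    logger.info(
        "transition %s -> %s: delta Omega = %.6g, closure residual = %.3g",
        t.states[0].name,
        t.states[-1].name,
        delta_omega,
        closure,
    )

    rho_defined = delta_omega != 0.0
    limitation_defined = omega_end != 0.0
    contributions = {
        name: InputContribution(
            name=name,
            xi_total=xi_totals[name],
            rho=(xi_totals[name] / delta_omega) if rho_defined else None,
            limitation=(xi_totals[name] / omega_end) if limitation_defined else None,
        )
        for name in changing
    }
    ctrl = None
    if control:
        cols = ["leg", "k", "input", "value", "delta", "xi", "sensitivity", "elasticity"]
        frame = (
            pd.concat(records, ignore_index=True)[cols]
            if records
            else pd.DataFrame(columns=cols)
        )
        ctrl = ControlSeries(frame=frame)
    return ContributionTable(
        contributions=contributions,
        omega_start=omega_start,
        omega_end=omega_end,
        state_outputs=state_outputs,
        closure_residual=closure,
        K=t.K,
        variant=variant,
        rho_defined=rho_defined,
        limitation_defined=limitation_defined,
        control=ctrl,
    )


def sensitivity(state: State, name: str, increment: float) -> float:
    """Finite-difference sensitivity S = [f(a+da, b) - f(a, b)]/da at a state."""
    if increment == 0:
        raise ValueError("increment must be nonzero")
    spec = MODELS[state.model]
    base = dict(state.inputs)
    pert = dict(base)
    pert[name] = base[name] + increment
    fa = float(spec.fn({k: np.asarray(v) for k, v in pert.items()}))
    fb = state.evaluate()
    return (fa - fb) / increment


def elasticity(state: State, name: str, i: float = 1.0e-4) -> float:
    """Finite-difference elasticity eta = d ln f / d ln a at a state, using
    the relative increment i (a -> a*(1+i))."""
    if not i > 0:
        raise ValueError(f"relative increment i must be > 0, got {i}")
    a = state.inputs[name]
    if not a > 0:
        raise ValueError(f"elasticity undefined: input {name!r} = {a} is not > 0")
    f0 = state.evaluate()
    if not f0 > 0:
        raise ValueError(f"elasticity undefined: output {f0} is not > 0 at the state")
    spec = MODELS[state.model]
    pert = dict(state.inputs)
    pert[name] = a * (1.0 + i)
    f1 = float(spec.fn({k: np.asarray(v) for k, v in pert.items()}))
    if not f1 > 0:
        raise ValueError("elasticity undefined: perturbed output is not > 0")
    return (np.log(f1) - np.log(f0)) / (np.log(a * (1.0 + i)) - np.log(a))
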