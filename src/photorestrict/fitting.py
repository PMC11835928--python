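"""Least-squares estimation of response-curve parameters.

Fits the A/C non-rectangular hyperbola (drivers Ci or Cm) and the
gross-assimilation light response (driver PPFD) to ordered (driver, A)
observations by unweighted nonlinear least squares
(``scipy.optimize.least_squares``, trust-region reflective, bounded).

Initial guesses are read off the data: the compensation point from linear
interpolation of the sign change in A, the initial slope from the two
lowest-driver points, the asymptote from 1.05 * max(A), curvature 0.7.
On non-convergence the fit is restarted from three jittered guesses and
flagged if still unsuccessful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .models import LightParams, NRHParams, cm_from_ci, light, nrh

__all__ = [
    "ResponseCurve",
    "FitResult",
    "fit_nrh",
    "fit_light",
    "curve_to_cm",
    "synthesize_curve",
]

DRIVER_KINDS = ("Ci", "Cm", "PPFD")


@dataclass(frozen=True)
class ResponseCurve:
    """Ordered (driver, assimilation) observations from one leaf.

    driver_kind : "Ci", "Cm" (umol mol-1) or "PPFD" (umol photons m-2 s-1)
    driver, a   : equal-length arrays; the curve is stored sorted by driver
    label       : plant/curve identifier
    ca          : ambient CO2 during the measurements, umol mol-1 (optional)
    g_m         : mesophyll conductance, mol m-2 s-1 (optional)
    """

    driver_kind: str
    driver: np.ndarray
    a: np.ndarray
    label: str = ""
    ca: float | None = None
    g_m: float | None = None

    def __post_init__(self) -> None:
        if self.driver_kind not in DRIVER_KINDS:
            raise ValueError(
                f"driver_kind must be one of {DRIVER_KINDS}, got {self.driver_kind!r}"
            )
        d = np.asarray(self.driver, float)
        a = np.asarray(self.a, float)
        if d.ndim != 1 or d.shape != a.shape:
            raise ValueError("driver and a must be equal-length 1-D arrays")
        if not (np.isfinite(d).all() and np.isfinite(a).all()):
            raise ValueError("driver and a must be finite")
        order = np.argsort(d)
        d, a = d[order], a[order]
        if np.any(np.diff(d) == 0):
            raise ValueError("duplicated driver values are not allowed")
        object.__setattr__(self, "driver", d)
        object.__setattr__(self, "a", a)

    def __len__(self) -> int:
        return len(self.driver)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a curve fit: parameters, RMSE, convergence flag, and
    which parameters were held fixed."""

    params: NRHParams | LightParams
    rmse: float
    converged: bool
    fixed: tuple[str, ...] = ()


def _check_fittable(curve: ResponseCurve) -> None:
    if len(curve) < 5:
        raise ValueError(f"need >= 5 points to fit, got {len(curve)}")
    if np.allclose(curve.a, curve.a[0]):
        raise ValueError("degenerate curve: all assimilation values identical")


def _gamma_guess(d: np.ndarray, a: np.ndarray) -> float:
    """Compensation-point guess from the sign change in A."""
    sign = np.signbit(a)
    idx = np.nonzero(sign[:-1] & ~sign[1:])[0]
    if idx.size:
        i = idx[0]
        # linear interpolation of the zero crossing
        return float(d[i] - a[i] * (d[i + 1] - d[i]) / (a[i + 1] - a[i]))
    return float(max(d[0] * 0.5, 0.0))


def fit_nrh(
    curve: ResponseCurve,
    fix_gamma: float | None = None,
    fix_omega: float | None = None,
    n_restarts: int = 3,
    seed: int = 0,
) -> FitResult:
    """Fit the non-rectangular hyperbola to an A/Ci or A/Cm curve.

    ``fix_gamma``/``fix_omega`` pin those parameters (as when refitting a
    flattened curve, whose curvature and compensation point are assumed
    unchanged by treatment).  Returns a :class:`FitResult` whose params
    carry the curve's basis.
    """
    if curve.driver_kind not in ("Ci", "Cm"):
        raise ValueError("fit_nrh needs a Ci- or Cm-driven curve")
    _check_fittable(curve)
    d, a = curve.driver, curve.a

    a_sat0 = 1.05 * float(a.max())
    if a_sat0 <= 0:
        raise ValueError("curve never reaches positive assimilation")
    ce0 = float((a[1] - a[0]) / (d[1] - d[0]))
    ce0 = ce0 if ce0 > 0 else 0.05
    gamma0 = fix_gamma if fix_gamma is not None else _gamma_guess(d, a)
    omega0 = fix_omega if fix_omega is not None else 0.7

    pos = d[a > 0]
    gamma_hi = float(pos.min()) if pos.size else float(d.max())
    names = ["a_sat", "ce", "omega", "gamma"]
    lo = {"a_sat": 1e-9, "ce": 1e-9, "omega": 1e-6, "gamma": 0.0}
    hi = {"a_sat": 10 * max(a.max(), 1.0), "ce": 10.0, "omega": 1.0, "gamma": gamma_hi}
    fixed = {}
    if fix_gamma is not None:
        fixed["gamma"] = float(fix_gamma)
    if fix_omega is not None:
        fixed["omega"] = float(fix_omega)
    free = [n for n in names if n not in fixed]
    x0 = np.array(
        [{"a_sat": a_sat0, "ce": ce0, "omega": omega0, "gamma": gamma0}[n] for n in free]
    )
    x0 = np.clip(x0, [lo[n] for n in free], [hi[n] for n in free])

    def assemble(x):
        p = dict(fixed)
        p.update(dict(zip(free, x)))
        return p

    def residuals(x):
        p = assemble(x)
        return nrh(d, p["a_sat"], p["ce"], p["omega"], p["gamma"]) - a

    rng = np.random.default_rng(seed)
    best = None
    guess = x0
    for attempt in range(1 + n_restarts):
        try:
            res = least_squares(
                residuals,
                guess,
                bounds=([lo[n] for n in free], [hi[n] for n in free]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except ValueError:
            res = None
        if res is not None and (best is None or res.cost < best.cost):
            best = res
        if best is not None and best.success and best.cost < 1e-10:
            break
        guess = x0 * rng.uniform(0.5, 1.5, size=x0.size)
        guess = np.clip(guess, [lo[n] for n in free], [hi[n] for n in free])
    if best is None:
        raise RuntimeError("hyperbola fit failed from every starting point")
    p = assemble(best.x)
    params = NRHParams(
        a_sat=p["a_sat"],
        ce=p["ce"],
        omega=min(p["omega"], 1.0),
        gamma=p["gamma"],
        basis=curve.driver_kind,
    )
    rmse = float(np.sqrt(np.mean(residuals(best.x) ** 2)))
    return FitResult(params=params, rmse=rmse, converged=bool(best.success),
                     fixed=tuple(sorted(fixed)))


def fit_light(
    curve: ResponseCurve, n_restarts: int = 3, seed: int = 0
) -> FitResult:
    """Fit the light-response hyperbola to a GA/PPFD curve."""
    if curve.driver_kind != "PPFD":
        raise ValueError("fit_light needs a PPFD-driven curve")
    _check_fittable(curve)
    d, a = curve.driver, curve.a
    ga0 = 1.05 * float(a.max())
    if ga0 <= 0:
        raise ValueError("curve never reaches positive assimilation")
    nz = d > 0
    y0 = float(a[nz][0] / d[nz][0]) if nz.any() else 0.05
    y0 = y0 if y0 > 0 else 0.05
    lo = np.array([1e-9, 1e-9, 1e-6])
    hi = np.array([10.0, 10 * max(a.max(), 1.0), 1.0])
    x0 = np.clip(np.array([y0, ga0, 0.7]), lo, hi)

    def residuals(x):
        return light(d, x[0], x[1], x[2]) - a

    rng = np.random.default_rng(seed)
    best = None
    guess = x0
    for attempt in range(1 + n_restarts):
        res = least_squares(residuals, guess, bounds=(lo, hi),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or res.cost < best.cost:
            best = res
        if best.success and best.cost < 1e-10:
            break
        guess = np.clip(x0 * rng.uniform(0.5, 1.5, size=3), lo, hi)
    params = LightParams(y_ll=best.x[0], ga_sat=best.x[1], m=min(best.x[2], 1.0))
    rmse = float(np.sqrt(np.mean(residuals(best.x) ** 2)))
    return FitResult(params=params, rmse=rmse, converged=bool(best.success))


def curve_to_cm(curve: ResponseCurve, g_m: float) -> ResponseCurve:
    """Convert an A/Ci curve to an A/Cm curve via Cm = Ci - A/g_m.

    Assimilation values are unchanged; only the driver is shifted point by
    point by the mesophyll draw-down.
    """
    if curve.driver_kind != "Ci":
        raise ValueError("curve_to_cm expects a Ci-driven curve")
    cm = cm_from_ci(curve.driver, curve.a, g_m)
    return ResponseCurve(
        driver_kind="Cm",
        driver=cm,
        a=curve.a.copy(),
        label=curve.label,
        ca=curve.ca,
        g_m=g_m,
    )


def synthesize_curve(
    params: NRHParams | LightParams,
    grid,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "synthetic",
) -> ResponseCurve:
    """Generate a response curve from known parameters.

    Evaluates the model on ``grid`` and adds i.i.d. Gaussian noise with
    standard deviation ``noise_sd`` (umol m-2 s-1; 0 gives exact model
    values).  Deterministic for a fixed ``seed``.  Used for tests and for
    the mechanistic-conversion refit pathway (10-15 dummy driver values
    run through a source model, then refitted with the hyperbola).
    """
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("driver grid must be non-empty")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if isinstance(params, NRHParams):
        a = nrh(grid, params.a_sat, params.ce, params.omega, params.gamma)
        kind = params.basis
    elif isinstance(params, LightParams):
        a = light(grid, params.y_ll, params.ga_sat, params.m)
        kind = "PPFD"
    else:
        raise TypeError(f"unsupported parameter type {type(params).__name__}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sd, size=grid.shape)
    return ResponseCurve(driver_kind=kind, driver=grid, a=a, label=label)
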