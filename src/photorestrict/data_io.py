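"""Bundled example data, CSV readers/writers, configs and reports.

The bundled fixture is a synthetic demonstration dataset for two plants —
an untreated ("healthy") plant and one subjected to a hypothetical
treatment that reduced its photosynthetic potential — comprising the
operational points, 9-point A/Ci response curves, the derived A/Cm curves
(mesophyll conductances 0.35 and 0.25 mol m-2 s-1), and the hyperbola
parameters fitted on each basis.  The healthy A/Ci column is noiseless
output of the Ci-based parameter set, which makes the fixture a complete
end-to-end oracle for fitting and for every worked analysis.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import DRIVER_KINDS, ResponseCurve
from .framework import MODELS, ContributionTable, State, Transition
from .models import Conductances, NRHParams, OperationalPoint

__all__ = [
    "PlantFixture",
    "load_fixture",
    "fixture_names",
    "read_curve_csv",
    "write_curve_csv",
    "write_report",
    "AnalysisConfig",
    "load_config",
    "REPORT_SCHEMA_VERSION",
    "AMBIENT_CA",
]

REPORT_SCHEMA_VERSION = "1.0"

#: Ambient CO2 mole fraction of the example conditions, umol mol-1.
AMBIENT_CA = 420.0

# --- bundled synthetic example data ----------------------------------------
# One row per CO2 step: Ci, then (A, Cm) for the healthy and treated plant.
# Cm columns are Ci - A/g_m rounded to integers, with g_m = 0.35 (healthy)
# and 0.25 (treated) mol m-2 s-1.
_CI = [24, 35, 50, 71, 101, 145, 210, 294, 420]
_HEALTHY_A = [-2.59, -1.22, 0.60, 3.00, 6.15, 10.1, 14.4, 17.9, 20.7]
_HEALTHY_CM = [32, 38, 48, 62, 84, 116, 166, 243, 361]
_TREATED_A = [-1.91, -0.90, 0.44, 2.21, 4.53, 7.42, 10.6, 13.2, 15.2]
_TREATED_CM = [32, 39, 48, 62, 83, 115, 164, 242, 359]

_FIXTURES = {
    "healthy": {
        "op": (13.9, 200.0, 160.0),  # A_op, Ci_op, Cm_op
        "g_s_op": 0.063,  # A_op/(Ca - Ci_op) as printed (2 sig figs)
        "g_m": 0.35,
        "a": _HEALTHY_A,
        "cm": _HEALTHY_CM,
        "params_ci": (26.0, 0.12, 0.7, 45.0),
        "params_cm": (26.0, 0.18, 0.54, 45.0),
    },
    "treated": {
        "op": (11.0, 220.0, 176.0),
        "g_s_op": 0.055,
        "g_m": 0.25,
        "a": _TREATED_A,
        "cm": _TREATED_CM,
        "params_ci": (19.0, 0.09, 0.7, 45.0),
        "params_cm": (19.0, 0.14, 0.54, 45.0),
    },
}


@dataclass(frozen=True)
class PlantFixture:
    """One plant of the bundled example: operational point, response
    curves on both CO2 bases, conductances, and fitted parameters."""

    label: str
    operational: OperationalPoint
    g_m: float
    g_s_op: float
    aci: ResponseCurve
    acm: ResponseCurve
    params_ci: NRHParams
    params_cm: NRHParams

    @property
    def conductances(self) -> Conductances:
        return Conductances(g_s=self.g_s_op, g_m=self.g_m)


def fixture_names() -> tuple[str, ...]:
    return tuple(sorted(_FIXTURES))


def load_fixture(name: str) -> PlantFixture:
    """Load a bundled example plant ("healthy" or "treated")."""
    try:
        raw = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        ) from None
    a_op, ci_op, cm_op = raw["op"]
    op = OperationalPoint(a_op=a_op, ci_op=ci_op, ca=AMBIENT_CA, cm_op=cm_op)
    g_s_op = raw["g_s_op"]  # the published operational value, not rederived
    aci = ResponseCurve(
        driver_kind="Ci",
        driver=np.array(_CI, float),
        a=np.array(raw["a"], float),
        label=name,
        ca=AMBIENT_CA,
        g_m=raw["g_m"],
    )
    acm = ResponseCurve(
        driver_kind="Cm",
        driver=np.array(raw["cm"], float),
        a=np.array(raw["a"], float),
        label=name,
        ca=AMBIENT_CA,
        g_m=raw["g_m"],
    )
    return PlantFixture(
        label=name,
        operational=op,
        g_m=raw["g_m"],
        g_s_op=g_s_op,
        aci=aci,
        acm=acm,
        params_ci=NRHParams(*raw["params_ci"], basis="Ci"),
        params_cm=NRHParams(*raw["params_cm"], basis="Cm"),
    )


# --- CSV curves -------------------------------------------------------------

def read_curve_csv(path) -> ResponseCurve:
    """Read a response curve from CSV.

    Expected layout: header ``<driver>,A`` where <driver> is Ci, Cm or
    PPFD; period decimal point, comma separator, UTF-8.  Locale variants
    with comma decimals are rejected explicitly.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=",", encoding="utf-8", float_precision="round_trip")
    if frame.shape[1] < 2:
        raise ValueError(
            f"{path}: expected columns '<driver>,A' (driver one of "
            f"{DRIVER_KINDS}); got {list(frame.columns)}"
        )
    driver_col = frame.columns[0].strip()
    if driver_col not in DRIVER_KINDS:
        raise ValueError(
            f"{path}: first column must name the driver ({', '.join(DRIVER_KINDS)}), "
            f"got {driver_col!r}"
        )
    if "A" not in frame.columns:
        raise ValueError(f"{path}: missing required column 'A'")
    for col in (frame.columns[0], "A"):
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame[col].astype(str)
            if bad.str.contains(",").any():
                raise ValueError(
                    f"{path}: column {col!r} uses comma decimals; this reader "
                    "accepts only period decimal point with comma separators"
                )
            raise ValueError(f"{path}: column {col!r} is not numeric")
    return ResponseCurve(
        driver_kind=driver_col,
        driver=frame[frame.columns[0]].to_numpy(float),
        a=frame["A"].to_numpy(float),
        label=path.stem,
    )


def write_curve_csv(curve: ResponseCurve, path) -> None:
    """Write a curve as ``<driver>,A`` CSV at full float precision."""
    frame = pd.DataFrame({curve.driver_kind: curve.driver, "A": curve.a})
    frame.to_csv(path, index=False, float_format="%.17g")


# --- reports ----------------------------------------------------------------

def write_report(
    table: ContributionTable,
    json_path=None,
    csv_path=None,
    analysis: str = "",
) -> dict:
    """Serialise a ContributionTable: JSON report (full, incl. per-interval
    series) and/or CSV metrics table.  Returns the report dict."""
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "analysis": analysis,
        "K": table.K,
        "variant": table.variant,
        "omega_start": table.omega_start,
        "omega_end": table.omega_end,
        "delta_omega": table.delta_omega,
        "closure_residual": table.closure_residual,
        "rho_defined": table.rho_defined,
        "limitation_defined": table.limitation_defined,
        "state_outputs": table.state_outputs,
        "inputs": {
            n: {"xi_total": c.xi_total, "rho": c.rho, "limitation": c.limitation}
            for n, c in table.contributions.items()
        },
        "meta": {
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in table.meta.items()
        },
    }
    if table.control is not None:
        def _plain(x):
            if isinstance(x, str):
                return x
            if pd.isna(x):
                return None
            return x.item() if isinstance(x, np.generic) else x

        report["control_series"] = {
            col: [_plain(x) for x in table.control.frame[col]]
            for col in table.control.frame.columns
        }
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report, indent=1), encoding="utf-8")
    if csv_path is not None:
        table.to_frame().to_csv(csv_path, index=False, float_format="%.17g")
    return report


# --- analysis configuration -------------------------------------------------

@dataclass(frozen=True)
class AnalysisConfig:
    """A generic transition specification parsed from YAML.

    Layout::

        model: nrh | coupled | light
        K: 1000                # optional, default 1000
        g_high: 1.0e6          # optional
        i: 1.0e-4              # optional, control-analysis increment
        seed: 0                # optional
        states:                # ordered mapping, >= 2 entries
          operational: {c: 200, a_sat: 26, ce: 0.12, omega: 0.7, gamma: 45}
          potential:   {c: 420, a_sat: 26, ce: 0.12, omega: 0.7, gamma: 45}
    """

    model: str
    K: int
    g_high: float
    i: float
    seed: int
    states: tuple[State, ...]

    def transition(self) -> Transition:
        return Transition(self.states, K=self.K)


def load_config(path) -> AnalysisConfig:
    """Parse and validate a YAML analysis config (see AnalysisConfig)."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {"model", "K", "g_high", "i", "seed", "states"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    model = doc.get("model")
    if model not in MODELS:
        raise ValueError(
            f"{path}: 'model' must be one of {sorted(MODELS)}, got {model!r}"
        )
    K = doc.get("K", 1000)
    if not (isinstance(K, int) and K >= 1):
        raise ValueError(f"{path}: 'K' must be an integer >= 1, got {K!r}")
    g_high = float(doc.get("g_high", 1.0e6))
    i = float(doc.get("i", 1.0e-4))
    seed = int(doc.get("seed", 0))
    raw_states = doc.get("states")
    if not isinstance(raw_states, dict) or len(raw_states) < 2:
        raise ValueError(f"{path}: 'states' must be a mapping with >= 2 entries")
    states = []
    for name, inputs in raw_states.items():
        if not isinstance(inputs, dict):
            raise ValueError(f"{path}: state {name!r} must map input names to numbers")
        states.append(State(name=str(name), model=model, inputs=inputs))
    return AnalysisConfig(
        model=model, K=K, g_high=g_high, i=i, seed=seed, states=tuple(states)
    )
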