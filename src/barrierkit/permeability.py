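"""Apparent permeability from tracer assays.

A fluorescent tracer (e.g. 70 kDa FITC-dextran) is loaded into the vascular
channel; after an incubation window the parenchymal-side medium is recovered
and its fluorescence converted to a concentration through a linear
calibration curve.  The apparent permeability coefficient is

    P_app = (V_rec * dC_rec) / (A * dt * C_t0)    [cm s^-1]

with V_rec the recovered volume (mL), dC_rec the tracer concentration gained
by the receiving compartment (mg/mL), A the diffusion area (cm^2), dt the
assay duration (s) and C_t0 the donor concentration at t = 0 (mg/mL).

Barrier tightness is summarised as the percent reduction of P_app relative
to a cell-free control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "TracerAssay",
    "fit_calibration",
    "concentration_from_signal",
    "apparent_permeability",
    "percent_reduction",
]


class AssayError(ValueError):
    """Invalid assay inputs (degenerate calibration, zero donor, ...)."""


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line signal = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise AssayError("calibration slope is zero; curve is degenerate")


@dataclass(frozen=True)
class TracerAssay:
    """One permeability measurement.

    ``c_rec`` is the recovered tracer concentration; ``c_background`` the
    receiving-compartment concentration at t = 0 (default 0 for a clean
    start).  ``signed_dc`` keeps the literal receiving-minus-donor
    difference instead, which is negative for any real barrier and is only
    useful for diagnostics.
    """

    v_rec_ml: float
    c_rec_mg_ml: float
    c_t0_mg_ml: float
    area_cm2: float
    dt_s: float
    c_background_mg_ml: float = 0.0
    signed_dc: bool = False

    def __post_init__(self) -> None:
        if self.v_rec_ml <= 0 or self.area_cm2 <= 0 or self.dt_s <= 0:
            raise AssayError("V_rec, A and dt must all be positive")
        if self.c_rec_mg_ml < 0:
            raise AssayError("recovered concentration cannot be negative")


def fit_calibration(standards: Sequence) -> CalibrationCurve:
    """Fit the signal-vs-concentration line by ordinary least squares.

    ``standards`` is a sequence of (concentration, signal) pairs; at least
    two distinct concentrations are required.
    """
    pts = np.asarray(list(standards), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise AssayError("need >= 2 (concentration, signal) standards")
    conc, sig = pts[:, 0], pts[:, 1]
    if np.ptp(conc) == 0:
        raise AssayError("all standards share one concentration; "
                         "cannot fit a calibration line")
    res = stats.linregress(conc, sig)
    return CalibrationCurve(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2))


def concentration_from_signal(curve: CalibrationCurve, signal: float) -> float:
    """Invert the calibration line; negative results clip to 0 with a warning.

    Blank noise routinely pushes signals below the intercept, so a negative
    inverted concentration is reported as zero rather than an error.
    """
    conc = (float(signal) - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn(
            f"signal {signal} inverts to negative concentration {conc:.3g}; "
            "clipped to 0", stacklevel=2)
        return 0.0
    return conc


def apparent_permeability(assay: TracerAssay) -> float:
    """P_app = V_rec * dC_rec / (A * dt * C_t0), cm/s.

    dC_rec defaults to recovered concentration minus the receiving-side
    background at t = 0 (clipped at 0); with ``signed_dc`` the literal
    receiving-minus-donor difference is used instead.
    """
    if assay.c_t0_mg_ml == 0:
        raise AssayError("donor concentration C_t0 is zero; P_app undefined")
    if assay.signed_dc:
        dc = assay.c_rec_mg_ml - assay.c_t0_mg_ml
    else:
        dc = max(assay.c_rec_mg_ml - assay.c_background_mg_ml, 0.0)
    return (assay.v_rec_ml * dc) / (
        assay.area_cm2 * assay.dt_s * assay.c_t0_mg_ml)


def percent_reduction(p_app_barrier: float, p_app_control: float) -> float:
    """100 * (1 - P_app_barrier / P_app_control).

    100% means no transport across the barrier; 0% means barrier and control
    are indistinguishable.
    """
    if p_app_control == 0:
        raise AssayError("control P_app is zero; reduction undefined")
    return 100.0 * (1.0 - p_app_barrier / p_app_control)
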