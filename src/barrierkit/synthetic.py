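"""Seeded synthetic inputs with known ground truth.

Every pipeline stage is testable without instrument data: staged impedance
spectra are generated from a shared circuit truth with multiplicative
magnitude noise and additive phase noise; tracer assays are built by running
the permeability equation forward from a known true P_app; drug-crossing
time courses follow a saturating exponential toward a plateau.

Zero-noise outputs are exact forward-model evaluations, and identical seeds
give identical draws, so generator output doubles as a recovery oracle for
the fitting and assay code.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .circuit_core import (
    FrequencyGrid,
    ImpedanceSpectrum,
    Stage,
    StagePreset,
    circuit_impedance,
    default_grid,
    stage_parameter_names,
    stage_preset,
)
from .eis_fit import DEFAULT_ELECTRODE_AREA_CM2
from .permeability import TracerAssay

__all__ = [
    "SpectrumNoiseModel",
    "GroundTruth",
    "generate_spectrum",
    "generate_staged_dataset",
    "generate_permeability_assay",
    "generate_drug_timecourse",
    "default_ground_truth",
]


@dataclass(frozen=True)
class SpectrumNoiseModel:
    """Multiplicative Gaussian noise on |Z| plus additive Gaussian phase noise.

    ``magnitude_cv`` is the relative SD of the magnitude factor (default 1%),
    ``phase_sd_deg`` the SD of the additive phase error in degrees.
    """

    magnitude_cv: float = 0.01
    phase_sd_deg: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.magnitude_cv < 0 or self.phase_sd_deg < 0:
            raise ValueError("noise levels must be non-negative")


# Ground-truth circuit parameters for the four assembly stages.  Shared
# elements (R_medium across all stages; matrix block I->II; lumped
# matrix+cells block and endothelial CPE III->IV) are literally shared.
# The default barrier resistance is chosen so TEER = R_teer * 2.35e-3 cm^2
# lands at the 17.8 ohm cm^2 scale typical of mature barrier-on-chip models.
@dataclass(frozen=True)
class GroundTruth:
    r_medium: float = 500.0
    cpe_electrode_q: float = 1e-5
    cpe_electrode_n: float = 0.85
    r_matrix: float = 5000.0
    cpe_matrix_q: float = 1e-6
    cpe_matrix_n: float = 0.90
    r_cells: float = 2000.0
    cpe_cells_q: float = 8.4e-6
    cpe_cells_n: float = 0.90
    cpe_cells_e_q: float = 8e-6
    cpe_cells_e_n: float = 0.85
    r_matrix_cells: float = 7000.0
    cpe_matrix_cells_q: float = 1.5e-6
    cpe_matrix_cells_n: float = 0.90
    r_teer: float = 17.83 / DEFAULT_ELECTRODE_AREA_CM2
    cpe_bbb_q: float = 5e-7
    cpe_bbb_n: float = 0.92
    true_papp_control_cm_s: float = 1e-5
    true_papp_barrier_cm_s: float = 2e-6
    drug_plateau_percent: float = 96.0
    drug_rate_per_min: float = 0.1116

    def stage_parameters(self, stage: Stage | str) -> dict:
        stage = Stage(stage)
        full = {
            "R_medium": self.r_medium,
            "CPE_electrode.Q": self.cpe_electrode_q,
            "CPE_electrode.n": self.cpe_electrode_n,
            "R_matrix": self.r_matrix,
            "CPE_matrix.Q": self.cpe_matrix_q,
            "CPE_matrix.n": self.cpe_matrix_n,
            "R_cells": self.r_cells,
            "CPE_cells.Q": self.cpe_cells_q,
            "CPE_cells.n": self.cpe_cells_n,
            "CPE_cells_E.Q": self.cpe_cells_e_q,
            "CPE_cells_E.n": self.cpe_cells_e_n,
            "R_matrix_cells": self.r_matrix_cells,
            "CPE_matrix_cells.Q": self.cpe_matrix_cells_q,
            "CPE_matrix_cells.n": self.cpe_matrix_cells_n,
            "R_teer": self.r_teer,
            "CPE_bbb.Q": self.cpe_bbb_q,
            "CPE_bbb.n": self.cpe_bbb_n,
        }
        return {k: full[k] for k in stage_parameter_names(stage)}

    def stage_model(self, stage: Stage | str) -> StagePreset:
        return stage_preset(stage, self.stage_parameters(stage))

    def with_teer_resistance(self, r_teer: float) -> "GroundTruth":
        return replace(self, r_teer=r_teer)


def default_ground_truth() -> GroundTruth:
    return GroundTruth()


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def generate_spectrum(preset: StagePreset, grid: FrequencyGrid | None = None,
                      noise: SpectrumNoiseModel | None = None,
                      ) -> ImpedanceSpectrum:
    """Forward-model spectrum with acquisition-like noise.

    Magnitude is multiplied by ``1 + cv * N(0,1)`` per point, phase gets an
    additive Gaussian error.  The raw draws are stored under
    ``metadata['noise_draws']`` for audit; with zero noise the output equals
    the exact forward model.
    """
    grid = grid or default_grid()
    noise = noise or SpectrumNoiseModel()
    clean = circuit_impedance(preset.model, grid)
    if noise.magnitude_cv == 0 and noise.phase_sd_deg == 0:
        return ImpedanceSpectrum(
            grid, clean.magnitude, clean.phase,
            {"stage": preset.stage.value, "amplitude_mV": 10.0})
    rng = np.random.default_rng(noise.seed)
    mag_draws = rng.standard_normal(len(grid))
    phase_draws = rng.standard_normal(len(grid))
    factor = 1.0 + noise.magnitude_cv * mag_draws
    factor = np.clip(factor, 0.05, None)  # keep magnitudes positive
    return ImpedanceSpectrum(
        grid,
        clean.magnitude * factor,
        clean.phase + noise.phase_sd_deg * phase_draws,
        {
            "stage": preset.stage.value,
            "amplitude_mV": 10.0,
            "noise_draws": {"magnitude": mag_draws, "phase": phase_draws},
        },
    )


def generate_staged_dataset(truth: GroundTruth | None = None,
                            grid: FrequencyGrid | None = None,
                            noise: SpectrumNoiseModel | None = None,
                            ) -> tuple:
    """Spectra for stages I-IV from one shared truth, plus the truth record.

    Per-stage noise draws are decorrelated by offsetting the seed with the
    stage index; the same (truth, grid, noise) call is fully reproducible.
    """
    truth = truth or GroundTruth()
    grid = grid or default_grid()
    noise = noise or SpectrumNoiseModel()
    spectra = {}
    for i, stage in enumerate(Stage):
        stage_noise = SpectrumNoiseModel(
            noise.magnitude_cv, noise.phase_sd_deg, noise.seed + 1000 * i)
        spectra[stage] = generate_spectrum(
            truth.stage_model(stage), grid, stage_noise)
    return spectra, truth


# ---------------------------------------------------------------------------
# permeability assay
# ---------------------------------------------------------------------------

def generate_permeability_assay(true_papp_cm_s: float,
                                v_rec_ml: float = 0.1,
                                area_cm2: float = 0.2,
                                dt_s: float = 3600.0,
                                c_t0_mg_ml: float = 1.0,
                                signal_noise_sd: float = 0.0,
                                seed: int = 0,
                                calibration_slope: float = 1000.0,
                                calibration_intercept: float = 50.0,
                                ) -> tuple:
    """Tracer assay built by inverting the permeability equation.

    The recovered concentration is the exact forward value
    ``dC = P_app * A * dt * C_t0 / V_rec``; it is converted to a fluorescence
    signal through a known calibration line and optionally noised.  Returns
    ``(assay, measured_signal, standards)`` where ``standards`` reproduce the
    calibration line exactly.
    """
    if true_papp_cm_s < 0:
        raise ValueError("true P_app must be non-negative")
    dc = true_papp_cm_s * area_cm2 * dt_s * c_t0_mg_ml / v_rec_ml
    signal = calibration_slope * dc + calibration_intercept
    if signal_noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal += signal_noise_sd * rng.standard_normal()
    standards = [(c, calibration_slope * c + calibration_intercept)
                 for c in (0.0, 0.002, 0.005, 0.01, 0.02, 0.05)]
    assay = TracerAssay(v_rec_ml=v_rec_ml, c_rec_mg_ml=dc,
                        c_t0_mg_ml=c_t0_mg_ml, area_cm2=area_cm2, dt_s=dt_s)
    return assay, float(signal), standards


# ---------------------------------------------------------------------------
# drug crossing time course
# ---------------------------------------------------------------------------

def generate_drug_timecourse(plateau_percent: float, rate_per_min: float,
                             timepoints_min, noise_sd: float = 0.0,
                             seed: int = 0) -> np.ndarray:
    """Normalized crossing fractions f(t) = plateau * (1 - exp(-rate t)).

    Emulates the saturating, plateau-reaching shape of normalized drug
    crossing versus time; no mechanistic transport claim is made.  Noiseless
    output is exactly the saturating exponential (monotone nondecreasing,
    f(0) = 0).
    """
    if not 0 < plateau_percent <= 100:
        raise ValueError("plateau must be in (0, 100] percent")
    if rate_per_min <= 0:
        raise ValueError("rate must be positive")
    t = np.asarray(timepoints_min, dtype=float)
    f = plateau_percent * (1.0 - np.exp(-rate_per_min * t))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + noise_sd * rng.standard_normal(t.shape)
    return f
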