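"""End-to-end barrier monitoring pipeline.

``run_monitor`` chains the analysis the sensorized chip enables: staged
circuit fits on the available spectra, TEER extraction from the complete
model, barrier classification against the cell-free control, and (when
assays are present) apparent-permeability summaries.  The report is
deterministic JSON: sorted keys, input files referenced by SHA-256 checksum,
timestamps excluded from the reproducibility contract.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .eis_fit import (
    DEFAULT_ELECTRODE_AREA_CM2,
    DEFAULT_RATIO_THRESHOLD,
    FitConfig,
    assess_barrier,
    extract_teer,
    staged_calibration,
)
from .circuit_core import Stage
from .io import read_assays_csv, read_calibration_csv, read_spectrum_csv
from .permeability import (
    apparent_permeability,
    concentration_from_signal,
    fit_calibration,
    percent_reduction,
    TracerAssay,
)

__all__ = ["RunConfig", "run_monitor", "write_report"]

logger = logging.getLogger(__name__)

STAGE_FILES = {
    Stage.I_MATRIX_ONLY: "stage_i.csv",
    Stage.II_MATRIX_PLUS_BRAIN_CELLS: "stage_ii.csv",
    Stage.III_LUMPED_WITH_ENDOTHELIUM: "stage_iii.csv",
    Stage.IV_COMPLETE: "stage_iv.csv",
}


@dataclass
class RunConfig:
    """Inputs for one monitoring run.

    ``spectra_dir`` must contain ``stage_i.csv`` .. ``stage_iv.csv`` (missing
    stages are tolerated and reported).  Assay/calibration files are optional.
    """

    spectra_dir: Path
    assays_path: Path | None = None
    calibration_path: Path | None = None
    area_cm2: float = DEFAULT_ELECTRODE_AREA_CM2
    crossover_hz: float = 50.0
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD
    seed: int = 0
    fit: FitConfig = field(default_factory=lambda: FitConfig(n_restarts=2))

    def __post_init__(self) -> None:
        self.spectra_dir = Path(self.spectra_dir)
        if not self.area_cm2 > 0:
            raise ValueError("electrode area must be positive")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps({
        "area_cm2": config.area_cm2,
        "crossover_hz": config.crossover_hz,
        "ratio_threshold": config.ratio_threshold,
        "seed": config.seed,
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _permeability_section(config: RunConfig, report: dict) -> None:
    assays = read_assays_csv(config.assays_path)
    standards = read_calibration_csv(config.calibration_path)
    curve = fit_calibration(standards)
    report["inputs"][str(config.assays_path)] = _sha256(Path(config.assays_path))
    report["inputs"][str(config.calibration_path)] = _sha256(
        Path(config.calibration_path))

    samples = []
    by_role: dict = {"barrier": [], "control": []}
    for _, row in assays.iterrows():
        conc = concentration_from_signal(curve, row["signal"])
        assay = TracerAssay(
            v_rec_ml=row["v_rec_ml"], c_rec_mg_ml=conc,
            c_t0_mg_ml=row["c_t0_mg_ml"], area_cm2=row["a_cm2"],
            dt_s=row["dt_s"])
        papp = apparent_permeability(assay)
        samples.append({"sample_id": str(row["sample_id"]),
                        "role": row["role"], "p_app_cm_s": papp})
        by_role[row["role"]].append(papp)

    section: dict = {
        "calibration": {"slope": curve.slope, "intercept": curve.intercept,
                        "r_squared": curve.r_squared},
        "samples": samples,
    }
    if by_role["barrier"] and by_role["control"]:
        mean = lambda xs: sum(xs) / len(xs)
        section["percent_reduction_vs_control"] = percent_reduction(
            mean(by_role["barrier"]), mean(by_role["control"]))
    report["permeability"] = section


def run_monitor(config: RunConfig) -> dict:
    """Run staged fit -> TEER -> barrier assessment -> permeability.

    Non-fatal stage failures are recorded under ``errors`` and the pipeline
    continues; the report carries the tool version and a config hash.
    """
    report: dict = {
        "tool_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "inputs": {},
        "errors": {},
        "stages": {},
        "teer": None,
        "barrier": None,
    }

    spectra = {}
    for stage, fname in STAGE_FILES.items():
        path = config.spectra_dir / fname
        if not path.exists():
            report["errors"][f"stage_{stage.value}"] = f"missing file {fname}"
            continue
        spectra[stage] = read_spectrum_csv(path)
        report["inputs"][str(path)] = _sha256(path)

    if spectra:
        fit_cfg = FitConfig(
            initial_values=config.fit.initial_values,
            bounds=config.fit.bounds,
            max_iterations=config.fit.max_iterations,
            tolerance=config.fit.tolerance,
            seed=config.seed, n_restarts=config.fit.n_restarts)
        try:
            results = staged_calibration(spectra, fit_cfg)
        except Exception as exc:
            report["errors"]["staged_fit"] = str(exc)
            results = {}
        for stage, res in results.items():
            report["stages"][stage.value] = {
                "parameters": res.parameters,
                "deviation_percent": res.deviation_percent,
                "accepted": res.accepted,
                "converged": res.converged,
                "iterations": res.iterations,
            }
            logger.info("stage %s: deviation %.3f%% -> accepted=%s",
                        stage.value, res.deviation_percent, res.accepted)

        if Stage.IV_COMPLETE in results:
            teer = extract_teer(results[Stage.IV_COMPLETE], config.area_cm2)
            report["teer"] = {
                "R_teer_ohm": teer.R_barrier,
                "area_cm2": teer.area_cm2,
                "teer_ohm_cm2": teer.teer_ohm_cm2,
            }

        if Stage.I_MATRIX_ONLY in spectra and Stage.IV_COMPLETE in spectra:
            try:
                assessment = assess_barrier(
                    spectra[Stage.I_MATRIX_ONLY], spectra[Stage.IV_COMPLETE],
                    config.crossover_hz, config.ratio_threshold)
                report["barrier"] = {
                    "crossover_hz": assessment.crossover_frequency_hz,
                    "mean_ratio": assessment.mean_magnitude_ratio_above_crossover,
                    "threshold": assessment.ratio_threshold,
                    "classification": assessment.classification,
                }
            except Exception as exc:
                report["errors"]["barrier_assessment"] = str(exc)
    else:
        report["errors"]["staged_fit"] = "no stage spectra found"

    if config.assays_path and config.calibration_path:
        try:
            _permeability_section(config, report)
        except Exception as exc:
            report["errors"]["permeability"] = str(exc)

    return report


def write_report(report: dict, path) -> None:
    """Serialize a report as deterministic JSON (sorted keys, fixed floats)."""
    path = Path(path)
    path.write_text(json.dumps(report, sort_keys=True, indent=2),
                    encoding="utf-8")
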