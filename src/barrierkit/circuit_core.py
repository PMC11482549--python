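"""Equivalent electrical circuits for two-electrode impedance spectra.

The barrier-on-chip is modelled by series/parallel networks of two element
kinds: ohmic resistors (cell culture medium, hydrogel matrix, the barrier
resistance that carries TEER) and constant phase elements (CPEs) describing
the distributed, non-ideal capacitance of electrode interfaces, hydrogel and
cell layers.  A CPE has impedance ``Z = 1 / (Q (j omega)^n)`` with
``0 < n <= 1``; ``n = 1`` is an ideal capacitor of capacitance ``Q``.

Four staged presets mirror the incremental assembly of the biological model:

* stage I   -- cell-free chip: electrode CPE, medium resistor, matrix R||CPE
* stage II  -- stage I plus brain cells (astrocytes/microglia) R||CPE block
* stage III -- endothelialised electrode; matrix+brain cells lumped R||CPE
* stage IV  -- complete model: endothelial CPE, medium, barrier R||CPE
               (the resistor is the TEER resistance), matrix+cells R||CPE
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyGrid",
    "ImpedanceSpectrum",
    "Resistor",
    "ConstantPhaseElement",
    "Series",
    "Parallel",
    "CircuitModel",
    "Stage",
    "StagePreset",
    "element_impedance",
    "circuit_impedance",
    "stage_preset",
    "stage_parameter_names",
    "bode_table",
    "default_grid",
    "STAGE_TOPOLOGIES",
]


class CircuitError(ValueError):
    """Invalid circuit structure or parameters."""


# ---------------------------------------------------------------------------
# frequency grid and spectrum containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly ascending grid of positive frequencies (Hz)."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise CircuitError("frequency grid must be a nonempty 1-D array")
        if np.any(f <= 0):
            raise CircuitError("frequencies must be strictly positive")
        if np.any(np.diff(f) <= 0):
            raise CircuitError("frequencies must be strictly ascending")
        object.__setattr__(self, "frequencies", f)

    @property
    def angular_frequencies(self) -> np.ndarray:
        """omega = 2 pi f, rad/s."""
        return 2.0 * np.pi * self.frequencies

    def __len__(self) -> int:
        return self.frequencies.size


def default_grid(f_min: float = 1.0, f_max: float = 1e5,
                 points_per_decade: int = 10) -> FrequencyGrid:
    """Log-spaced sweep grid; defaults cover 1 Hz - 100 kHz at 10 pts/decade."""
    n_dec = math.log10(f_max / f_min)
    n = int(round(n_dec * points_per_decade)) + 1
    return FrequencyGrid(np.logspace(math.log10(f_min), math.log10(f_max), n))


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Magnitude/phase representation of a two-electrode sweep.

    ``magnitude`` in ohm (positive), ``phase`` in degrees, negative for
    capacitive behaviour (Bode-plot convention).
    """

    grid: FrequencyGrid
    magnitude: np.ndarray
    phase: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mag = np.asarray(self.magnitude, dtype=float)
        ph = np.asarray(self.phase, dtype=float)
        n = len(self.grid)
        if mag.shape != (n,) or ph.shape != (n,):
            raise CircuitError("magnitude/phase length must match the grid")
        if np.any(mag <= 0):
            raise CircuitError("impedance magnitude must be positive")
        object.__setattr__(self, "magnitude", mag)
        object.__setattr__(self, "phase", ph)

    @property
    def complex_impedance(self) -> np.ndarray:
        return self.magnitude * np.exp(1j * np.deg2rad(self.phase))

    @classmethod
    def from_complex(cls, grid: FrequencyGrid, z: np.ndarray,
                     metadata: dict | None = None) -> "ImpedanceSpectrum":
        z = np.asarray(z, dtype=complex)
        return cls(grid, np.abs(z), np.rad2deg(np.angle(z)),
                   metadata or {})


# ---------------------------------------------------------------------------
# circuit elements and composition tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Resistor:
    name: str
    R: float

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise CircuitError(f"resistor {self.name!r}: R must be > 0")


@dataclass(frozen=True)
class ConstantPhaseElement:
    """CPE with Z = 1/(Q (j omega)^n); Q in S*s^n, 0 < n <= 1."""

    name: str
    Q: float
    n: float

    def __post_init__(self) -> None:
        if not self.Q > 0:
            raise CircuitError(f"CPE {self.name!r}: Q must be > 0")
        if not 0 < self.n <= 1:
            raise CircuitError(f"CPE {self.name!r}: n must be in (0, 1]")


Element = Union[Resistor, ConstantPhaseElement]


@dataclass(frozen=True)
class Series:
    children: tuple

    def __init__(self, *children):
        object.__setattr__(self, "children", tuple(children))


@dataclass(frozen=True)
class Parallel:
    children: tuple

    def __init__(self, *children):
        object.__setattr__(self, "children", tuple(children))


Node = Union[Series, Parallel, Resistor, ConstantPhaseElement]


def element_impedance(element: Element, omega) -> np.ndarray:
    """Complex impedance of a single element at angular frequency omega.

    A resistor is frequency independent (R + 0j).  A CPE follows
    ``1/(Q (j omega)^n)``: magnitude ``1/(Q omega^n)``, phase ``-n * 90``
    degrees.
    """
    w = np.asarray(omega, dtype=float)
    if np.any(w <= 0):
        raise CircuitError("angular frequency must be positive")
    if isinstance(element, Resistor):
        return np.broadcast_to(element.R + 0j, w.shape).copy()
    if isinstance(element, ConstantPhaseElement):
        return 1.0 / (element.Q * (1j * w) ** element.n)
    raise CircuitError(f"unknown element type: {type(element).__name__}")


def _evaluate(node: Node, omega: np.ndarray) -> np.ndarray:
    if isinstance(node, (Resistor, ConstantPhaseElement)):
        return element_impedance(node, omega)
    if isinstance(node, Series):
        if not node.children:
            raise CircuitError("SERIES node has no children")
        return sum(_evaluate(c, omega) for c in node.children)
    if isinstance(node, Parallel):
        if not node.children:
            raise CircuitError("PARALLEL node has no children")
        y = sum(1.0 / _evaluate(c, omega) for c in node.children)
        return 1.0 / y
    raise CircuitError(f"unknown node type: {type(node).__name__}")


def _leaves(node: Node) -> Iterable[Element]:
    if isinstance(node, (Resistor, ConstantPhaseElement)):
        yield node
    else:
        for c in node.children:
            yield from _leaves(c)


@dataclass(frozen=True)
class CircuitModel:
    """Series/parallel tree with uniquely named R/CPE leaves."""

    root: Node

    def __post_init__(self) -> None:
        names = [leaf.name for leaf in _leaves(self.root)]
        if not names:
            raise CircuitError("circuit tree is empty")
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CircuitError(f"duplicate leaf names: {dupes}")

    @property
    def elements(self) -> dict:
        return {leaf.name: leaf for leaf in _leaves(self.root)}

    def parameter_values(self) -> dict:
        """Flat name->value map; CPEs contribute ``<name>.Q`` and ``<name>.n``."""
        out: dict = {}
        for leaf in _leaves(self.root):
            if isinstance(leaf, Resistor):
                out[leaf.name] = leaf.R
            else:
                out[f"{leaf.name}.Q"] = leaf.Q
                out[f"{leaf.name}.n"] = leaf.n
        return out

    def with_parameters(self, values: Mapping[str, float]) -> "CircuitModel":
        """Rebuild the tree with updated parameter values (same topology)."""

        def rebuild(node: Node) -> Node:
            if isinstance(node, Resistor):
                return Resistor(node.name, values.get(node.name, node.R))
            if isinstance(node, ConstantPhaseElement):
                return ConstantPhaseElement(
                    node.name,
                    values.get(f"{node.name}.Q", node.Q),
                    values.get(f"{node.name}.n", node.n),
                )
            if isinstance(node, Series):
                return Series(*(rebuild(c) for c in node.children))
            return Parallel(*(rebuild(c) for c in node.children))

        return CircuitModel(rebuild(self.root))


def circuit_impedance(model: CircuitModel, grid: FrequencyGrid,
                      metadata: dict | None = None) -> ImpedanceSpectrum:
    """Evaluate a circuit over a frequency grid.

    Series nodes sum impedances; parallel nodes sum admittances and invert.
    """
    z = _evaluate(model.root, grid.angular_frequencies)
    return ImpedanceSpectrum.from_complex(grid, z, metadata)


def circuit_complex(model: CircuitModel, omega: np.ndarray) -> np.ndarray:
    """Raw complex impedance at angular frequencies (fit-path helper)."""
    return _evaluate(model.root, np.asarray(omega, dtype=float))


# ---------------------------------------------------------------------------
# staged presets
# ---------------------------------------------------------------------------

class Stage(str, Enum):
    I_MATRIX_ONLY = "i"
    II_MATRIX_PLUS_BRAIN_CELLS = "ii"
    III_LUMPED_WITH_ENDOTHELIUM = "iii"
    IV_COMPLETE = "iv"


# (kind, name) leaf lists per stage; wiring built in _stage_topology.
# R_teer/CPE_bbb are the barrier block (the resistor carries the TEER).
STAGE_TOPOLOGIES: dict = {
    Stage.I_MATRIX_ONLY: [
        ("cpe", "CPE_electrode"),
        ("r", "R_medium"),
        ("block", ("R_matrix", "CPE_matrix")),
    ],
    Stage.II_MATRIX_PLUS_BRAIN_CELLS: [
        ("cpe", "CPE_electrode"),
        ("r", "R_medium"),
        ("block", ("R_matrix", "CPE_matrix")),
        ("block", ("R_cells", "CPE_cells")),
    ],
    Stage.III_LUMPED_WITH_ENDOTHELIUM: [
        ("cpe", "CPE_cells_E"),
        ("r", "R_medium"),
        ("block", ("R_matrix_cells", "CPE_matrix_cells")),
    ],
    Stage.IV_COMPLETE: [
        ("cpe", "CPE_cells_E"),
        ("r", "R_medium"),
        ("block", ("R_teer", "CPE_bbb")),
        ("block", ("R_matrix_cells", "CPE_matrix_cells")),
    ],
}


def stage_parameter_names(stage: Stage) -> list:
    """Flat parameter names (R name, CPE name.Q / name.n) for a stage."""
    names: list = []
    for kind, spec in STAGE_TOPOLOGIES[Stage(stage)]:
        if kind == "r":
            names.append(spec)
        elif kind == "cpe":
            names += [f"{spec}.Q", f"{spec}.n"]
        else:
            r_name, c_name = spec
            names += [r_name, f"{c_name}.Q", f"{c_name}.n"]
    return names


@dataclass(frozen=True)
class StagePreset:
    stage: Stage
    model: CircuitModel


def stage_preset(stage: Stage | str, parameters: Mapping[str, float]) -> StagePreset:
    """Bind a parameter map to the canonical topology of a maturation stage.

    The map must cover every leaf parameter of the stage exactly; missing or
    extra names raise a configuration error listing the offenders.
    """
    stage = Stage(stage)
    expected = set(stage_parameter_names(stage))
    given = set(parameters)
    missing = sorted(expected - given)
    extra = sorted(given - expected)
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing parameters: {missing}")
        if extra:
            parts.append(f"unexpected parameters: {extra}")
        raise CircuitError(f"stage {stage.value}: " + "; ".join(parts))

    nodes: list = []
    for kind, spec in STAGE_TOPOLOGIES[stage]:
        if kind == "r":
            nodes.append(Resistor(spec, parameters[spec]))
        elif kind == "cpe":
            nodes.append(ConstantPhaseElement(
                spec, parameters[f"{spec}.Q"], parameters[f"{spec}.n"]))
        else:
            r_name, c_name = spec
            nodes.append(Parallel(
                Resistor(r_name, parameters[r_name]),
                ConstantPhaseElement(
                    c_name, parameters[f"{c_name}.Q"], parameters[f"{c_name}.n"]),
            ))
    return StagePreset(stage, CircuitModel(Series(*nodes)))


# ---------------------------------------------------------------------------
# tabular view
# ---------------------------------------------------------------------------

def bode_table(spectrum: ImpedanceSpectrum) -> pd.DataFrame:
    """Spectrum as a (freq_hz, z_mod_ohm, z_phase_deg) table."""
    return pd.DataFrame({
        "freq_hz": spectrum.grid.frequencies,
        "z_mod_ohm": spectrum.magnitude,
        "z_phase_deg": spectrum.phase,
    })
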