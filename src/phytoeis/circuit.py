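"""Exact complex impedance of the unified Randles–Debye suspension circuit.

The circuit is a series combination of two blocks:

* a Randles block — series access resistance ``R_s`` followed by the
  charge-transfer resistance ``R_ct`` in parallel with the double-layer
  element (an ideal capacitor ``C_dl`` or, more generally, a constant-phase
  element ``1/(C_dl (jw)^alpha)``);
* an extended Debye block for the suspension — the solution resistance
  ``R_1`` in parallel with the cell branch (cell resistance ``R`` in series
  with the cell capacitance ``C``) and with the water-polarization
  capacitance ``C_1``.

The Warburg diffusion element of the full Randles model is deliberately
omitted: it only matters below the bottom of the measurement band (a few Hz)
and is out of scope for this analysis.

All public interfaces use frequency in Hz; angular frequency (rad/s) is an
internal convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "CircuitParameters",
    "FrequencyGrid",
    "ImpedanceSpectrum",
    "evaluate_impedance",
    "medium_impedance",
]


class ValidationError(ValueError):
    """A parameter, frequency or contract precondition is invalid."""


def _require_positive(name: str, value: float) -> None:
    if value is None or not math.isfinite(value) or value <= 0:
        raise ValidationError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class CircuitParameters:
    """Lumped components of the unified Randles–Debye suspension circuit.

    The cell branch (``R`` in series with ``C``) is optional: a cell-free
    medium is represented by leaving both ``R`` and ``C`` as ``None``, never
    by sentinel values such as an infinite resistance.

    Parameters
    ----------
    R_s : float
        Series (solution-access) resistance of the Randles block, ohm.
    R_ct : float
        Charge-transfer resistance, ohm.
    C_dl : float
        Double-layer capacitance, farad.  When ``alpha_dl < 1`` this is the
        CPE coefficient Q in Z = 1/(Q (jw)^alpha), with units F s^(alpha-1).
    R_1 : float
        Resistance of the solution in the Debye block, ohm.
    C_1 : float
        Water-polarization capacitance, farad.
    R : float, optional
        Resistance of the cells, ohm.  ``None`` for a cell-free medium.
    C : float, optional
        Capacitance due to the presence of cells, farad.
    alpha_dl : float
        CPE exponent in (0, 1]; 1 recovers the ideal double-layer capacitor
        assumed by all closed-form asymptotics.
    """

    R_s: float
    R_ct: float
    C_dl: float
    R_1: float
    C_1: float
    R: float | None = None
    C: float | None = None
    alpha_dl: float = 1.0

    def __post_init__(self) -> None:
        for name in ("R_s", "R_ct", "C_dl", "R_1", "C_1"):
            _require_positive(name, getattr(self, name))
        if (self.R is None) != (self.C is None):
            raise ValidationError("cell branch requires both R and C (or neither)")
        if self.R is not None:
            _require_positive("R", self.R)
            _require_positive("C", self.C)
        if not (0.0 < self.alpha_dl <= 1.0):
            raise ValidationError(f"alpha_dl must be in (0, 1], got {self.alpha_dl!r}")

    @property
    def has_cell_branch(self) -> bool:
        return self.R is not None

    def without_cell_branch(self) -> "CircuitParameters":
        """The corresponding cell-free (medium-only) circuit."""
        return replace(self, R=None, C=None)

    def scaled(self, lam: float) -> "CircuitParameters":
        """All resistances scaled by ``lam``, all capacitances by ``1/lam``.

        This transformation leaves every corner frequency unchanged and
        multiplies the impedance by ``lam`` at all frequencies (only exact
        for ``alpha_dl = 1``).
        """
        _require_positive("lam", lam)
        return CircuitParameters(
            R_s=self.R_s * lam,
            R_ct=self.R_ct * lam,
            C_dl=self.C_dl / lam,
            R_1=self.R_1 * lam,
            C_1=self.C_1 / lam,
            R=None if self.R is None else self.R * lam,
            C=None if self.C is None else self.C / lam,
            alpha_dl=self.alpha_dl,
        )


@dataclass(frozen=True)
class FrequencyGrid:
    """A strictly increasing grid of positive frequencies, Hz."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValidationError("frequencies must be a non-empty 1-D array")
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ValidationError("frequencies must be strictly positive and finite")
        if np.any(np.diff(f) <= 0):
            raise ValidationError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)

    @classmethod
    def log_spaced(
        cls, f_min: float = 4.0, f_max: float = 2.0e10, points_per_decade: int = 10
    ) -> "FrequencyGrid":
        """Logarithmic grid, default spanning the 4 Hz – 20 GHz band."""
        _require_positive("f_min", f_min)
        _require_positive("f_max", f_max)
        if f_max <= f_min:
            raise ValidationError("f_max must exceed f_min")
        n = max(2, int(round(math.log10(f_max / f_min) * points_per_decade)) + 1)
        return cls(np.logspace(math.log10(f_min), math.log10(f_max), n))

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies, rad/s."""
        return 2.0 * np.pi * self.frequencies

    def __len__(self) -> int:
        return self.frequencies.size


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex impedance values paired with a frequency grid."""

    grid: FrequencyGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.values, dtype=complex)
        if z.shape != self.grid.frequencies.shape:
            raise ValidationError("values must match the frequency grid length")
        if not np.all(np.isfinite(z)) or np.any(np.abs(z) <= 0):
            raise ValidationError("impedance values must be finite with positive magnitude")
        object.__setattr__(self, "values", z)

    @property
    def frequencies(self) -> np.ndarray:
        return self.grid.frequencies

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase_deg(self) -> np.ndarray:
        """Phase in degrees, capacitive = negative, in [-90, 90]."""
        return np.degrees(np.arctan2(self.values.imag, self.values.real))

    def __len__(self) -> int:
        return len(self.grid)

    def slice_band(self, f_lo: float, f_hi: float) -> "ImpedanceSpectrum":
        """The sub-spectrum with f_lo <= f <= f_hi (may raise if empty)."""
        mask = (self.frequencies >= f_lo) & (self.frequencies <= f_hi)
        if not np.any(mask):
            raise ValidationError("requested band contains no grid points")
        return ImpedanceSpectrum(FrequencyGrid(self.frequencies[mask]), self.values[mask])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": self.frequencies,
                "z_real_ohm": self.values.real,
                "z_imag_ohm": self.values.imag,
            }
        )


def _as_grid(grid: FrequencyGrid | Iterable[float]) -> FrequencyGrid:
    return grid if isinstance(grid, FrequencyGrid) else FrequencyGrid(np.asarray(list(grid), float))


def evaluate_impedance(params: CircuitParameters, grid: FrequencyGrid) -> ImpedanceSpectrum:
    """Exact complex impedance of the unified circuit on a frequency grid.

    The Randles block is ``R_s`` in series with the double-layer element in
    parallel with ``R_ct``; the Debye block is the admittance sum of ``R_1``,
    ``C_1`` and (when present) the series ``R``–``C`` cell branch.
    """
    grid = _as_grid(grid)
    jw = 1j * grid.omega
    # double layer: CPE Z = 1/(C_dl (jw)^alpha); alpha = 1 is the ideal capacitor
    y_dl = params.C_dl * jw**params.alpha_dl
    z_randles = params.R_s + 1.0 / (1.0 / params.R_ct + y_dl)
    y_debye = 1.0 / params.R_1 + jw * params.C_1
    if params.has_cell_branch:
        y_debye = y_debye + 1.0 / (params.R + 1.0 / (jw * params.C))
    return ImpedanceSpectrum(grid, z_randles + 1.0 / y_debye)


def medium_impedance(params: CircuitParameters, grid: FrequencyGrid) -> ImpedanceSpectrum:
    """Impedance of the circuit with the cell R–C branch removed.

    Used as the cell-free reference when computing the region-5 deviation of
    a suspension from its medium.
    """
    return evaluate_impedance(params.without_cell_branch(), grid)
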