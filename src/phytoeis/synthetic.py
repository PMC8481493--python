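"""Synthetic concentration series emulating the four study suspensions.

Two cell lines (tomato "MSK8-like", tobacco "BY2-like") in two media
("MS-like" growth medium, higher conductivity; "PB-like" phosphate buffer,
lower conductivity) are emulated through concentration-dependent circuit
parameters.  The presets are fixtures engineered to reproduce the
qualitative behaviour of real suspensions — they are not calibrated to any
measured cell line:

* more cells lower the cell resistance (k = R/R_1 falls) and raise the cell
  capacitance, so both negative phase peaks deepen with concentration;
* dilute suspensions converge to the behaviour of their medium, dense ones
  to the behaviour of their cell type;
* the lower-conductivity medium (larger R_1) shows the larger region-5
  deviation from its cell-free reference;
* cell agglomeration multiplies the cell capacitance by a lognormal factor
  per sample, which scatters f4 while barely touching f6.

All randomness flows from a single user seed: ``generate_series`` spawns
one child seed per concentration via ``numpy.random.SeedSequence.spawn``,
and ``generate_spectrum`` draws, in order, one agglomeration factor, the
per-point magnitude factors, and the per-point phase jitter from
``numpy.random.default_rng(seed)``.  No global state is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .circuit import (
    CircuitParameters,
    FrequencyGrid,
    ImpedanceSpectrum,
    ValidationError,
    evaluate_impedance,
)
from .detection import SuspensionSeries

__all__ = ["ScenarioPreset", "CELL_TYPES", "MEDIA", "preset", "generate_spectrum", "generate_series"]

CELL_TYPES = ("MSK8-like", "BY2-like")
MEDIA = ("MS-like", "PB-like")

#: reference solution resistance against which media coupling is measured
_R1_REFERENCE = 80.0


@dataclass(frozen=True)
class ScenarioPreset:
    """Concentration response and noise model of one emulated suspension.

    Concentration is in arbitrary relative units in (0, 1] of a stock; 0
    denotes the cell-free medium.  The response maps concentration c to the
    circuit parameters as

    * ``k(c) = k_full / c * (R1_ref / R_1)^media_coupling`` (so k = R/R_1
      falls with concentration and depends weakly on the medium),
    * ``C(c) = C_full * c`` times one lognormal agglomeration draw,
    * ``R_s(c) = R_s0 / (1 + access_relaxation * c)`` — a mild drop of the
      electrode access resistance with cell loading, which lets the
      region-6 peak deepen with concentration while the region-5 plateau
      falls, as observed in real suspensions.

    ``agglomeration_cv`` is the coefficient of variation of the lognormal
    factor on C; ``noise_magnitude_cv`` a lognormal multiplicative CV on
    |Z|; ``noise_phase_deg`` an additive Gaussian jitter on the phase.
    """

    cell_type: str
    medium: str
    base: CircuitParameters
    k_full: float
    cell_capacitance_full: float
    media_coupling: float = 0.2
    access_relaxation: float = 0.6
    agglomeration_cv: float = 0.3
    noise_magnitude_cv: float = 0.02
    noise_phase_deg: float = 0.3

    def __post_init__(self) -> None:
        if self.base.has_cell_branch:
            raise ValidationError("preset base parameters must be cell-free (medium only)")
        if self.k_full <= 0 or self.cell_capacitance_full <= 0:
            raise ValidationError("k_full and cell_capacitance_full must be positive")
        for name in ("agglomeration_cv", "noise_magnitude_cv", "noise_phase_deg"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    def k_at(self, concentration: float) -> float:
        """Cell/solution resistance ratio at a concentration (> 0)."""
        if concentration <= 0:
            raise ValidationError("k is undefined for the cell-free medium")
        medium_factor = (_R1_REFERENCE / self.base.R_1) ** self.media_coupling
        return self.k_full * medium_factor / concentration

    def params_at(self, concentration: float, agglomeration_factor: float = 1.0) -> CircuitParameters:
        """Circuit parameters at a concentration; 0 returns the bare medium."""
        if concentration < 0:
            raise ValidationError("concentration must be non-negative")
        r_s = self.base.R_s / (1.0 + self.access_relaxation * concentration)
        if concentration == 0:
            return replace(self.base, R_s=r_s)
        if agglomeration_factor <= 0:
            raise ValidationError("agglomeration_factor must be positive")
        k = self.k_at(concentration)
        return replace(
            self.base,
            R_s=r_s,
            R=k * self.base.R_1,
            C=self.cell_capacitance_full * concentration * agglomeration_factor,
        )


def preset(cell_type: str, medium: str) -> ScenarioPreset:
    """Default preset for one of the four emulated suspensions.

    The PB-like buffer has the larger solution resistance (lower
    conductivity); the two cell types differ in the concentration response
    of the cell resistance (``k_full``) and in the cell capacitance scale.
    """
    if cell_type not in CELL_TYPES:
        raise ValidationError(f"unknown cell type {cell_type!r}; valid: {CELL_TYPES}")
    if medium not in MEDIA:
        raise ValidationError(f"unknown medium {medium!r}; valid: {MEDIA}")
    r_1 = 80.0 if medium == "MS-like" else 400.0
    base = CircuitParameters(R_s=2.0, R_ct=5000.0, C_dl=2.0e-6, R_1=r_1, C_1=5.0e-12)
    if cell_type == "MSK8-like":
        k_full, c_full = 3.0, 2.0e-9
    else:
        k_full, c_full = 8.0, 1.2e-9
    return ScenarioPreset(
        cell_type=cell_type, medium=medium, base=base,
        k_full=k_full, cell_capacitance_full=c_full,
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray | float:
    """Unit-mean lognormal multiplicative factor(s) with the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_spectrum(
    scenario: ScenarioPreset,
    concentration: float,
    grid: FrequencyGrid | None = None,
    seed: int = 0,
) -> ImpedanceSpectrum:
    """One noisy spectrum of a suspension at a given concentration.

    Builds the circuit parameters from the concentration response, applies
    one seeded agglomeration draw to the cell capacitance, evaluates the
    exact circuit, then perturbs magnitude (lognormal multiplicative) and
    phase (additive Gaussian, degrees).  Deterministic for a fixed seed.
    """
    if concentration < 0:
        raise ValidationError("concentration must be non-negative")
    if grid is None:
        grid = FrequencyGrid.log_spaced()
    rng = np.random.default_rng(seed)
    agglom = float(_lognormal_factor(rng, scenario.agglomeration_cv))
    params = scenario.params_at(concentration, agglomeration_factor=agglom)
    clean = evaluate_impedance(params, grid)
    mag_factor = _lognormal_factor(rng, scenario.noise_magnitude_cv, size=len(grid))
    phase_jitter = (
        rng.normal(0.0, scenario.noise_phase_deg, size=len(grid))
        if scenario.noise_phase_deg > 0
        else np.zeros(len(grid))
    )
    mag = np.abs(clean.values) * mag_factor
    phase = np.angle(clean.values) + np.radians(phase_jitter)
    return ImpedanceSpectrum(grid, mag * np.exp(1j * phase))


def generate_series(
    scenario: ScenarioPreset,
    concentrations,
    grid: FrequencyGrid | None = None,
    seed: int = 0,
) -> SuspensionSeries:
    """A full concentration series with spectra and true parameters attached.

    Per-concentration seeds are spawned from the user seed with
    ``SeedSequence.spawn``, so individual spectra are reproducible and
    statistically independent.  The attached ``params`` are the noise-free
    truths (unit agglomeration factor) for recovery testing.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    if conc.size == 0 or np.any(np.diff(conc) <= 0):
        raise ValidationError("concentrations must be non-empty and strictly increasing")
    if np.any(conc <= 0):
        raise ValidationError("series concentrations must be positive (0 is the bare medium)")
    if grid is None:
        grid = FrequencyGrid.log_spaced()
    children = np.random.SeedSequence(seed).spawn(conc.size)
    spectra = tuple(
        generate_spectrum(scenario, c, grid, seed=child)
        for c, child in zip(conc, children)
    )
    truths = tuple(scenario.params_at(c) for c in conc)
    return SuspensionSeries(
        cell_type=scenario.cell_type,
        medium=scenario.medium,
        concentrations=tuple(conc.tolist()),
        params=truths,
        spectra=spectra,
    )
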