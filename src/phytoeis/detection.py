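"""Phase-peak detection metrics for differentiating cell suspensions.

From a fitted (or known) parameter set the module derives the observables
the detection methodology rests on: the resistance ratios k = R/R_1 and
p = R_s/R_1, the region-4 and region-6 phase-peak depths and frequencies
(phi4, f4, phi6, f6), the region-5 plateau magnitude |Z|_5, and the
deviation d — the ratio of a suspension's region-5 level to that of its
cell-free medium.  It also locates phase peaks numerically in sampled
spectra, compares suspension series pairwise through the mean deviation in
phi4, and traces d-versus-k sensitivity curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks as _find_peaks

from . import asymptotics
from .asymptotics import PhasePeak, RatioSet
from .circuit import CircuitParameters, ImpedanceSpectrum, ValidationError, _require_positive

__all__ = [
    "AlignmentError",
    "DetectionMetrics",
    "SuspensionSeries",
    "metrics_from_params",
    "find_phase_peaks",
    "delta_phi4",
    "mean_delta_phi4",
    "sensitivity_curve",
]


class AlignmentError(ValueError):
    """Two suspension series do not share the same concentration ladder."""


@dataclass(frozen=True)
class DetectionMetrics:
    """The per-suspension observables of the phase-peak methodology.

    ``d`` is present only when a medium reference was supplied; it is the
    ratio of the suspension's region-5 plateau to the cell-free medium's
    plateau (R_s + R_1 of the reference), so ``d < 1`` for any finite cell
    resistance and ``d -> 1`` as the suspension dilutes toward pure medium.
    """

    ratios: RatioSet
    phi4: float
    f4: float
    phi6: float
    f6: float
    z5: float
    d: float | None = None

    @property
    def k(self) -> float:
        return self.ratios.k

    @property
    def p(self) -> float:
        return self.ratios.p


def metrics_from_params(
    params: CircuitParameters,
    medium_reference: CircuitParameters | None = None,
    *,
    medium_z5: float | None = None,
) -> DetectionMetrics:
    """Closed-form detection metrics of a suspension circuit.

    Parameters
    ----------
    params : CircuitParameters
        Suspension circuit; the cell branch must be present.
    medium_reference : CircuitParameters, optional
        Cell-free medium circuit; its region-5 level (R_s + R_1, any cell
        branch is ignored) is the denominator of the deviation ``d``.
    medium_z5 : float, optional
        Measured region-5 magnitude of the medium, ohm.  Overrides
        ``medium_reference`` when both are given.
    """
    if not params.has_cell_branch:
        raise ValidationError("detection metrics require the cell R-C branch")
    k = params.R / params.R_1
    p = params.R_s / params.R_1
    two_pi = 2.0 * math.pi
    d = None
    if medium_z5 is not None:
        _require_positive("medium_z5", medium_z5)
    elif medium_reference is not None:
        medium_z5 = medium_reference.R_s + medium_reference.R_1
    if medium_z5 is not None:
        d = asymptotics.z5_magnitude(params.R_1, k, p) / medium_z5
    return DetectionMetrics(
        ratios=RatioSet(k=k, p=p),
        phi4=asymptotics.phi4(k),
        f4=asymptotics.omega4(params.C, params.R_1, k) / two_pi,
        phi6=asymptotics.phi6(k, p),
        f6=asymptotics.omega6(params.C_1, params.R_1, k, p) / two_pi,
        z5=asymptotics.z5_magnitude(params.R_1, k, p),
        d=d,
    )


def _parabolic_refine(logf: np.ndarray, phase: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through three samples around grid minimum i."""
    if i == 0 or i == len(phase) - 1:
        return 10.0 ** logf[i], phase[i]
    x0, x1, x2 = logf[i - 1], logf[i], logf[i + 1]
    y0, y1, y2 = phase[i - 1], phase[i], phase[i + 1]
    # Newton-form parabola; uniform-in-log grids are the common case but
    # are not assumed
    h1, h2 = x1 - x0, x2 - x1
    s1, s2 = (y1 - y0) / h1, (y2 - y1) / h2
    a = (s2 - s1) / (h1 + h2)
    if a <= 0:  # not convex around the sample; keep the raw minimum
        return 10.0 ** x1, y1
    x_min = 0.5 * (x1 + x2) - s2 / (2.0 * a)
    x_min = min(max(x_min, x0), x2)
    y_min = y1 + s2 * (x_min - x1) + a * (x_min - x1) * (x_min - x2)
    return 10.0 ** x_min, max(min(y_min, 0.0), -90.0)


def find_phase_peaks(
    spectrum: ImpedanceSpectrum,
    search_band: tuple[float, float] | None = None,
    min_depth_deg: float = 1.0,
    refine: bool = True,
) -> list[PhasePeak]:
    """Locate negative phase peaks (local phase minima) in a sampled spectrum.

    Peaks are local minima of the phase over log frequency with prominence of
    at least ``min_depth_deg`` degrees (shallower wiggles are treated as
    noise).  Each peak is refined by a 3-point parabolic interpolation in
    log frequency unless ``refine`` is False; the raw grid minimum is always
    reported alongside.  An empty search band yields an empty list.

    A grid density of at least ~10 points per decade is recommended for the
    refinement to be meaningful.
    """
    if search_band is not None:
        f_lo, f_hi = search_band
        mask = (spectrum.frequencies >= f_lo) & (spectrum.frequencies <= f_hi)
        if not np.any(mask):
            return []
        freqs = spectrum.frequencies[mask]
        phase = spectrum.phase_deg[mask]
    else:
        freqs = spectrum.frequencies
        phase = spectrum.phase_deg
    if len(freqs) < 3:
        return []
    idx, _ = _find_peaks(-phase, prominence=min_depth_deg)
    logf = np.log10(freqs)
    peaks: list[PhasePeak] = []
    for i in idx:
        if refine:
            f_peak, phi_min = _parabolic_refine(logf, phase, int(i))
        else:
            f_peak, phi_min = float(freqs[i]), float(phase[i])
        peaks.append(
            PhasePeak(
                f_peak=float(f_peak),
                phi_min=float(np.clip(phi_min, -90.0, 0.0)),
                f_raw=float(freqs[i]),
                phi_raw=float(phase[i]),
                index=int(i),
            )
        )
    peaks.sort(key=lambda pk: pk.f_peak)
    return peaks


@dataclass(frozen=True)
class SuspensionSeries:
    """A concentration series of one suspension (cell type in a medium)."""

    cell_type: str
    medium: str
    concentrations: tuple[float, ...]
    params: tuple[CircuitParameters, ...]
    spectra: tuple[ImpedanceSpectrum, ...] | None = None
    metrics: tuple[DetectionMetrics, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size == 0 or np.any(np.diff(conc) <= 0):
            raise ValidationError("concentrations must be non-empty and strictly increasing")
        if len(self.params) != conc.size:
            raise ValidationError("one parameter set required per concentration")
        if self.spectra is not None and len(self.spectra) != conc.size:
            raise ValidationError("one spectrum required per concentration")
        if self.metrics is not None and len(self.metrics) != conc.size:
            raise ValidationError("one metrics record required per concentration")

    def with_metrics(self, medium_reference: CircuitParameters | None = None) -> "SuspensionSeries":
        """Attach closed-form metrics computed from the stored parameters."""
        metrics = tuple(metrics_from_params(p, medium_reference) for p in self.params)
        return SuspensionSeries(
            cell_type=self.cell_type, medium=self.medium,
            concentrations=self.concentrations, params=self.params,
            spectra=self.spectra, metrics=metrics,
        )

    def phi4_values(self) -> np.ndarray:
        if self.metrics is not None:
            return np.array([m.phi4 for m in self.metrics])
        return np.array([asymptotics.phi4(p.R / p.R_1) for p in self.params])


def delta_phi4(series_a: SuspensionSeries, series_b: SuspensionSeries) -> np.ndarray:
    """Per-concentration absolute difference in phi4 between two suspensions.

    Both series must share the same concentration ladder.
    """
    ca = np.asarray(series_a.concentrations, float)
    cb = np.asarray(series_b.concentrations, float)
    if ca.shape != cb.shape or not np.allclose(ca, cb, rtol=1e-9):
        raise AlignmentError("series do not share the same concentration ladder")
    return np.abs(series_a.phi4_values() - series_b.phi4_values())


def mean_delta_phi4(pairs: Sequence[tuple[SuspensionSeries, SuspensionSeries]]) -> np.ndarray:
    """Unweighted mean of ``delta_phi4`` over several suspension pairs.

    This is the aggregation used when comparing all same-cell-type pairs
    against all same-medium pairs across a concentration ladder.
    """
    if not pairs:
        raise ValidationError("at least one pair of series is required")
    return np.mean([delta_phi4(a, b) for a, b in pairs], axis=0)


def sensitivity_curve(
    p: float,
    k_grid: Sequence[float],
    medium_z5: float,
    R_1: float,
) -> list[tuple[float, float]]:
    """Deviation d as a function of k for a fixed medium reference.

    d(k) = R_1 (p + k/(k+1)) / medium_z5.  With the cell-free reference
    medium_z5 = R_1 (p + 1), d stays below 1 for all finite k and rises
    toward 1 as k grows (dilute suspensions converge to their medium);
    lower-conductivity media (larger R_1, smaller p) push d further from 1.
    """
    _require_positive("p", p)
    _require_positive("medium_z5", medium_z5)
    _require_positive("R_1", R_1)
    ks = np.asarray(list(k_grid), dtype=float)
    if ks.size == 0:
        raise ValidationError("k_grid must be non-empty")
    if np.any(ks <= 0) or not np.all(np.isfinite(ks)):
        raise ValidationError("all k values must be strictly positive and finite")
    d = R_1 * (p + ks / (ks + 1.0)) / medium_z5
    return list(zip(ks.tolist(), d.tolist()))
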