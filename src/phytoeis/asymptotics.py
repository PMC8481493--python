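"""Closed-form asymptotic analysis of the unified suspension circuit.

With an ideal double layer (``alpha_dl = 1``) the impedance spectrum splits
into three first-order dispersions, one per capacitor, giving three
pole/zero pairs and hence seven regions on a log-log Bode plot: four flat
plateaus (regions 1, 3, 5, 7) joined by three -20 dB/decade slopes
(regions 2, 4, 6).

Each dispersion is a bilinear function (1 + jw/w_zero)/(1 + jw/w_pole) with
w_pole < w_zero.  On a log-frequency axis its phase is bell-shaped, reaching
its most negative value at the geometric mean of pole and zero; the depth of
that negative peak depends only on the pole/zero ratio.  The region-4 and
region-6 peak depths therefore depend only on the resistance ratios
k = R/R_1 and p = R_s/R_1 — not on the capacitances — which is the basis of
the phase-peak detection metrics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .circuit import CircuitParameters, ValidationError, _require_positive

__all__ = [
    "PoleZeroLadder",
    "RatioSet",
    "PhasePeak",
    "BodeSegment",
    "corner_frequencies",
    "min_phase",
    "peak_frequency",
    "phi4",
    "phi6",
    "omega4",
    "omega6",
    "z5_magnitude",
    "region4_pole_zero",
    "region6_pole_zero",
    "asymptotic_bode",
    "skeleton_magnitude_db",
]

#: adjacent dispersions closer than this many decades degrade the closed forms
WELL_SEPARATED_DECADES = 2.5


@dataclass(frozen=True)
class RatioSet:
    """Dimensionless resistance ratios k = R/R_1 and p = R_s/R_1."""

    k: float
    p: float

    def __post_init__(self) -> None:
        _require_positive("k", self.k)
        _require_positive("p", self.p)


@dataclass(frozen=True)
class PhasePeak:
    """A negative phase peak: its frequency (Hz) and depth (degrees, <= 0).

    ``region`` identifies the Bode region (4 or 6) when known; detected
    peaks from raw spectra may leave it ``None``.  ``f_raw``/``phi_raw``
    carry the unrefined grid minimum when the peak came from a sampled
    spectrum.
    """

    f_peak: float
    phi_min: float
    region: int | None = None
    f_raw: float | None = None
    phi_raw: float | None = None
    index: int | None = None

    def __post_init__(self) -> None:
        if not (-90.0 <= self.phi_min <= 0.0):
            raise ValidationError(f"phi_min must lie in [-90, 0] degrees, got {self.phi_min!r}")


@dataclass(frozen=True)
class PoleZeroLadder:
    """The six corner angular frequencies and four plateau magnitudes.

    Corners are rad/s; ``omega_ij`` separates regions i and j.  For a
    cell-free circuit the region-4/5 entries are ``None`` and regions 3-5
    merge into a single plateau.  ``well_separated`` is False when the
    dispersions sit closer than ``WELL_SEPARATED_DECADES`` decades apart, in
    which case the closed-form peak expressions degrade.
    """

    omega_12: float
    omega_23: float
    omega_34: float | None
    omega_45: float | None
    omega_56: float
    omega_67: float
    plateau_1: float
    plateau_3: float
    plateau_5: float | None
    plateau_7: float
    well_separated: bool = True

    def corners(self) -> list[float]:
        """The defined corner angular frequencies in ascending region order."""
        all_corners = [self.omega_12, self.omega_23, self.omega_34,
                       self.omega_45, self.omega_56, self.omega_67]
        return [w for w in all_corners if w is not None]

    @property
    def min_separation_decades(self) -> float:
        """Smallest log10 gap between adjacent dispersions."""
        gaps = [self.omega_56 / self.omega_23] if self.omega_34 is None else [
            self.omega_34 / self.omega_23, self.omega_56 / self.omega_45]
        return math.log10(min(gaps))


def corner_frequencies(params: CircuitParameters, warn: bool = True) -> PoleZeroLadder:
    """Pole/zero ladder of the circuit from the capacitor matching conditions.

    Each capacitor switches on where its impedance matches the resistance it
    shunts and off where it becomes negligible against the resistance left in
    series: C_dl works against R_s + R_ct + R_1 then R_s + R_1; the cell
    capacitance C against R + R_1 then R; C_1 against R_s + R_1||R then R_s.
    Plateau magnitudes are the corresponding resistive levels.

    Only valid for an ideal double layer (``alpha_dl = 1``).
    """
    if params.alpha_dl != 1.0:
        raise ValidationError("corner formulas require alpha_dl = 1 (ideal double layer)")
    r_s, r_ct, r_1 = params.R_s, params.R_ct, params.R_1
    plateau_1 = r_s + r_ct + r_1
    plateau_3 = r_s + r_1
    omega_12 = 1.0 / (params.C_dl * plateau_1)
    omega_23 = 1.0 / (params.C_dl * plateau_3)
    if params.has_cell_branch:
        r, c = params.R, params.C
        omega_34 = 1.0 / (c * (r + r_1))
        omega_45 = 1.0 / (c * r)
        r_par = r_1 * r / (r_1 + r)
        plateau_5 = r_s + r_par
    else:
        omega_34 = omega_45 = None
        plateau_5 = None
        r_par = r_1
    omega_56 = 1.0 / (params.C_1 * (r_s + r_par))
    omega_67 = 1.0 / (params.C_1 * r_s)
    ladder = PoleZeroLadder(
        omega_12=omega_12, omega_23=omega_23, omega_34=omega_34, omega_45=omega_45,
        omega_56=omega_56, omega_67=omega_67,
        plateau_1=plateau_1, plateau_3=plateau_3, plateau_5=plateau_5, plateau_7=r_s,
    )
    separated = ladder.min_separation_decades >= WELL_SEPARATED_DECADES
    if not separated and warn:
        warnings.warn(
            "dispersions are separated by less than "
            f"{WELL_SEPARATED_DECADES} decades; closed-form peak expressions degrade",
            stacklevel=2,
        )
    return PoleZeroLadder(**{**ladder.__dict__, "well_separated": separated})


def _bilinear_min_phase_deg(omega_pole: float, omega_zero: float) -> float:
    """Peak phase of (1+jw/w_zero)/(1+jw/w_pole) in degrees; any argument order."""
    ratio = math.sqrt(omega_pole / omega_zero)
    return math.degrees(math.atan(ratio) - math.atan(1.0 / ratio))


def min_phase(omega_pole: float, omega_zero: float) -> float:
    """Most negative phase of a bilinear dispersion, degrees.

    Equals arctan(sqrt(w_pole/w_zero)) - arctan(sqrt(w_zero/w_pole)); the
    pole must not exceed the zero, so the result is in [-90, 0].
    """
    _require_positive("omega_pole", omega_pole)
    _require_positive("omega_zero", omega_zero)
    if omega_pole > omega_zero:
        raise ValidationError("omega_pole must not exceed omega_zero")
    return _bilinear_min_phase_deg(omega_pole, omega_zero)


def peak_frequency(omega_pole: float, omega_zero: float) -> float:
    """Frequency of the bilinear phase peak: the geometric mean of pole and zero."""
    _require_positive("omega_pole", omega_pole)
    _require_positive("omega_zero", omega_zero)
    return math.sqrt(omega_pole * omega_zero)


def phi4(k: float) -> float:
    """Depth of the region-4 phase peak, degrees; depends only on k = R/R_1.

    arctan(sqrt(k/(k+1))) - arctan(sqrt((k+1)/k)).  Approaches -90 deg as
    k -> 0 and 0 deg as k -> infinity; for k >= 1 it is bounded below by
    about -20 deg.
    """
    _require_positive("k", k)
    ratio = math.sqrt(k / (k + 1.0))
    return math.degrees(math.atan(ratio) - math.atan(1.0 / ratio))


def phi6(k: float, p: float) -> float:
    """Depth of the region-6 phase peak, degrees, from k = R/R_1, p = R_s/R_1.

    arctan(sqrt(p/(p+k/(k+1)))) - arctan(sqrt((p+k/(k+1))/p)).  Since the
    access resistance is normally orders of magnitude below the solution
    resistance (p << 1), this peak sits close to -90 deg (about -74 deg at
    k = 1, p = 0.01).
    """
    _require_positive("k", k)
    _require_positive("p", p)
    ratio = math.sqrt(p / (p + k / (k + 1.0)))
    return math.degrees(math.atan(ratio) - math.atan(1.0 / ratio))


def omega4(C: float, R_1: float, k: float) -> float:
    """Region-4 peak angular frequency: (1/(C R_1)) sqrt(1/(k(k+1))), rad/s.

    Identical to the geometric mean of the ladder corners 1/(C(R+R_1)) and
    1/(C R) with R = k R_1.  Like the published arctan depth forms, this is
    the p = R_s/R_1 -> 0 limit of the exact dispersion (see
    :func:`region4_pole_zero`).
    """
    _require_positive("C", C)
    _require_positive("R_1", R_1)
    _require_positive("k", k)
    return math.sqrt(1.0 / (k * (k + 1.0))) / (C * R_1)


def omega6(C_1: float, R_1: float, k: float, p: float) -> float:
    """Region-6 peak angular frequency: (1/(C_1 R_1)) sqrt(1/(p(p+k/(k+1)))), rad/s.

    Identical to the geometric mean of the ladder corners
    1/(C_1 (R_s + R_1||R)) and 1/(C_1 R_s); underestimates the exact peak
    frequency by the factor 1 + p/kappa (see :func:`region6_pole_zero`),
    which is negligible in the p << 1 regime the method assumes.
    """
    _require_positive("C_1", C_1)
    _require_positive("R_1", R_1)
    _require_positive("k", k)
    _require_positive("p", p)
    return math.sqrt(1.0 / (p * (p + k / (k + 1.0)))) / (C_1 * R_1)


def z5_magnitude(R_1: float, k: float, p: float) -> float:
    """Region-5 plateau magnitude |Z|_5 = R_1 (p + k/(k+1)), ohm."""
    _require_positive("R_1", R_1)
    _require_positive("k", k)
    _require_positive("p", p)
    return R_1 * (p + k / (k + 1.0))


def region4_pole_zero(params: CircuitParameters) -> tuple[float, float]:
    """Exact pole/zero pair (rad/s) of the region-4 dispersion.

    In the band where C_dl is a short and C_1 an open, the circuit reduces
    to R_s in series with R_1 || (R + 1/(jwC)), an exact bilinear function
    with pole 1/(C(R+R_1)) and zero (R_s+R_1)/(C(R_s(R+R_1)+R_1 R)).  The
    published peak expressions are the R_s -> 0 limit of this pair; for
    appreciable p = R_s/R_1 use this pair with :func:`min_phase` and
    :func:`peak_frequency` instead.
    """
    if not params.has_cell_branch:
        raise ValidationError("region-4 dispersion requires the cell branch")
    r_s, r_1, r, c = params.R_s, params.R_1, params.R, params.C
    pole = 1.0 / (c * (r + r_1))
    zero = (r_s + r_1) / (c * (r_s * (r + r_1) + r_1 * r))
    return pole, zero


def region6_pole_zero(params: CircuitParameters) -> tuple[float, float]:
    """Exact pole/zero pair (rad/s) of the region-6 dispersion.

    Above the cell dispersion the circuit is R_s in series with
    R_p || C_1 where R_p = R_1 || R (or R_1 alone for a cell-free medium):
    pole 1/(C_1 R_p), zero (R_s+R_p)/(C_1 R_p R_s).  The geometric mean of
    this pair exceeds the published region-6 peak frequency by the factor
    1 + p/kappa (kappa = k/(k+1)); the peak depth ratio pole/zero is
    identical to the published arctan form.
    """
    r_s, r_1 = params.R_s, params.R_1
    r_p = r_1 * params.R / (r_1 + params.R) if params.has_cell_branch else r_1
    pole = 1.0 / (params.C_1 * r_p)
    zero = (r_s + r_p) / (params.C_1 * r_p * r_s)
    return pole, zero


@dataclass(frozen=True)
class BodeSegment:
    """One straight segment of the asymptotic log-magnitude skeleton."""

    region: int
    slope_db_per_decade: float
    f_start_hz: float
    f_stop_hz: float
    mag_db_start: float
    mag_db_stop: float


def _db(x: float) -> float:
    return 20.0 * math.log10(x)


def asymptotic_bode(
    params: CircuitParameters,
    f_min: float | None = None,
    f_max: float | None = None,
) -> list[BodeSegment]:
    """Piecewise-linear asymptote skeleton of 20*log10|Z| over log frequency.

    Plateau regions (1, 3, 5, 7) are horizontal at the resistive plateau
    levels; transition regions (2, 4, 6) fall at exactly -20 dB/decade from
    the preceding plateau, with breakpoints at the ladder corners.  For a
    cell-free circuit the merged 3-5 plateau is reported as a single
    region-3 segment and regions 4-5 are omitted.

    ``f_min``/``f_max`` bound the outer plateaus and default to one decade
    beyond the outermost corners.
    """
    ladder = corner_frequencies(params, warn=False)
    two_pi = 2.0 * math.pi
    f12, f23 = ladder.omega_12 / two_pi, ladder.omega_23 / two_pi
    f56, f67 = ladder.omega_56 / two_pi, ladder.omega_67 / two_pi
    if f_min is None:
        f_min = f12 / 10.0
    if f_max is None:
        f_max = f67 * 10.0
    if f_min >= f12 or f_max <= f67:
        raise ValidationError("f_min/f_max must bracket the outermost corners")
    l1, l3, l7 = _db(ladder.plateau_1), _db(ladder.plateau_3), _db(ladder.plateau_7)
    segments = [
        BodeSegment(1, 0.0, f_min, f12, l1, l1),
        BodeSegment(2, -20.0, f12, f23, l1, l1 - 20.0 * math.log10(f23 / f12)),
    ]
    if params.has_cell_branch:
        f34, f45 = ladder.omega_34 / two_pi, ladder.omega_45 / two_pi
        l5 = _db(ladder.plateau_5)
        segments += [
            BodeSegment(3, 0.0, f23, f34, l3, l3),
            BodeSegment(4, -20.0, f34, f45, l3, l3 - 20.0 * math.log10(f45 / f34)),
            BodeSegment(5, 0.0, f45, f56, l5, l5),
            BodeSegment(6, -20.0, f56, f67, l5, l5 - 20.0 * math.log10(f67 / f56)),
        ]
    else:
        segments += [
            BodeSegment(3, 0.0, f23, f56, l3, l3),
            BodeSegment(6, -20.0, f56, f67, l3, l3 - 20.0 * math.log10(f67 / f56)),
        ]
    segments.append(BodeSegment(7, 0.0, f67, f_max, l7, l7))
    return segments


def skeleton_magnitude_db(segments: list[BodeSegment], frequencies: np.ndarray) -> np.ndarray:
    """Evaluate the asymptote skeleton at arbitrary frequencies (Hz)."""
    f = np.asarray(frequencies, dtype=float)
    out = np.full(f.shape, np.nan)
    for seg in segments:
        mask = (f >= seg.f_start_hz) & (f <= seg.f_stop_hz)
        out[mask] = seg.mag_db_start + seg.slope_db_per_decade * np.log10(
            f[mask] / seg.f_start_hz
        )
    return out
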