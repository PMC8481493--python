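"""Complex nonlinear least-squares fitting of spectra to the unified circuit.

Spectra are fitted by minimizing the weighted sum of squared real and
imaginary residuals.  Parameters are optimized in log space, which enforces
positivity and copes with the 6+ orders of magnitude separating the
double-layer capacitance from the water-polarization capacitance.  The
default weighting is proportional (1/|Z|), so the low-ohm high-frequency
plateaus contribute on an equal footing with the kilo-ohm charge-transfer
plateau.  A seeded multi-start (jittered restarts around the initial guess)
guards against local minima; the lowest weighted chi-square wins.

Initialization inverts the asymptote skeleton: plateau magnitudes give the
resistances, detected phase-peak frequencies give the capacitances through
the pole/zero ladder formulas.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .circuit import (
    CircuitParameters,
    ImpedanceSpectrum,
    ValidationError,
    evaluate_impedance,
)
from .detection import find_phase_peaks

__all__ = ["FitOptions", "FitResult", "InitializationError", "initial_guess", "fit_spectrum"]

_PARAM_NAMES = ("R_s", "R_ct", "C_dl", "R", "R_1", "C", "C_1")
_MEDIUM_PARAM_NAMES = ("R_s", "R_ct", "C_dl", "R_1", "C_1")


class InitializationError(RuntimeError):
    """The spectrum lacks the features needed to build an initial guess."""


@dataclass(frozen=True)
class FitOptions:
    """Settings for :func:`fit_spectrum`.

    weighting : 'unit', 'proportional' (1/|Z|, default) or 'modulus_squared'
        (1/|Z|^2) residual weights.
    n_starts : number of seeded multi-start restarts (first start is the
        unjittered initial guess).
    jitter_sigma : log-space standard deviation of the restart jitter.
    free_alpha : also fit the CPE exponent (bounded in (0, 1]).
    bounds : optional per-parameter (low, high) positive intervals.
    """

    weighting: str = "proportional"
    max_iterations: int = 200
    tolerance: float = 1e-12
    free_alpha: bool = False
    n_starts: int = 5
    jitter_sigma: float = 0.3
    seed: int = 0
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weighting not in ("unit", "proportional", "modulus_squared"):
            raise ValidationError(f"unknown weighting {self.weighting!r}")
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be positive")
        if self.max_iterations < 1 or self.n_starts < 1:
            raise ValidationError("max_iterations and n_starts must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if lo <= 0 or hi <= lo:
                raise ValidationError(f"bounds for {name} must satisfy 0 < low < high")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a spectrum fit."""

    estimate: CircuitParameters
    residual_norm: float
    converged: bool
    n_iterations: int
    start_point: CircuitParameters
    stderr: dict[str, float] | None = None


def _plateau_levels(spectrum: ImpedanceSpectrum, peak_indices: list[int]) -> list[float]:
    """|Z| at the flattest point (phase closest to 0) between phase peaks."""
    phase = spectrum.phase_deg
    mag = spectrum.magnitude
    bounds = [0, *peak_indices, len(phase) - 1]
    levels = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        seg = slice(lo, hi + 1)
        j = lo + int(np.argmax(phase[seg]))
        levels.append(float(mag[j]))
    return levels


def initial_guess(spectrum: ImpedanceSpectrum, min_depth_deg: float = 1.0) -> CircuitParameters:
    """Asymptote-driven starting point for :func:`fit_spectrum`.

    Detects the negative phase peaks, reads the plateau magnitudes between
    them, and inverts the skeleton: the four plateaus give
    R_s + R_ct + R_1, R_s + R_1, R_s + R_1||R and R_s; the peak frequencies
    give the capacitances through the geometric-mean ladder formulas.

    When the low-frequency (Randles) dispersion is outside the measured
    band, ``R_ct`` falls back to the lowest plateau level and ``C_dl`` to
    the value placing its corner at the bottom band edge; a warning flags
    the fallback.  A spectrum with no detectable dispersions (e.g. a pure
    resistor) raises :class:`InitializationError`.
    """
    peaks = find_phase_peaks(spectrum, min_depth_deg=min_depth_deg)
    if len(peaks) < 2:
        raise InitializationError(
            f"need at least 2 negative phase peaks to initialize, found {len(peaks)}"
        )
    peak_indices = [pk.index for pk in peaks]
    levels = _plateau_levels(spectrum, peak_indices)
    omega_peaks = [2.0 * math.pi * pk.f_peak for pk in peaks]
    randles_fallback = len(peaks) == 2
    if randles_fallback:
        # truncated band: assume the two peaks are regions 4 and 6
        l3, l5, l7 = levels
        l1 = None
    else:
        # the three lowest-frequency deep peaks are regions 2, 4, 6
        if len(peaks) > 3:
            order = np.argsort([pk.phi_min for pk in peaks])[:3]
            keep = sorted(int(i) for i in order)
            peaks = [peaks[i] for i in keep]
            peak_indices = [pk.index for pk in peaks]
            levels = _plateau_levels(spectrum, peak_indices)
            omega_peaks = [2.0 * math.pi * pk.f_peak for pk in peaks]
        l1, l3, l5, l7 = levels

    r_s = max(l7, 1e-12)
    r_1 = max(l3 - r_s, 1e-6 * r_s)
    r_par = max(l5 - r_s, 1e-6 * r_s)
    if r_par < r_1:
        r = r_par * r_1 / (r_1 - r_par)
    else:
        warnings.warn("region-5 plateau not below region-3 plateau; falling back to R = R_1")
        r = r_1

    if randles_fallback:
        r_ct = l3
        omega_lo = 2.0 * math.pi * spectrum.frequencies[0]
        c_dl = 1.0 / (omega_lo * (r_ct + l3))
        warnings.warn(
            "Randles dispersion not detected in band; R_ct and C_dl set to fallback values"
        )
        omega_p4, omega_p6 = omega_peaks
    else:
        r_ct = max(l1 - l3, 1e-6 * l3)
        omega_p2, omega_p4, omega_p6 = omega_peaks
        c_dl = 1.0 / (omega_p2 * math.sqrt(l1 * l3))
    c = 1.0 / (omega_p4 * math.sqrt(r * (r + r_1)))
    c_1 = 1.0 / (omega_p6 * math.sqrt(r_s * (r_s + r_par)))
    return CircuitParameters(R_s=r_s, R_ct=r_ct, C_dl=c_dl, R_1=r_1, C_1=c_1, R=r, C=c)


def _weights(spectrum: ImpedanceSpectrum, weighting: str) -> np.ndarray:
    mag = spectrum.magnitude
    if weighting == "unit":
        return np.ones_like(mag)
    if weighting == "proportional":
        return 1.0 / mag
    return 1.0 / mag**2


def _pack(params: CircuitParameters, names: tuple[str, ...]) -> np.ndarray:
    return np.log([getattr(params, n) for n in names])


def _unpack(theta: np.ndarray, names: tuple[str, ...], alpha: float) -> CircuitParameters:
    values = dict(zip(names, np.exp(theta)))
    return CircuitParameters(alpha_dl=alpha, **values)


def fit_spectrum(
    spectrum: ImpedanceSpectrum,
    init: CircuitParameters | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit a spectrum to the unified circuit by weighted complex least squares.

    The weighted real and imaginary residuals are minimized over the free
    parameters in log space with seeded multi-start restarts.  Requires at
    least 8 spectrum points per free parameter.  Non-convergence is reported
    through ``converged=False`` rather than an exception; unidentifiable
    parameters show up as exploding standard errors.
    """
    opts = options or FitOptions()
    if init is None:
        init = initial_guess(spectrum)
    names = _PARAM_NAMES if init.has_cell_branch else _MEDIUM_PARAM_NAMES
    n_free = len(names) + (1 if opts.free_alpha else 0)
    if len(spectrum) < 8 * n_free:
        raise ValidationError(
            f"need at least {8 * n_free} points to fit {n_free} parameters, got {len(spectrum)}"
        )
    w = _weights(spectrum, opts.weighting)
    z_data = spectrum.values
    grid = spectrum.grid

    def residuals(theta: np.ndarray) -> np.ndarray:
        alpha = theta[-1] if opts.free_alpha else init.alpha_dl
        params = _unpack(theta[: len(names)], names, alpha)
        z_model = evaluate_impedance(params, grid).values
        diff = z_model - z_data
        return np.concatenate([w * diff.real, w * diff.imag])

    lo = np.full(n_free, math.log(1e-18))
    hi = np.full(n_free, math.log(1e18))
    for i, name in enumerate(names):
        if name in opts.bounds:
            lo[i], hi[i] = (math.log(b) for b in opts.bounds[name])
    if opts.free_alpha:
        lo[-1], hi[-1] = 0.05, 1.0

    theta0 = _pack(init, names)
    if opts.free_alpha:
        theta0 = np.append(theta0, init.alpha_dl)
    theta0 = np.clip(theta0, lo, hi)

    rng = np.random.default_rng(opts.seed)
    best = None
    for start in range(opts.n_starts):
        theta_start = theta0.copy()
        if start > 0:
            jitter = rng.normal(0.0, opts.jitter_sigma, size=len(names))
            theta_start[: len(names)] += jitter
            theta_start = np.clip(theta_start, lo, hi)
        try:
            res = least_squares(
                residuals,
                theta_start,
                bounds=(lo, hi),
                method="trf",
                x_scale="jac",
                ftol=opts.tolerance,
                xtol=opts.tolerance,
                gtol=opts.tolerance,
                max_nfev=opts.max_iterations * n_free,
            )
        except (ValueError, FloatingPointError):
            continue
        if best is None or res.cost < best.cost:  # ties keep the earlier start
            best = res
    if best is None:
        raise RuntimeError("all fit starts failed to evaluate")

    alpha = float(best.x[-1]) if opts.free_alpha else init.alpha_dl
    estimate = _unpack(best.x[: len(names)], names, alpha)
    chi2 = float(2.0 * best.cost)

    stderr = None
    dof = 2 * len(spectrum) - n_free
    if dof > 0:
        jac = best.jac
        try:
            cov_log = np.linalg.pinv(jac.T @ jac) * (chi2 / dof)
            se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
            stderr = {
                name: float(getattr(estimate, name) * se_log[i]) for i, name in enumerate(names)
            }
            if opts.free_alpha:
                stderr["alpha_dl"] = float(se_log[-1])
        except np.linalg.LinAlgError:
            stderr = None

    return FitResult(
        estimate=estimate,
        residual_norm=chi2,
        converged=bool(best.status > 0),
        n_iterations=int(best.nfev),
        start_point=init,
        stderr=stderr,
    )
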