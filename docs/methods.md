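# Methods

## Circuit model and assumptions

The impedance of a plant-cell suspension between two electrodes is modelled
as a Randles electrode block in series with an extended Debye block:

    Z(ω) = R_s + (R_ct ‖ Z_dl) + [ R_1 ‖ (R + 1/(jωC)) ‖ C_1 ]

with `Z_dl = 1/(C_dl (jω)^α)`. All closed-form analysis assumes an ideal
double layer (`α = 1`); the CPE exponent may be freed during fitting only.
The Warburg diffusion element of the standard Randles model is excluded:
its influence is confined to frequencies below the bottom of the supported
band (a few Hz), so within 4 Hz – 20 GHz the seven-region picture is
complete. Inductive artifacts, electrode-geometry (cell-constant)
conversion to conductivity, and temperature dependence are out of scope.

A cell-free medium is represented by an explicit absent cell branch
(`R = C = None`), never by sentinel values, so validation can stay strict
(every present component must be positive and finite).

Unit conventions: Hz at every public interface, rad/s internally; phase in
degrees with capacitive = negative; ohms and farads throughout.

## Pole/zero ladder and the peak closed forms

Each capacitor produces one dispersion. The ladder corners follow from
matching conditions: a capacitor "switches on" where its impedance matches
the resistance it shunts and "off" where it is negligible against the
resistance remaining in series:

| corner | expression | plateau below/above |
|---|---|---|
| ω₁₂ | 1/(C_dl (R_s+R_ct+R_1)) | R_s+R_ct+R_1 |
| ω₂₃ | 1/(C_dl (R_s+R_1)) | R_s+R_1 |
| ω₃₄ | 1/(C (R+R_1)) | — |
| ω₄₅ | 1/(C R) | R_s+R_1‖R |
| ω₅₆ | 1/(C_1 (R_s+R_1‖R)) | — |
| ω₆₇ | 1/(C_1 R_s) | R_s |

These corner definitions make the −20 dB/dec segments of the Bode skeleton
land exactly on the next plateau in regions 2 and 6 (the corner ratio
equals the plateau ratio there); in region 4 the mismatch is O(p) and the
skeleton is drawn with the canonical −20 dB/dec slope anyway. A numeric
3 dB-crossing test pins each corner to within 5% of the exact spectrum's
crossing when dispersions are far apart.

The published peak expressions (ω₄, ω₆, φ₄, φ₆ as functions of k = R/R_1,
p = R_s/R_1) are the geometric means and arctan depths of these ladder
pairs. They are exact only in the limit p → 0. The exact bilinear
dispersions, obtained by reducing the circuit within each band, are

* region 4: pole 1/(C(R+R_1)), zero (R_s+R_1)/(C(R_s(R+R_1)+R_1R));
* region 6: pole 1/(C_1 R_p), zero (R_s+R_p)/(C_1 R_p R_s), R_p = R_1‖R.

The exact region-6 geometric mean exceeds the published ω₆ by the factor
1 + p/κ (κ = k/(k+1)) — about 21% at p = 0.15 but under 6% for the p ≤ 0.02
regime the methodology assumes (access resistance orders of magnitude
below the solution resistance). Both forms are exposed:
`omega4`/`omega6`/`phi4`/`phi6` are the published API, and
`region4_pole_zero`/`region6_pole_zero` provide the exact pairs used as
the tight oracle in the tests.

**Well-separatedness.** The closed forms assume the three dispersions do
not overlap. The within-dispersion corner ratios are fixed by the
resistance ratios (e.g. ω₄₅/ω₃₄ = (k+1)/k) and are necessarily small for
k ≥ 1, so the separation flag is computed on the *inter-dispersion* gaps
ω₃₄/ω₂₃ and ω₅₆/ω₄₅: a ladder is flagged (with a warning) when either gap
falls below 10^2.5. Below that, peak depths and locations progressively
blend and the analytic/numeric agreement guarantees no longer hold.

## Numeric peak detection

`find_phase_peaks` finds local minima of phase over log frequency with a
prominence threshold (default 1°) that suppresses noise wiggles, then
refines each peak by a three-point parabola in log f (non-uniform grids
supported; non-convex neighborhoods fall back to the raw grid minimum,
and raw grid values are always reported alongside). A pure resistor yields
no peaks; an empty search band yields an empty list, not an error. At
least ~10 grid points per decade are recommended for the refinement to add
accuracy.

## Fitting

Weighted complex least squares: the residual vector stacks
`w·Re(Z_model−Z_data)` and `w·Im(Z_model−Z_data)`. Weight choices are
`unit`, `proportional` (1/|Z|, default) and `modulus_squared` (1/|Z|²);
proportional is the default because the band spans ~3 decades of |Z| and
unit weights would let the kilo-ohm charge-transfer plateau drown the
few-ohm high-frequency region that determines R_s and C_1.

Parameters are optimized in log space (positivity by construction, and the
~6 decades between C_dl and C_1 become O(1) coordinates) with
`scipy.optimize.least_squares` (trf, `x_scale="jac"`, ftol = xtol = gtol =
1e-12, default bounds 1e-18..1e18 on each parameter). Five seeded
multi-start restarts (log-space Gaussian jitter, σ = 0.3) guard against
local minima; the lowest weighted χ² wins, ties keep the earliest start.
Non-convergence returns `converged=False` rather than raising. Standard
errors come from the pseudo-inverse of JᵀJ scaled by the residual
variance; unidentifiable parameters show up as exploding errors.

Initialization inverts the skeleton: detected phase peaks split the grid
into plateau segments; |Z| at the flattest point (phase nearest 0) of each
segment estimates the four plateau levels, from which the resistances
follow by differences; the capacitances follow from the refined peak
frequencies through the geometric-mean formulas. If the low-frequency
(Randles) dispersion is outside the band, R_ct falls back to the
mid-plateau level and C_dl to the value placing its corner at the bottom
band edge, with a warning; a spectrum with fewer than two detectable
dispersions raises an initialization error. If the region-5 plateau is not
resolved below region 3, R falls back to R_1 (k = 1).

A derived consequence, asserted in the tests: under magnitude noise the
recovered φ₄ is conditioned far better than the raw capacitances, which is
precisely why the methodology builds on peak depths.

## Synthetic suspensions

The generator emulates four suspensions — {MSK8-like, BY2-like} ×
{MS-like, PB-like} — via concentration-dependent circuit parameters.
Concentration is in relative units of a stock, (0, 1]; 0 denotes the bare
medium. Defaults (fixtures chosen to satisfy the well-separatedness the
closed forms need and to reproduce the qualitative suspension trends; they
are not calibrated to real cells):

* media: `R_s0 = 2 Ω`, `R_ct = 5 kΩ`, `C_dl = 2 µF`, `C_1 = 5 pF`,
  `R_1 = 80 Ω` (MS-like) / `400 Ω` (PB-like, lower conductivity);
* cells: `k_full = 3.0`, `C_full = 2.0 nF` (MSK8-like) and `k_full = 8.0`,
  `C_full = 1.2 nF` (BY2-like);
* response: `k(c) = k_full (R1_ref/R_1)^0.2 / c`,
  `C(c) = C_full · c`, `R_s(c) = R_s0/(1 + 0.6 c)`;
* noise: agglomeration CV 0.3 (lognormal, multiplicative on C, one draw
  per sample), magnitude CV 0.02 (lognormal per point), phase jitter 0.3°
  (Gaussian per point).

Why this shape: k falling as 1/c deepens φ₄ with concentration and makes
dilute suspensions converge to their medium (d → 1, φ₄ → 0). The weak
(exponent 0.2) medium coupling of k makes same-cell-type pairs cluster
more tightly in φ₄ than same-medium pairs at high concentration — the
clustering-by-cell-type behaviour — while still letting the medium shift
the peaks. The mild relaxation of the access resistance with cell loading
deserves a note: with R_s and R_1 strictly fixed, the circuit algebra
rigidly ties the region-6 depth to the region-5 plateau (φ₆ depth is a
monotone function of R_s/|Z|₅), so a suspension whose plateau falls with
concentration would necessarily show a *shallowing* φ₆ — contradicting
what real suspensions show, where both peaks deepen and f₆ tracks
concentration through the medium's response. Letting R_s relax downward
~2× over the concentration range (a phenomenological stand-in for the
changing near-electrode environment) reproduces the joint trend: φ₄ and
φ₆ both deepen monotonically, d falls monotonically below 1, p(c) falls so
f₆ shifts systematically with concentration. This is an engineered
emulation of observed behaviour, not a mechanistic claim.

Agglomeration is modelled as lognormal jitter on C only, because clumping
chiefly perturbs the effective interfacial capacitance: it scatters f₄
(∝ 1/C) strongly while leaving φ₄ (capacitance-free) and the region-6
observables nearly untouched — the Monte-Carlo tests quantify this as a
sample-CV ordering, CV(f₄) ≫ CV(f₆).

What the generator does *not* emulate: instrument-specific error profiles
across the multi-instrument band, drift/ageing, CPE behaviour (presets use
α = 1), Maxwell–Wagner volume-fraction physics, growth-phase dynamics, or
absolute concentration units. Tests passing on these presets therefore
demonstrate the correctness and robustness of the *method* under its
stated assumptions, not quantitative agreement with any real cell line.

**Randomness.** Every stochastic routine takes one seed. Series spawn
per-concentration child seeds with `numpy.random.SeedSequence.spawn`; a
single spectrum draws, in order, the agglomeration factor, the magnitude
factors and the phase jitter from `numpy.random.default_rng(seed)`. No
global state.

## Problem sizes and tolerances

Default grids use 10–12 points per decade over 4 Hz – 20 GHz (~100–120
points). The oracle-equivalence suite draws 20 random circuits with
3.2-decade inter-dispersion gaps and p ∈ [1e-3, 0.02]; analytic peaks are
required to match numeric minima within 1.5° and 15% in frequency. The
noisy-recovery study uses 2% multiplicative magnitude noise over 20 seeds
(3 restarts per fit) with median-recovery targets of 10% per parameter and
1° on φ₄; the agglomeration Monte-Carlo uses 100 draws at concentration
0.7 with agglomeration CV 0.5. These sizes make the entire suite and the
acceptance script run in seconds while leaving comfortable statistical
margins.

## Known limitations

* The closed-form API inherits the small-p assumption; for p ≳ 0.05 use
  the exact dispersion pairs.
* Corner formulas and the Bode skeleton require α = 1; no closed forms are
  provided for CPE spectra.
* `delta_phi4` requires identical concentration ladders; no interpolation
  across ladders is attempted.
* The deviation d uses the modelled medium plateau (R_s + R_1 of the
  reference circuit) by default; a measured region-5 magnitude can be
  supplied instead (`medium_z5`), and the two differ when the medium
  spectrum itself is imperfectly described by the circuit.
* Classification of unknown spectra (assigning cell type/concentration) is
  deliberately out of scope: the package stops at separability metrics.
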