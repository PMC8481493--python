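# phytoeis

Equivalent-circuit modelling and phase-peak analysis of plant-cell
suspension impedance spectra.

`phytoeis` is for researchers using electrical impedance spectroscopy (EIS)
to monitor plant cell lines in suspension — e.g. tomato (MSK8) or tobacco
(BY2) cells in Murashige–Skoog (MS) growth medium or phosphate buffer (PB).
It simulates, fits and analyzes ultra-wide-band spectra (4 Hz – 20 GHz)
with the unified Randles–Debye equivalent circuit, and implements the
asymptotic phase-peak methodology that turns a fitted circuit into a small
set of well-conditioned observables for telling suspensions apart by cell
concentration, cell type and medium.

## The model

The suspension is modelled as two blocks in series:

* **Randles block** (electrode interface): series access resistance `R_s`,
  then the charge-transfer resistance `R_ct` in parallel with the
  double-layer capacitance `C_dl` (optionally a constant-phase element
  `1/(C_dl (jω)^α)`). The Warburg diffusion element is omitted — it only
  matters below the bottom of the band.
* **Extended Debye block** (suspension dielectrics): solution resistance
  `R_1` in parallel with the cell branch (cell resistance `R` in series
  with cell capacitance `C`) and with the water-polarization capacitance
  `C_1`.

With ideal capacitors the spectrum splits into three first-order
dispersions — one per capacitor — giving a seven-region Bode skeleton:
four plateaus (`R_s+R_ct+R_1`, `R_s+R_1`, `R_s+R_1‖R`, `R_s`) joined by
−20 dB/decade slopes. Each dispersion is a bilinear function
`(1+jω/ω_zero)/(1+jω/ω_pole)` whose phase is bell-shaped on a log axis,
bottoming out at the geometric mean `√(ω_pole ω_zero)` with depth

    φ_min = arctan(√(ω_pole/ω_zero)) − arctan(√(ω_zero/ω_pole)).

Writing `k = R/R_1` and `p = R_s/R_1`, the region-4 and region-6 peaks
obey (in the `p ≪ 1` regime the method assumes)

    ω₄ = (1/(C R_1)) √(1/(k(k+1)))          φ₄ = arctan(√(k/(k+1))) − arctan(√((k+1)/k))
    ω₆ = (1/(C_1 R_1)) √(1/(p(p+k/(k+1))))  φ₆ = arctan(√(p/(p+κ))) − arctan(√((p+κ)/p)),  κ = k/(k+1)

so the peak **depths depend only on the resistance ratios**, never on the
capacitances — which is what makes them robust observables (cell
agglomeration scatters `C`, hence `f₄`, but leaves `φ₄` untouched). The
region-5 plateau `|Z|₅ = R_1(p + κ)` yields the deviation
`d = |Z|₅,suspension / |Z|₅,medium`, a second concentration-sensitive
observable that is largest (furthest from 1) in low-conductivity media.

## Worked example

Simulate a noisy MSK8-like suspension in PB-like buffer at 70% of stock
concentration, fit it, and derive the detection metrics:

```python
from phytoeis import preset, generate_spectrum, fit_spectrum, metrics_from_params

scenario = preset("MSK8-like", "PB-like")
spectrum = generate_spectrum(scenario, concentration=0.7, seed=42)
result = fit_spectrum(spectrum)
m = metrics_from_params(result.estimate, scenario.base)
print(f"phi4={m.phi4:.2f} deg at f4={m.f4/1e3:.1f} kHz")
print(f"phi6={m.phi6:.2f} deg at f6={m.f6/1e9:.2f} GHz")
print(f"|Z|5={m.z5:.1f} ohm  d={m.d:.3f}")
```

prints

```
phi4=-8.06 deg at f4=79.3 kHz
phi6=-82.25 deg at f6=1.54 GHz
|Z|5=303.4 ohm  d=0.755
```

Read: the fitted cell/solution resistance ratio (k ≈ 3.1) puts a −8°
phase peak at 79 kHz — the cell-sensitive signature in the ~1 kHz–10 MHz
window — while the deep −82° peak at 1.5 GHz reflects the medium
(p ≈ 0.003). The region-5 plateau sits 24.5% below the cell-free buffer's
(d = 0.755): the suspension is clearly distinguishable from its medium.

The same pipeline is scriptable from a shell:

```sh
phytoeis simulate --config scenario.yaml --outdir sim/
phytoeis fit sim/*.csv --out fits.csv
phytoeis analyze --params fits.csv --out metrics.csv
phytoeis compare --metrics metrics.csv --out delta_phi4.csv
phytoeis sensitivity --p 0.02 --r1 200 --out d_vs_k.csv
```

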