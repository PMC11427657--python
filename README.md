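# seirakit

Coupled-mode simulation and spectral analysis for metamaterial-absorber
SEIRA sensors.

Surface-enhanced infrared absorption (SEIRA) sensing reads out molecular
fingerprint vibrations through the near field of a resonant nanostructure.
For a metal–insulator–metal absorber (zero transmission, so absorbance
`A = 1 − R`), temporal coupled-mode theory (TCMT) gives the full reflection
response of the device coupled to molecular oscillators:

```
r(ω) = κ² / D(ω) − 1,      κ² = 2 γr
D(ω) = j(ω − ω₀) + (γr + γa) + Σᵢ μᵢ² / ( j(ω − ω_mᵢ) + γ_mᵢ )
A(ω) = 1 − |r(ω)|²,        ΔA(ω) = A(ω) − A(ω)|μ=0
```

with all rates on the wavenumber axis (cm⁻¹): `γr` the radiative loss, `γa`
the internal loss, `(ω_m, γ_m, μ)` a molecular line and its coupling to the
device.  Three reduced coordinates organise the physics:

* **loss ratio** `f = γr/γa` — overcoupled (OC) for f > 1, undercoupled (UC)
  for f < 1, critical coupling (perfect on-resonance absorption) at f = 1;
* **coupling ratio** `ξ = μ/γ_m` — the system crosses from weak to strong
  coupling at ξ = 1, where the complex-plane trajectory of r(ω) develops a
  *secondary loop* (a self-intersection at ω_m ± √(μ² − γ_m²));
* **detuning** `Δω = ω₀ − ω_m`.

The signed sensitivity `I_SEIRA = ΔA(ω_m)` is positive in OC devices
(fingerprints appear as enhanced peaks) and negative in UC devices (dips with
Fano distortion).  The package is aimed at people designing or analysing
such sensors: it provides

* the forward model, sensitivity maps over (f, ξ, Δω), enhancement-bandwidth
  and anticrossing diagnostics (`seirakit.tcmt`, `seirakit.atlas`);
* loop-topology analysis of r(ω) for coupling-regime diagnosis
  (`seirakit.loops`);
* measurement-side processing: asymmetric-least-squares (AsLS) baseline
  extraction of ΔA, Savitzky–Golay derivative spectra, peak tables, CSV and
  JCAMP-DX I/O (`seirakit.spectral`);
* parameter inversion by bounded multi-start least squares, concentration
  calibrations and 3σ limits of detection (`seirakit.fitting`);
* chemometrics over ΔA spectra: PCA, linear-SVM molecule classification,
  non-negative unmixing, concentration regression, Amide-I secondary-structure
  summaries (`seirakit.chemometrics`);
* a fully seeded synthetic FTIR generator with device/molecule presets, so
  every stage is testable without instrument data (`seirakit.synthetic`).

## Worked example

Simulate the strongly coupled overcoupled preset ("OC-Hmu", γr = 400,
γa = 40 cm⁻¹) loaded with a PMMA film, diagnose the coupling regime from the
reflection trajectory, and invert the parameters back from a noisy spectrum:

```python
from seirakit import fit_tcmt, seira_sensitivity
from seirakit.loops import loop_report
from seirakit.synthetic import NoiseModel, make_system, simulate_measurement

system = make_system("OC-Hmu", "PMMA", coverage=1.0)
print(system.resonator.f, system.oscillators[0].xi)
# 10.0 2.5                        -> overcoupled, strong coupling by design

print(round(seira_sensitivity(system), 4))
# 0.3191                          -> +32% enhanced carbonyl signal at 1730 cm^-1

report = loop_report(system)
print(report.coupling_label, [round(w, 1) for w in report.crossing_frequencies])
# strong [1707.1, 1752.8]         -> secondary loop at 1730 +/- sqrt(mu^2 - gamma_m^2)

spectrum = simulate_measurement(system, noise=NoiseModel(sigma=0.005, seed=0))
result = fit_tcmt(spectrum, n_oscillators=6, regime_prior="OC", seed=0,
                  line_hints=tuple(o.omega_m for o in system.oscillators))
print(round(result.resonator.gamma_r, 1), round(result.resonator.gamma_a, 1),
      round(result.oscillators[0].mu, 2))
# 398.6 39.9 24.83                -> generator rates recovered from noisy data
```

The printed sensitivity is the model value of ΔA at the line position; the
inversion recovers the generating rates (400, 40, 25) to better than 1% at
σ = 0.005 absorbance noise.

A CLI mirrors the library for shell use, e.g.

```sh
seirakit synth --device OC-Hmu --molecule PMMA --sigma 0.005 --seed 0 --out s.csv
seirakit baseline --in s.csv --out delta.csv
seirakit fit --in s.csv --oscillators 1 --regime OC --hint 1730 --out fit.json
seirakit atlas --plane f-detuning --xi 1.0 --out map.csv
```

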