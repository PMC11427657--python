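# Methods

## Model

The device is a single-mode metal–insulator–metal absorber treated by
temporal coupled-mode theory.  One bright mode at ω₀ couples to the incident
beam with radiative rate γr (input coupling κ² = 2γr) and dissipates
internally at rate γa.  Each molecular vibration is a dark Lorentzian
oscillator (ω_m, γ_m) coupled to the bright mode with coefficient μ and
enters the response as an additive self-energy term μ²/(j(ω−ω_m)+γ_m) in the
denominator — the standard TCMT form for independent dark modes, which is
what makes multi-line molecules (e.g. the six PMMA bands) a sum of such
terms.  Because the absorber transmits nothing, absorbance is A = 1 − |r|².

Assumptions worth stating explicitly:

* all symbols live on the wavenumber axis (cm⁻¹) and the γ are HWHM-type
  rates, so the bare absorption FWHM is 2(γr+γa); no angular-frequency
  factors are carried anywhere;
* the input coupling κ² = 2γr is taken frequency-independent, i.e. the
  radiative continuum is flat across the band;
* molecular oscillators are mutually independent (no intermolecular
  coupling); γ_m = 0 is rejected as input rather than regularized, since it
  places a pole of the response on the real axis;
* the sign convention is r = κ²/D − 1 (so the bare off-resonant limit is
  r → −1).  A point-reflected convention would change plots but not the loop
  topology, which is all the regime diagnosis uses.

Useful closed forms used as oracles throughout the tests: at zero detuning
the co-resonant absorbance is A(ω_m) = 4γr·γeff/(γr+γeff)² with
γeff = γa + Σμᵢ²/γ_mᵢ (molecular channels act as extra internal loss), and
the trajectory self-intersection sits at ω_m ± √(μ²−γ_m²) with
r = κ²/(γr+γa+γ_m) − 1 there — hence the strong-coupling criterion ξ > 1.

## Loop detection

The reflection trajectory is sampled adaptively: a coarse global grid over
ω₀ ± 10(γr+γa), fine windows around every molecular line (loops live there),
then chord bisection until no segment exceeds 2% of the trajectory diameter.
Self-intersection is decided by computational geometry (GEOS `is_simple`);
crossing locations come from a blocked all-pairs segment intersection and are
polished by a two-frequency root solve of r(ω₁) = r(ω₂).  A trajectory whose
longest chord exceeds 5% of its diameter raises a resolution error instead of
silently reporting "no loop".  With several lines, the largest loop by
enclosed arc length is reported.  At ξ = 1 exactly the crossing degenerates
to a tangency and is classified as "no loop"; a 0.01-step ξ-scan therefore
first detects the loop at 1.01.

## Sensitivity atlas

Maps of I_SEIRA use the reduced coordinates with reference scales
γa = γ_m = 1 rate unit (defaults f ∈ [0.1, 20] log-spaced, ξ ∈ {0.5…3.0},
Δω ∈ ±25 γ_m units), evaluated through the exact closed form at ω = ω_m.
"Enhancement bandwidth" is defined here as the contiguous detuning interval
where |I_SEIRA| ≥ 10% of its maximum; the floor is this package's choice and
is a parameter.  The anticrossing diagnostic sweeps ω₀ through ω_m and traces
prominence-filtered extrema of |ΔA| (minimum prominence 1% of the maximum).
Two scalars summarise it: the minimum separation between coexisting branches,
and the largest excursion of the dominant extremum from ω_m.  In undercoupled
strong coupling the branches avoid crossing and the dominant feature wanders
by of order the Rabi splitting; in the overcoupled regime the feature stays
pinned at the line.  Note that "pinned" is not exact: even at f = 10 the peak
is pulled up to ≈ 0.48 γ_m off the line at ξ = 3 by residual level repulsion,
so the package's criterion for "no anticrossing" is a deviation below half a
molecular linewidth, not below one grid step.

## Baseline extraction (AsLS)

ΔA is recovered from a measured absorbance spectrum by asymmetric least
squares smoothing: minimise Σwᵢ(yᵢ−zᵢ)² + λΣ(Δ²z)² with wᵢ = p above the
baseline and 1−p below, iterated to a relative tolerance of 1e−6 (cap 30
iterations — the weight pattern on the canonical fixtures settles in ~25).
The pentadiagonal system is solved by banded Cholesky.  Defaults λ = 1e4 and
p = 0.01 on ~2 cm⁻¹ grids were fixed by two competing requirements measured
on noiseless fixtures: the baseline must follow a smooth bare-absorber
envelope (FWHM ~ 900 cm⁻¹) to well under 1%, yet pass beneath a molecular
line (FWHM ~ 20 cm⁻¹) so the recovered peak height is within 10% of truth.
Larger λ or smaller p inflate the envelope sag (λ = 1e5, p = 0.001 sags 14%
at the peak); smaller λ or larger p swallow the narrow peaks.  Undercoupled
devices produce dips, handled by flipping p → 1−p via the regime flag.

Savitzky–Golay derivatives default to an 11-point cubic window, matched to
4 cm⁻¹-class FTIR resolution; non-uniform grids are linearly resampled first.

## Parameter inversion

`TcmtFitter` runs bounded nonlinear least squares on (ω₀, γr, γa) plus
(ω_m, γ_m, μ) per line, initialised from the spectrum (peak → ω₀, FWHM/2 →
γr+γa, peak height → γr·γa) with a multi-start set that seeds lines both at
vibrational-linewidth scale and at absorber scale.  Line-position hints, when
given, bound each ω_m to ±100 cm⁻¹ of its hint so weak lines cannot migrate.

Amplitude-only spectra carry intrinsic ambiguities.  A bare Lorentzian is
exactly symmetric under γr ↔ γa, so the loss assignment must come from a
`regime_prior` (in practice the device geometry fixes it).  With coupled
lines, further discrete reparameterisations can reproduce |r| on the real
axis essentially exactly (zero-flip ambiguity of amplitude data), so `auto`
mode does not try to outrun the degeneracy with residuals: it first decides
the regime from the data — AsLS-extract the molecular feature and read its
sign (peak ⇒ overcoupled, dip ⇒ undercoupled, a moderate-coupling
assumption) — and then fits under that prior; a feature below 0.005
absorbance raises an ambiguity error.  Reported uncertainties are asymptotic
standard errors from the Jacobian.  The loaded-device resonance ω₀₁ is the
absorbance maximum of the fitted coupled system; the coupling label comes
from loop detection on the fitted parameters.

Calibration curves are linear or extended-Langmuir
(I_max·(Kc)ⁿ/(1+(Kc)ⁿ), n = 1 by default); the 3σ limit of detection is
3σ_blank divided by the calibration slope at zero concentration.

## Chemometrics

Classification uses a linear-kernel SVM (C = 1.0) in a one-vs-rest scheme
with a seeded stratified 80/20 split.  Mixture unmixing is plain non-negative
least squares against reference ΔA spectra; reconstruction error is the mean
squared residual.  Concentration regression offers a small dense network
(three 64-unit rectified-linear hidden layers, two linear outputs, adam on
squared error, 200 epochs, batch 16, step 1e−3, fully seeded) and a
deterministic linear backend that inverts the least-squares concentration→
spectrum map by NNLS (exact on noiseless linear mixtures).  Its error metric
is the per-sample L1 concentration error divided by the true total, in
percent — chosen because titration labels include exact zeros.  Regression is
meant to run on ΔA spectra (the informative representation); feeding raw
absorbance roughly doubles the held-out error.  Amide-I secondary structure
integrates the negative lobes of the second derivative over
α-helix 1648–1660 cm⁻¹ and β-sheet 1620–1640 / 1670–1690 cm⁻¹ windows
(literature-informed defaults, overridable), normalised over 1600–1700 cm⁻¹.

## Synthetic generator

Device presets (cm⁻¹): OC-Hmu γr = 400, γa = 40, coupling scale 25;
OC identical rates with scale 6; UC-Hmu γr = 40, γa = 100, scale 25 — chosen
to realise f = 10 / f = 0.4 and ξ ≈ 2.5 (strong) vs ≈ 0.6 (weak) on the PMMA
carbonyl at unit coverage.  Molecule presets are Lorentzian line tables;
the PMMA C=O at 1730 cm⁻¹ and the protein Amide I/II/III assignments
(α-helix 1657 cm⁻¹) are anchored fingerprints, the remaining positions are
standard literature IR values (flagged in the preset metadata).  Coupling
scales as μᵢ = scale·√(coverage·strengthᵢ) — coupling energy proportional to
molecule number — and coverage maps to concentration through a Langmuir
isotherm coverage = c/(c+c_half).  Measurements add seeded Gaussian noise
(default σ = 0.005 absorbance) and optionally a slow cubic drift (≤ 0.02),
then clip to [0, 1].  The default grid is 800–4000 cm⁻¹ with 1687 points.

Mixtures weight-sum the components' oscillator strengths before coupling, so
ΔA is only approximately linear in the mixing weights; at the preset protein
coupling the 7-ratio unmixing closure is good to ~0.016 in weight units.
The unmixing pipeline uses ΔA references extracted from noiseless
pure-component simulations (a high-SNR reference library, as one would
record in practice); extracting references from σ = 0.01 data instead adds a
~0.008 systematic through the AsLS baseline.

What the generator does *not* emulate: instrument lineshape and apodization,
atmospheric H₂O/CO₂ bands, detector drift beyond the polynomial term,
scattering backgrounds, or any geometry→rate mapping (spacer thickness and
antenna gap exist only through the preset rates).  Passing tests therefore
demonstrate internal consistency of model + pipeline under realistic noise,
not transferability to a specific instrument.

## Problem sizes and numerical choices

Test and acceptance runs use the 1687-point grid, 250-spectrum
classification sets, 350-spectrum titrations, 20 noise realizations for the
inversion study and 0.01-step ξ-scans — sizes chosen so the full suite
completes in a few minutes on one core.  Regime classification treats
|f − 1| ≤ 1e−9 as critical.  The loop-scan tolerance, AsLS settings and
prominence floors are all exposed as parameters rather than constants.

## Known limitations

* The inversion's `auto` regime detection assumes moderate coupling; deep in
  the strong-coupling UC regime a split feature can confuse the sign test —
  pass an explicit prior there.
* Multi-line inversion (≥ 15 parameters) needs line hints to be reliable;
  unhinted fits can land in spiky local minima that overfit noise.
* The extended-Langmuir slope at the origin (hence the LOD) is undefined for
  exponent ≠ 1; the package raises rather than extrapolating.
* AsLS peak-height recovery carries a systematic few-percent bias that
  depends on λ and p; quantitative work should calibrate against the forward
  model, as the acceptance pipeline does.
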