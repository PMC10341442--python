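# Methods

## Mixture model and fitting

A suspension spectrum between 500 and 700 nm is modelled as

D(λ) = L·(ε_HbO2(λ)·C_HbO2 + ε_Hb(λ)·C_Hb + ε_MetHb(λ)·C_MetHb) + M + S/λ⁴.

Units are fixed so the product is dimensionless absorbance: absorptivities in
L·mmol⁻¹·cm⁻¹, concentrations in mmol/L, path length L in cm (default 0.1 cm,
a 1 mm cuvette layer). M (AU) describes scattering by the cells themselves,
which are large compared with the wavelength; it is left unconstrained
because it also absorbs cuvette/blank drift. S (AU·nm⁴) is the Rayleigh
contribution of sub-wavelength membrane roughness and is constrained
non-negative along with the three concentrations.

The model is linear in all five unknowns, so the "nonlinear curve fitting" of
general-purpose plotting software reduces to bounded linear least squares
(`scipy.optimize.lsq_linear`). This is deterministic — no initial values and
no local minima. Numerical choices:

* The S/λ⁴ column is rescaled internally to (550/λ)⁴; the raw nm⁻⁴ values
  (~10⁻¹¹) would destroy the conditioning of the normal equations. S is
  reported back in AU·nm⁴.
* Coefficients within 10⁻¹⁰ (relative to the largest coefficient) of the zero
  bound are snapped to exactly zero, so downstream logic can test the active
  set exactly.
* Standard errors come from σ̂²·(XᵀX)⁻¹ of the design restricted to the free
  (unpinned) parameters, with σ̂² = SSres/(n − p_free). Parameters pinned at a
  bound have no meaningful curvature-based SE and report NaN. R² is
  1 − SSres/SStot.
* Rank deficiency (e.g. two identical basis curves) raises an error naming
  the near-collinear columns rather than returning an arbitrary solution.
* Spectra are cropped, never resampled, to the fitting window (default
  500–700 nm); the *basis* is the resampled object, by linear interpolation
  only (monotone, cannot overshoot below zero).

Whether the original instrument-software fits constrained concentrations to
be non-negative is unknowable from the outputs alone; the constrained
convention used here is recorded in every result's metadata
(`UnmixResult.to_dict()["constraints"]`). `FitOptions` can also restrict the
fit to a subset of components or drop the scattering terms, which is useful
for supernatant spectra and for low-dimensional cross-checks against
exhaustive search.

## Extinction basis

No public machine-readable absorptivity table ships with the package, so the
packaged fixture `data/extinction_synthetic.csv` is **synthetic**: each
derivative's curve is a sum of Gaussian peaks at the derivatives'
characteristic positions — HbO₂ at 542 and 577 nm, Hb at 555 nm, MetHb at
630 nm — with heights (14.6, 15.4, 13.0, 3.9 L·mmol⁻¹·cm⁻¹) of the magnitude
tabulated for human hemoglobin and widths (8–12 nm) narrow enough that each
peak survives as a distinct local maximum on the 1 nm grid. Every analysis
accepts a user-supplied measured table in the same CSV dialect; nothing in
the package's conclusions depends on the specific fixture, which the test
suite enforces by running all recovery tests against `synth_basis()` output.

## Hemolysis

K = 100·(dilution_ratio · total_heme_supernatant)/total_heme_suspension, with
total heme the sum of the three fitted derivative concentrations — the same
estimator for numerator and denominator, making K invariant to joint
rescaling of both spectra. `dilution_ratio` defaults to 1 (no dilution
correction is applied by default); K may exceed 100 under noise and is never
clipped silently. Supernatant fits use the full five-parameter model by
default; the supernatant of an incompletely hemolysed sample still scatters
(cell fragments), and the restricted options are available when it does not.

## Transition kinetics

The deoxyhemoglobin percentage versus storage day is fitted by
y(t) = base + (plateau − base)·Φ((t − tm)/σ), weighted by 1/sd² when
per-point SDs are supplied. Initialisation is deterministic and data-driven:
base = min(y), plateau = max(y), tm = the linearly interpolated crossing of
the mid-level, σ = span/4; bounds are 0 ≤ base, plateau ≤ 100 and
σ ∈ (0, span]. Both asymptotes are *fitted* (with bounds), not fixed at the
observed extremes, and that convention is visible in the output. A handful of
deterministically jittered restarts guard against the rare saddle; an
unidentifiable flat series raises a dedicated error rather than returning a
meaningless σ.

The **formation rate** is defined as 1/tm. The alternative reading — the
maximum slope of the fitted curve, (plateau − base)/(σ√(2π)) — is exposed
separately as `peak_slope_pct_per_day` so the two cannot be confused. "Time
to 50% Hb" is ambiguous between the CDF midpoint tm and the absolute
50-percentage-point level; both are reported (`tm_days` and
`time_to_50pct_days`, the latter by analytic inversion
t = tm + σ·Φ⁻¹((50 − base)/(plateau − base)), NaN when 50% lies outside the
fitted range).

With the storage schedule of five sampling days and four free parameters
there is a single residual degree of freedom, so the covariance-based SEs on
a 5-point fit are themselves noisy; the SE-calibration test therefore uses a
10-point schedule, where the reported SE agrees with the seed-to-seed scatter
within a factor of two.

## ROS balance model

F(C) = a·C² − b·C + F₀ with a the oxidant-system and b the
antioxidant-system performance constants; the decomposition F_os = a·C² and
F_aos = b·C is exposed so the balance equation dC_ROS/dt = F_os − F_aos + F₀
is directly testable. For a > 0 the optimum is C_opt = b/(2a),
F_min = F₀ − b²/(4a). Oxygen concentration stays in arbitrary units tracking
oxygen partial pressure (mmHg); the model is qualitative and no unit
conversion is attempted. Reference points such as normoxemia/anoxemia levels
carry no canonical numeric values and are annotated only from user input.
Fitting (a, b, F₀) to measured ROS data is out of scope — no such
measurements exist at desk scale.

## Synthetic study generator

The generator emulates the storage-study design: two tube states
(closed = hypoxemia/anoxemia, open = normoxemia) × storage-solution
fractions {0, 30, 60, 100}% × sampling days {0, 7, 14, 21, 29}. Per
condition, Hb(t) follows the Normal-CDF course; MetHb is zero before an
onset day (default 7) and ramps linearly to its final level on the last day
— the simplest shape consistent with a delayed onset and a known endpoint;
HbO₂ is the remainder, and a configuration implying negative HbO₂ on any
sampled day is rejected. The default closed-tube trajectory (base 20%,
plateau 85%, tm 11 d, σ 3 d) reproduces the observed course without additive
solution; `default_study()` sets tm = 15.2 and 17.7 d for 30% and 60%
additive, a flat 20% course with 25% MetHb for closed 100%, and plateaus of
62/85/70% for the open-tube conditions.

Spectra are rendered through the *same* design-matrix code path the fit
uses (a single source of truth for the forward model, enforced by an
identity test), with additive homoscedastic Gaussian noise in absorbance —
the standard instrument-noise assumption; default SD 0.005 AU. Default total
heme of 0.66 mmol/L puts peak absorbance near 1 AU at the 1 mm path for the
packaged basis, appropriate for a ~1.3% hematocrit suspension; default
scattering is M = 0.02 AU and S = 0.03 AU at 550 nm. Every generator is a
pure function of (config, seed): identical inputs give bit-identical output,
with per-spectrum sub-seeds derived via `numpy.random.SeedSequence`.

What the generator does **not** emulate: wavelength-dependent
(heteroscedastic) instrument noise, turbidity beyond M + S/λ⁴, cell
morphology (no generative mechanism exists for shape-class counts),
derivative spectra, or within-hour reoxygenation dynamics — a reoxygenation
switch is representable only as two endpoint configurations. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated noise model, not robustness to every artefact of real cuvette
measurements.

## Problem sizes

The Monte-Carlo studies use 100 seeded replicates (transition-time and
hemolysis recovery; forward-inverse identity) and 200 replicates for the
bias checks at instrument noise; the lattice-search cross-checks use 20
five-wavelength toy problems at 10⁻³ resolution. These sizes give Monte-Carlo
standard errors comfortably below the tolerances asserted (e.g. ~0.07 d on
the mean tm against a 0.3 d band).

## Known limitations

* Carboxyhemoglobin and other minor derivatives are not modelled; a real
  sample containing them biases the three-component fit.
* The hemolysis estimator inherits any unmixing bias common to supernatant
  and suspension but not biases that differ between them (e.g. very
  different turbidity regimes).
* The CDF fit assumes a single monotone transition; biphasic courses are not
  detected.
* The ROS model is an illustration of the optimal-hypoxemia hypothesis, not
  a calibrated predictor.
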