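# hemospec

Quantitative spectroscopy of red blood cells (RBCs) stored under
hypoxemia/anoxemia (closed tubes) versus normoxemia (open tubes):

* **Spectral unmixing** — decompose a 500–700 nm absorbance spectrum of an
  RBC suspension into oxyhemoglobin (HbO₂), deoxyhemoglobin (Hb) and
  methemoglobin (MetHb) concentrations plus two scattering terms,
* **Hemolysis** — quantify the hemolysis percentage from paired
  supernatant/suspension spectra,
* **Kinetics** — fit a Normal-CDF transition model to deoxyhemoglobin time
  courses and report the transition time *t*ₘ and formation rate,
* **ROS balance** — the quadratic oxidant/antioxidant model with its
  optimal-hypoxemia point,
* **Synthetic data** — a generator that emulates the full storage study, so
  every stage is testable by parameter recovery without raw instrument data.

## The models

**Unmixing.** Measured absorbance is fitted by the Beer–Lambert mixture

```
D(λ) = ε_HbO2(λ)·C_HbO2·L + ε_Hb(λ)·C_Hb·L + ε_MetHb(λ)·C_MetHb·L + M + S/λ⁴
```

with path length *L* (default 1 mm), an offset *M* for scattering by objects
large compared with λ, and a Rayleigh term *S*/λ⁴ for sub-wavelength membrane
roughness. The model is linear in the five unknowns, so it is solved as
bounded linear least squares (concentrations and *S* non-negative, *M* free),
with value ± SE and R² reporting. Derivative *fractions* are each
concentration as a percentage of total heme.

**Hemolysis.** `K = 100 · total_heme(supernatant) / total_heme(suspension)`,
both totals from the same mixture fit.

**Kinetics.** During closed-tube storage Hb rises sigmoidally as oxygen is
consumed; the fraction-versus-day course is fitted by
`y(t) = base + (plateau − base)·Φ((t − tm)/σ)` with Φ the standard normal
CDF. The formation rate is `1/tm` (e.g. tm = 11.0 d → 0.09 day⁻¹,
tm = 17.7 d → 0.06 day⁻¹).

**ROS balance.** Net reactive-oxygen-species production versus oxygen
concentration *C* is `F(C) = a·C² − b·C + F₀` (quadratic oxidant system,
linear antioxidant system). For a > 0 the minimum lies at `C_opt = b/(2a)`
with `F_min = F₀ − b²/(4a)` — an intermediate, "optimal hypoxemia" oxygen
level at which storage damage is smallest.

## Worked example

Simulate a closed tube without additive solution at instrument-level noise
(0.005 AU), unmix every storage day, and fit the deoxygenation kinetics:

```python
import hemospec as hs

basis = hs.default_basis()
config = hs.TrajectoryConfig(noise_sd_au=0.005, seed=42)
spectra = hs.make_series({("closed", 0.0): config}, basis=basis)
table = hs.batch_fit(spectra, basis, path_length_cm=0.1)
print(table[["day", "hbo2_pct", "hb_pct", "methb_pct", "r_squared"]].round(3))

series = hs.KineticSeries(times=table["day"], hb_pct=table["hb_pct"])
fit = hs.fit_cdf(series)
print(f"tm = {fit.tm_days:.1f} ± {fit.se['tm_days']:.1f} days, "
      f"rate = {fit.rate_per_day:.2f} /day")

opt = hs.optimum(hs.RosParams(a=0.02, b=2.0, f0=55.0))
print(f"C_opt = {opt.c_opt:.0f}, F_min = {opt.f_min:.0f}")
```

prints

```
 day  hbo2_pct  hb_pct  methb_pct  r_squared
   0    79.842  19.821      0.337      1.000
   7    74.053  25.947      0.000      1.000
  14    25.475  74.480      0.045      0.999
  21    15.009  84.859      0.132      1.000
  29    14.976  84.749      0.275      0.999
tm = 11.0 ± 0.0 days, rate = 0.09 /day
C_opt = 50, F_min = 5
```

The suspension starts ~80% oxygenated, deoxygenates around day 11 and
plateaus near 85% Hb; the fitted transition time recovers the generating
value, and the ROS model's optimum for the illustrative parameters
(a = 0.02, b = 2, F₀ = 55) sits at oxygen level 50 with minimal rate 5.

The same workflow is available from the shell:

```
hemospec simulate --seed 7 --noise-sd 0.003 --out sim/
hemospec unmix --spectra sim/ --out fits.csv
hemospec report --fits fits.csv --out summary.csv
hemospec ros-curve -a 0.02 -b 2 --f0 55 --out curve.csv
```

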