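# Methods

`cuticula` implements the computational chain of a slope-contrast study of
leaf-cuticle water permeability in an alpine dwarf shrub: microclimate
characterisation, effective solar irradiance on tilted canopy surfaces,
minimum diffusive conductance (g_min) from bench-drying mass loss, an
exponential temperature response of g_min, Raman hyperspectral cuticle
chemometrics, and the group-comparison statistics that tie the pieces
together.  Because no field raw data are deposited, every stage is paired
with a synthetic-data generator whose parameters are calibrated to the
published group-level results; the generators are first-class, tested code
and define the ground truth that recovery tests check against.

## Solar geometry and effective PPFD

Solar position uses the NOAA "General Solar Position Calculations"
equations (Fourier series in the fractional year for declination and the
equation of time).  The accuracy contract is agreement with an independent
published ephemeris to 0.5° in both angles; the test suite checks this
against a separately implemented Michalsky (1988) ephemeris.  Azimuths are
degrees clockwise from north.

Horizontally measured PPFD is converted to a beam estimate by dividing by
`sin(elevation)` — but only above 10° solar elevation.  Below 10° the
measured flux is left unchanged: near the horizon the correction factor
diverges and the signal is diffuse-dominated.  The rule is deliberately a
step, not a blend.  Effective PPFD on a canopy surface is the beam estimate
times `max(0, n·s)`, the clamped scalar product of the unit surface normal
and the unit sun direction; negative products (self-shaded surface) clamp
to zero, and the projection is applied to the corrected value at all
elevations.  Daily maxima use site-local civil days.

## g_min from bench-drying mass loss

A stem-sealed twig is weighed repeatedly while drying.  Per weighing
interval,

    E = Δm / (M_w · A · Δt)     (transpiration, mmol m⁻² s⁻¹)
    g = E / D                   (conductance, mmol m⁻² s⁻¹)

with Δm the mass decrement [g], M_w = 18.015 g mol⁻¹, A the projected
one-sided leaf area [m²], Δt the interval [s], and D the mole-fraction
vapour pressure deficit `(e_s(T_leaf) − RH/100·e_s(T_air))/P` recomputed
per interval from concurrent ambient records.  Saturation vapour pressure
uses the Magnus approximation `0.61094·exp(17.625T/(T+243.04))` kPa.  Leaf
temperature is taken equal to ambient during bench drying, and stomata are
assumed fully closed on the plateau, so estimates are labelled g_min
rather than cuticular conductance.

**Plateau detection.**  The conductance series has three phases: stomatal
closure (fast decline), a long constant plateau, and a terminal decline
once the tissue desiccates.  The plateau is the longest contiguous run —
after excluding any strictly monotone decline of at least `min_run`
intervals at the record's end — in which the relative change of a smoothed
g per hour stays below `rel_slope_threshold` (default 2 %/h; `min_run`
default 6 intervals).  The smoothing span and slope lag are chosen
adaptively from a robust estimate of the per-interval noise (1.4826·MAD of
first differences), scaled so noise-induced apparent slopes sit below the
threshold: with a 0.1 mg balance and 20-min weighings the per-interval
noise can reach ~40 % of the mass decrement at 25 °C, and no fixed span
works across exposure temperatures.  Because balance noise is zero-mean in
the decrements, the plateau mean (the g_min estimate) is insensitive to
the exact run bounds as long as they lie inside the true plateau; the
estimator's bias is below 0.5 % in every calibrated cell.

**Forward model (generator).**  Total conductance is a constant cuticular
term plus an exponentially closing stomatal term,
`g(t) = g_min + g₀·exp(−t/τ)` (defaults g₀ = 8 mmol m⁻² s⁻¹, τ = 0.8 h, so
stomata are effectively closed after ~3.5 h).  The twig holds a losable
water pool (default 45 % of the 0.4 g initial mass); once a set fraction
of it is transpired (default 85 %) the cuticular term declines linearly
with the remaining pool, reproducing the late downward slope of real
drying curves.  Defaults: 20-min weighings, 24 h duration, 0.1 mg Gaussian
balance noise per reading, 35 % RH, 101.3 kPa, A = 5.4 cm².  At 25/38 °C
these defaults give an 18–20 h plateau; at 43 °C drying is ~10× faster and
the plateau shortens to a few hours, which is why the terminal-decline
exclusion matters.  The balance precision and weighing interval are
documented defaults, not values taken from any field protocol.

**Calibrations.**  Cell calibrations (mean, SD in mmol m⁻² s⁻¹):
N-site 25 °C 1.78±0.32, 38 °C 2.58±0.75, 43 °C 6.91±1.20; SE-site 25 °C
1.39±0.46, 38 °C 1.86±0.46, 43 °C 3.53±1.21.  No 41 °C group means are
published, so that cell carries no calibration and the default study
design uses the three calibrated temperatures.  When simulating a cell,
per-twig true conductances are drawn in antithetic pairs (z, −z) around
the calibration mean — a variance-reduction device that makes the sample
mean of the drawn truths equal the calibration mean exactly for even
replicate counts, so recovery errors reflect the estimator, not
Monte-Carlo noise in the study conditions.

## Exponential temperature response

    g_min(T) = g_min(0 °C) + A·exp(R₀·T)

fitted by bounded nonlinear least squares (all three parameters ≥ 0,
tolerances 1e-14).  Initialisation is deterministic: g_min(0 °C) from the
minimum observed conductance, R₀ from the slope of `log(g − 0.9·min g)`
against T, A from the back-transformed intercept.  Noiseless synthetic
points are recovered to 1e-6 relative; with 10 % multiplicative noise at
the design temperatures (25, 38, 41, 43 °C, 36 replicates each) predicted
g_min stays within 10 % of truth.  Fitting supports per-twig points or
group means; the default is all points.

## Raman cuticle chemometrics

Cubes are regular 2-D grids of spectra (default 0.3 µm pixels, 785 nm
excitation).  Preprocessing is enforced in the order crop (120–1810 cm⁻¹)
→ cosmic-ray removal → baseline subtraction; each cube records its applied
stages and out-of-order calls raise.

* **Despiking:** channels deviating more than 8× the robust SD
  (1.4826·MAD) from a 5-channel running median, in groups of at most 2
  channels, are replaced by linear interpolation.  The threshold is
  floored at 4 % of the spectrum's dynamic range so that, on
  near-noiseless spectra, band curvature never masquerades as a spike.
* **Baseline:** asymmetric penalised least squares per pixel (smoothness
  1e5, asymmetry 0.01, banded solver).
* **Band imaging:** trapezoidal integral over 1452 ± 30 cm⁻¹ (the CH
  deformation band of cutin); the ±30 cm⁻¹ window is a documented choice,
  only the band centre being standard.
* **Unmixing:** non-negative matrix factorisation of the pixel×channel
  matrix for model orders 1–6; the order is the smallest k whose further
  relative error reduction falls below 1 % (error elbow).  Components
  whose spectra have lag-1 autocorrelation below 0.5 are flagged as noise
  and excluded; the requested number of relevant components is returned,
  ordered by total abundance.  This is a functional re-specification of
  vendor "true component analysis", not a bit-level reimplementation.
* **Layer thickness:** per transect perpendicular to the surface, the
  longest contiguous run of pixels with abundance ≥ 50 % of the map
  maximum, times the pixel size; mean ± SD over transects.
* **Band assignment:** local maxima (2 % prominence floor) matched within
  ±8 cm⁻¹ against a reference table — flavonoids 1570/1250; aromatic ring
  1607; anthocyanins 631/1630; triterpenoids 463/532/564/683/729/746
  (746 specifically ursolic/oleanolic acid); cutin 1443/1306; cinnamic
  acid 1630/1170; crystalline long-chain alkanes 1064/1133/1297 cm⁻¹.

The generator builds endmembers as sums of Gaussians (FWHM 12 cm⁻¹) at the
table positions on a 1 cm⁻¹ axis, stacks them into layers of known
thickness, and adds a smooth quadratic baseline, white noise, and 1–2
channel spikes.  At 1 cm⁻¹ spacing the bands are well resolved from
2-channel spikes; coarser axes make the apex of a narrow band formally
indistinguishable from a spike under the width criterion.

## Microclimate

The generator produces site-local series of per-sensor leaf temperature
(diurnal sinusoid peaking at 14:00 + per-day offset + clear-sky radiative
heating ∝ sin²(elevation) + white noise), wind, and horizontal PPFD
constructed as `beam · clearness(day) · max(0, sin(elevation))` so the
sine correction recovers the beam exactly.  Summaries pool all sensors and
timestamps; a frost night is a site-local calendar day whose minimum leaf
temperature drops below 0 °C; heat episodes are maximal contiguous runs
with any sensor above 40 °C.  Site presets (N: 10.3 °C mean, normal
45°/350°; SE: 13.8 °C mean, normal 35°/135°, stronger radiative heating)
reproduce the qualitative contrast — more frost nights on the north slope,
heat episodes only on the southeast slope.

## Statistics

Two-way ANOVA (site × leaf side) uses Type-II sums of squares — identical
to the classical decomposition for the balanced designs generated here —
with Tukey HSD on the four cells and Levene/Shapiro–Wilk assumption
checks on the residuals.  Two-group comparisons are gated per group by a
Kolmogorov–Smirnov normality check (Welch t when normal, Mann–Whitney U
otherwise; degenerate zero-variance groups fall to the rank test).
Kruskal–Wallis uses the tie-corrected H; its post-hoc is Dunn's rank test
with Holm adjustment, rendered as a compact letter display (insertion with
an absorption pass).  Under permutation nulls the realised type-I error of
the gated two-group test and of Kruskal–Wallis is 5 % ± 2 % at α = 0.05
over 1000 label shufflings.

Thickness calibrations: site-level 10.9 ± 4.4 µm (N) and 15.9 ± 4.2 µm
(SE); per-side means (9.965/11.835 µm N adaxial/abaxial, 17.485/14.315 µm
SE) are derived by solving the published pairwise cell differences against
the site means and are internally consistent.  Group draws are truncated
at zero rather than resampled; at these means the effect on group means is
< 0.1 %.

## What the synthetic data do and do not show

The generators emulate the statistical structure of the study — group
means and spreads, drying-curve phases, layered cuticle chemistry, diurnal
microclimate — but not sensor drift, autocorrelated weather, stomatal
heterogeneity between twigs, instrument line-shape effects, or spatial
texture within cuticle layers.  Passing recovery tests therefore
demonstrates that the analysis chain is unbiased and correctly implemented
under the stated forward models, not that it is robust to every artefact
of real field data.

## Problem sizes

Recovery runs use 200–400 simulated drying experiments per site ×
temperature cell (seconds per cell), 5000 thickness values per site, and
cubes of roughly 50 × 20 pixels × 1900 channels — sizes at which every
Monte-Carlo bound in the test suite is comfortably resolved.
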