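# Methods

## Flashlet schedule

A measurement consists of 300 excitation flashlets uniformly spaced over
0.75 ms (spacing 0.75/299 ≈ 0.00251 ms) followed by 127 relaxation flashlets
over the next 200 ms.  Only the total relaxation duration and the qualitative
"decreasing repetition rate" are fixed by the instrument description, so the
relaxation gaps grow geometrically from the induction spacing, with the
growth ratio (≈1.070) solved numerically so the 127 gaps sum to exactly
200 ms.  This yields ~60 samples inside the 0.8–5.9 ms window and ~16 inside
0.8–1.47 ms, dense where the reoxidation statistics integrate.  The timing
profile is an assumption; any schedule satisfying the `FlashSchedule`
contract can be substituted.

## Transient statistics

Flashlet ordinals are 1-based: F_o is the yield of the 1st flashlet, F_m the
mean of the 301st and 302nd (the 300th is depressed by quenching during
induction and never used).  Window times are measured from the first
excitation flashlet, so the windows W1 = [0.8, 1.47] ms and W2 = [0.8, 5.9] ms
both lie inside the relaxation phase beginning at 0.75 ms.  The bracketed
window bounds are authoritative; the nominal labels "0.65 ms" and "5 ms" are
the window widths rounded.

The reoxidation statistic over a window [t0, t1] is

    ratio = ∫ (F_m − F(t)) dt / ((F_m − F_o) · (t1 − t0)),

integrated by the trapezoidal rule on the flashlet samples inside the window
with linear interpolation at both edges — exact for piecewise-linear data and
checkable against closed forms: for a single-exponential relaxation
F(t) = F_o + F_v·exp(−(t−0.75)/τ), the ratio over W2 is
1 − τ(e^(−0.05/τ) − e^(−5.15/τ))/5.1 (≈0.647 at τ = 2 ms; W1 gives ≈0.171).
The 127-point schedule reproduces these to ~2×10⁻⁴ relative.

Because F_m is read from the first two relaxation flashlets, it sits slightly
(≈0.3 %) below the true F_m′ of the underlying kinetics: relaxation is already
under way.  The composition tests integrate their analytic oracle against the
*measured* F_m, exactly as the empirical statistic does.

Dark/light classification uses ambient PPFD < 5 µmol m⁻² s⁻¹; the same
arithmetic then produces F_v/F_m, F_r/F_v (dark) or F_q′/F_m′, F_r′/F_q′
(light).  SNR is defined as F_m divided by the standard deviation of the
between-flashlet background readings (+∞ when the background is noiseless);
its magnitude is calibrated so the 50/100 discard thresholds are meaningful
on the synthetic data.  No kinetic model is fitted to transients: the
statistics are deliberately empirical areas.

## Synthetic campaign generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

**Kinetics.** Relaxation is a three-exponential mixture with time constants
0.2 / 0.7 / 3.0 ms, carrying the reported reoxidation phases (Q_A⁻→Q_B,
Q_B⁻→Q_B²⁻, plastoquinone exchange).  Amplitude weights 0.08 / 0.17 / 0.75
describe the *apparent* contribution of each phase to the observed
canopy-level relaxation: re-excitation by the relaxation flashlets is not
modeled, so the slow phase must dominate for realistic F_r1/F_v (≈0.22 at
20 °C) and F_r2/F_v (≈0.62) — values that, as in the real campaign, mostly
survive the published QC thresholds (0.35 / 0.8) across 2–36 °C.

**Temperature.** All time constants scale by the Arrhenius factor
exp((E_eff/R)(1/T_K − 1/T_ref,K)) with t_ref = 20 °C and e_act = 30 kJ mol⁻¹
(Q10 ≈ 1.5).  Cold tolerance lowers the effective activation energy,
E_eff = e_act·(1 − cold_tolerance): a fully tolerant genotype keeps its
reference kinetics in the cold.  The soybean panel presets encode tolerant
(Amarok 0.85, Gallec/Tourmaline 0.70) versus sensitive (S1 0.10, 22216 0.15)
genotypes plus the chlorophyll-deficient MinnGold (chlorophyll level 0.45).
Tolerance magnitudes are the generator's own calibration, chosen once.

**Light.** NPQ is Stern–Volmer with hyperbolic light dependence,
NPQ = npq_max·PPFD/(PPFD + k) (npq_max = 1.5, k = 350 µmol m⁻² s⁻¹),
quenching F_m′ = F_m/(1+NPQ) while F_o′ is left unquenched — the simplest
form that reproduces the observed decline of F_q′/F_m′ with light.  Induction
closes centers per flashlet with probability σ = 0.04 (single-hit Poisson; PSII
connectivity is ignored, a documented simplification).  Reopening during the
0.75 ms induction is neglected.

**Canopy structure.** Each measurement draws a lognormal amplitude scale
(σ = 0.25, the leaf-angle effect — it cancels in all ratio statistics but
moves SNR) and a lognormal light-penetration factor (≤1) that attenuates
station PPFD at the measured leaf.  Leaf-level light drives NPQ and the PRI
band; the covariates the models see are station-level, so PRI carries canopy
information beyond PPFD — the mechanism behind the index's explanatory power.

**Environment.** Minute resolution.  PPFD follows a solar arc (zero outside
06:00–20:00) times a smooth AR(1)-driven cloud factor in [0.3, 1].
Temperature is a piecewise-cosine diurnal course (minimum 05:00, maximum
14:00, amplitude 7.5 °C) on a linear seasonal ramp 9→29 °C over the default
14-day campaign, spanning ≈2–36 °C so that both the 5 °C and 35 °C analysis
bins are populated; RH is anti-correlated with temperature and clipped to
[20, 100] %.

**Spectra.** 201 even-2-nm bins, 400–800 nm.  True canopy reflectance has a
green bump (550 nm), a chlorophyll-dependent red trough (680 nm), a logistic
red edge to a 0.45 NIR plateau, and a 531-nm dip proportional to the
quenching state (the PRI response).  Digital numbers are irradiance ×
reflectance × gain (20 DN per unit) + 120 DN dark current, with shot noise
0.4·√DN + 2 — per-band relative noise ≈1 %, consistent with the ~1.8 s
integration time and with the requirement that a gray scan corrected by its
own LUT bin return R = 0.5 ± 0.02 per band.  With probability 0.03 a spectrum
targets soil (flat, featureless) instead of canopy; soil hits are injected
into spectra only, motivating the spectral outlier filter.  Transient yields
carry additive Gaussian noise (2 % of F_m′) plus a background channel
proportional to ambient PPFD with its own noise.

**What the generator does not emulate:** radiative transfer through the
canopy, PSI fluorescence, gas exchange, PSII connectivity, flashlet
re-excitation during relaxation, sun–sensor geometry, and real sensor drift.
Passing tests therefore demonstrate the correctness and statistical behavior
of the *analysis*, not instrument-level fidelity.

## Spectral processing

Native ~0.46-nm samples are averaged into half-open 2-nm bins [λ−1, λ+1) per
even wavelength.  The prior night's dark-current scan (latest dark record
before 04:00 of the measurement day) is subtracted, clipped at zero.  The
gray-panel lookup table bins dark-subtracted panel scans into 10-µmol PPFD
intervals over [100, 1350] (centers 105…1345); empty bins are filled from the
nearest nonempty bin and flagged.  Correction divides by the reference
spectrum of the closest bin center (exact ties toward the lower bin) scaled
by the panel's 50 % reflectance: R = dn/(dn_ref/0.5).  Spectra below
100 µmol m⁻² s⁻¹ are uncorrectable and keep only pseudo-indices, which apply
the same band formulas to raw DN.  `reflectance_sum` is the raw-DN sum over
450–800 nm; `r685` (the ChlF detection band) is reported as the mean of the
684 and 686 nm bins since the even grid has no 685 bin.  Whether the original
correction used the 50 % algebra or the raw panel ratio is unknowable from
the description; the two differ by a constant factor that cancels in every
normalized-difference index.

## QC

Strict inequalities throughout (equality survives): drop when SNR < 50
(maize, rapeseed, soybean) or < 100 (barley, wheat); when F_v/F_m or F_r1/F_v
is negative; when F_r1/F_v > 0.35 or F_r2/F_v > 0.8.  Spectral rows with
linked PPFD < 30 µmol m⁻² s⁻¹ are dropped first; then Tukey fences
(Q1 − 1.5·IQR, Q3 + 1.5·IQR, linear-interpolation percentiles) per species and
per index remove outliers such as soil hits — the standard boxplot reading of
an ambiguous rule; the exact quantile convention of the original analysis is
unknown.  Fences need ≥4 values per species (else skipped and logged).  The
third measurement of each scan line is removed because the positioning system
most likely measured the same spot twice.  The rapeseed threshold is kept in
the species map for fidelity even though no rapeseed data are generated.

## Linkage

Environment joins by exact minute (truncation, not rounding); multiple
stations reporting the same minute are averaged.  VPD (kPa) uses the Magnus
form es = 0.6108·exp(17.27T/(T+237.3)), vpd = es(1 − RH/100).  Days after
sowing counts whole days, sowing day = 0.  "Daytime" enters the models as the
numeric hour of day (a categorical block is available by passing it as a
factor).  The observation join is left on the fluorescence side; measurements
without a surviving paired spectrum keep NaN indices and drop out of modeling
only.

## Modeling

Continuous covariates (PPFD, temperature, RH, VPD, reflectance sum, R685,
GNDVI, NDVI, NDVI_II, PRI, MTCI, DAS, hour) are standardized to mean 0, SD 1
on the training data, with the constants reapplied to validation data;
categorical covariates (species, genotype, week, month) are one-hot encoded
with the reference level dropped; zero-variance columns are dropped with a
warning.  The Lasso path is coordinate descent (scikit-learn) over a 100-point
logarithmic λ grid spanning 4 decades below the data-driven maximum, with λ
chosen at minimum mean CV error over 10 folds assigned by a seeded shuffle,
then refit on the full training data.  Half-days splits alternate calendar
days deterministically by date parity (a seeded-random alternation is
available); by-season splits require labeled seasons.  Accuracy is Pearson r
per genotype computed after averaging predictions and observations within
(genotype, day, hour) cells; genotypes with <3 cells or constant vectors are
flagged instead.

Variance partitioning is sequential (Type-I): factor blocks enter strictly in
the given order and each factor's SS is the drop in residual SS, computed by
incremental least squares.  The formula interface of the usual ANOVA helpers
reorders main effects (categoricals first), which silently breaks a
user-supplied entry order, so the decomposition is computed directly; the
tests verify it against `statsmodels.anova_lm(typ=1)` on order-preserving
designs.  Rank-deficient blocks are absorbed with 0 df (e.g. DAS after date),
single-level factors are skipped and recorded.  The default factor order for
the reoxidation response is temperature-led (temperature, month, species,
hour, date, genotype, plot, DAS, √temperature); the PSII-efficiency response
uses a light/canopy-led order (PPFD, √PPFD, PRI, …) — per-response factor
sets mirror per-response covariate selection, and with Type-I SS the order is
part of the model statement.  Response curves are per-group OLS on
transformed terms: √PPFD for the light response, and temperature + √T (+ T²)
for the temperature response.

No mixed-effects or correlated-error structure is fitted, and no p-values are
attached to the partition.

## Numerical and design notes

* Ratios are undefined (errors) when F_m ≤ F_o (degenerate trace) or windows
  leave the relaxation span (insufficient samples); zero index denominators
  give NaN plus a flag rather than an error.
* All randomness flows from one integer seed through fixed per-stage streams;
  reruns are byte-identical (the run manifest records sha256 digests).
* The pipeline aborts with the failing stage's name; a bundle without an
  environment table fails at spectral processing, the first stage that needs
  same-minute PPFD.
* Expected behavior under the default conditions, all recomputed by the test
  suite and `scripts/acceptance.py` at run time: F_r2/F_v rises with
  temperature and separates cold-tolerant from sensitive genotypes at 5 °C
  with disjoint 95 % CIs while F_v/F_m does not; temperature takes the largest
  Type-I share for the reoxidation response but a negligible share (behind
  PPFD and PRI) for the PSII-efficiency response.  The cold-tolerant
  genotype's prediction accuracy is intrinsically lower than the sensitive
  genotype's: its response is temperature-flat, leaving less signal.
* Default problem sizes — a 14-day, 4-plot, hourly campaign (8064 paired
  records) — were chosen so the complete suite and the acceptance script each
  run in a few minutes while keeping every analysis bin populated.
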