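# Methods

This note documents the models implemented in `whalefmr`, the defaults
and their provenance, the numerical choices made where the design was
open, and what the synthetic-data tests do and do not demonstrate.

## Allometric chain

Body length is `Normal(8.61 m, 0.89 m)`, truncated below at a
configurable floor (default 4 m; the floor sits >5 SD below the mean, so
it only guards against non-physical tail draws and does not move the
moments). Mass uses the whaling-era growth relation
`M = 1.25 × 0.0196 L^2.74` with the coefficient in **tonnes**, converted
to kg; the 1.25 factor corrects flensed weights for fluid loss. Because
the exponent exceeds 1 the mass distribution is right-skewed and its
mean (~9.15 t) exceeds the mass of the mean-length whale (~8.93 t);
all confidence intervals in the package are therefore empirical
2.5th/97.5th percentile intervals of the Monte Carlo draws, never
normal-theory intervals.

Lung volumes: `TLC = 0.026 M` litres (diving lung volume taken as total
lung capacity) and `V_c = 0.85 TLC` (cetacean vital capacity is 80–90%
of TLC). Basal metabolism is Kleiber's curve in kJ:
`BMR = 293.1 M^0.75` kJ/day (the kJ form of 70 kcal kg^-0.75 day^-1),
concave, so the mean BMR over the mass distribution (~272.5 MJ/day) is
slightly below BMR at the mean mass. `ADMR = β BMR` with `β = 2`,
appropriate for a low-cost-of-living species.

## Respiration pathway

Surfacings are segmented 80/20 into periods 1 and 2 up to the 9-min
standard; the excess is period 3. Defaults per period (respiration rate
with 95% CI, V_t proportion range of V_c, mean E_O2, daily minutes):

| period | f_R (min⁻¹) | V_t (%V_c) | E_O2 | min/day |
|---|---|---|---|---|
| 1 | 5.06 (3.78–6.10) | 60–80 | 0.80 | 135.83 |
| 2 | 3.50 (3.20–3.80) | 40–50 | 0.50 | 33.96 |
| 3 | 1.37 (0.81–1.93) | 30–40 | 0.35 | 422.09 |

Distributional choices:

* **f_R** is lognormal (positive, right-skewed). The parameters are
  `sigma = ln(CI_hi/CI_lo)/(2×1.96)` and `mu = ln(mean) − sigma²/2`, so
  the distribution mean equals the measured mean *exactly* while the CI
  is matched approximately — the printed CIs are slightly asymmetric in
  a way no lognormal can match exactly, and downstream targets are
  means, so mean-matching wins.
* **V_t**: the per-iteration mean proportion of V_c is uniform on the
  period's range. Per-breath jitter (Normal, SD 0.1 V_c, truncated to
  (0, V_c]) integrates out of the mean; it is applied only in the
  optional `per_breath_jitter` mode, where the period's representative
  tidal volume receives Normal noise of SD `0.1 V_c / sqrt(N_breaths)`
  (the exact distribution of an N-breath average).
* **E_O2** is `Beta(mean·κ, (1−mean)·κ)` with concentration κ = 50 by
  default — a moderate spread within the physiological range (<10%
  after short surfacings to ~80% after long dives) that keeps draws
  well inside (0, 1). κ is configurable; κ = ∞ gives the fixed-value
  mode used by the sensitivity engine.
* f_R, the V_t proportion and E_O2 are sampled **independently** within
  an iteration. Their physiological covariation with dive effort is
  real but no joint model is quantified; independence leaves the means
  unchanged and is the transparent default.

Per iteration, period energy is
`f_R × minutes × 0.21 × V_t × E_O2 × 20.1` kJ (0.21 = O2 fraction of
inspired air; 20.1 kJ per litre O2), and the daily total is the
within-iteration sum — so the total's draws are exactly the sum of the
period draws and all linearity/scaling properties hold by construction.
Daily minutes are fixed at the tag-derived point values by default; an
optional mode samples the daily time *proportions* from truncated
normals matched to their reported CIs.

The closed-form mean
`E[FMR] = f_R_mean × minutes × 0.21 × mid(V_t range) × E[V_c] × E_O2_mean × 20.1/1000`
follows from independence and is used as an analytic oracle in the
tests: simulation means must agree within 3 standard errors.

## ODBA signal processing

* **High-pass**: zero-phase (forward–backward) 4th-order Butterworth at
  0.068 Hz = 0.4 × the 0.17-Hz dominant fluking frequency. Butterworth
  order 4 is the biologging default; zero-phase filtering is required so
  the rotation prediction can be subtracted in phase.
* **Rotation removal**: in animals this size, pitch oscillation during
  fluking sweeps gravity through the body frame inside the passband and
  dominates dynamic acceleration. The oscillation angle about the
  lateral (y) axis is estimated from the magnetometer: the Earth's field
  is inertially fixed, so `theta = atan2(m_z, m_x)` tracks body pitch.
  theta is low-pass smoothed at 2× the fluking frequency (central
  noise control), unwrapped and high-passed; the predicted
  gravity-sweep acceleration
  `(g_x(cosφ−1) − g_z sinφ, 0, g_x sinφ + g_z(cosφ−1))` — built from the
  low-passed (static) acceleration — is subtracted from DA to give
  specific acceleration. Samples where the field lies within 25° of the
  rotation axis (projection degenerates) or has zero norm are flagged
  invalid and excluded from ODBA averaging. This implements the stated
  estimator (lateral-axis rotation from the magnetometer + 25° gate);
  details beyond that level (smoothing constants, the small-angle-free
  exact rotation of gravity) are internal choices documented here.
* **Minute ODBA** is the **mean** per-sample L1 norm over 60-s windows
  (a rate — window length and sampling rate cancel, which is what the
  affine locomotion calibration consumes), computed over valid samples
  only; windows below 50% validity are missing (NaN), never zero.
* **Normalization**: each individual's minutes are scaled so its median
  equals the median of the individual medians (configurable to the
  pooled-minutes median). This equalizes tag calibration without
  touching within-individual rank order, and is idempotent.
* **Trimming**: the first dive cycle or first hour (whichever is
  longer) is dropped to avoid tag-reaction behaviour, and the final
  dive is dropped when the tag detached during it.

## Dive simulation and FMR_ODBA

Phase durations (descent, bottom, ascent) are multivariate normal
(truncated positive, resampled) with a 3×3 correlation; phase ODBA is
multivariate lognormal (normal on logs, exponentiated). The shipped
defaults are **surrogates**: descent N(10, 2), bottom N(28, 5), ascent
N(9, 2) min with pairwise duration correlation 0.3 (total ≈ 47 min,
inside the typical 45–50-min dive), and ODBA lognormal with log-SD 0.4
and mean 0.0740 calibration units, back-computed so mean locomotion
power is `0.09 + 9.01 × 0.0740 ≈ 0.757 W/kg` — the value consistent
with the reported ~360 MJ/day of locomotion cost for a ~9165-kg whale
diving 864 min/day. The per-phase distributions underlying the original
tags are not published; these defaults are configuration, not measured
truth, and the associated checks are self-consistency checks.

`COL = 0.09 + 9.01 × ODBA` (W/kg) is the dolphin-derived calibration;
ODBA enters in the calibration's own units, and processed tag ODBA maps
onto them through a single configurable scale factor (`odba_scale`,
default 1). Dive energy integrates COL × mass over phase durations;
durations are minutes at the interface and converted to seconds
internally (W × s / 1000 = kJ — the only unit reading consistent with
locomotion costs of hundreds of MJ/day; a unit-guard test pins the
60× relationship). Daily locomotion cost scales the duration-weighted
mean diving power to 864 diving minutes (60% of the day); post-dive and
non-foraging periods contribute no locomotion term (surface ODBA is
unreliable under sea-state noise), so `FMR_ODBA = COL_daily + BMR`.
The Monte Carlo averages 10 individuals × 100 dives per iteration.
An `fmr_odba_in_situ` path applies the same calibration to measured
minute ODBA instead of simulated dives; it has no published numeric
target because the per-tag inputs are not printed.

## Sensitivity engine

One-at-a-time scenarios override the V_t proportion range and/or fix
E_O2 (point mass) per period or globally, then rerun the respiration
Monte Carlo (1000 iterations each) under a common seed so differences
between scenarios are purely parametric. The six shipped scenarios are
the two described extremes (V_t 20–60% with E_O2 0.50; V_t 40–80% with
E_O2 0.80) plus four symmetric fill-ins; the original six scenario
definitions are not published, so scenario outputs are not numeric
targets. Two analytic properties are enforced instead: mean FMR is
monotone in a fixed E_O2, and widening the V_t range symmetrically about
its midpoint preserves the closed-form mean while widening the CI.

## Synthetic tag generator

The generator emulates the *statistical structure* the analysis
assumes: alternating ~47-min dives and ~9-min post-dive surfacings, a
0.3-probability ~74-min non-foraging surface block per cycle (chosen so
a long deployment spends ~60/10/30% of time diving / post-dive /
non-foraging), breath events as an exponential-interval renewal process
at each period's mean rate (the simplest process matching a mean), and
sensor streams built from first principles: gravity rotated by a
smoothed state pitch (−55° descent / +55° ascent) plus a
fluking-frequency pitch oscillation (the rotation contamination the SA
estimator must remove), true specific-acceleration sinusoids at 0.17 Hz
with state-specific amplitude, the Earth's field at 55° inclination
under a constant per-deployment heading, white sensor noise, and a
piecewise-linear depth profile. The ground-truth specific acceleration
is stored alongside so recovery can be scored exactly.

What passing tests show: the processing chain recovers known signal
structure (deployment-mean ODBA within 10% of truth; rotation
suppressed below 10%; rates, moments and correlations recovered within
3 SE). What they do not show: performance on real tags — the generator
has constant heading (no yaw/roll contamination), no tag slip, no
sea-state noise, no acoustic channel, and clean phase transitions, so
real-data residual errors will be larger.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.Generator`; every public
  sampler accepts a seed or Generator, and identical config + seed give
  byte-identical summary CSVs (floats written at fixed precision).
* Truncated distributions (lengths, durations, tidal volumes) use
  rejection resampling, not clipping, so densities keep their shape.
* Degenerate inputs are defined, not errors: zero-SD lengths return the
  mean; zero daily minutes give zero FMR; fully-masked ODBA windows are
  missing; a zero-norm magnetic sample is invalid, not a crash.
* The distribution-overlap statistic integrates the pointwise minimum
  of two shared-grid histogram densities (100 bins over the pooled
  range). It is exactly 1 for identical samples and 0 for disjoint
  ones; against the closed-form overlap of unit-variance normals one SD
  apart (2Φ(−½) ≈ 0.617) the histogram estimator at 1e5 samples is
  accurate to ~1%.
* Default problem sizes (1e4–1e5 Monte Carlo iterations, 1e4 simulated
  dives, 10-Hz test streams) were chosen so Monte Carlo standard errors
  sit well below the 1–3% comparison tolerances while the whole suite
  runs in seconds.

## Known limitations

* The FMR-to-BMR multiples can be computed as ratio-of-means or
  mean-of-ratios; for these skewed distributions they differ by several
  percent, and published multiples are not exactly recoverable from the
  published means under either convention — both are therefore always
  reported side by side and neither is asserted.
* E_O2's beta concentration (κ = 50) is a documented modelling choice,
  not a measured quantity; it affects CI width, not means.
* The dolphin COL calibration is applied beyond its body-size range;
  the intercept and slope are carried as constants with a scale hook,
  not re-derived.
* Oxygen-debt dynamics across successive surfacings are not modelled;
  period-level mean rates absorb them.
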