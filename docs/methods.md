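# Methods

## Probability-ellipse evaluation

A COP record is treated as a sample from a bivariate normal distribution.
The probability ellipse at coverage level p is constructed from the sample
mean and the sample covariance Σ (denominator n−1): semi-axes √(q·λᵢ) along
the eigenvectors of Σ, where q is the χ² quantile with 2 degrees of freedom
at p. For two degrees of freedom the quantile has the closed form
q = −2·ln(1−p), so q ≈ 4.60517 at the default p = 0.900; the test suite
checks the scipy quantile against this closed form. Under the bivariate
normal model the squared Mahalanobis distance of a point from the mean is
χ²₂-distributed, so the ellipse {d² ≤ q} contains probability mass p; the
empirical containment fraction of large samples is 0.900 within Monte-Carlo
noise (asserted at 0.900 ± 0.006 on 50,000 points across seeds).

Descriptors and conventions:

- **Declination ϑ** is the angle of the major axis measured from the +y
  (anterior–posterior) axis toward +x (the participant's left), i.e. a
  leftward tilt is positive. The major axis is an axis, not a ray; before
  the angle is computed its eigenvector is canonicalized to a nonnegative y
  component (and +x when y = 0), which removes solver-dependent sign flips.
  ϑ lies in (−90°, 90°]; an exactly lateral axis is reported as +90° so the
  boundary case remains representable.
- **Ties.** When the two eigenvalues coincide (relative gap ≤ 1e−12) the
  orientation is unidentifiable; the fit reports ϑ = 0 and Ψ = 0 (the
  physiologically neutral midline) and sets a `degenerate_orientation` flag.
- **Rank-1 covariance** (all variance on one axis) yields a valid ellipse
  with short diameter 0 and eccentricity exactly 1, flagged `degenerate`;
  containment queries are refused for it. A record whose points are all
  identical has no ellipse and raises an error.
- **Eccentricity** ε = √((a²−b²)/a²) is ratio-invariant: full or semi
  diameters give the same value.
- **Lateral component** Ψ = sin(ϑ)·δ/2 inherits the sign of ϑ and is
  bounded by the semi-diameter.

The estimator is exposed scikit-learn style (`ProbabilityEllipseModel`,
`fit`/`predict`/`mahalanobis`/`score_samples`, `get_params`/`set_params`,
fitted attributes with trailing underscores) so it composes with sklearn
tooling; `predict` uses the inlier convention (+1 inside, −1 outside) of
`EllipticEnvelope`. Equivariance properties are tested to 1e−9: rotating
the data by φ changes ϑ by −φ (wrapped on the axis circle), scaling by c > 0
scales δ and Ψ by c and leaves ϑ and ε unchanged, translation moves only the
center.

## Cohort evaluation

- **Outlier exclusion.** The per-participant statistic is the maximum
  absolute lateral component over quiet-stance (silent-condition) records.
  Participants strictly outside the Tukey fences Q1 − 1.5·IQR / Q3 + 1.5·IQR
  (quartiles by linear interpolation) are excluded; a value exactly on a
  fence is retained. Re-applying the rule with frozen fences to the
  retained set is a no-op; recomputing fences on the retained set may
  exclude further participants and is deliberately not iterated.
- **Effects of stimuli** are ratios (second/first) for eccentricity and long
  diameter and differences (second − first) for declination and lateral
  component, both for the background-vs-array contrast and for trial 1 vs
  trial 2 within each headphone condition. Trials are never pooled.
- **Paired inference.** The headline comparison is the first-trial paired
  two-sided t test of declination, array-only vs each headphone condition:
  t = mean(d)/(sd(d)/√n), d = a − b, sd with denominator n−1, CI at 0.95 by
  the Student quantile. Second-trial contrasts are computed and reported
  but not flagged as headline. Raw p values are reported; a Holm adjustment
  across the three first-trial contrasts is available as an option.
  Degenerate inputs: identical samples give t = 0, p = 1, CI (0, 0) with a
  `degenerate` flag; a constant nonzero difference gives t = ±∞ with p
  undefined (NaN).
- **Normality diagnostics** of the paired differences: the exact one-sample
  Kolmogorov–Smirnov test of the self-standardized differences against the
  standard normal, and the Shapiro–Wilk test. Because the normal parameters
  are estimated from the same sample, the exact KS p value is conservative
  (no Lilliefors correction is applied); Shapiro–Wilk is the stricter guard.
- **CI reconstruction.** `ci_from_summary` recovers a confidence interval
  from printed summary numbers via se = |mean difference / t|; feeding back a
  fitted test's own summary reproduces its CI to 1e−9.
- **Counterbalancing.** The six permutations of the three headphone
  conditions are assigned round-robin over participants in order (n/6 each
  when divisible, remainder round-robin with a warning), optionally shuffling
  the permutation list with a seed.

## Virtual-impact model

Defaults: array speakers 1 m left and right of the midline (D = 2 m) scanned
in 1 s → 2 m/s; inter-auricular distance L = 0.20 m with an assumed
effective scan of 0.5 s → 0.4 m/s; inner-ear separation 0.12 m over 0.5 s →
0.24 m/s. Impact = effective mass (default 100 kg = 1 kg unit mass × 10²)
times speed: 200 / 40 / 24 kg·m/s, so devices rank ears-free > closed >
bone. The 0.5-s effective scan time is an assumption, not a measurement,
and is exposed as a parameter. Note the inner-ear arithmetic is not fully
self-consistent in the source geometry (L of 20 cm minus 6 cm of ear canals
is 14 cm, not 12 cm); 0.12 m is kept as the authoritative default because
the 0.24 m/s and 24 kg·m/s figures depend on it. The bone-conduction tissue
path (0.03 m at 1,500 m/s, the speed of sound in water) gives a 0.02-ms
travel time, an equivalent rate of 50 kHz.

## Synthetic cohort generator

The generator emulates the reference protocol: 60-s records at 100 Hz
(the sampling rate is a package default — typical for consumer-balance-board
stabilometry, whose true rate is device-dependent — and is configurable);
five conditions (quiet stance, array speakers only, and the array combined
with bone-conduction, closed, and ears-free headphones); one record for the
first two conditions and two trials for each headphone condition; ten 1,000-ms
pannings per record, alternating left-to-right / right-to-left, separated by
5-s pauses.

**Baseline.** Each axis is an exact-discretization stationary
Ornstein–Uhlenbeck process, independent across axes, with stationary SDs
σx = 2.2 mm (lateral) and σy = 4.9 mm (AP) and time constant τ = 0.4 s.
These defaults reproduce quiet-stance ellipses with ε ≈ 0.89 and δ ≈ 21 mm,
matching the population the method targets. Sample SDs of 60-s records stay
within 10% of the configured values on average.

**Participant heterogeneity.** Each participant carries a lognormal sway
scale multiplier (σ = 0.10, applied to both axes), a lognormal response-gain
multiplier (σ = 0.30), and a habitual stance-tilt trait that rotates the
baseline covariance, drawn **uniformly** in ±20°. The uniform bound, rather
than a Gaussian trait, is a deliberate design choice with two grounds: the
implied cross-participant quiet-stance declination SD (≈ 11.5°) matches
observed cohorts, and a bounded trait keeps healthy participants' lateral
components inside the Tukey fences so the box-plot rule isolates a genuinely
pathological participant. With Gaussian-tailed traits the 1.5·IQR rule on a
30-participant cohort flags roughly half an extra participant per cohort on
average — the filter would then not be a reliable one-outlier detector, which
is the behavior the pipeline is designed around. Screened healthy young
adults standing on marked foot positions with a gaze point plausibly have
bounded habitual asymmetry; this is what the trait models.

**Stimulus response.** Each panning onset adds a transient displacement
g·m·h^(trial−1)·exp(−t/1.0 s) along an axis tilted 45° from the AP midline,
with sign following the panning direction (left-to-right pannings push
leftward). The 45° tilt encodes that an evoked lean has both lateral and
anterior components. This coupling is essential: with independent baseline
axes, a *purely lateral* zero-mean alternating response adds only lateral
variance, leaves cov(x, y) at zero, and therefore cannot move the mean
declination at all — it would only widen the ϑ distribution symmetrically.
A tilted response axis adds variance along that axis, rotating the fitted
ellipse toward it. A consequence of this variance-mixing mechanism is that
the mean declination shift scales *quadratically* in the gain in the
small-gain limit (tan 2ϑ is proportional to the added variance, hence to
g²), not linearly; the tests assert the quadratic scaling.

**Condition gains.** Per-stimulus gains follow the virtual-impact ratios:
ears-free 7.25 mm, closed 7.25·(40/200), bone 7.25·(24/200); quiet stance
and array-only have zero gain (the array-only condition serves as the
reference and shows no lateral tilt). The ears-free gain is calibrated once
so the cohort mean declination shift (array-only vs ears-free, first trials)
is ≈ +7°, the effect size the paired test is powered for: at n = 29 the test
rejects at α = 0.05 in essentially every replicate cohort (asserted ≥ 80%
over 200 cohorts), while with all gains zero the rejection rate is the
nominal 5% (asserted 5% ± 2% over 1,000 cohorts, a replicate count chosen to
keep the binomial standard error near 0.7%).

**Habituation.** Second-trial response amplitudes are multiplied by
h = 0.5; the attenuation factor is a free default (the direction —
a weaker second-trial response — is the modeled phenomenon, its exact size
is not).

**Outlier participant.** Optionally one participant (seeded choice,
recorded in the ground truth) has her lateral baseline SD inflated ×3,
which flips her quiet-stance ellipse to lateral-dominant and produces a
lateral component (≈ 14 mm) far above the cohort fences.

**Determinism.** Every (participant, condition, trial) record draws from
its own substream derived from the single cohort seed, so cohorts are
bit-reproducible and insensitive to generation order.

**Ground truth and recovery.** For every record the generator can state its
exact population covariance (rotated baseline plus the response kernel's
empirical variance along the response axis), hence exact population values
of all four descriptors. `parameter_recovery` compares fitted
condition-level declination and lateral-component shifts against these
population contrasts; the recovered ears-free shift stays within 1.5° of
truth averaged over replicate cohorts at n = 29.

## What the generator does and does not emulate

It reproduces: AP-dominant quiet stance with realistic ellipse descriptors,
stimulus-locked lateral responses ordered by device impact, habituation,
between-participant heterogeneity, counterbalanced orders, and a
box-plot-detectable outlier. It does **not** emulate: non-Gaussian or
nonstationary real COP dynamics (drift, intermittent corrective torques,
long-range correlations), device-specific measurement noise or filtering
(none is applied anywhere — whether acquisition software filters before its
ellipse computation is unknown, so no filtering is assumed), fatigue across
the session, or any acoustics. Passing tests therefore validate the
*pipeline* — estimator correctness, calibration, power at the design effect
— not the physiological realism of any particular cohort.

## Numerical choices and problem sizes

- Covariance uses denominator n−1 (immaterial at ~6,000 samples per record,
  but fixed so exact-value tests are well-defined).
- Trajectory CSVs are written with 12 significant digits; round trips
  reproduce coordinates to better than 1e−9 mm.
- Isotropy/rank tie tolerances are relative 1e−12 on the eigenvalue gap.
- Fitted eccentricity is biased upward on finite records (sample eigenvalues
  always split), so an isotropic process yields mean fitted ε ≈ 0.4 at the
  default record length rather than 0; tests assert the drop below the
  AP-dominant value, not ε = 0.
- Calibration checks use 50,000-point samples for coverage, 100 ellipses ×
  1,000 points for the Mahalanobis-vs-geometry oracle equivalence, 200
  replicate cohorts for power and 1,000 for type-I error — sizes chosen to
  keep Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- The exact KS p value on self-standardized differences is conservative
  (estimated parameters); it is reported because it is the conventional
  companion statistic, with Shapiro–Wilk as the stricter test.
- The Tukey-fence rule on a ~half-normal statistic (an absolute value) has a
  nonzero false-positive rate even with the bounded trait (roughly 4% of
  30-participant cohorts exclude a second participant); downstream code
  treats the retained set, not the number 29, as authoritative.
- Ellipse descriptors assume an approximately stationary bivariate-normal
  record; heavy drift or multimodal sway violates the model and shows up as
  inflated diameters rather than a diagnostic.
- The virtual-impact model is a deliberate heuristic ranking device
  stimulation strength; it is not a biomechanical quantity.
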