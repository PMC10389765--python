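# Methods

`swaymetrics` re-implements, as a tested pipeline, a multi-metric
postural-control analysis: a subject stands on a motion platform wearing
a VR headset through a fixed 320 s protocol — 120 s stationary baseline,
a 40 s quiet-standing **PRE** phase (visual sea scene only), three 40 s
platform-motion phases at 25/50/75 % wave amplitude, and a final 40 s
quiet-standing **POST** phase — while centre-of-pressure (CoP, 90 Hz),
six-channel lower-limb surface EMG (1600 Hz), 64-channel EEG (4096 Hz)
and heart rate (1 Hz) are recorded.  Two cohorts (healthy controls and
early-stage Parkinson's disease) are compared feature-by-feature in the
PRE and POST phases.

Because no raw recordings are publicly deposited, the package ships a
seeded synthetic cohort generator with known, programmed effect
directions.  Every statistical claim the test suite makes is therefore a
claim about *method correctness and recovery of programmed effects*, not
about any clinical dataset.

## Phase segmentation

Time runs in seconds from recording start; phase windows are half-open
`[start, end)` and sliced by sample index
`[floor(rate*start), floor(rate*end))`, so concatenated phase slices
reconstruct the scheduled span exactly at every sampling rate.

## Signal conditioning

* **EMG** — zero-phase (forward–backward) 4th-order Butterworth
  band-pass, 20–450 Hz, the surface-EMG convention.  Features are
  computed on the filtered signal, not an envelope.
* **CoP** — Savitzky–Golay smoothing, window 7 samples, polynomial
  order 3 (the common stabilogram choice; order 3 reproduces cubic
  trajectories exactly).  Endpoints use the polynomial fit on the
  truncated window.  Features are computed on the smoothed trajectory.
* **EEG** — anti-aliased FIR decimation 4096 → 1024 Hz, then a
  zero-phase 1–45 Hz 4th-order Butterworth band-pass.  Channels that are
  flat, or whose median absolute amplitude exceeds the channel median by
  more than 5 MAD-scaled robust SDs, are replaced by the mean of the
  remaining channels and flagged in metadata (more than 50 % bad
  aborts).  This amplitude gate is a deliberately simple, documented
  stand-in for interactive/classifier-based artifact screening and for
  montage-geometry interpolation; it is switchable off.

## Feature batteries

**Stabilogram (35 features).**  The trajectory is centred on its
per-phase mean, which defines the origin.  Path statistics: total
excursion `TOTEX = Σ√(ΔML²+ΔAP²)` and per-axis variants; mean and RMS
distances (`RD`, `MDIST-·`, `RDIST-·`); mean velocities
(`MVELO = TOTEX / ((n−1)/rate)`); axis SDs; SD of displacement
magnitudes and of displacement directions (computed on increments —
"direction of a centred position" is ill-defined).  The 95 % confidence
ellipse comes from the eigen-decomposition of the 2×2 sample covariance
with semi-axes `√(λ_i · χ²₂(0.95))`; the quantile is computed, not
hard-coded, and coverage is verified against simulation.  Displacement
magnitude/direction Shannon entropies use 36 equal-width bins
(10° angular bins).  Directional extremes report the farthest sample in
each half-plane (antero AP>0, postero AP<0, left ML<0, right ML>0).

**Sample entropy and complexity.**  `SampEn(m, r) = −ln(A/B)` with
template length `m = 2`, Chebyshev tolerance `r = 0.15·SD`, self-matches
excluded; undefined values (zero match counts) are returned as NaN and
excluded from group statistics.  Multiscale entropy coarse-grains by
non-overlapping window means at scales 1..10 with `r` anchored to the
scale-1 SD (the classic convention; per-scale re-estimation is a
documented alternative the paper trail does not settle).  The complexity
index (CI) is the sum over scales.  The bivariate CI embeds both axes
into one composite delay vector (`m` lags each); the conditional stage
averages matches over the two single-channel extensions, making the
statistic symmetric under channel swap.  Kernels are numba-compiled
O(n²) direct counts; the tests compare them against an independent
pure-Python enumeration oracle.

**Surface EMG (43 features per muscle and phase).**  Seven spectral
features from a Welch periodogram (2 s Hann, 50 % overlap): total and
peak power, peak/median/mean frequency, spectral kurtosis and skewness.
Thirty-six time-domain features with the standard definitions (MAV, WL,
SSI, RMS, zero-mean VAR, difference statistics, log detectors,
Teager–Kaiser energy, windowed variants with full weight on the central
half of the segment, a threshold zero-crossing count at 0.01·RMS, and
robust moments).  Where the literature admits variants (ASM, ASS, MSR,
VARE, VO) the definition used is stated in the code: ASM/ASS are sums of
cube/square roots of |x|, MSR the mean square root, VARE the ordinary
sample variance about the mean (vs the zero-mean VAR), VO the third
v-order statistic `(E|x|³)^{1/3}`.  These are package choices, not
community standards.  Every feature carries a scaling law
(homogeneity table) asserted in the tests.

**EEG band power.**  Welch PSD (2 s Hann, 50 % overlap, 0.5 Hz
resolution) on each preprocessed phase segment; absolute band power is
the trapezoidal integral over δ (0–4], θ (4–8], α (8–13], β (13–30] Hz.
Adjacent bands share edge bins, so band powers partition the total
exactly.  Absolute (not relative) power is the default.

## Group comparison

Per feature: Shapiro–Wilk on each group; Welch's unequal-variance t-test
if both groups look Gaussian (p > 0.05), otherwise the two-sided
Mann–Whitney U-test (exact enumeration when both n ≤ 8 without ties,
mid-rank/tie-corrected normal approximation otherwise).  The "visual
inspection" component of normality checking is not automatable; the
both-groups Shapiro rule is the strictest literal policy and is a config
key.  Cliff's delta is always computed by full pairwise enumeration,
with "large" meaning |δ| > 0.42 and the conventional 0.147/0.33 cut-offs
below that.  EMG/CoP/HR families are tested at raw p < 0.05 with no
multiplicity correction (an optional FDR switch exists); the EEG
topographic branch applies Benjamini–Hochberg FDR across the 64
electrodes of one (band, phase) family and flags adjusted p ≤ 0.05.
Healthy is always the first group, so positive delta = healthy larger.
The empirical type-I error of the gated procedure at the study's group
sizes (29 vs 9) is verified to sit inside the binomial 95 % band around
0.05 under Gaussian and lognormal nulls.

## Synthetic cohorts

The generator emulates the *reported effect directions*, not the
physiology; its defaults are the study conditions (29 healthy, 9 PD):

| quantity | healthy | PD | rationale |
|---|---|---|---|
| CoP sway SD (mm) | 3.0 | 2.0 | reduced sway in PD |
| ML white-jitter weight | 0.3 | 0.7 | higher medio-lateral complexity in PD |
| right-TA EMG gain | 1.3 | 1.0 | healthy-larger right-TA amplitudes |
| α power factor at FC5, T7, T8, FT8, P4, PO6 | 1.0 | 0.5 | PD alpha suppression |
| HR mean (bpm) / POST trend | 82.5 / +0 | 88.8 / +5.4 | PD HR higher, rising after motion |

CoP sway is a discretised Ornstein–Uhlenbeck process per axis
(mean-reversion time 1 s; stationary SD = the sway scale) — stationary,
two-parameter, and with SD and complexity independently tunable, which
fractional-Brownian models are not.  The ML channel is a convex mixture
of a smooth OU component and white jitter, rescaled to the target SD.
EMG is 20–450 Hz band-limited Gaussian noise (synthesised in the
frequency domain) modulated by a smooth positive burst envelope.  EEG is
a 1/f background (PSD 20/f µV²/Hz, synthesised 0.5–120 Hz; content
above is negligible and removed by the 1–45 Hz analysis band) plus one
random-phase spectral line per band (2, 6, 10.5, 21.5 Hz; base
amplitudes 6/5/10/3 µV); the per-(electrode, band) group factor
multiplies that line's power.  Heart rate is a per-subject baseline plus
slow AR(1) wander, with the POST trend added in that phase.

Between-subject variability makes the cohorts overlap: log-normal
jitters on sway scale (σ=0.25), EMG gain (σ=0.2), EEG global amplitude
(σ=0.15) and per-band amplitude (σ=0.1); additive jitter on the ML
complexity weight (SD 0.08, clipped to [0,1]); HR baselines spread with
the reported between-subject SDs (14.6 / 18.1 bpm).  The EEG sigmas were
set from a direct power calculation so that the programmed α-suppression
construction is recoverable after BH-FDR at the study's group sizes
(per-seed recovery ≈ 0.8) while null electrodes stay controlled; larger
sigmas would make the generator's own advertised construction
undetectable at n = 38.

Determinism: every stream derives from
`SeedSequence([seed, group, subject_index, stream, phase_index])`, so
adding subjects never reshuffles existing ones, and each scheduled phase
is an independent stationary block.  Phase boundaries coincide with
segmentation boundaries, so generating a phase in isolation is
bit-identical to slicing the full session — which is what lets the
pipeline materialise only the phases it analyses.

What the generator does **not** emulate: neuromuscular coupling between
modalities, platform kinematics, non-stationarity within a phase,
electrode covariance structure, artifacts, or motion sickness.  Passing
recovery tests therefore demonstrate that the pipeline detects effects
of the programmed kind at the study's sample sizes — nothing more.

## Numerical choices and degenerate inputs

* Constant series: tolerance floored at 1e-12 so SampEn is exactly 0;
  EMG moment features fall back to 0; all-tied comparisons record p = 1
  with a flag.
* Collinear sway clouds: degenerate ellipse (minor axis and area 0),
  flagged.
* Log-family EMG features guard exact zeros with a denormal floor
  (1e-300) rather than erroring on silent channels.
* Ellipse angle mapped to (−90, 90] CCW from +ML; empty half-planes
  yield magnitude 0 with NaN angle.
* CSV round-trips write 10 significant digits (relative error < 1e-9).

## Problem sizes used in the test suite

Unit tests run on miniature schedules (the 320 s protocol scaled 1/8 or
1/64) and short series; oracle comparisons use series up to length
200–3600.  The calibration checks use 100,000-point ellipse clouds and
2,000-replicate null simulations at n = 29 vs 9.  The end-to-end
recovery check runs the full study conditions — 29/9 subjects at native
rates, POST phase, 10 independent seeds — and requires each programmed
effect (a healthy-larger sway distance, PD-larger ML complexity index,
and at least one suppressed α electrode surviving FDR) to be recovered
in a majority of seeds.

## Known limitations

* The EMG feature mnemonics without published formulas are implemented
  as documented best guesses; comparisons across implementations of
  those five features are not meaningful.
* The artifact gate is amplitude-only; it cannot emulate ICA-based
  classifiers, and flagged channels are mean-replaced rather than
  spatially interpolated.
* The gated test's type-I error is verified marginally per feature; the
  EMG/CoP families are deliberately uncorrected for multiplicity, so
  family-wise error grows with family size exactly as in the analysis
  being re-implemented.
* Multiscale entropy at scale 10 on 40 s of 90 Hz CoP rests on 360
  coarse-grained samples; entropy estimates at the deepest scales are
  noisy and occasionally undefined (then flagged and excluded).
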