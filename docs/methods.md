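# Methods

This note documents the models, estimators, numerical choices, and
design decisions behind `chemofc`, and what the synthetic-data tests do
and do not establish about real recordings.

## LFP preprocessing and spectral estimation

**Periods.** The pre-injection window is the 10 min up to the injection
timestamp; the post-injection window starts after the drug waiting
period (15 min for DCZ/vehicle, 30 min for CNO) and lasts 20 min.
Reduced-scale runs may configure shorter windows; every window must hold
at least fifty non-overlapping 4-s slots.

**Bipolar referencing.** Sites are differences of neighboring contacts
within an array (16 contacts → 15 sites), which cancels any signal
common to adjacent contacts exactly. Noisy-site rejection is automated
for reproducibility: a site is rejected when its RMS exceeds 5× the
median RMS of its array or its 60 Hz power exceeds 10× the array
median. These thresholds replace visual inspection; on clean synthetic
data they reject nothing, and they catch single-site broadband (20× RMS)
or line-noise contamination.

**Filtering.** Band-pass 0.5–200 Hz plus 2-Hz-wide band-stops at 60,
120, 180 Hz, all 4th-order Butterworth. The default implementation
multiplies the squared magnitude response |H(f)|² of the cascade onto
the signal spectrum, which is the steady-state forward–backward
(zero-phase) response without edge transients; a time-domain
`sosfiltfilt` path is available and agrees away from the edges.

**Trials and repetitions.** Each repetition draws 50 slots uniformly
without replacement from the fixed non-overlapping 4-s grid of a period,
with a per-repetition sub-seed. Spectral coefficients are computed once
per slot and indexed by repetitions — numerically identical to
transforming each repetition separately (asserted in a test) and the
reason the Monte-Carlo calibrations are affordable.

**Multitaper.** DPSS tapers with time–bandwidth product T·W = 4 s ×
1 Hz give 2·T·W − 1 = 7 tapers, all with concentration > 0.9. The
analysis grid is 1–100 Hz at 0.5 Hz; on 4-s windows the native DFT
resolution is 0.25 Hz, so the grid is every other native bin and no
zero-padding or interpolation is involved. With unit-norm tapers the
one-sided PSD is 2|X|²/fs, which satisfies Parseval on band-limited
input within the tested 5 %.

**Power statistics.** Post-injection power is z-scored per frequency bin
by the mean and SD across the pre-injection repetitions. Per-bin tests
are Wilcoxon signed-rank (zeros dropped, ties mid-ranked) across
repetition values per site, pooled across sites by default — the pairing
unit is exposed as an argument because the choice is genuinely open.
Significance requires p < 0.01 in at least 5 consecutive bins; under
i.i.d. uniform p this family-wise rule fires in fewer than 1 % of
199-bin spectra (Monte-Carlo, 10⁴ draws).

## Imaginary coherency and the band of interest

Cross-spectra pool 50 trials × 7 tapers (350 degrees of freedom per
repetition); coherency is normalized per repetition and then averaged
across repetitions. The imaginary part is used throughout because it
vanishes for zero-lag (volume-conducted) coupling: for two unit-coherence
signals with phase lag φ it equals sin(φ) exactly (closed-form test at
10⁻³).

**Permutation null.** For every repetition a matched null re-orders each
site's 50 trials independently before the cross-spectra, destroying
cross-site association while preserving trial content, taper set, and
grid. Observed and null coherograms are compared per amygdala–vlPFC
site pair with signed-rank tests per bin (pair values pooled over
periods), masked by the 5-consecutive-bin rule. At least 6 pairs are
required. Contralateral-amygdala sites are excluded from inter-areal
pairing.

**Band extraction.** The grand-average amygdala–vlPFC profile (averaged
over pairs, periods, and conditions) is scanned inside the significance
mask; the peak is the largest |value| (ties resolved toward the lower
frequency) and the band is the contiguous run around the peak where the
profile stays at or above one third of the peak, with a 10⁻⁹ relative
tolerance so exact one-third crossings land inside the band. Band
extraction uses the magnitude of the pair-averaged profile so the result
does not depend on the sign convention of the lag. Cross-subject
combination takes the minimum low edge and maximum high edge; the
combined peak is reported as the grid-rounded mean of subject peaks
(reporting only — downstream averaging uses the edges).

**Drug comparison.** Per amygdala site, band coherency is averaged over
band bins and all vlPFC sites, and the pre-injection value subtracted
from the post-injection value. These per-site changes enter a two-way
type-II ANOVA (condition × subject plus interaction).

## Spike analysis

Rates are counts in 30-s bins divided by the bin width (plain counts;
no kernel smoothing — the 4-bin moving average in `plotting` is display
only). z-normalization uses the pre-period mean and population-(n)
SD; silent units (zero pre SD) are excluded with a log entry. A unit is
modulated when |z| > 1.96 in at least 4 post bins; the bins are **not**
required to be consecutive (a config flag enables the consecutive
variant). Direction is the majority sign of super-threshold bins, exact
ties giving "none".

**Calibration.** When the post-bin z are i.i.d. standard normal — i.e.
the baseline is known — the false-positive probability is exactly
P(Binomial(40, 0.05) ≥ 4) ≈ 0.138, and the Monte-Carlo calibration in
the acceptance suite reproduces it. With the standard 20-bin estimated
baseline the realized rate on stationary Poisson units is substantially
higher (≈ 0.3–0.4), because the estimated mean and SD inject correlated
errors into all 40 post-bin z values; the calibration experiment
therefore uses an extended baseline so normalization error is negligible
and the exact binomial reference applies. This inflation is a property
of the criterion itself, worth remembering when interpreting modulated
fractions from short baselines.

The modulated-proportion model is a logistic regression with
area × condition fixed effects and a random animal intercept, fitted by
variational Bayes (`BinomialBayesMixedGLM`); the reported statistic is
posterior mean / posterior SD against a normal reference. Separated
designs (an all-0 or all-1 cell) fall back to an L2-penalized
fixed-effects logit, flagged in the output.

## rs-FC analysis

Runs are demeaned and variance-normalized per voxel within each run and
concatenated within a period. Seed maps are Fisher-z (atanh, clipped at
|r| = 1 − 10⁻⁷) correlations with the seed-mean series; constant voxels
map to z = 0 with a warning count. The drug contrast is
[drug(post − pre)] − [vehicle(post − pre)], computed voxelwise or on
ROI×ROI connectome matrices (session-averaged inputs supported).

**Voxelwise p and clustering.** Each per-condition map difference is a
difference of Fisher-z values with variance ≈ 1/(n − 3) each (n =
concatenated in-period timepoints), so the difference of differences is
referred to a normal with variance 4/(n − 3). BH-FDR at q = 0.05 runs
on the two-sided p over the mask; surviving voxels additionally pass the
cluster-forming threshold p ≤ 0.0485, are split by sign, connected with
6-neighbor (face) adjacency, and components under 30 voxels are
dropped. The 29/30-voxel boundary is exact and tested. No MION sign
inversion is applied anywhere; with MION contrast the raw BOLD sign
convention is inverted, but a consistent convention cancels in every
difference this package computes.

**Connectome ANOVA.** Per-session (post − pre) ROI-pair changes enter a
two-way type-II ANOVA (condition × subject) with the ROI pair as a
categorical blocking term — in a balanced design this yields the same F
for the fixed factors as modeling the pair as a random effect, and it
keeps an interpretable ANOVA table. Session is nested within subject by
construction of the long table. Voxel-pooled global tests use the same
two-way ANOVA on voxelwise changes (one row per voxel per session),
matching whole-brain degrees-of-freedom conventions.

**Voxel-pair analysis.** For each amygdala voxel the mean Fisher-z over
all vlPFC voxels is computed per period; hemispheres are analyzed
independently (masks restricted to the x-midline halves on the synthetic
grid; real data would supply hemisphere masks directly).

## Stereology

Expression is the pooled ratio 100 × DAB-positive / Nissl-positive,
rounded half-even to two decimals (raw doubles retained in tables). The
optical-fractionator sampling geometry is metadata; the pooled ratio is
the quantity reported, and it is scale-invariant. Worked values:
(399, 7998) → 4.99 % and (533, 10239) → 5.21 %.

## Synthetic-data generator

The generator produces the statistical structure the analyses assume,
not biophysical realism.

* **LFP.** Per-contact independent 1/f noise (white noise shaped to
  power ∝ 1/f above 0.5 Hz, flat below; unit total variance), a common
  60 Hz sinusoid, and a shared narrow-band oscillation with a Hann
  power envelope over the coupling band (default 9–12 Hz). The
  oscillation is built as a complex analytic signal so the vlPFC array
  receives an exact constant phase lag (default π/4). Contacts carry it
  with a large common-mode factor plus a unit per-contact gradient, so
  bipolar referencing attenuates but does not remove it — matching the
  observation that inter-areal coherency survives bipolar referencing.
  `coupling_gain` is defined as the in-band power SNR at the bipolar
  site level (default 4, the "documented SNR" of the recovery
  experiments); drug conditions scale the post-injection SNR by 1.5 by
  default. The ground-truth band is derived in closed form: site-level
  coherence c(f)/(1 + c(f)) with c(f) = SNR · E(f) · f/f_c (the 1/f
  background tilts the in-band SNR), times sin(lag), averaged over the
  period plan, smoothed by a ±1 Hz boxcar standing in for the taper
  bandwidth, then the same FW(1/3) rule. Recovery within one 0.5 Hz
  grid step is the tested property.
* **Spikes.** Homogeneous Poisson units (default 5 Hz); under a drug
  condition a configured fraction (default 0.3) multiplies its rate by
  `rate_step` (default 2) from the injection timestamp; vehicle sessions
  are stationary. Ground truth lists the stepped units and direction.
* **BOLD.** Six cuboid ROIs tile a 24³ grid (x-halves × y-thirds:
  amygdala/vlPFC/control, left and right). ROI latent series follow a
  correlation matrix (baseline 0.1 off-diagonal, 0.3 on the ipsilateral
  amygdala–vlPFC pairs); voxels are their ROI latent plus unit i.i.d.
  noise. Under DCZ the coupled pairs gain `delta_r` (default 0.2) in
  post-injection runs only; the expected Fisher-z increment includes the
  small ROI-mean attenuation 1/(1 + σ²/V). Non-positive-definite
  matrices after the increment are rejected.
* **Stereology.** Binomial DAB counts at a configured expression
  probability against fixed Nissl totals.

All draws come from seeded generators with sub-seeds derived
deterministically from (seed, generator kind, condition, session index);
fixed configs are byte-identical across calls.

**What the synthetic tests do not show.** The generator has no
hemodynamic response, scanner noise, head motion, anatomy, volume
conduction geometry, spike-waveform variability, or cross-frequency
structure; passing tests demonstrate that the estimators and decision
rules recover the structure they assume at realistic SNR, not that
preprocessing of real data is adequate.

## Problem sizes of the calibration experiments

Chosen as the package's own desk-scale defaults: null calibration uses
100 uncoupled sessions (2 arrays × 4 contacts, 240-s periods, 8
repetitions — 9 inter-areal pairs, comfortably above the 6-pair
minimum); band recovery uses 50 coupled sessions (6 contacts/array,
600-s periods, 10 repetitions); modulation calibration uses 2500 null
units and 200 stepped units; connectome recovery uses 2 sessions per
condition at the full 3 × 300-volume design. The open-ended parameters
(repetition count, session counts) trade Monte-Carlo precision against
runtime and are fixed here once; the per-paper parameters (50 trials of
4 s, 7 tapers, 30-s bins, thresholds) are never scaled.

## Known limitations

* Real multi-session designs with per-session accepted-site bookkeeping
  are supported by the data structures but the orchestration pipeline
  (`run_pipeline`) demonstrates a single synthetic session pair.
* The variational mixed-logistic fit understates posterior variance in
  extreme designs; with only two animals the random intercept is weakly
  identified regardless of fitter.
* The FFT filter path assumes stationarity across the recording; the
  `sos` path should be preferred for signals with large transients.
* Coherency significance treats site pairs as exchangeable observations;
  spatial correlation between neighboring bipolar sites makes the
  signed-rank test somewhat liberal at the bin level, which the
  consecutive-bin rule and the session-level calibration (≤ 5 % false
  band declarations) absorb.
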