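# Methods

This note documents the models, estimators and design decisions behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Calcium imaging

**Signal model.** An ROI's raw fluorescence is treated as
`F(t) = F0·(1 + ΔF/F(t)) + c·B(t) + ε(t)`, where `B` is out-of-focus
neuropil background, `c` its coupling into the ROI, and `ε` frame noise.
The neuropil channel `Fn` measures `B` plus its own noise. Processing:

1. **Neuropil correction.** `Fcorr(t) = F(t) − 0.7·Fn(t)`. The 0.7
   coefficient is the conventional scaling for somatic ROIs; it is a
   parameter (`neuropil_coef`) because the optimal value depends on optics
   and indicator. Negative corrected frames are retained, never clipped —
   clipping would bias the baseline estimate.
2. **Baseline.** `F0` is an iteratively clipped mean: recompute mean and SD
   excluding samples more than 2 SD *above* the current mean until the mean
   converges (tolerance 1e-6, ≤ 50 iterations). One-sided clipping
   down-weights positive-going transients while keeping the noise floor.
   ROIs whose baseline resolves ≤ 0 cannot be normalised and are excluded
   with a logged reason.
3. **Noise floor.** The ΔF/F noise SD is 1.4826 × the median absolute value
   of samples at or below the baseline. Sub-baseline samples form a
   half-normal sample untouched by transients, and 1.4826 × their median
   absolute value recovers σ for Gaussian noise. A constant trace yields
   noise SD 0 (and no events); a zero noise SD on a non-constant trace is
   an estimation error, not a silent pass.
4. **Detection.** An event is a maximal run of frames above
   `2 × noise SD` lasting at least `min_duration_frames` (default 3 frames,
   100 ms at 30 Hz); onset is the first frame of the run, the peak its
   argmax. `detect_transients` implements exactly this contract and is
   tested against a brute-force scan on tens of thousands of random traces.
5. **Curation surrogate.** Frame-wise thresholding of noisy traces has two
   known failure modes: isolated noise crossings (false events) and single
   noisy frames dipping below threshold mid-transient (one event fragments
   into several — empirically a ~2.7× count inflation at SNR 5). Manual
   curation usually repairs both; `analyze_recording` instead applies two
   explicit, documented steps before the detector: the detection trace is a
   centred 5-frame (167 ms) moving average of ΔF/F while the threshold
   stays at 2× the *raw-trace* noise SD (so smoothing raises the effective
   threshold in smoothed-noise units, suppressing false crossings), and
   suprathreshold runs separated by fewer than 10 frames (333 ms) are
   merged. With these defaults the simulated hyperactive fraction (15%,
   4 transients/min, SNR 5) is recovered to within ~1.5 percentage points
   and the median per-ROI rate error is zero.
6. **Classification.** Exactly 0 transients/min → *silent*; strictly more
   than 3/min → *hyperactive*; otherwise *normal*. The boundaries are
   deliberately strict: a rate of exactly 3.0/min is normal.
7. **Summaries.** Hyperactive/silent percentages are computed per animal
   (the unit of replication); transient rates are pooled across all cells
   of a group for cumulative-distribution plots (right-continuous ECDF).

**Resolution limit.** A threshold detector cannot separate transients whose
suprathreshold excursions overlap; the excursion lasts roughly
`decay × ln(amplitude / threshold)`, so very bright events merge over wider
windows. Perfect class recovery on synthetic data therefore requires the
hyperactive rate to sit away from the 3/min boundary relative to these
merge losses; at 4/min and SNR 5 the recovered percentage sits ~1.5 points
below truth, a bias the tests measure rather than hide.

## Spike units

The violation fraction of a unit is `#{ISI < 2 ms} / (n_spikes − 1)`; the
denominator is the ISI count (the natural sample size for ISIs; stated
explicitly because "spikes violating" is ambiguous) and is what the QC
compares against the strict 1% bound — a fraction of exactly 0.01 fails.
Ties at exactly 2.000 ms are non-violations. Units with fewer than two
spikes are unassessable and excluded with a log message.

Depth bins are inclusive on both ends (superficial 0–400 µm, layer 5
550–800 µm); the 400–550 µm gap and anything deeper than 800 µm is
unassigned and excluded from binned summaries. Mean firing rate is the mean
of spike counts over 1-s bins divided by the bin width — identical to
`n_spikes / duration` whenever the bin width divides the duration (a
trailing partial bin is dropped and logged). Zero-rate units are excluded
from log₁₀ distributions (no flooring) and counted separately, because
log₁₀(0) is undefined and distributions are summarised as medians and
quartiles on the log scale.

## LFP

Each channel is low-pass filtered and decimated from 2.5 kHz to 500 Hz with
an 8th-order Chebyshev Type 1 IIR filter (0.05 dB passband ripple, cutoff
0.8× the output Nyquist) run forward–backward for zero phase — the standard
decimation filter, via `scipy.signal.decimate`. The decimation factor must
be an integer.

**Referencing.** Subtracting the across-channel mean (CAR) and then
averaging *the same* channels returns an identically zero trace — the mean
of mean-subtracted rows is zero. The meaningful version of "CAR then
average" references the averaged cortical channels against probe sites
*outside* the averaged set: `preprocess_lfp` takes the reference mean over
non-cortical channels (depth > 800 µm by default) and averages the
referenced cortical channels. Without depth information the common-mode
subtraction is skipped with a warning rather than silently nulling the
signal. `common_average_reference` itself keeps plain full-mean semantics
(idempotent; exact removal of channel-common signals).

**Band power.** Welch PSD with 40-s Hann segments, 50% overlap and linear
detrending per segment; 40-s windows give 0.025 Hz resolution, enough to
resolve the 0.1 Hz lower edge of the slow band. A band's value is the mean
of PSD bins whose centre frequency lies in the closed interval — both the
band-averaged density (signal²/Hz) and the integrated power (signal²) are
reported, since "mean power" can denote either. Analytic anchors used in
tests: a unit sinusoid integrates to A²/2 = 0.5 in its band; white noise of
variance σ² sits at the flat one-sided density σ²/(fs/2); the integrated
PSD obeys Parseval against the trace variance to well under 2%.

## Proteomics

Differential abundance between two groups of log₂ intensities uses the
two-sided Welch t-statistic with Welch–Satterthwaite degrees of freedom,
vectorised over proteins and NaN-aware: a protein is tested only with at
least `min_valid_per_group` (default 3) finite values per group; there is
no imputation. Zero variance in both groups gives t = 0, p = 1 when means
agree; with unequal means the p-value is set to the smallest positive
normal float and the row flagged `degenerate`. Multiplicity is controlled
with Benjamini–Hochberg at 5% — deterministic and exactly testable against
the step-up formula (permutation-based FDR variants exist but are neither
reproducible without a seed convention nor needed at these group sizes).
On simulated nulls (2000 proteins, groups of 4/5/6) the realized
false-call rate is ≪ 0.1% of proteins and on 10% spiked effects of
|log₂FC| = 1.5 the realized FDR stays below the nominal 5% with power
above 95%.

Over-representation of a gene set of size K in a query of size n from a
universe of N tested proteins is the hypergeometric upper tail
P(overlap ≥ k), BH-adjusted across sets; the universe is the set of
*tested* proteins (post-filter), not all annotated genes, which keeps the
null calibrated to the experiment. Identifiers match after case-folding;
query ids outside the universe are reported and dropped, never silently.

The upstream-regulator stage is a transparent stand-in for proprietary
causal-network tools: the input set is every tested protein with p < 0.05
and linear fold change ≥ 1.5 (interpreted as |log₂FC| ≥ log₂ 1.5 — the
fold-change window convention of the commercial tool this mirrors); each
candidate regulator gets a one-sided Fisher exact p for target overlap with
the input set and an activation score
z = (n_sign_consistent − n_sign_inconsistent)/√n_signed_overlap over its
sign-annotated targets. Regulators with no overlapping targets are reported
inert (p = 1, z undefined) rather than dropped.

## Synthetic data

All generators are pure functions of their arguments including `seed`: a
single `numpy.random.SeedSequence` is spawned into named child streams in a
fixed order, so extending one stream never perturbs another.

* **Calcium.** A quota of `round(frac_hyper · n_rois)` ROIs is hyperactive;
  event counts are Poisson conditioned on the realized rate falling on the
  correct side of 3/min, so the truth fraction is exact and every truth
  class equals the classifier applied to the true rate. Events are placed
  uniformly in time and convolved with a unit-peak double-exponential
  kernel (rise 0.1 s, decay 1.0 s — plausible red-indicator kinetics,
  configurable since real kinetics vary); amplitudes are lognormal with
  median `snr` × the frame-noise SD in ΔF/F units. The neuropil channel
  carries a shared 1-s-smoothed background plus independent noise, and the
  ROI channel couples that background with coefficient `neuropil_coupling`
  (default 0.7, matching the correction). Defaults: 300-s recordings at
  30 Hz, baseline 100 units, noise SD 2 units, base rate 0.5/min.
* **Spikes.** Clean units are renewal processes with exponential ISIs plus
  a 2.5-ms dead time, rate-corrected so the mean ISI is exactly 1/rate
  (zero refractory violations by construction). Contaminated units receive
  injected doublets 0.5–1.5 ms after randomly chosen anchors, sized so the
  final violation fraction is ~`contamination_fraction` (default 5%).
  Rates are log-normal, log₁₀ Hz ~ N(0, 0.4) — a plausible cortical-rate
  spread; 10-min recordings by default.
* **LFP.** Cortical channels share one band-limited Gaussian field,
  synthesised in the frequency domain and scaled to the target integrated
  power *exactly* per band; coherence across channels reflects volume
  conduction at probe scale. Extra reference channels (default 2, depths
  > 800 µm) carry only the channel-common offset, giving the preprocessing
  a clean reference set.
* **Proteome.** log₂ intensities are Gaussian per protein with
  inverse-gamma per-protein variances (shape 4, mean 0.04 — SDs near 0.2,
  typical of TMT); a deterministic quota of proteins receives an additive
  log₂ shift in non-reference groups (default groups WT n=4 / GR400 n=5,
  the study's sizes extendable to a third n=6 group); `var_heterogeneity`
  multiplies non-reference variances by a lognormal factor so group
  variances genuinely differ (exercising the Welch assumption). ECM labels
  are Bernoulli with a configurable odds ratio between DE and non-DE
  proteins, solved from the marginal ECM fraction, so enrichment stages
  have known truth.

**What the generator does not emulate** — and what passing tests therefore
do not demonstrate about real data: motion artefacts, ROI segmentation
errors and slow drift in imaging; bursting, correlated firing and waveform-
dependent sorting errors in spikes; 1/f spectral background, line noise and
non-stationarity in LFP; intensity-dependent missingness, batch structure
and normalisation artefacts in proteomics. The generators validate the
*estimators* under their stated models, not the upstream acquisition steps
(motion correction, segmentation, spike sorting, MS search), which are out
of scope.

## The two-genotype scenario

`run_genotype_scenario` simulates a full experiment — per-animal
superficial-layer imaging (3 animals × 250 ROIs per group; mutant 15%
hyperactive vs control 2%), layer-5 spike sets drawn from identical rate
distributions, per-animal LFP with slow-band power halved and gamma power
doubled in the mutant, and a 2000-protein table with an up-shifted
ECM module — then runs the full analysis and reports six directional
checks: higher hyperactive percentage in the mutant, indistinguishable
layer-5 median log₁₀ rates (|Δ| < 0.1), slow power down, both gamma bands
up, and the ECM set top-ranked among up-enriched sets. Problem sizes were
chosen so the whole scenario completes in seconds while keeping each
direction estimate far from its decision boundary.

## Known limitations

* Event detection reports threshold runs, not deconvolved spikes; rates
  for very bright or very fast indicators will undercount overlapping
  transients (see the resolution limit above).
* The regulator score is a deliberately simple overlap-plus-sign statistic;
  it ranks strong, coherent regulators correctly on synthetic truth but is
  not a reimplementation of any commercial causal network algorithm.
* Welch band power assumes stationarity within 40-s windows; state
  transitions under anaesthesia violate this and are not modelled.
* The pipeline performs no cross-genotype hypothesis tests (ANOVAs etc.);
  it emits per-group descriptive summaries by design.
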