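# Methods

## Savitzky-Golay smoothing

`sg_smooth` replaces each sample by the value at the window centre of the
degree-n polynomial fitted by least squares to the m samples of the window
centred there (m odd). Because that value is a fixed linear combination of the
window samples, the filter is a convolution; the weights are computed once per
(window, degree) pair by solving the least-squares problem in a Legendre basis
on [-1, 1] and reading off the centre row of the pseudoinverse. The Legendre
basis keeps the normal equations well conditioned even at the aggressive
detrending configuration window = 311, degree = 40 used on 487-TR runs, where
a raw monomial Vandermonde matrix would be numerically useless. The test suite
verifies the convolution weights against an explicit per-window polynomial fit
at every index, including boundaries.

Series ends are handled by endpoint-inclusive mirror extension: the first
(m−1)/2 samples are prepended in reverse order and the last (m−1)/2 appended
in reverse order, so `[1,2,3,4,5]` with m = 5 becomes
`[2,1,1,2,3,4,5,5,4]`. SG(3/1) then reduces exactly to a three-point moving
average of the padded series.

## Reference (SPM-style) filters

* **DCT detrending basis** — orthonormal discrete-cosine columns with periods
  ≥ cutoff (default 128 s), k = floor(2·N·TR/cutoff) columns; at 487 TRs and
  TR 1.24 s this is 9 columns.
* **Gaussian low-pass** — unit-sum discrete Gaussian kernel with mirror
  boundaries. The classical "width of 2.48 s" is interpreted as the kernel
  **standard deviation** (σ ≈ 2 TR), not the FWHM. Rationale: only the σ
  reading reproduces the published autocorrelation behaviour of
  Gaussian-cleaned BOLD data (lag-1 ≈ exp(−TR²/4σ²) ≈ 0.94, matching the
  reported ≈ 0.93; the FWHM reading would give ≈ 0.71). `width_kind="fwhm"`
  is available for the other convention.
* **HRF low-pass** — causal convolution with the canonical double-gamma
  hemodynamic response (peak 6 s, undershoot 16 s, ratio 6, length 32 s)
  sampled at TR and normalized to unit sum so constants pass unchanged; the
  run start is mirror-extended as warm-up. Unit-sum normalization is a design
  choice; it leaves correlation-based metrics invariant.

## GLM denoising and detrending

Each grey-matter series is regressed on
[intercept | 12 nuisance PCs | trend column(s)] and replaced by the OLS
residual. Nuisance PCs (5 white-matter, 5 ventricle, 2 motion) are the
unit-norm left singular vectors of the column-centred raw channel matrices.
PCs are centred and normalized before entering the design purely for
conditioning — the residual span is unchanged. An explicit intercept is always
included (the "13 nuisance regressors" count of the SG-detrended design
excludes it). The SG trend regressor is the SG smooth of the raw series
itself, computed once, not iterated. Designs are rank-checked and rank
failures name the offending columns. Prewhitening/AR(1) correction of serial
correlation is deliberately out of scope.

The nine named presets: `raw`, `denoise`, `detrend_spm` (DCT-128 s),
`clean_hrf`, `clean_gauss` (both on the DCT-detrended base), `detrend_sg69_6`,
`detrend_sg311_40`, `clean_sg15_8` (on the 69/6 base), `clean_sg3_1` (on the
311/40 base).

## Predictor construction

The empirical HRF of a node is the mean over the 24 event segments of the
processed series; each segment spans the event window plus the portion of the
following (jittered) baseline shared by all events. The predictor is this
average tiled once per event; the observed series is aligned by concatenating
the same segments, so predictor and observed have equal length and can be
correlated directly. Canonical-HRF regression predictors are intentionally not
provided: the empirical average respects large between-subject differences in
response shape.

## Two-phase brute-force optimization

*Detrend phase*: for each grid cell (odd windows 3…487, degrees 1…window−1)
the observed series are denoised + SG-detrended; predictors come from the
denoise-only pipeline of the other run; the cell score is the mean of the
2 × n_nodes × n_subjects cross-run Pearson correlations.

*Clean phase*: the detrending filter is fixed, candidates (degree capped at
50) are applied after the GLM. Each cell also records the RMSE between the
lag 1–4 autocorrelations of the cleaned observed series and of the predictor
series. The autocorrelations are grand-averaged per lag across nodes, subjects
and run directions before the RMSE is taken (a per-series RMSE, then averaged,
is available via `grand_average_autocorr=False`; the two readings are both
defensible and the grand-average one matches how the published
autocorrelation tables are assembled). Cells with RMSE ≥ 0.1 are masked out,
then the best mean correlation wins; exact ties break toward the smaller
window, then the smaller degree (ties are not expected in practice; the rule
just makes the search deterministic). Correlations are averaged as raw Pearson
r, not Fisher z, to stay on the scale of the reported grand means. Zero
variance series yield missing correlations that are counted, logged and
excluded from means.

## Metric suite

* Time-course reliability: Pearson r between full filtered test and retest
  series (Pearson rather than ICC because BOLD amplitude is arbitrary, and the
  attenuation bound is defined on Pearson reliabilities).
* Connectivity: per-run node × node Pearson matrices, averaged over test and
  retest per subject (561 paths at 34 nodes).
* Upper bound: √(ρ_A·ρ_B) when both reliabilities are positive, else the path
  is corrupt. Detectable connectivity: positive observations are capped at the
  bound, negative ones at minus the bound, corrupt paths are set to 0;
  |observed| > bound flags the path overestimated.
* Grand means include corrupt paths at value 0 (for the bound and detectable
  columns), matching the zero-assignment rule; the overestimation percentage
  is computed per subject among non-corrupt paths, then averaged. Corrupt-path
  percentage is pooled over subjects × paths.
* Group ICC(2,1): two-way random effects, absolute agreement, single measure,
  (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n), computed per path across
  subjects over the two sessions and averaged; verified against an independent
  ANOVA implementation to 1e-9.
* Feasibility: thresholds are round-half-away-from-zero of 20% of the node and
  path counts (34 → 7 nodes, 561 → 112 paths); per reliability cutoff
  (0.4 / 0.6 / 0.75) the summary reports the percentage of subjects whose
  connectome survives.

## Spectra

One-sided rectangular-window FFT power spectra of mean-removed series, scaled
so the bin sum equals n·variance; grand means average power (not amplitude,
not complex coefficients) across nodes, runs and subjects. The residual noise
series of a cleaning filter is (denoised+detrended) − cleaned; band power over
0.04–0.25 Hz measures how much task-band content the filter discarded.

## Synthetic data generator

The generator's defaults are the study conditions: 67 subjects, 34 nodes,
487 TRs at TR = 1.24 s, 24 events. Values the source material does not print
are declared here once: event length 12 TRs with inter-trial baselines
jittered uniformly over 6–8 TRs (mean period ≈ 23.6 s ≈ 0.042 Hz, matching the
~0.04 Hz task rate); test and retest share one event schedule per subject.

Each node series is the exact sum of four stored components:

* **signal** (shared across runs): the subject's double-gamma HRF (peak
  ~N(6, 0.8) s, undershoot ~N(16, 1) s) convolved with the event boxcar,
  standardized, plus a subject-specific within-trial waveform of three random
  sinusoids in 0.04–0.25 Hz (amplitude 0.5) repeated at every event; node
  amplitudes are log-normal (σ = 0.3).
* **drift** (run-specific): a random mixture of all DCT components below
  0.04 Hz, std 1.0 — deliberately including the 0.008–0.04 Hz band that a
  128-s DCT detrend cannot reach, so SG detrending has something conventional
  detrending misses.
* **nuisance leakage** (run-specific): six latent AR(0.8) sources mixed into
  both the grey-matter nodes (std 0.6, node-specific anatomical weights) and
  the raw white-matter/ventricle/motion channels from which the nuisance PCs
  are extracted, so PC regression genuinely denoises.
* **noise**: stationary AR(1), coefficient 0.4, per node per run.

With `target_reliability` set (default 0.25, the conventional single-subject
ceiling), the AR noise variance is calibrated from the variance ratio
ρ = var(shared)/(var(shared) + var(unshared)) against the mean node signal
variance, so per-node reliabilities scatter realistically around the target;
the calibration is verified empirically to ±0.05. The AR coefficient and
amplitude choices were fixed by matching the published lag 1–4 autocorrelation
structure of raw, denoised, detrended and cleaned series (agreement within
roughly 0.05–0.12 at every lag and pipeline), not by tuning to any test
outcome.

What the generator does **not** emulate: spatial/voxel structure,
physiological waveforms (cardiac/respiration), scanner artifacts,
session-to-session amplitude drift, non-stationary noise, and any
heavier-than-AR(1) low-frequency tail in the noise spectrum. Passing tests
therefore demonstrate the internal consistency and the qualitative behaviour
of the framework under these conditions, not performance on real scanner data.
One known consequence: the AR(1) noise tail above ~0.15 Hz is flatter than
empirical BOLD noise, which inflates the absolute band power that *any*
well-behaved low-pass filter removes near the band edge; filter comparisons in
that region should be read as ordering statements.

The Monte Carlo audit draws independent AR(1) pairs (defaults: 1000 pairs,
487 TRs, AR ∈ {0, 0.3, 0.6}), cleans both members and reports the mean and
standard deviation of the null correlations: a cleaning filter that widens the
null distribution (Gaussian σ = 2.48 s roughly doubles it) can manufacture
spurious reliability, while SG(15/8) inflates it far less.

## Numerical choices and degenerate inputs

* SG weights via Legendre pseudoinverse; convolution by `np.correlate`.
* OLS via `numpy.linalg.lstsq`; designs validated full rank beforehand.
* Zero-variance series: correlations become missing (NaN), counted and
  excluded; autocorrelation of a constant raises.
* ICC is NaN when the between-subject variance vanishes.
* Pareto thresholds round half away from zero.
* DCT cutoff ≤ 2·TR is rejected; a cutoff longer than twice the run yields an
  empty basis with a warning.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give bit-identical datasets and search tables.

## Known limitations

* The full 243-window grid at study scale is feasible but slow on one core;
  the CLI and tests use documented sub-grids (window/degree subsets) that
  bracket the known optima.
* Reliability calibration targets the dataset mean, not each node, so extreme
  node gains can produce individual reliabilities far from the target.
* The HRF low-pass filter is a unit-sum kernel reconstruction of the classical
  approach, not a line-by-line port of the original MATLAB implementation.
* Averaging raw Pearson r (rather than Fisher z) slightly biases grand means
  toward zero; the optional `fisher_z` flag exists but the reported defaults
  stay on the raw-r scale.
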