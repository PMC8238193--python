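# Methods

`callcode` analyzes how selectivity for conspecific-call features and
stimulus information are distributed across auditory processing stages.
Because it ships with its own synthetic test bed, every algorithm can be
exercised end-to-end without any recorded data.  This note documents the
models, the defaults and why they were chosen, the numerical decisions,
and what the synthetic data can and cannot establish.

## Synthetic stimuli

Sixteen call-like stimuli (8 categories x 2 exemplars, 0.4-3.5 s,
totalling ~35 s) are synthesized at 100 kHz from four parametric motifs:
harmonic stacks (rumble, whine, scream), FM sweeps (chirp, wheek), pulse
trains (purr at 10-12 Hz, teeth chatter at 18-22 Hz), and noise-burst
sequences ("other").  Exemplars within a category differ in at least one
motif parameter (fundamental, sweep range, pulse rate, band edges).  All
waveforms receive 10 ms cosine ramps and are RMS-equalized; the common RMS
(0.05 full scale) defines the nominal 70 dB SPL presentation level.  The
motifs are caricatures: they reproduce the qualitative spectrotemporal
classes of rodent calls (periodicity, harmonicity, FM direction, noisiness)
but make no attempt at acoustic realism.  Spectral parameters are
validated against the 200 Hz - 25.6 kHz analysis range.

## Cochleagram

The model input is a 31-channel log-spaced spectrogram: center
frequencies 250 Hz to 16 kHz at 5 steps/octave (inclusive endpoints, so
31 channels and, with 10 time lags, 310 receptive-field weights), 40 ms
Hann analysis windows with a 20 ms hop, triangular weighting onto the
channel grid with bandwidth equal to the spacing.  Band levels in dB
(re a unit-amplitude tone) pass through the weighted sum of three
sigmoidal rate-level functions standing in for low-, medium-, and
high-threshold auditory-nerve fibers; defaults are thresholds
{-60, -40, -20} dB, common slope 0.3 /dB, saturation 1, equal weights,
chosen to span the stimuli's dynamic range.  Silence maps exactly to 0
(the sigmoid floor), and the transform is monotone in overall level and
invariant to waveform polarity.  The frame count is
`ceil(duration / 20 ms)`; the trailing partial frame is zero-padded.

## Ground-truth neurons

Three archetypes with stage-typical spontaneous rates (log-normal around
medians 3.67, 2.31, 1.51 spk/s for thalamus-like, granular-layer-like and
superficial-layer-like populations; sigma = 0.35 preserves the median):

* **Thalamus-like / L4-like** (`conjunction_k = 1`): one Gaussian
  spectrotemporal subunit (sigma 0.5 / 0.3 octaves respectively, lags
  within 0-60 ms) at a best frequency drawn log-uniformly from 500 Hz to
  12.8 kHz.  The drive threshold sits at the 50th/60th percentile of the
  filter drive over the call library and the output is a softplus
  (sharpness 8), so responses are dense and spectrally predictable; the
  gain is set so peak driven rates fall in 30-60 spk/s.
* **L2/3-like** (`conjunction_k` of 2 or 3): subunits are placed on the
  strongest, spectrally separated channels of a randomly chosen
  high-energy frame of one call, with lags matched to that frame's recent
  history -- i.e., the neuron is built to detect a feature conjunction
  that actually occurs in the stimulus set.  The neuron fires only when
  all subunits simultaneously exceed per-subunit thresholds.  Writing
  m(t) = min_i d_i(t)/p99_i (each subunit drive normalized by its own
  99th percentile), the gate opens exactly where m(t) > beta; beta is set
  just above the third-ranked per-category maximum of m(t), which
  guarantees by construction that at most two call categories can open
  the gate (with a floor of 0.65 x max so gating stays temporally
  sparse).  Peak gated rates are drawn from 40-80 spk/s.

Calibrating thresholds against the stimulus library is part of the
generative definition of these archetypes (a conjunction detector is only
meaningful relative to a stimulus ensemble), not a fit to data.

Spikes are drawn from an inhomogeneous Poisson process in 20 ms frames
(counts per frame, times uniform within the frame), with 0.5 s of
spontaneous-only activity before onset and 1 s after offset; the drive
decays over the 200 ms filter memory after offset.  Trials are
independent; no intertrial interval or slow gain fluctuation is
simulated.  Pure-tone responses (7 octaves from 200 Hz at 10 steps/oct,
20 dB level spacing) are simulated the same way for tuning summaries.

## Response-window detection

Windows of 100 ms slide in 50 ms steps from 50 ms after onset to 100 ms
after offset.  Seeds require the window rate to exceed the spontaneous
mean by 6 SEM (mean and SEM from the full 0.5 s pre-onset segments,
pooled over all stimuli) and a one-tailed two-sample t-test to pass
p <= 0.1 after Benjamini-Hochberg correction across all candidate windows
of the neuron.  Two statistical choices matter here:

* **Variance-matched null.**  The t-tests compare window trial rates
  against spontaneous rates re-measured in window-length-matched
  segments of the pre-onset data (e.g., five 100 ms segments per 0.5 s
  pre-window).  Rates over short windows have several-fold larger
  sampling variance than rates over the full segments; testing against
  the unmatched 0.5 s rates makes the pooled t-test strongly
  anticonservative (measured false-positive run rate above 50% on pure
  Poisson rasters), while a Welch test against either null caps the
  attainable t-statistic near 3 when only half the trials respond,
  which would make the trial-fraction relaxation unreachable.  The
  matched-segment pooled test is calibrated for windows up to the
  pre-window length and conservative beyond it.
* **Final-threshold correction.**  The final p <= 1e-4 criterion is
  applied to the raw p times the number of candidate windows scanned
  (per-neuron Bonferroni).  The scan covers hundreds of lattice windows;
  an uncorrected final threshold would make the false-positive rate
  grow with stimulus duration.  With the correction, pure-spontaneous
  rasters yield zero windows in ~100% of seeded runs while strong
  injected responses are still recovered in 100%.

Seeds grow by adding adjacent lattice windows while the added window
passes p <= 0.1 and the enlarged window exceeds 10 SEM with p <= 0.01
(growth is greedy and symmetric, left neighbor first; these intermediate
thresholds stay uncorrected).  Trial rates with z > 1.96 within the
grown window are replaced by the window mean before the final test:
rate above 14 SEM, corrected p <= 1e-4, and spikes on at least 60% of
trials.  Windows closer than 100 ms are coalesced only if the merged
window still passes.  If no stimulus yields a window, criteria
relax cumulatively in a fixed order -- trial fraction to 50%, burst z to
2.5, window to 200 ms (slide 100 ms) -- and the relaxation level is
reported.  Degenerate inputs are defined: an all-zero raster returns no
windows (not an error), and the t-test falls back to a 0/1 decision when
both samples have zero variance.  Predominantly suppressed responses are
flagged (`inhibitory_`) but never produce windows; quantifying inhibition
is out of scope.

## Selectivity and sparseness

Call selectivity counts categories with at least one window on either
exemplar.  Temporal metrics are windows-per-call and the summed window
length as a fraction of call duration.  Sparseness uses (1) the excess
kurtosis of trial-wise rates over the single span [onset + 50 ms,
offset + 100 ms], pooled across all stimuli and trials (160 values at the
default 16 x 10 design; population moments, so 0 for normal rates), and
(2) the activity fraction A = (mean r)^2 / mean(r^2), which is 1/N for a
one-hot rate vector and 1 for uniform rates, and is scale-invariant.
Tone summaries take best frequency/level as the argmax of mean rate and
bandwidth from an equal-area rectangle fit: height is the peak rate above
spontaneous at the best level, width (in octaves) is the excess area
under the tuning curve divided by that height.

## LN-STRF estimation

The encoding model is a 31 x 10 weight matrix (200 ms of history at
20 ms resolution) convolved with the concatenated cochleagram, followed
by a double-exponential output nonlinearity
y = b + a*exp(-exp(-k(x - s))).  The target is the trial-mean PSTH in
20 ms bins.  Fitting proceeds in three steps per cross-validation fold:

1. **Linear stage**: the weights solve a regularized least-squares
   problem with an L2 penalty (1e-4) plus a Laplacian smoothness penalty
   (1e-3) on the channel x lag grid.  Smoothness encodes the standard
   prior that receptive fields vary gradually in frequency and time; a
   plain ridge cannot distinguish high-frequency weight noise from
   structure and, with strongly collinear natural-stimulus designs,
   either over-shrinks or overfits.
2. **Nonlinearity stage**: (b, a, s, k) are fit to (Xw, y) by
   Nelder-Mead least squares.
3. **Joint refinement**: weights and (b, a, s) are refined together by
   L-BFGS-B with the analytic gradient, stopping when the relative loss
   change falls below 1e-6 or after 10,000 iterations.  The curvature k
   is frozen at its stage-2 value: the model family is invariant under
   (w, k, s) -> (cw, k/c, cs), so a free curvature would let the
   optimizer rescale the weights to evade the penalties; freezing k
   removes that degeneracy without restricting the function class.

Cross-validation uses 10 contiguous, nonoverlapping validation segments
covering the data exactly once (90/10 splits).  Performance r is the
Pearson correlation between predicted and observed validation PSTHs,
averaged over folds; its significance uses a 1,000-resample bootstrap
over pooled validation bins (95% CI excluding zero).  The displayed STRF
is the fold-mean weight matrix times a significance mask: per-cell nulls
come from scrambling each fold's weight matrix (permuting all 310 cell
positions, independently per fold per shuffle, 1,000 shuffles),
two-tailed permutation p-values are BH-FDR corrected across the 310
cells at q = 0.05.  The permutation p floors at zero (no +1 small-sample
correction) -- with the correction, a lone extreme cell could never clear
FDR across 310 comparisons at any practical shuffle count.  STRF
complexity is scored as sparsity = max|W| / sd(W) over all cells of the
masked STRF (zeros included) and the excess kurtosis of the masked
weights; both are flagged undefined when the mask is empty.

## Stimulus-specific information

Responses are symbolized as spike counts in sliding windows (default
100 ms, slide always half the window; sizes 14-400 ms supported) over a
fixed span from 50 ms before onset to 1,457 ms, truncating longer calls
so bins align across stimuli.  Per bin, with a uniform prior over the 16
stimuli, I_SP(resp) = H(stim) - H(stim|resp) and
I_SSI(stim) = sum_resp p(resp|stim) I_SP(resp); the prior-weighted mean
of I_SSI equals the mutual information exactly (this identity is tested
to machine precision).  Sampling bias is removed by subtracting the mean
of 100 all-way shuffles (stimulus labels permuted across all
stimulus x trial responses, independently within each bin; a global
shuffle scope is available as a config switch).  The MI sparsity index
SI_MI is the mean, over high-MI bins (MI above mean + 1 SD of the
neuron's MI time course), of the excess kurtosis of the 16 per-stimulus
I_SSI values.  Information-spike coupling pools all (stimulus, bin)
pairs: Pearson correlation and least-squares slope of I_SSI against the
window-binned PSTH (bits per spike).  All analyses require complete,
equal trial counts.

## Statistics

Stage comparisons use Kruskal-Wallis omnibus tests with Dunn z-tests on
pooled mean ranks (tie-corrected) and Sidak adjustment
p' = 1 - (1 - p)^m.  Effect sizes are Cliff's delta,
(#{x>y} - #{x<y}) / (n_x n_y); ties count for neither side.  Joint
distributions (windows per call vs. fractional response length) are
compared with Peacock's all-quadrant two-dimensional Kolmogorov-Smirnov
test; the p-value uses the asymptotic approximation with the
correlation-based correction, and the Fasano-Franceschini restriction to
data-point quadrants is not used (the full Peacock statistic is exact on
the pooled point set).  FDR control is Benjamini-Hochberg.  Category
representation uses a two-sided label-permutation test BH-corrected
across all stage x category cells.  A common-slope ANCOVA (bandwidth on
best frequency with stage intercepts, Tukey HSD contrasts) is provided
for tuning summaries.

## Pipeline and problem sizes

`run_full_analysis` simulates the population, runs every per-neuron
analysis, and reports per-stage medians, pairwise Cliff's deltas and
Dunn-Sidak p-values for all nine metrics, plus the sign of each
L2/3-like minus L4-like median contrast.  Undefined values propagate as
explicit NaN flags, never dropped rows; runs with fewer than two neurons
per stage are flagged underpowered.  Everything is reproducible from the
master seed, which is split deterministically across stimuli, neurons,
shuffles and bootstraps.  The reference configuration uses 20 neurons
per stage, 10 trials per stimulus, 1,000 mask shuffles, 200 bootstrap
resamples and 100 bias-correction shuffles; the test suite uses smaller
populations (2-15 per stage) and shuffle counts where only directions or
invariants are asserted.

## What the synthetic test bed does and does not show

Passing tests establish that the algorithms are implemented correctly
(exact information anchors, brute-force oracle agreement, permutation
calibration) and that the pipeline recovers the qualitative
superficial-vs-granular contrast pattern from populations constructed to
embody the feature-conjunction hypothesis: lower call selectivity, higher
trial-rate kurtosis, lower activity fraction, lower LN validation r,
higher SI_MI and higher information-per-spike slope in the
conjunction-gated population.  They do not validate the biological claim
itself: the generator's archetypes assume the conclusion (conjunction
gating) rather than test it, real spike trains are non-Poisson and
history-dependent, and real call acoustics are richer than the motif
caricatures.  Two known mismatches with real populations: the
conjunction archetype's STRF complexity runs opposite to real superficial
neurons (its few compact subunits yield sparser masked STRFs, not more
complex ones), and absolute validation r values at 10 trials are below
typical recorded values because the simulated PSTHs are noisier than
averaged real responses.  Directional contrasts, not absolute values,
are the supported comparisons.
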