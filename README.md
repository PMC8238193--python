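# callcode

Analysis of call-feature selectivity and stimulus-specific information in
auditory neural populations — with a fully synthetic test bed, so the
entire pipeline runs end-to-end without any recorded data.

## The problem

Along the ascending auditory pathway, neurons in the thalamus (vMGB) and
the thalamorecipient cortical layer (A1 L4) respond densely to most
conspecific vocalizations, following their spectral tuning.  In the
superficial layers (A1 L2/3), many neurons instead respond to only one or
two call types, and only to brief feature-bearing segments of them — the
signature of de-novo feature-conjunction selectivity.  Quantifying that
transformation requires a chain of analyses:

* **Response windows** — significant excitatory response intervals found
  by a seed/grow/finalize algorithm: seeds where the windowed rate
  exceeds the spontaneous mean by 6 SEM with an FDR-corrected one-tailed
  t-test at p ≤ 0.1; growth under 10 SEM / p ≤ 0.01; acceptance under
  14 SEM / p ≤ 1e-4 with responses on ≥ 60% of trials; fixed relaxation
  schedule when nothing is found.
* **Selectivity and sparseness** — call selectivity (categories with ≥ 1
  window), excess kurtosis of trial-wise rates, and the activity fraction
  A = (Σᵢ rᵢ/N)² / Σᵢ(rᵢ²/N) ∈ [1/N, 1].
* **LN-STRF models** — a 31-channel × 10-lag spectrotemporal receptive
  field on a log-spaced cochleagram, with a double-exponential output
  nonlinearity y = b + a·exp(−exp(−k(x−s))), 10-fold nested
  cross-validation, and a scramble-permutation significance mask
  (BH-FDR over the 310 weights).
* **Stimulus-specific information** — per time bin,
  I_SSI(s) = Σ_r p(r|s)·[H(S) − H(S|r)], whose prior-weighted mean is the
  mutual information (4 bits maximum for 16 equiprobable calls), with
  all-way shuffle bias correction, the MI sparsity index SI_MI, and the
  I_SSI–PSTH correlation and slope (information per spike).
* **Stage statistics** — Kruskal–Wallis with Dunn–Šidák post-hocs,
  Cliff's delta effect sizes, Peacock's 2-D Kolmogorov–Smirnov test,
  Benjamini–Hochberg FDR, and category-representation permutation tests.

The synthetic module generates the study conditions: 16 call-like stimuli
(8 categories × 2 exemplars, RMS-equalized, ~35 s total) and ground-truth
LN neurons of three archetypes — dense spectrally driven thalamus-like
and L4-like cells, and L2/3-like conjunction detectors that fire only
when ≥ 2 feature subunits are simultaneously super-threshold.

## Worked example

```python
from callcode.pipeline import RunConfig, run_full_analysis

report = run_full_analysis(RunConfig(seed=1, n_per_stage=4))
print(report.medians.round(3))
print(report.sign_l23_vs_l4)
```

prints per-stage medians (a 4-neurons-per-stage run; column order may
vary):

```
stage                L2/3-like  L4-like  vMGB-like
call_selectivity         2.000    6.000      7.000
sparseness_kurtosis      4.121   -0.707     -0.922
activity_fraction        0.521    0.668      0.768
r_mean                   0.185    0.371      0.363
strf_sparsity            5.817    4.001      3.521
strf_kurtosis           12.115    2.053      1.801
si_mi                    5.355    1.510      0.807
issi_psth_corr           0.959    0.924      0.894
issi_psth_slope          0.723    0.350      0.302
```

Reading the table: the simulated superficial-layer population responds to
a median of 2 of 8 call categories versus 6 for the granular-layer
population, with sparser rates (higher kurtosis, lower activity
fraction), worse LN-model generalization (lower r), and information that
is concentrated on few stimuli and carried by fewer spikes (higher SI_MI
and I_SSI–PSTH slope).  `report.sign_l23_vs_l4` records the sign of each
contrast, and `report.pairwise` holds Cliff's deltas and Dunn–Šidák
p-values per stage pair.

A command-line interface wraps the same pipeline:

```bash
callcode simulate --n-per-stage 10 --seed 1 --out out/      # calls + rasters
callcode run --seed 1 --n-per-stage 20 --out report_dir/    # full analysis
```

## Layout

| Module | Contents |
| --- | --- |
| `callcode.calls` | synthetic call library (WAV I/O, motif synthesis) |
| `callcode.cochleagram` | log-spaced rate-level spectrographic input |
| `callcode.neurons` | ground-truth LN neurons, Poisson raster simulator |
| `callcode.windows` | response-window detection (`ResponseWindowDetector`) |
| `callcode.selectivity` | selectivity, kurtosis, activity fraction, tuning |
| `callcode.strf` | LN-STRF estimator (`STRFModel`), masks, complexity |
| `callcode.information` | I_SSI / MI / SI_MI (`StimulusInformation`) |
| `callcode.stats` | Kruskal–Dunn–Šidák, Cliff's δ, 2-D K–S, FDR, ANCOVA |
| `callcode.pipeline` | end-to-end orchestration and stage-contrast report |

See `docs/methods.md` for the models, defaults, numerical choices, and
the limits of what the synthetic test bed demonstrates.
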