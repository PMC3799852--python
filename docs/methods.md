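# Methods

`erpbci` simulates and analyses a BCI-aptitude prediction study: a cohort of
severely motor-impaired participants performs an auditory oddball task, and
the ERP components of the oddball response (N1, P2, N2, P3) are used to
predict how many errors each participant makes with a visual row/column P300
matrix speller. Because no raw EEG from such a cohort is publicly available,
the package generates synthetic cohorts with a *planted*, known coupling
between ERP strength and speller performance, runs the full signal-processing
and classification chain on them, and checks that the rank-correlation
analysis recovers what was planted.

## The virtual cohort

Each participant is a parameter set: a latent aptitude in [0, 1], one
amplitude scale and one latency per ERP component, a background-noise SD and
a blink rate.

**ERP model.** A response is a sum of four Gaussian-windowed components
projected through fixed scalp topographies over the 16-channel montage
(F3, Fz, F4, T7, T8, C3, Cz, C4, Cp3, Cp4, P3, Pz, P4, Po7, Po8, Oz):

* N1 — negative, fronto-central *and* occipital, 22 ms width;
* P2 — positive, fronto-central, 20 ms width;
* N2 — negative, frontal and occipital lobes, 45 ms width;
* P3 — positive, centro-parietal, asymmetric (35 ms rise, 110 ms decay),
  the classic P300 morphology.

The N1/N2 topographies deliberately carry genuine occipital negativity
rather than a pure frontal dipole. Two observations force this choice: the
group peak table this generator is calibrated against shows *positive*
occipital N1/N2 values in the posterior sign-inverted reporting convention
(i.e. the raw common-average-referenced occipital traces were negative, not
flipped), and only an occipitally negative N2 makes the sign of the
recovered Oz-N2-vs-errors correlation equal the sign of the planted
coupling. The polarity flip that the common average reference produces for
fronto-central components appears at the temporal sites instead.

**Calibration.** Latency means and SDs per component are the published Cz
group values (N1 159.45 ms, P2 236.51 ms, N2 304.69 ms, P3 361.51 ms);
parameter SDs are 0.7x the published SDs because the published spread also
contains single-session measurement noise that the generator adds
separately. Latencies are drawn from a truncated normal so every latency
stays inside its component's detection window. Amplitude scales are
lognormal (median-preserving) around means chosen so the post-CAR Fz/Cz
amplitudes have the published signs and roughly the published magnitudes.
The P3 amplitude at Fz and Oz is deliberately small (centro-parietal
topography); a large frontal P3 lobe would erase the frontal N2 negativity
of the difference wave, and a large occipital one would contaminate the Oz
N2 window.

**Planted coupling.** Aptitude is Phi(z + 0.4) for a standard normal z; the
0.4 shift calibrates the expected mean error count of the default
40-selection task to the published cohort mean of 15.1 errors. The N2
amplitude scale is coupled to aptitude through a Gaussian copula with
Pearson correlation 2*sin(pi*rho_s/6), the exact inverse of the
bivariate-normal Spearman relation, so the population Spearman correlation
between N2 strength and *expected* errors equals the requested `planted_rho`
exactly. Expected errors are `n_selections * (1 - acc(a))` with
`acc(a) = chance + (1 - chance) * a` — a generator-level construct used for
planting and verification; the error counts the pipeline analyses come from
actually simulating the speller.

**Stimulation.** Oddball: 3 runs x 20 sequences x 5 tones, 160 ms tones,
800 ms ISI (960 ms asynchrony, 96 s per run, 288 s per session),
standards:deviants 4:1 enforced exactly per run with uniformly random
deviant positions. Deviants evoke all four components; standards evoke 50%
N1/P2 only. Speller: row/column flashes of 62.5 ms with a 125 ms inter-flash
interval; target flashes evoke `standard + aptitude * (deviant - standard)`,
so aptitude 0 is exactly a null effect. ERP templates are identically zero
outside 0-800 ms, so consecutive oddball epochs never overlap (speller
flashes overlap heavily, as in reality). Tones and flashes are events only;
no audio or visual rendering.

**Noise.** Per-channel 1/f noise (alpha = 1, FFT-shaped), 35% of its
variance shared across channels through three smooth spatial patterns
(global, anterior-posterior, left-right); per-channel SD is normalized to
the participant's `noise_sd` (mean 9 uV). Blinks are 400 ms raised-cosine
transients, ~100 uV at the frontal channels with a fixed frontally-dominant
topography, Poisson arrivals at `blink_rate` (mean 8/min). The generator
does not emulate line noise, electrode drift/pops, muscle artifacts,
non-stationarity, or realistic volume conduction; passing tests therefore
demonstrate correctness of the analysis chain under this model, not
performance on arbitrary real recordings.

## Preprocessing

The offline chain is fixed: band-pass filter, AMUSE ocular removal, common
average reference, epoching (0-800 ms), baseline correction (-100-0 ms).
Every product carries a provenance log of the steps applied.

* **Filter** — least-squares FIR high-pass at 0.5 Hz then low-pass at 20 Hz,
  each applied forward and backward (zero phase). Tap counts follow the
  3 x fs/corner heuristic rounded to odd (1537 taps for the high-pass, 39
  for the low-pass at 256 Hz) with 15% transition bands; measured two-pass
  response: DC suppressed to 0.0015, <3% attenuation at 10 Hz, |H| = 0.0003
  at 40 Hz.
* **AMUSE** — center, whiten (eigenvalues above 1e-10 of the largest are
  retained, which tolerates CAR rank deficiency), eigendecompose the
  symmetrized lag-1 covariance of the whitened data, order components by
  descending lag eigenvalue. Ocular components are selected by a
  deterministic rule of this package (the method itself prescribes none):
  >60% of source power below 3 Hz *and* mixing-column peak at a frontal
  channel (F3/Fz/F4). Both thresholds and the lag are configurable.
* **CAR** — subtract the cross-channel mean per sample (idempotent, exact
  zero-sum).
* **Epoching** — one epoch per event, half-open sample windows; epochs
  exceeding the recording are dropped with a logged count; per-channel
  baseline mean subtracted. No epoch rejection exists anywhere, matching the
  protocol's "no other artifact correction" stance.

## ERP features

Condition averages are plain means. A peak is the extremal *strict* local
optimum of the component's polarity inside its window (N1 min 100-200 ms,
P2 max 200-250 ms, N2 min 250-375 ms, P3 max 250-700 ms), falling back to
the window's global extremum when no strict local optimum exists; ties break
to the earliest latency. For the eight channels posterior to Cz the
*reported amplitude* is negated (CAR flips apparent polarity of
fronto-central components posteriorly); detection itself always runs on the
raw waveform and latencies are never altered, which is the convention under
which the calibration table's positive occipital N1 appears at the N1's
usual latency. Negating twice restores raw values; the inversion set is
recorded in every peak table.

## SWLDA speller

Single-trial features: crop to 0-1000 ms, 25-sample centered moving average
(edges truncated to available samples), keep every 25th sample starting at
the first — 16 channels x 11 bins = 176 features, channel-major. The
decimation phase is a fixed dialect choice of this package. A fast path
computes these features directly from the continuous recording via one
cumulative sum; it is numerically equivalent to epoch-then-average (tested).

Selection is forward/backward stepwise regression of the 0/1 label: add the
candidate with the smallest partial-F p-value while p < 0.1 (if the very
first step finds none, model generation *fails* with an explicit error);
after each addition remove included features whose partial p rises to 0.15
or above (largest first; removed features do not re-enter, which guarantees
termination); stop at 60 included features — the "60 iterations" cap is read
as a feature-count cap, the common BCI implementation. Weights are the OLS
coefficients of the final selected set. Classification sums per-flash linear
scores over all flashes of each row and each column and takes both argmaxes
(ties to the lowest index); no bias term is used since the offset is common
to all stimuli of a selection.

The default simulated calibration is 17 selections at 15 repetitions (one
run); the default test task is 40 selections at 10 repetitions on the 7x7
matrix. A calibration that fails model generation is treated by the pipeline
as a participant who cannot control the speller: that session's selections
are drawn at chance (the library call itself propagates the error).

## Aptitude statistics

The performance variable is the error count averaged over a participant's
sessions. All correlations are Spearman rank correlations (average ranks),
p-values from the t-approximation on n-2 df (an exact-permutation option is
deliberately *not* the default; at n = 11 the t-approximation's null
false-positive rate measures 0.052 in this package's own calibration check).
The correlation map correlates every (channel, time) sample of the
deviant-average ERP with mean errors and reports signed r2 =
sign(rho) * rho^2; no multiple-testing correction by default (the peak table
exists for that reason), Benjamini-Hochberg available on request. The peak
table masks correlations with p > 0.1 and flags p < 0.05, mirroring the
published table's readability rules. The median split assigns ties and the
middle participant of an odd cohort to the low-error (high-aptitude) group —
with 11 participants, groups of 6 and 5 and a pooled-variance t-test on
9 df; a split whose groups have identical values returns t = 0, p = 1, and a
split that leaves one side empty (heavily tied tiny cohorts) is recorded as
undefined by the pipeline. Estimated accuracy is
100 * required / (required + mean_errors), rounded to integer percent.

## Problem sizes

Defaults mirror the study: 11 participants, 3 sessions, full-length oddball
and speller tasks. The test suite and the acceptance script run scaled-down
problem sizes chosen once (smaller cohorts, fewer selections/repetitions,
shorter pauses, single sessions); each reported quantity states the size
used. The planted-effect recovery check uses 10 cohorts of 10 participants
with 2-run oddball sessions and an 8-selection test task — the generator and
statistics contracts it exercises are size-independent.

## Known limitations

* The ERP model is a fixed-topography template generator: no dipole/forward
  model, no latency jitter within a session, no habituation or attention
  drift, and visual speller responses reuse the auditory component
  machinery.
* Simulated speller error counts are monotone in aptitude but their absolute
  scale depends on the SNR of the template model; they are not calibrated to
  the published 15.1-error mean (the generator's *expected* errors are).
* Cohort amplitude means approximate the published group table at Fz/Cz
  only; the P3 frontal/occipital means and the Pz rows are intentionally not
  matched (see the topography rationale above).
* EDF output is plain EDF (16-bit, 1 s records, zero-padded final record)
  with a sidecar TSV for events; EDF+ annotations are not written.
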