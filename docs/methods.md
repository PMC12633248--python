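# Methods

This note documents the models, estimators and numerical choices behind
`eegcrit`, and what the synthetic-data generator does and does not emulate.

## Scientific background

The package treats resting-state EEG as the observable of a cortical system
whose distance from a critical operating point is controlled by the balance
of excitation and inhibition. Near criticality, band-limited oscillation
amplitudes are expected to show (i) switching between low- and high-power
modes (bistability), (ii) long-range temporal correlations (LRTC) in the
amplitude envelope, and (iii) a characteristic coupling between the local
oscillation amplitude and the normalized amplitude fluctuations. The
package quantifies these per subject, per frequency bin, and feeds the
resulting table into covariate-adjusted group statistics and a sparse
classifier.

## Epoch harmonization

All metrics operate on a fixed 278.8-s (4.65-min) eyes-closed series per
subject. Controls contribute five 1-min epochs that are concatenated;
patients contribute a continuous ~5-min record that is split into five
1-min epochs and reordered 1-3-5-2-4 before concatenation. 10.6 s are
trimmed from both ends, leaving segments of (49.4, 60, 60, 60, 49.4) s,
conventionally reported as (49, 60, 60, 60, 49). Both paths produce
byte-identical segment structure, so downstream estimates are comparable
across groups.

Filtering, Hilbert transformation and every windowed statistic treat the
five segments as separate realizations: no filter state or analysis window
crosses a segment join. Concatenating across joins would be the
alternative; the per-segment choice is the conservative one (it can only remove spurious long-range
structure, not create it).

## Frequency bands

Thirteen contiguous bins span 1-73 Hz: one delta bin (1-4 Hz) followed by
twelve geometric bins from 4 to 73 Hz (common ratio (73/4)^(1/12) ~ 1.274).
This is the unique simple construction whose edges land on the
conventional boundaries (5.1, 6.5, 8.3, 10.5, 13.4, 17.1, 27.8 and
35.4 Hz, each within 0.2 Hz of the commonly quoted values). Edges are kept at full precision internally; rounding to
0.1 Hz is display-only.

Band envelopes are obtained per segment by an order-4 Butterworth band-pass
applied forward-backward (zero phase, `sosfiltfilt`), followed by the
analytic-signal magnitude; 1 s is trimmed from each segment end to remove
filter and Hilbert transients. The filter family is a package choice; any
zero-phase recursive band-pass of similar order gives equivalent envelopes.

## Envelope-power model (BiS, E/I_HLP, E+I_HLS)

Power is defined as the squared Hilbert envelope, p(t) = A(t)^2 — for
narrowband Gaussian noise p is exponentially distributed, which motivates
the model family. Two models are fit to the power samples:

* single exponential, MLE in closed form (rate = 1/mean), k = 1 parameter;
* two-component exponential mixture, fit by EM, k = 3 parameters.

Model evidence is approximated by BIC = -2L + k ln n. The three indices:

* **BiS = BIC1 - BIC2** (evidence units; positive favours two modes;
  unbounded, not floored; 0 with a flag when the mixture is not
  identified);
* **E/I_HLP = w_hi / w_lo** (mode-occupancy ratio, dimensionless > 0);
* **E+I_HLS = log10(mu_hi / mu_lo)** (mode separation in decades, >= 0).

No canonical closed-form definitions of these three indices are fixed in
the literature available to us; the definitions above are the minimal
constructions matching their usual verbal descriptions, and each is
isolated behind a single function (`bistability_index`, `ei_hlp`,
`ei_hls`) so an alternative formula can be swapped in without touching the
fitting code. All three are invariant to positive rescaling of the
envelope (exponential-family scale cancellation), which the tests verify.

Numerical choices: EM uses 20 quantile-based initializations (split the
sample at quantiles 0.25..0.95, use the conditional means on each side),
a 25-iteration vectorized burn-in on a <=1500-point thinned subsample to
rank the starts, then the best start is polished on the full data to a
relative log-likelihood tolerance of 1e-8 with at most 500 iterations.
Power is thinned to at most 20 samples/s before fitting because BIC
assumes independent observations and envelope autocorrelation at the full
rate violates that badly; 50 ms corresponds to the fastest within-mode
power fluctuations the generator produces. Degenerate inputs (constant
power) return the single model with the mixture flagged non-identified.

## Detrended fluctuation analysis

Per segment, the envelope is demeaned and cumulatively summed into a
profile; windows of length s advance with 50% overlap; each window is
linearly detrended; F(s) pools the mean squared residuals over all windows
of all segments. The exponent is the least-squares slope of log10 F versus
log10 s over 10 geometrically spaced window sizes in [S_min, 30 s].
S_min = max(1 s, 8 / f_lo) per band — at least eight cycles of the band's
slowest component in the smallest window, a standard DFA guideline; the
choice of per-band minima is otherwise open. With segments of
(49.4, 60, 60, 60, 49.4) s the 30-s ceiling yields 8 non-overlapping
windows at the largest scale (the conventional count for this layout).

## Functional E/I ratio

Windows of 5 s advance with 80% overlap (1-s step), never straddling
segment joins. Per window: wAmp = mean amplitude; the amplitude is divided
by wAmp, 1 is subtracted, the result cumulatively summed, linearly
detrended, and summarized by its RMS (wDNF). fE/I = 1 - Pearson
correlation(wAmp, wDNF) over all windows. Values near 1 indicate no
amplitude/fluctuation coupling; the sign convention follows the original
method (the correlation is subtracted from 1). Estimates are only valid
when the band's DFA exponent exceeds 0.6; gated estimates are missing
(NaN) and propagate as cell-wise missingness.

## Lempel-Ziv complexity

The broadband signal (1-45 Hz band-passed, decimated to <=128 Hz) is
binarized at its median — an amplitude-robust threshold — and parsed with
the exhaustive-history LZ76 rule: each new phrase is the shortest prefix
of the remaining string not yet seen anywhere in the preceding text
(self-overlap allowed). The normalized complexity is c(n) log2(n) / n,
which tends to 1 for an iid fair-coin sequence. Per-channel values are
averaged. Broadband input is adopted (rather than per-band complexity)
because the measure is interpreted as a whole-signal irregularity index.

## Group statistics

Per metric x band cell, on channel-averaged subject values (patients minus
controls):

* Welch's unequal-variance t with Satterthwaite df; 95% CI on the mean
  difference from the same SE/df.
* Cohen's d with pooled (n-1)-weighted SD; CI from the Hedges-Olkin
  variance (n1+n2)/(n1 n2) + d^2/(2(n1+n2)) with normal quantiles.
* Benjamini-Hochberg step-up FDR across the 13 bands within each metric
  (textbook step-up, monotonicity enforced, capped at 1).
* Robust regression of the metric on intercept + group + z-scored age +
  sex (male = 1): IRLS with Tukey bisquare (c = 4.685), scale = MAD of
  residuals / 0.6745 re-estimated per iteration, convergence at relative
  coefficient change < 1e-8. SEs from the classical weighted covariance
  sigma^2 (X'WX)^-1 with sigma^2 = sum(w r^2)/(n - p); t-tests on n - p df.
* Freedman-Lane permutation: residuals of the reduced (age + sex) robust
  model are permuted and added back to its fitted values; the full robust
  model is refit per surrogate; p = (1 + #{|t*| >= |t|})/(1 + B),
  two-sided, add-one estimator. The robust fit generates the reduced-model
  residuals as well (internal consistency; switchable by passing a
  different fitter).

Broadband complexity additionally gets Mann-Whitney U and a label-swap
permutation test (difference of means statistic), matching the separate
treatment it receives.

fE/I missingness is handled cell-wise: gated subjects are dropped from
that cell and the per-cell n is reported. Cells whose covariate design is
degenerate (too few subjects, constant sex) report the unadjusted
statistics and flag the skipped covariate model rather than failing the
whole table.

## Classification

Feature pool: {BiS, E/I_HLP, fE/I, E+I_HLS} x the ten bands whose upper
edge is at or below ~35 Hz (higher gamma excluded as muscle-artifact
prone; a band qualifies if its exact edge exceeds the 35.2-Hz cutoff by no
more than the 0.3-Hz display rounding), plus broadband LZC, age and sex —
43 columns. DFA features are excluded by default (short-segment
reliability) and can be included (+10 columns). Labels: patients = 1.

Training protocol, all computed on training rows only (the tests verify
test-row perturbations cannot change the model): stratified 70/30 split;
missing fE/I imputed with training-column means (no missingness indicator,
keeping the feature count stable); z-scoring by training mean/SD; a
100-point geometric penalty grid from lambda_max = max|X'(y - ybar)|/n
down four decades; per-lambda L1-penalized logistic fits (saga solver,
tol 1e-7, intercept unpenalized); 10-fold stratified cross-validated
deviance; the 1-SE rule picks the largest penalty within one standard
error of the minimum mean deviance. CV fits use a looser tolerance
(1e-5) and a 5000-epoch cap — held-out deviance is insensitive to the
final digits, and near-separable folds at the small-lambda end would
otherwise dominate runtime; the final path is solved at full tolerance
and errors on genuine non-convergence.

Evaluation: AUC as the tie-corrected rank statistic; accuracy,
sensitivity and specificity at probability threshold 0.5 (the threshold is
a package choice); ROC and precision-recall point lists.

## Synthetic-data generator

The generator produces the statistical structure the metrics assume — not
biophysical EEG. Three envelope families:

* **fractional**: A = baseline * exp(0.35 z), z unit-variance fractional
  Gaussian noise synthesized exactly by circulant embedding (eigenvalues
  checked; negative embeddings raise rather than being approximated). The
  exponential keeps A > 0 and, at this modulation depth, leaves the
  scaling exponent within the DFA tolerance (recovery of H in {0.5, 0.6,
  0.75, 0.9} to +-0.05 is an acceptance check).
* **bistable**: a two-state Markov chain with exponential dwells chooses
  the mode (occupancy w_hi, occupancy-weighted mean dwell `dwell`);
  within-mode power is mu_mode * E(t), where E(t) = (g1^2 + g2^2)/2 for
  two smoothed unit-variance Gaussians — the marginal is exactly Exp(1),
  so the power distribution is exactly the two-component exponential
  mixture the bistability model fits.
* **coupled**: two *independent* fractional processes are split
  spectrally at the fE/I window scale (0.1 Hz for 5-s windows): the slow
  part sets windowed mean amplitudes, the fast part the within-window
  fluctuations. The fast part's local strength is modulated by
  1 + gamma tanh(u), where u is the standardized slow level and
  gamma = rho / (1.75 - 1.52 |rho|) — an odd rational map, calibrated once
  on the default profile, that makes the realized windowed correlation
  track the requested rho. The fast factor is divided by its own 5-s
  running mean so fluctuation strength cannot leak into the window means.
  Independence of the two processes makes the rho = 0 case decoupled *by
  construction* (an earlier single-process design with affine jitter
  scaling carried a +0.04..0.07 correlation bias from the shared driving
  noise and was discarded).

Band signals are the envelope times a constant-amplitude FM carrier whose
instantaneous frequency wanders inside the band (random initial phase).
The constant carrier amplitude means the Hilbert envelope of the synthetic
signal reproduces the programmed envelope up to one final step: each
component is band-pass filtered to its own bin after synthesis, because
fast envelope structure (mode switching, jitter) creates spectral
sidebands that would otherwise leak into neighbouring bins of a
multi-band mixture and contaminate their metrics — most visibly the
functional E/I ratio, whose windowed fluctuations are easily swamped by
leaked power. Band-limiting at synthesis mirrors what the analysis filter
does anyway for the component's own bin and removes only the cross-band
leakage. Subjects are sums of
band components plus spectrally synthesized 1/f background 20 dB below the
oscillatory power; five 60-s epochs; all randomness flows from a single
seed (identical spec + seed gives bit-identical cohorts).

Cohorts: each band is realized by the profile family matching the axis
implanted there (fractional for DFA effects, coupled for fE/I effects,
bistable for the power-distribution axes and for bands without effects).
A band can carry effects on {BiS, E/I_HLP, E+I_HLS} jointly, on DFA
alone, or on fE/I alone; other combinations raise an error naming the
steerable axes. Knob base values and between-subject SDs: Hurst 0.72
(SD 0.05), w_hi 0.35 (SD 0.06), log10 separation 1.0 (SD 0.20), rho 0.0
(SD 0.12); cohort bistable dwell 0.4 s (sub-second metastable switching
keeps the mode process out of the 1-30 s scaling range, so DFA and fE/I
stay group-equal in non-implanted bands). Effect sizes are in SD units of
the knob; a positive effect raises the metric in the patient group. Ages
are Normal(47, 16) truncated to [18, 80] years; sex is Bernoulli with
male fractions 55/133 (controls) and 60/183 (patients); default group
sizes 133/183 mirror the study the package models.

What the generator does **not** emulate: volume conduction and channel
covariance (channels are independent realizations), eye/muscle/cardiac
artifacts, non-stationary drowsiness drifts, realistic cross-band phase
coupling, and electrode geometry. Passing tests therefore demonstrate
that the estimators recover the dynamical structure they target under
clean conditions with realistic durations and sampling rates — not that
the pipeline is robust to recording artifacts (clinical preprocessing
chains that remove such artifacts are out of scope here).

Knob-to-metric fidelity through the full signal path (carrier synthesis,
band-pass, Hilbert) depends on band width: the fast fluctuation content
that the rho and w_hi knobs shape must fit inside the band. Steering is
strong for bands wider than ~2 Hz; in the narrowest, slowest bins (1-4,
4-5.1, 5.1-6.5 Hz) fE/I and occupancy effects are attenuated by the
filter. The end-to-end recovery checks therefore implant effects in
mid-frequency bands (theta through low gamma); implanting in the narrow
delta/theta bins is possible but yields smaller realized effect sizes.
Realized metric-level effect sizes are attenuated relative to the knob
shift by measurement noise (roughly d_metric ~ 0.6-1.0 x d_knob for the
implants used in the acceptance checks, measured, at 2 channels).

Knobs also cross-couple between metrics, and the coupling map is exposed
via `perturbed_cells`: the mode-separation knob moves both BiS and
E+I_HLS strongly (same knob) and the occupancy *estimate* weakly (mixture
blurring); the occupancy knob moves E/I_HLP strongly and fE/I
substantially (windows rich in high-mode samples have both higher mean
amplitude and different normalized fluctuations), plus BiS weakly.
`perturbed_cells(spec)` lists the strong same-knob cells an
effect-detection check should flag; `perturbed_cells(spec, extended=True)`
adds the weaker cross-coupled cells, which a classifier may legitimately
select. In full multi-band mixtures the fE/I estimate also carries a
small negative-correlation offset (~ +0.1 on the fE/I scale) from
residual broadband noise inside the analysis band; it is common to both
groups and cancels in contrasts. The decoupled-envelope calibration
(fE/I = 1.0 +- 0.05) is defined on directly realized envelopes, where no
mixture is involved.

## Problem sizes used in the checks

The verification suite uses 278.8-s envelopes at 100 Hz for calibration
and recovery checks (metric values are sampling-rate invariant at these
rates), a 100 + 100-subject cohort at 250 Hz with 2 channels for the
end-to-end recovery, 200 null replicates at B = 500 for permutation
calibration, and n = 50,000 samples for mixture recovery. These sizes
give Monte-Carlo error comfortably below each stated tolerance.

## Known limitations

* BIC-based BiS treats thinned power samples as independent; residual
  autocorrelation inflates |BiS| in strongly smoothed envelopes. Group
  contrasts are unaffected (both groups share the bias), but absolute BiS
  values should not be compared across sampling rates.
* The robust-regression SEs use the classical weighted covariance, not a
  sandwich estimator; with heavy contamination the Freedman-Lane
  permutation p is the more trustworthy inference.
* The EM mixture fit can report convergence at a local optimum when modes
  overlap heavily (separation < ~2x); the 20 quantile-based restarts make
  this rare but not impossible.
* EDF files can be read (via mne) but not written; the native interchange
  format is a CSV matrix with a JSON sidecar.
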