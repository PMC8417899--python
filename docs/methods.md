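# Methods

This note documents the models, conventions and design choices behind
`hrvstim`, in the order of the processing chain.

## Synthetic RR series and ECG

RR intervals are generated beat by beat: the k-th interval is

    RR_k = mean_rr + A_LF·sin(2π f_LF t_k) + A_HF·sin(2π f_HF t_k) + ε_k,

with the modulations evaluated at the running beat time `t_k` and
`ε_k ~ N(0, jitter_sd²)` i.i.d. This is a deliberate simplification of
integral pulse frequency modulation: modulation frequencies are recovered
accurately by a Lomb–Scargle periodogram of the beat-anchored series, but
the fine phase structure of real cardiac pacemaker dynamics is not
reproduced. Defaults (mean 900 ms, LF 0.1 Hz/30 ms, HF 0.25 Hz/20 ms,
jitter 5 ms) sit in the middle of resting adult ranges, with both
modulation frequencies inside the canonical LF (0.04–0.15 Hz) and HF
(0.15–0.4 Hz) bands. Configurations whose worst-case deterministic
amplitude reaches the mean are rejected up front; a jitter draw that would
still produce a non-positive interval raises rather than clipping, so the
generator never silently distorts its own spectrum.

ECG traces are a sum of five Gaussian bumps (P, Q, R, S, T) per beat, with
offsets and widths scaled by the local RR so complexes never collide. The
template is tuned for a 1 s beat (R amplitude 1 mV, T 0.3 mV, P 0.15 mV); a
0.3 s lead-in precedes the first beat so its complex is complete. The model
gives exact R-apex ground truth, which is what the detector tests need; it
makes no claim to clinical morphology (no ST segments, U waves, or
arrhythmia). Noise is added after clean synthesis — sinusoidal baseline
wander, sinusoidal mains with random phase, and broadband Gaussian noise at
a target SNR relative to the clean trace — and the clean trace is retained
so filtering can be scored exactly. Sample rates below 250 Hz are rejected,
the floor for adequate ECG bandwidth.

Studies assign each subject a randomized order of `epochs_per_class` epochs
per leaf class, separated by 5 s of silence (stimulus epochs must last at
least 10 s, the minimum for HRV indices to establish a pattern). The
stimulus effect model is an assumption of this package, not an empirical
claim: leaf class k (normalized rank u = k/(K−1)) shifts mean RR by
+40·u·`effect_size` ms, LF amplitude by +25·u ms and HF amplitude by
−12·u ms — a monotone sympathovagal gradient across the stimulus order.
With `effect_size = 0` all classes are generated identically, which is the
null condition used to check that the pipeline does not hallucinate
structure. Per-subject random streams are derived from the top-level seed
by a fixed offset (10 000 per subject), so adding a subject never perturbs
the others.

## Preprocessing

Baseline wander is removed by subtracting a two-pass cascaded moving-filter
estimate. Each pass is a moving *median* (0.2 s, then 0.6 s): the short
window rejects QRS complexes, the long one rejects P/T waves. Medians are
used instead of means because a mean cascade tracks the beat-periodic
(~1 Hz) component of the ECG itself and subtracts part of the T wave with
it — on synthetic records the mean cascade left only 0.986 correlation with
the clean trace, versus 0.996 for the median cascade. The stepwise median
output is smoothed by a zero-phase 1 Hz Butterworth low-pass, and the
estimate is refined once on the residual; the refinement cancels the small
duty-cycle offset of the median (the 50th percentile of a window sits
slightly above the true baseline when positive waves occupy part of it) and
makes the operation approximately idempotent (< 1% RMS change on a second
application).

Mains interference is cancelled with a second-order IIR notch (default
Q = 30) run forward–backward; the QRS-enhancement band is a 4th-order
Butterworth 5–15 Hz bandpass, also zero-phase. All filters preserve length
and introduce no group delay, verified by a zero cross-correlation lag on
clean QRS. Filtering performance is assessed as
`SNR = 10·log10(P_ref / P_residual)` against a reference trace, capped at
120 dB when the residual vanishes.

## Beat detection and NN cleaning

The R-peak detector follows the classic Pan–Tompkins stages with the usual
constants (5–15 Hz bandpass, 5-point derivative, 150 ms integration window,
200 ms refractory period, running-estimate update factor 1/8, threshold
fraction 1/4), plus a search-back pass that rescans any gap longer than
1.66× the running mean RR at half threshold. Detected fiducials are refined
to the local maximum of the bandpassed ECG within ±50 ms, so reported times
are R apexes. All constants are exposed in `PanTompkinsParams`.

RR intervals are the successive differences of beat times in ms, anchored
at each interval's second beat. The NN ("normal-to-normal") rule is a
documented heuristic, not a clinical ectopy classifier: intervals outside
[300, 2000] ms or deviating more than 20% from an 11-beat running median
are flagged and excluded from NN statistics.

## HRV features

- **Dispersion statistics** (SDNN, SDANN, SDNN index) use the sample (n−1)
  standard deviation. SDANN and the SDNN index are computed over
  non-overlapping 5-min windows and flagged undefined below 10 min.
- **Frequency domain** uses the Lomb–Scargle periodogram on the
  mean-centred, beat-anchored series — no resampling, so irregular beat
  spacing is handled natively. The density is scaled so integrating across
  a peak recovers the variance contribution (A²/2 for amplitude A), giving
  band powers in ms². Bands are half-open [lo, hi): ULF [0, 0.0033), VLF
  [0.0033, 0.04), LF [0.04, 0.15), HF [0.15, 0.4]. The 0.0033 Hz ULF/VLF
  edge is adopted as the single shared boundary. The frequency grid
  oversamples the record length fourfold.
- **Poincaré** SD1/SD2 use population moments via the variance identities
  `sd1² = var(ΔRR)/2`, `sd2² = 2·var(RR) − sd1²`, so
  `sd1² + sd2² = 2·var(RR)` holds exactly and constructed series hit their
  closed forms exactly; the SD1/SD2 ratio is flagged undefined when SD2 is
  zero. This is the one feature group that deviates from the sample-SD
  convention, deliberately, for the exactness of the identity.
- **Geometric**: histogram bin width defaults to 1/128 s = 7.8125 ms, bins
  aligned to multiples of the width. TRI is N over the modal bin height.
  TINN minimizes the squared error of a triangle rising from zero at N to
  the modal height and falling to zero at M, searched over bin-center
  candidates; a single-occupied-bin histogram gives TRI = 1, TINN = 0.
- **DFA** integrates the centred series, detrends linearly per
  non-overlapping box, and fits log F(s) on log s over 4–16 beats (α1) and
  16–64 beats (α2), with ~10 log-spaced box sizes per range and at least
  4 boxes of the largest size required. Linear detrending at very small
  boxes biases the white-noise exponent slightly above the asymptotic 0.5
  (measured ≈ 0.59 over 4–16); this is a known property of standard DFA at
  short scales, shared by common HRV toolchains, and is left uncorrected.
- **Entropy**: ApEn (self-matches included) and SampEn (excluded), m = 2,
  tolerance r = 0.2 × SD, Chebyshev distance. Zero-variance series return
  (0, 0) flagged; SampEn with no matches is NaN flagged.
- **Fractal dimension**: Higuchi with k_max = 10; Katz computed on the
  z-scored series with unit index spacing, which makes it scale-invariant
  (the raw Katz formula depends on the series' units).
- Degenerate inputs produce NaN values plus an entry in the result's
  `flags` set — never a silent zero and, except for an empty series, never
  an exception, so batch pipelines survive odd segments.

## Association pipeline

Epochs are half-open [onset, onset+duration); an RR interval belongs to the
epoch containing its anchor time. Epochs shorter than the configured
minimum (default 10 s) are dropped with a warning. Augmentation preserves
labels and records parent ids: noise addition draws k jittered copies;
windowing slides a window with fractional overlap and passes oversized
segments through unchanged with a warning.

Feature datasets drop (default) or median-impute columns flagged in any
segment, recording dropped columns explicitly. Scalograms use the analytic
complex Morlet wavelet, with the RR sequence treated as beat-indexed
samples at the mean interval for the scale-to-frequency map. Feature
ranking estimates mutual information with equal-frequency binning (8 bins)
— deterministic, ties broken by column index. Splits are seeded; the
group-aware mode assigns whole subjects to one side and asserts the
subject intersection is empty on every plan. The built-in backends
(nearest-centroid, k-NN with standardization) are deliberately light;
anything exposing `fit(X, y)` / `predict(X)` plugs in.

## Evaluation

Accuracy, per-class/macro F1, Cohen's κ and multiclass MCC (Gorodkin's R_K)
are computed directly from the confusion matrix. κ is labelled on the
Landis–Koch intervals (0–0.20 slight, 0.21–0.40 fair, 0.41–0.60 moderate,
0.61–0.80 substantial, 0.81–1.00 almost perfect); negative values, though
outside the conventional scale, are reported verbatim with the label
"below scale". MCC with a degenerate margin returns 0 with a warning.

The hierarchical cost matrix follows the construction described in the
README. Two points deserve emphasis:

- **Within-class assignment.** For a true subclass at rank r, the class's
  subclasses are sorted by (hierarchical distance |r − r′|, rank) and
  receive the sorted weight vector in that order. Indexing weights directly
  by distance would under-spend the budget for middle ranks (two subclasses
  can share a distance); the rank-of-distance assignment is the only
  reading under which every row is a permutation of the weights and sums to
  C exactly, while preserving "adjacent costs less than distant".
  Equidistant neighbours are tie-broken toward the lower rank.
- **Singleton general classes.** A general class with one subclass has no
  within-class wrong option; its sub-cost share is redistributed uniformly
  over the row's cross-class options (factor n_general/(n_general − 1)) so
  the budget is still spent exactly. A hierarchy with fewer than two leaf
  classes is rejected.

The Gompertz denominator sums the same expression over j = 1..n that the
numerator evaluates at i. Normalized cost divides total cost by the
*per-row* worst case (each instance sent to its own row's most expensive
prediction), which keeps the value 1 attainable; a single global-maximum
reading would make 1 unreachable for most hierarchies.

## Problem sizes and what the tests show

The test suite and the acceptance script run on synthetic data sized for
tight statistical envelopes at interactive runtimes: 300 s series for
spectral recovery, 1000-beat series × 50 replicates for DFA, 60–120 s ECG
for detector fidelity, and 6-subject × 16-epoch studies (5 effect and 10
null replicates) for end-to-end decoding. Passing these shows the chain is
internally consistent and recovers planted effects; it does not show
robustness to real-world phenomena the generator omits — ectopy, electrode
motion artifacts, non-stationary autonomic tone, respiration coupling — and
the stimulus effect model is an assumed monotone gradient, not a measured
one.

## Known limitations

- The RR generator is additive, not an integral-pulse-frequency-modulation
  model; spectral sidebands of real heart-rate modulation are absent.
- The NN cleaning rule and the 20% median tolerance are heuristics and
  should be stated when reporting results derived from them.
- Deep/transfer-learning backends are out of scope; scalograms are produced
  as the representation such models would consume.
- Respiration, EEG, EDA, blood pressure and PPG channels are not simulated
  or analysed.
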