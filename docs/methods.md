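# Methods

## The activation synchrony index

Interhemispheric synchrony (IHS) in the discontinuous EEG of newborns near
term age is the temporal co-incidence of high-amplitude bursts between
homotopic regions of the two hemispheres. The ASI operationalizes this as an
information-theoretic contrast: if bursting is co-incident, the statistical
dependency between the two hemispheres' amplitude envelopes is concentrated
at (near-)zero lag; if bursting is independent, dependency at small lags is
no larger than at lags far beyond the burst timescale.

For one homotopic pair of bipolar derivations the computation is:

1. **Bipolar derivation.** Anterior minus posterior electrode per
   hemisphere (e.g. C3−O1 and C4−O2). IHS is conventionally read from
   bipolar derivations; no referential variant is offered.
2. **Preprocessing.** 4th-order Butterworth band-pass 0.5–20 Hz applied
   forward–backward (zero phase), then a first-difference pre-emphasis
   `y[t] = x[t] − α·x[t−1]` with `α = 0.95`. The band covers neonatal burst
   energy; pre-emphasis weights the faster components that distinguish
   burst onsets from slow drifts. Both are configurable; pre-emphasis can
   be disabled (`preemphasis: null`).
3. **Amplitude envelope.** Full-wave rectification, 1.0-s moving-average
   smoothing, then one frame per 1/16 s (the mean of the smoothed signal in
   the frame). The 1-s/16-Hz combination preserves burst timing (seconds)
   while discarding carrier phase.
4. **Quantization.** Equal-occupancy (quantile) binning into `Q = 8`
   levels, computed on the analysis window itself; codes are assigned by
   rank with stable tie-breaking. Equal occupancy maximizes the marginal
   entropy of each code sequence and makes the index *exactly* invariant to
   channel gain and to any strictly monotone amplitude transform (exact up
   to floating-point collisions: a transform that maps two distinct sample
   values to the same float changes the tie structure).
5. **Lagged dependency and the scalar index.** `I(τ)` is the plug-in
   (maximum-likelihood histogram) mutual information, in bits, of the joint
   `Q×Q` distribution of the two code sequences at relative lag `τ` on the
   frame grid. Then

   `ASI = mean{I(τ) : |τ| ≤ 0.5 s} / mean{I(τ) : 5 s ≤ |τ| ≤ 30 s}`.

   The numerator window tolerates sub-second physiological asymmetry in
   burst onsets; the baseline sits beyond the burst-duration timescale
   (~5 s) but within a window short enough that 2.5-min analysis windows
   retain ≥100 frames of overlap at every lag. The baseline mean is floored
   at `ε = 10⁻⁴` bits (result flagged when the floor binds). Lags with
   fewer than 100 overlapping frames are dropped with a warning.

No bias correction is applied to the plug-in MI: the index is a *ratio* of
MI averages, and the (Q−1)²/(2N ln 2) small-sample bias inflates numerator
and baseline nearly equally, so independent envelopes score close to 1 by
construction. The per-cell MI terms are accumulated with exact summation
(`math.fsum`) so results are independent of accumulation order and
bit-comparable against a naive reference implementation.

All of these constants (band, α, smoothing, frame rate, Q, lag windows, ε)
are stand-in choices for an algorithm whose published description leaves
them open; they live in `ASIConfig` precisely so alternative settings can be
dropped in without touching code.

## Windowing, stability and the MSD criterion

An ASI estimate needs a few minutes of data to stabilize; windows shorter
than 2.5 min are refused. Five schemes spend (part of) a 10-min quiet-sleep
epoch: `1x10`, `4x2.5`, `2x5`, `2x2.5`, `1x5` (n windows × minutes,
contiguous from the epoch start; per-window ASIs are averaged). Test–retest
stability across a subject's two 10-min epochs is scored by

`MSD = (1/n) Σᵢ (ASI₁,ᵢ − ASI₂,ᵢ)²`

and minimized over the 5×5 grid of derivation pairs × schemes. On synthetic
cohorts the averaged short-window schemes beat the single long window
(averaging reduces estimator variance when the planted synchrony is
stationary), reproducing the expected ordering; the centro-occipital pair is
used for classification throughout.

Windows containing NaNs or annotated artifact are rejected; in `strict` mode
(default, mirroring manually selected clean epochs) any rejection aborts the
subject, in `tolerant` mode the mean is taken over survivors with a logged
count. The subsequent-vs-separated quiet-sleep comparison
(`epoch_sources_compare`) contrasts per-subject squared epoch differences
between the two sampling conditions with a two-sided Mann–Whitney U test —
exact null distribution when both arms have n ≤ 20, normal approximation
with tie correction otherwise.

## Classification

`ASI_class = min(mean₁ ASI₂.₅, mean₂ ASI₂.₅)` represents the lowest
synchrony level observed in a subject. Low ASI ⇒ abnormal: a subject is
predicted abnormal iff `ASI_class ≤ threshold`, ties at the threshold
deliberately classified abnormal (conservative for screening). The default
threshold 3.6 is the published operating point and is never re-fitted; the
ROC module reports Youden's J alongside it. The ROC staircase is built over
all distinct score cut points with tied scores forming one step; the
trapezoid AUC is asserted on every call to equal the Mann–Whitney
pair-counting probability (½ credit for ties). The group comparison uses
Welch's t-test (no variance-equality assumption). The data-budget study
takes the first b/2 minutes of each of the two epochs for a budget of b
minutes, combines per-window ASIs within each half by mean/min/max, and
reduces the two halves by min; regimes whose window exceeds the per-epoch
share are skipped.

The age check regresses `ASI_class` on postmenstrual age (OLS, per group and
pooled) and reports the slope with its confidence interval; with no planted
age effect the CI should cover zero at its nominal rate.

## The synthetic generator

Real neonatal recordings are not publicly shareable, so validation rests on
a generator that emulates the *one* property the method measures:
discontinuous background with controllable interhemispheric burst timing.

- Burst onsets are a renewal process: after each burst, an exponential
  off-gap with mean `60/rate − duration_mean` (floored at 0.5 s), so bursts
  never overlap and the long-run burst-state fraction is
  `min(~1, rate·duration/60)`. Defaults: 6 bursts/min, 5 ± 1.5 s duration —
  roughly half the time in burst state, a tracé-alternant-like cadence.
  These defaults are stipulated, not fitted to any cohort.
- The per-sample envelope gate is 1 in bursts and 0.15 between them
  (inter-burst amplitude ratio), with 0.5-s raised-cosine edge ramps so
  band-pass filtering does not ring at transitions.
- Each channel is independent Gaussian noise band-passed to 0.5–10 Hz,
  scaled to ≈200 µV peak-to-peak in bursts, multiplied by its hemisphere's
  gate. Independent carriers keep within-hemisphere bipolar derivations
  from cancelling.
- The **synchrony plant**: left-hemisphere channels share one burst train;
  right-hemisphere bursts are shifted by a fixed lag, jittered per burst
  (Gaussian, `onset_jitter_sd`), and dropped unilaterally with
  `miss_prob`. Jitter (or misses) monotonically destroys zero-lag envelope
  dependency, moving the record along the synchronous → asynchronous
  continuum.
- Default cohort: 14 "normal" subjects (0.2-s jitter — essentially
  synchronous) and 17 "abnormal" (8-s jitter — beyond the burst duration,
  destroying co-incidence), PMA uniform 36–42 weeks with no influence on
  the signal (an optional `pma_jitter_slope` hook plants an age trend for
  power studies), 1200-s records with two subsequent 10-min quiet-sleep
  epochs. All generators are pure functions of their seed; per-record seeds
  spawn deterministically from the cohort seed.

What the generator does **not** emulate: sleep-state cycling, age-specific
graphoelements (delta brushes, encoches frontales), realistic artifact
taxonomies (only a single high-amplitude transient injector is provided),
inter-subject variability in burst morphology, and volume-conduction
correlations between channels. Passing tests therefore demonstrate that the
pipeline recovers *planted burst-timing synchrony* under clean, stationary
conditions — not clinical performance on real recordings, whose headline
numbers (accuracy, AUC, MSD magnitudes) depend on a specific non-public
clinical cohort and are not reproducible here.

## Problem sizes and numerical choices

- Validation studies use cohorts of 31 records (14 + 17) of 1200 s at
  256 Hz; multi-cohort properties (label recovery, stability ordering,
  budget ordering) average over 10 cohort seeds, and the age-null coverage
  over 20 — enough to separate the planted effects cleanly while keeping a
  full run in the minutes range on one CPU.
- Epochs and annotations use half-open `[start, end)` intervals in seconds
  from record start, everywhere.
- Degenerate inputs fail loudly with typed errors: flat envelopes
  (unquantizable), missing electrodes (named in the error), short windows,
  NaNs, one-class metric requests (reported as undefined, never as 0).
- EDF output uses a built-in plain-EDF writer (16-bit, 1-s records) with a
  JSON sidecar for annotations and ground-truth metadata; EDF reading goes
  through mne, with vendor channel labels normalized to canonical 10-20
  names ("EEG Fp1-Cz" → "Fp1") and unknown labels passed through untouched,
  failing only when a montage actually requests them.
- Every pipeline run writes its resolved configuration and a hash of it
  beside the outputs and refuses to overwrite a directory produced by a
  different configuration.

## Known limitations

- The exact constants of the original published ASI (its band, envelope
  estimator, Q, and lag sets) are not public in the main literature; this
  implementation's defaults are reasoned stand-ins, so absolute ASI values
  are not directly comparable to published ones (thresholds like 3.6
  transfer only in the sense of "an operating point between the planted
  groups").
- Whether the original index uses a single zero-lag value or a small
  zero-centred numerator window is unspecified; the ±0.5-s window was
  chosen for robustness to sub-second physiological asymmetry and is
  configurable (`numerator_max_lag`).
- The subsequent-vs-separated epoch comparison tests one reading of the
  published procedure (U test on per-subject squared epoch differences);
  other constructions of the two arms are possible.
- Quiet-sleep epochs must be supplied as annotations; automated sleep
  staging is out of scope.
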