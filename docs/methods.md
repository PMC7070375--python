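# Methods

## The problem

A phonocardiogram (PCG) records the acoustic vibrations of the heart at the
chest surface. Its two dominant events per heart cycle are the first heart
sound S1 (closure of the mitral/tricuspid valves, start of systole) and the
second heart sound S2 (closure of the aortic/pulmonary valves, start of
diastole), both concentrated in roughly the 20–200 Hz band and each no longer
than about 150 ms. `heartsounds` detects these events and labels them S1 or
S2 using only the envelope of the PCG — no training data, no probabilistic
state model — so that the method remains cheap enough for wearable,
real-time use and does not depend on a training corpus matched to posture,
auscultation site or exercise state.

## Processing model

The pipeline per recording is:

1. **Band-pass filtering.** A Butterworth cascade of a high-pass section at
   `f_lower` (order `order_hp`) and a low-pass section at `f_upper` (order
   `order_lp`). Defaults: 40–190 Hz, orders 4/10 for the Hilbert route;
   20–120 Hz, orders 4/10 for the STFT route. Filtering is causal by
   default — the constant group delay shifts every PCG-derived event equally
   and is absorbed by the 150 ms evaluation tolerance; a zero-phase mode
   (forward–backward) exists for offline analysis.

2. **Segmentation.** After discarding a synchronization prefix (8 s by
   default, where the ECG-alignment knocks live), the recording is split
   into `n_segments` (5) equal, non-overlapping intervals that are analysed
   independently. For envelope extraction and peak detection each segment is
   padded by one maximal heart-sound length (150 ms) of neighboring signal
   — a sound cut by a segment boundary has no interior envelope maximum in
   either half and would otherwise be lost — and only events whose time falls
   inside the segment proper are kept, so segment event sets stay disjoint.
   Events within 75 ms of the physical edges of the analysed slice are
   discarded: their neighborhood is unobservable and envelope edge
   transients concentrate there.

3. **Envelope extraction**, by one of two selectable back-ends:
   * *Hilbert transform (HT)*: `E(t) = sqrt(x(t)^2 + H[x](t)^2)`, the
     analytic-signal magnitude, computed over the whole segment in the
     frequency domain. Valid for narrowband signals such as heart sounds;
     keeps the full 4 kHz time base.
   * *STFT*: Hamming-windowed short-time Fourier transform with window
     length b = 128 samples and overlap k = 96.875 % (hop 4 samples ⇒ 1 ms
     time base at 4 kHz); the envelope is the per-frame **maximum of the
     power spectral density** |S(t, ω)|². Power stays in linear units;
     dB scaling is display-only. Incomplete edge frames are dropped rather
     than zero-padded so no fabricated low-power frames bias the envelope
     mean.

4. **Peak detection.** Local maxima are gradient sign changes from + to −
   (plateaus reduce to their first sample). Maxima below
   `mean(envelope) · n` are discarded; the mean is taken per analysis
   segment, and `n` depends on the heart-rate regime (`n_normal` = 1.9 / 1.0,
   `n_high` = 1.3 / 0.6 for HT / STFT — the STFT envelope is smoother, hence
   lower thresholds). Peaks closer than 150 ms — the maximal duration of one
   heart sound — are collapsed greedily onto the largest of the cluster
   (ties to the earlier peak), which is what makes split sounds resolve to a
   single detection.

5. **Cardiac timing from the autocorrelation (ACF).** The ACF of the
   mean-removed envelope has major maxima at multiples of the heart cycle
   (full overlap) and minor maxima at the systole/diastole offsets
   (S1-against-S2 overlap). The average cycle is the lag of the first major
   maximum after zero, searched within 1.5 s — fixing 40 bpm as the lowest
   detectable rate; lags below the 300 ms cycle of the 200 bpm ceiling are
   excluded a priori. Average heart rate is `60000 / cycle_ms`.

   The average systolic length SYS comes either from the first minor ACF
   maximum (lag < cycle/2, positive value) or — the default, which proved
   more stable — from the empirical linear regressions

       SYS(HR) = −1.14·HR + 371.55 ms   (HR > 80 bpm)
       SYS(HR) = −6.58·HR + 766.44 ms   (otherwise)

   The two branches disagree at HR = 80 exactly (240.04 vs 280.35 ms); the
   boundary uses the "otherwise" branch by the strict reading of the
   condition. Then DIA = 60000/HR − SYS, and a ±175 ms tolerance — the
   150 ms maximal sound duration plus a 25 ms systolic standard deviation —
   gives SYSmin/SYSmax; the diastole bounds follow by conservation
   (DIAmax = cycle − SYSmin, DIAmin = cycle − SYSmax).

6. **Classification**, switched on the estimated rate at 80 bpm:
   * *Increased rate (> 80 bpm)*: systole and diastole are nearly equal, but
     S1 is physiologically louder than S2. Scanning left to right, a gap
     shorter than SYSmax whose left peak is taller than its right makes an
     S1/S2 pair; a gap longer than SYSmax marks an S1 whose S2 went
     undetected. A trailing peak is S1 when its preceding gap exceeds SYSmax
     or completes a valid diastole after a labelled S2.
   * *Normal rate (≤ 80 bpm)*: amplitudes are unreliable, but the systole is
     clearly shorter than the diastole. Extra peaks (S3, S4, artifacts) are
     removed first, in two passes over the inter-peak gaps Δx (recomputed
     after every removal):
     - Pass 1 (*invalid diastole*): the right peak of a gap below DIAmin is
       dropped when a valid systole precedes it and another follows two gaps
       on, and the merged gap would be a valid diastole — removal must
       repair the diastole it claims is broken. A missing-S2 variant accepts
       a valid diastole + systole before the gap instead of the trailing
       systole. When several gaps qualify simultaneously the *shortest* gap
       is resolved first: an extra sound late in the diastole makes the gap
       from it to the next S1 masquerade as a valid systole, and
       worst-violation-first removes the extra before that spurious context
       can sacrifice a genuine S2.
     - Pass 2 (*extra sound shortly before S1*): such a peak leaves the
       preceding diastole valid, so pass 1 cannot see it. The right peak of
       a valid-diastole gap is dropped when a valid systole precedes, the
       gap onward to the next peak falls short of SYSmin (the "shortly
       before" signature — without it the condition also fires on clean
       sequences), and a valid systole follows two gaps on (three with one
       S2 missing).
     The surviving gaps are true systoles, diastoles and cycles: a peak
     flanked by two gaps above SYSmax is an S1 with the neighboring S2
     undetected; remaining gaps label their endpoints (systole band: left
     S1/right S2; diastole band: left S2/right S1; earlier labels win; a
     gap inside the band overlap counts as systole, the more stable phase).
     One pairing refinement: two consecutive systole-band gaps cannot both
     be real, so when the second is followed by a valid diastole the first
     does not label — otherwise a leading extra sound just before a
     segment's first S1 steals its label. Leftover peaks stay unclassified.
     At most one anomaly (extra peak or missing S2) per diastole is
     resolved; denser clutter yields unclassified events, a known
     limitation.

7. **Evaluation against the ECG.** The R-peak of the ECG is synchronous with
   the S1 onset, so R-peaks are the reference for S1 (S2 has no ECG
   counterpart and is only checked against synthetic ground truth). Each
   R-peak spawns a symmetric tolerance window (150 ms wide); a classified S1
   inside an unconsumed window is a true positive (greedy one-to-one
   matching in time order; a duplicate inside a consumed window is ignored),
   an S1 outside every window a false positive, an unconsumed window a false
   negative, and a detected non-S1 event outside every window a true
   negative — the "true negative" of event detection is not canonical, and
   this observable definition is what the reported specificity and accuracy
   mean here. Sensitivity, specificity, accuracy, precision and F1 follow;
   0/0 is reported as NaN, never as 0. Counts are summed per recording
   before computing metrics (micro-averaging). R-peaks outside the analysed
   span (e.g. in the discarded prefix) are not scoreable.

### Heart-rate picker details

Identifying the first *major* ACF maximum is the one genuinely open design
point. Three standard period-estimation guards are combined: (i) candidate
lags are restricted to [0.3 s, 1.5 s], the cycle range of 40–200 bpm — at
very high rates the merged systole/diastole minor maxima form a strong peak
near half the cycle, but they imply an impossible rate; (ii) candidates are
scored by harmonic summing, `ACF(L) + 0.5 · max ACF near 2L`: a true cycle
lag repeats at its double, a minor maximum does not, and the double-cycle
harmonic is penalized because its own double is weak; (iii) as a backstop
against jitter making the two-cycle peak win outright, the pick descends to
a comparable local maximum (≥ 75 %) near half its lag while one exists.
Without these guards, octave errors and minor-maximum confusions each occur
in roughly one of thirty 6 s segments on jittered synthetic data.

## The synthetic-data generator

Real recordings with reference ECGs are not distributed with the package, so
every quantitative claim is made on synthetic PCG/ECG pairs with known ground
truth. The generator emulates exactly the structure the algorithm assumes:

* S1 and S2 are Gaussian-tapered cosine bursts (taper σ = duration/6):
  smooth, band-limited, narrowband — the regime where the Hilbert envelope is
  a faithful amplitude contour. Defaults: S1 50 Hz / 100 ms, S2 70 Hz /
  80 ms, both inside 20–200 Hz. No quantitative spectral centers are
  established for S1/S2 beyond that band; these are physiologically
  plausible choices and are exposed as configuration.
* Cycle lengths are 60/HR plus zero-mean Gaussian jitter (default SD 20 ms,
  ordinary short-term heart-rate variability); each cycle's systole is
  recomputed from the empirical formula at the instantaneous rate, so the
  timing model of the data matches the classifier's assumptions. The S2 peak
  sits one systole after the S1 peak, matching how the algorithm measures
  systoles (major peak to major peak).
* Amplitudes get 5 % relative per-event jitter. The S1:S2 ratio defaults to
  1.0 (at normal rates S1 need not dominate); increased-rate scenarios use
  1.8, the lower end of the measured high-rate dominance of S1.
* Optional artifacts: split sounds (a second sub-burst 40 ms after the
  first, at 0.7 relative amplitude — ground-truth times unchanged), S3 extra
  sounds (35 Hz, 60 ms, 0.35 of the S2 amplitude, 150 ms after the S2 peak,
  early-diastolic as physiology has it), and additive white noise scaled to
  the S1 amplitude.
* The ECG channel (500 Hz) places an R-like deflection (narrow positive
  Gaussian with small Q/S dips) at each S1 onset; the R-peak train is the
  evaluation reference.
* One integer seed drives deterministic sub-streams for timing, amplitudes
  and noise; identical seeds give bit-identical recordings.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: murmurs and valve pathology, respiratory
amplitude modulation, body-surface transfer functions, sensor and contact
noise with non-white spectra, S4 sounds, and drifting (non-stationary) heart
rates within a segment. Results on synthetic data bound the algorithm's
behavior under its own assumptions; they do not predict clinical
performance.

## Numerical and scale choices

* Times are absolute seconds throughout; the ECG is never resampled to the
  PCG rate. Lengths in the timing model are milliseconds.
* All band thresholds (systole/diastole bounds) are strict inequalities;
  amplitude ties in peak suppression resolve to the earlier peak.
* The ACF is computed by FFT on the mean-removed envelope (zero-padded to
  avoid circular wrap) over lags up to half the segment duration.
* Analyses use 30 s recordings for rate-recovery and scoring runs and 20 s
  for the noise ladder, with segmentation into 5 intervals — enough cycles
  per segment (≥ 5 at 50 bpm) for a stable ACF at a few seconds' compute.
* The noise ladder is a doubling sequence 0, 0.125, 0.25, 0.5, 1.0 × S1
  amplitude (clean to roughly 0 dB SNR). Beyond 0 dB scoring becomes
  noise-dominated and uninformative.
* Degenerate inputs fail loudly with typed exceptions (constant envelope,
  sub-window signals, rates outside 40–200 bpm, unsynchronizable channels);
  the pipeline converts per-segment failures into unclassified segments and
  continues.

## Known limitations

* One anomaly per diastole: two or more extra peaks between consecutive
  sounds defeat the removal rules (events go unclassified).
* A cycle that both lost its S2 *and* gained an extra sound at a segment
  boundary is locally indistinguishable from a genuine S2–S1 diastole pair;
  labels there may be wrong.
* Pathological sounds (murmurs) are out of scope; S3/S4 are only ever
  "extra peaks" to remove, never identified as such.
* The ECG R-peak detector is built for the clean synthetic reference
  channel; it is not a general-purpose QRS detector.
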