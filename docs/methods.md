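# Methods

## Signal model and processing chain

The input is a multi-lead murine ECG: amplitudes in mV, acquisition rate
typically 2000 Hz, leads I/II/III in the Einthoven configuration (lead II
usually carries the strongest murine signal and is the default analysis
lead). Long recordings are processed in 20-minute fragments; a trailing
partial fragment is kept and flagged, and its true duration is used for
heart-rate normalisation, so no data is silently dropped.

The pre-processing chain runs, in order:

1. **Zero-phase high-pass.** A 2nd-order Butterworth with 5 Hz cut-off,
   applied forward-backward (`filtfilt`) with reflected padding of 3× the
   filter order. This removes baseline wander and respiratory drift without
   shifting the R peak in time.
2. **Decimation** to the working rate (default 1000 Hz), by keeping every
   k-th sample. No separate anti-alias filter is inserted: the following
   hard band-pass removes most aliased out-of-band energy, and keeping the
   stage minimal preserves the exact timing of the retained samples. The
   decimation factor must be an integer.
3. **FFT band-pass**, 100–200 Hz. The murine QRS concentrates its energy
   well above the P/T waves and below EMG; a brick-wall mask in the
   frequency domain (zero all bins outside the band, inverse FFT) isolates
   it. The mask makes the operation idempotent and exactly zero-phase. The
   cut-offs are fixed in Hz; if the working Nyquist frequency falls below
   the upper cut-off (e.g. a 250 Hz working rate) the band is clipped to
   Nyquist and a warning is emitted rather than rescaling the band.
4. **Zero-phase derivative**: central difference (x[i+1] − x[i−1])·rate/2
   with replicated edges, in mV/s. The symmetric kernel keeps zero phase; a
   first difference would shift features by half a sample.

Every stage except decimation preserves length, and every stage preserves
R-peak timing; this is what makes sample-accurate beat annotation possible.

## R-peak detection

Candidates are local maxima of the **rectified** derivative signal.
Rectification is deliberate: a zero-phase derivative turns the QRS into a
symmetric positive/negative slope pair whose polarity depends on lead
orientation and on whether the R or S limb is steeper, so the magnitude is
the robust detection statistic. The height threshold (default 0.05 mV) is
expressed on the trace's amplitude scale and applied to the mV-equivalent
per-sample slope (derivative / sample rate). Candidates closer than the
minimum peak distance (default 50 ms, about half the shortest plausible
murine RR interval) are thinned keeping the taller one; equal heights keep
the earlier candidate, making the rule deterministic. Each surviving
candidate is then moved to the maximum of the band-passed trace within
±10 ms, so reported positions sit on the waveform a reviewer inspects, and
the distance rule is re-applied after refinement.

## Heart rate and variability

HR (bpm) is the peak count divided by the recording time in minutes — on an
unedited trace, so stretches of bad signal bias it slightly; this matches
how the value is defined for batch reporting. RR intervals are successive
peak differences in ms, each anchored to the terminating peak. Variability
is summarised as the FWHM of the RR histogram with fixed integer-aligned
1 ms bins `[k, k+1)`: the distance from the left edge of the first bin
reaching half the maximum count to the right edge of the last such bin. No
sub-bin interpolation is used — 1 ms is the method's stated resolution, and
interpolating would claim spurious precision. Consequently the minimum FWHM
is 1 ms and the discrete FWHM of a Gaussian rhythm exceeds the continuous
limit 2.355σ by up to one bin: for sd 3 ms the analytic binned expectation
is 8 ms for continuous interval values, and 7 ms (within 2% of 2.355σ) once
intervals lie on the 1 ms grid that 1000 Hz peak indices impose — the
regime in which the statistic is actually computed. Because the half-max
level is tied to the modal bin, sparse tail bins from ectopic beats or
detection errors do not widen the FWHM.

## Ectopic-beat flagging

The reference rhythm for interval *i* is the mean of up to 100 intervals in
a window centred on *i* (50 each side, clipped at the series edges),
**excluding interval *i* itself** so an aberrant interval cannot drag its
own reference toward itself. An interval deviating from this local mean by
more than 30% is flagged. Whether the original rule's window was trailing
or centred, inclusive or exclusive, is not documented anywhere we know of;
the centred-exclusive choice treats pre- and post-event context
symmetrically and is exposed as configuration. A premature beat with a
full compensatory pause produces two consecutive deviant intervals sharing
a beat; such runs merge into a single region of interest anchored on the
most deviant interval, with the review window spanning the run. Flagging is
intentionally only triage: ROIs are exported as a CSV table plus one PDF
panel per event (band-passed trace ± 500 ms, detected peaks marked) for
manual classification — PVC vs PAC vs blocked P wave vs sinus arrest needs
the unfiltered 2000 Hz trace and, ideally, all three leads, and is out of
scope for automation here.

False ectopic flags track detection quality directly: every detection false
positive splits one interval into two ~50% deviations. The flagging rule is
therefore only as clean as the upstream peak detection, which is why the
completeness guarantees below are stated at the generator's default noise
conditions.

## Detector evaluation

Detected and reference annotations are matched one-to-one by greedy nearest
neighbour within ±10 ms (≈ one murine QRS width; configurable). Greedy
matching differs from optimal assignment only when several peaks crowd
within the tolerance, which a 50 ms minimum peak distance precludes.
True negatives are counted at the sample level, TN = total − TP − FP − FN,
which makes the four counts sum exactly to the fragment's sample count
(1,200,000 for 20 minutes at 1000 Hz). Metrics are reported at 6-decimal
precision, and the paired two-sided comparison between two detectors (t
test by default, Wilcoxon as an option) runs on those reported per-file
values. With ten files per detector, metric differences of ~10⁻³ are within
noise — the bundled benchmark reproduces exactly this: p = 0.144 / 0.408 /
0.360 for sensitivity / precision / specificity, i.e. no significant
difference between the custom detector and PhysioZoo. Note the bundled
PhysioZoo TN counts are reproduced verbatim from their source even though
they are internally inconsistent with the 1.2 M-sample total; sensitivity
and precision do not involve TN, and specificity reproduces from the
printed TN values themselves.

## Synthetic data: what it emulates and what it does not

`simulate_rr` draws intervals from Normal(mean RR, sd) truncated at ±4 sd
(defaults 100 ms, 3 ms — a resting adult mouse at 600 bpm). Scripted
events rewrite intervals: a premature beat at fraction f replaces one
interval by f·RR and the next by (2−f)·RR (classical full compensatory
pause, time-conserving); a sinus arrest doubles one interval.
`render_waveform` places a fixed Gaussian-sum P-QRS-T template at each
beat: P at −25 ms (0.10 mV, σ 3 ms), Q at −3.5 ms (−0.25 mV, σ 1 ms), R at
0 (1.0 mV, σ 1.1 ms), S at +2.8 ms (−0.65 mV, σ 1 ms), T at +18 ms
(0.15 mV, σ 6 ms) — a ~10–12 ms QRS with the sharp R and prominent S
typical of murine lead II. Template amplitudes are rendering defaults
chosen for realistic spectral content (sufficient 100–200 Hz energy
relative to the noise floor), not measured murine values. Lead I is a 0.6×
projection of the same template, lead III = II − I by construction, and
noise is then added independently per lead: sinusoidal baseline wander
(default 0.1 mV at 1.5 Hz), white Gaussian noise, band-limited 300–600 Hz
EMG noise (placed above the QRS band so the band-pass demonstrably removes
it), and optional Hanning-windowed movement bursts. R-peak ground truth is
exact by construction, and a fixed seed gives bit-identical output.

The generator does **not** model autonomic/circadian HR modulation,
beat-to-beat morphology variability, electrode drift, or genuine ectopic
*morphology* (an injected premature beat perturbs timing, not shape).
Passing tests therefore demonstrate the correctness of the processing
arithmetic and the detector's behaviour against a controlled noise floor —
not clinical-grade performance on real animal recordings, where trace
quality, movement artifacts and true morphological variation dominate.

## Verified operating characteristics

Quantities below are computed by the test suite and `scripts/acceptance.py`
at every run (20-minute fragments, 2000 Hz acquisition, 1000 Hz working
rate, defaults throughout unless stated):

- Zero noise: end-to-end sensitivity and precision are exactly 1.0, and at
  a native 1000 Hz the detected sample indices equal ground truth exactly.
- White noise at 20% of the R amplitude (plus wander and EMG noise):
  sensitivity ≥ 0.995. Precision degrades first (band-pass ringing plus
  noise produces spurious candidates at the minimum-distance boundary),
  consistent with false-positive counts being the quality-sensitive column
  in the bundled benchmark.
- Default noise: HR and mean RR recovered within 1%, RR-sd within 10%
  (quantisation on the 1 ms grid adds √(1/6) ms ≈ 0.4 ms in quadrature).
- FWHM at n = 10⁵ grid-aligned intervals, sd 3 ms: exactly 7 ms.
- Every injected premature beat (f = 0.6) is flagged by the 100-interval /
  30% rule, one merged ROI per event, and a constant rhythm yields zero
  flags.
- Moving-average and peak-matching outputs equal brute-force
  recomputations on series up to length 500.

## Numerical and degenerate-input choices

Sample indices are 0-based; fragment intervals are half-open. Readers
reject non-mV units rather than rescaling. Filtering a signal shorter than
the filter warm-up (3× order) is an error; an empty detection signal yields
empty annotations; fewer than two peaks yields an empty RR series with a
warning; an empty RR series has no histogram. Zero-denominator metrics are
NaN (undefined), never 0. A paired test on identical lists returns NaN
rather than a fabricated p-value. Batch fragments that fail are logged and
skipped; the run manifest records the error and the exit status reports
partial failure.
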