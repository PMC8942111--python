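# Methods

## The metric

Breathing intensity is quantified as a band-limited signal-to-noise ratio,

SNR_dB = 10 log10(P_S / P_N) = P_S,dB − P_N,dB,

with both powers integrated over a configurable analysis band (default
100–1000 Hz, the band where chest-wall breath sounds carry most of their
energy; it excludes DC drift and most S1/S2 heart-sound energy, which lies
at 20–150 Hz). P_S is the breath-sound power during breathing activity;
P_N is the noise power, conceptually the sum of ambient background noise
and the acoustic turbulence generated by obstructed airflow. Because
turbulence counts as noise, obstruction lowers the SNR — that is the
clinical content of the metric.

Reported SNR values are capped at ±60 dB so noise-free or signal-free
degenerate sessions produce finite numbers that can be averaged.

### Operational estimates

The recording itself is the only observable, so the two powers are
estimated from its own segmentation:

- **P_N** — band power over the concatenated *quiet* intervals (no
  airflow), which observe ambient noise alone.
- **P_S** — band power over the concatenated *active* intervals minus P_N,
  floored at 10⁻⁶·P_N so the subtraction is never negative (standard
  ambient-subtraction practice).

Turbulence co-occurs with airflow and therefore ends up inside the
active-interval power rather than in P_N. Under the severity model used by
the simulator (below), obstruction simultaneously weakens the clean breath
sound and injects turbulence that is broader-band than the analysis band,
so the estimated SNR still decreases monotonically with obstruction — the
estimator is a biased but order-preserving reading of the true
clean-signal-to-noise ratio. This one-sided attribution is a deliberate
design choice: no operational procedure can separate ambient from
turbulence noise during breathing without ground truth.

All powers go through a Welch PSD (Hann window, 1 s segments, 50% overlap,
no detrending) whose one-sided density is normalized so that integrating it
over [0, Nyquist] returns the time-domain power (Parseval contract); band
powers are trapezoid integrals with the density interpolated at the exact
band edges, making band powers exactly additive over adjacent bands.
Signals shorter than one Welch segment fall back to a single periodogram
with a logged warning. An independent route to the same quantity
(`band_power_direct`: zero-phase Butterworth band-pass, then time-domain
variance) is used for simulator ground truth so truth never depends on the
estimator it judges.

## Segmentation

Breath activity is detected on the RMS envelope (100 ms frames, 25 ms hop)
of the band-passed signal. The noise floor is the median of the
lowest-quartile envelope frames — robust as long as at least ~25% of the
session is quiet, which any protocol with inter-breath pauses satisfies; a
session with no envelope contrast at all is labelled entirely quiet.
Hysteresis thresholding (enter active above 3× floor, exit below 1.5×
floor) suppresses chatter; intervals shorter than 250 ms are dropped or
bridged (breath bursts at rest last ≥ 0.5 s). Intervals always tile the
recording exactly.

Depth (normal vs deep) is classified per session by exact 1-D two-means on
the per-interval dB band powers — relative rather than absolute, because
absolute levels depend on sensor coupling and fabric. If the cluster means
separate by less than 3 dB everything is labelled normal; a single active
interval is labelled n/a. Deep intervals are included in the signal-power
estimate by default (configurable), since the protocol treats both as
breathing activity.

Motion gating flags (never deletes) any interval that overlaps a
motion-trace sample deviating more than 5× the trace's robust baseline RMS
(1.4826 × MAD about the median). Flagged intervals are excluded from all
power estimates; gating is idempotent.

## Bilateral combination

The multi-tap per-lung filters are realized for combination as single-tap
delay-and-sum: the inter-channel lag is the argmax of the normalized
cross-correlation within ±50 ms, computed only over non-rejected
breath-active samples (the breath signal, not the noise, is the coherent
component), with ties broken toward the smallest |lag| and then negative.
Channels are summed with weights proportional to their linear SNR
estimates. If the peak correlation falls below 0.2 the channels are treated
as incoherent and the better channel is used alone — blind summing of
incoherent channels costs SNR, and this fallback keeps the combined result
within 0.5 dB of the best single channel in the worst case. The combined
signal is re-segmented and re-estimated with the same configuration before
the array gain (combined minus best single, in dB; may be negative) is
reported. Estimating full multi-tap impulse responses from data is out of
scope.

## Cohort analysis

Each subject's sessions/channels are averaged in dB (the group curve is a
dB-derived quantity) into one value, with low-confidence results (fewer
than two usable active intervals, or incoherent combinations) dropped when
confident ones exist. Group means per occupied health-scale value are
min-max normalized to [0, 1]; unoccupied scales are omitted, not
interpolated, and an all-equal set of group means is an error by default
(configurable to report 0.5). The association between the ordinal 1–10
health scale and mean SNR is tested by Spearman rank correlation (average
ranks for ties) with a one-sided permutation p-value (shuffle the health
scales; add-one correction, so p ∈ [1/(n+1), 1] and is reproducible under a
fixed seed). Rank correlation and min-max normalization make the cohort
outputs invariant to any affine transform of the dB values. COPD subjects
enter the same pooled correlation; the group column preserves the
distinction for reporting.

## The simulator

The generator realizes the received-signal model directly and keeps the
books: every simulated session stores its clean and noise components, the
exact active/quiet segmentation, and per-channel truth SNR computed from
the components in the analysis band (motion-burst windows excluded, since
they model exactly what the pipeline is supposed to reject).

- **Source**: band-limited (100–1000 Hz) unit-variance noise modulated by a
  smooth per-breath envelope — a tapered (Tukey, α = 0.3) burst covering
  70% of each breath cycle, with a slightly quieter expiration after the
  inspiration fraction (40%) and silence between breaths. Default 15
  breaths/min; deep blocks are boosted by 6 dB (amplitude). The default
  protocol alternates 40 s normal / 20 s deep blocks for ~4 min.
- **Channels**: sparse tap sums (delays rounded to the nearest sample at
  the 4 kHz default rate — a typical electronic-stethoscope rate), fabric
  attenuation applied to the breath signal before noise is added (ambient
  noise arises at the sensor, not behind the fabric), white ambient
  Gaussian noise (default power 0.01 W), and turbulence noise during
  breath-active windows only (airflow exists only then).
- **Heart sounds**: S1/S2-like damped tone bursts (45/65 Hz) on the left
  channel. By default they count toward truth signal power
  (`heart_counts_as_signal=True`), reproducing the elevated left-thorax
  SNR observed over the heart; the accounting is exposed as a flag because
  heart sounds are genuinely ambiguous between "signal" and "interference".
- **Severity**: the 1–10 health scale (10 = excellent) drives two coupled
  maps. Turbulence power falls by 2 dB per scale step from 7.5 mW at scale
  1; the clean breath gain falls 16 dB across the scale toward poor health
  (diminished breath sounds). Turbulence occupies 100–1900 Hz — overlapping
  and confounded with the analysis band but broader, as physical flow
  turbulence is. Under this pairing truth SNR spans roughly 19 dB across
  the scale and both truth and estimated SNR are strictly decreasing in
  severity; with turbulence alone (no clean-signal coupling) the
  quiet-interval estimator would mistake added turbulence for signal.
- **Motion artifacts**: 0–3 bursts per session (0.3 s, uniform placement),
  each a 20–300 Hz audio thump at ~6× the clean RMS on both channels plus a
  simultaneous motion-trace spike ≥ 5× the trace baseline RMS (trace at
  50 Hz, baseline σ = 0.02).
- **Cohorts**: health scales drawn skewed-high for healthy subjects
  (recreational runners) and centered at 5.5 for COPD subjects; ~70% male,
  matching the pilot demographic the defaults emulate. Everything is
  reproducible bit-for-bit from one seed via spawned child seeds.

### What the simulator does not emulate

Real adventitious sounds (wheezes, crackles) as clinical classes,
inter-subject anatomical variability of the transfer functions,
nonstationary ambient environments, sensor nonlinearity and clipping, and
real questionnaire noise in the health scale. Passing tests therefore
demonstrate that the pipeline correctly recovers the quantities its model
defines — not clinical validity on real patients, which requires recorded
data and pulmonary-function ground truth.

## Problem sizes and numerical choices

Tests and the acceptance script use the ~4-min default protocol where the
property concerns estimator accuracy (consistency across 0–30 dB truth
SNR) and a 24 s short protocol for multi-subject sweeps and the 38-subject
cohort simulations, keeping between-subject contrasts (≥ 2 dB per severity
step) far above the ≈0.1 dB estimation error at these durations. The
type-I-error calibration of the permutation test runs on 500 sampled
cohort tables (health scales from the cohort sampler, SNR drawn
independently of scale), since the property under test is a property of
the statistic, not of the audio chain. Other fixed choices: tap delays are
rounded to integer samples; two-means ties resolve by exhaustive
within-cluster-variance minimization (no random initialization); a
flat-positive envelope yields "all quiet" rather than "all active" because
the robust floor equals the envelope itself; correlation against a
constant SNR column raises an explicit undefined-result error instead of
silently returning 0.

## Known limitations

The ~7 dB bilateral gain and ~8 dB left-over-right difference reported for
individual pilot subjects in the motivating study are empirical,
device-and-subject-specific observations; two-element delay-and-sum with
independent noise is bounded by 3.01 dB, and this package reports whatever
its estimator actually measures. The quiet-interval noise estimator
reflects ambient noise only; sessions without quiet gaps (continuous loud
breathing) cannot be analyzed and raise an insufficient-data error.
Inspiration/expiration sub-phases are not labelled, and no absolute
acoustic calibration (Pa, dB SPL) is attempted.
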