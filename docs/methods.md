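# Methods

## Signal chain

The package estimates the heart-retina time (HRT): the lag between
ventricular contraction (ECG R peak) and the arrival of the corresponding
pulse wave in a retinal arteriole, observed through fringe washout in
time-resolved OCT B-scans. The chain is ECG resampling → R-peak detection →
rigid B-scan registration → vessel-subarea SNR → washout inversion →
pulse-arrival detection → cross-correlation lag analysis → cohort CoV
statistics. This note records the modelling choices, defaults and known
limitations.

## ECG handling

The monitor logs irregularly timestamped samples (µs precision, arbitrary
voltage units). Clock alignment between the ECG and OCT devices is reduced
to a single additive constant `clock_offset_ms`; the network-time mechanics
that produce it are out of scope, and every downstream time is expressed on
the OCT clock. Resampling to the 125 Hz acquisition grid uses linear
interpolation with no extrapolation; duplicate timestamps are collapsed to
their mean before interpolation.

R peaks are detected with the Engelse–Zeelenberg scheme: a 4-sample
differentiator, a [1, 4, 6, 4, 1] low-pass, and an adaptive threshold M
tracked over the last five complexes with a linear decay between beats, a
200 ms refractory period, and confirmation by a negative excursion below −M
within 160 ms of the upward crossing. The reported time is the raw-signal
maximum inside the confirmation window (the R apex). One deliberate
deviation from the textbook warm-up: during the first five seconds the
threshold is initialised from the whole training window rather than a
running maximum, because an as-yet-untrained threshold near zero otherwise
fires once on baseline noise before the first beat. On synthetic ECGs
(50–100 bpm, 5 % R-R jitter, 15 dB SNR) the detector recovers >99.9 % of
beats within ±2 samples with no spurious detections.

Event trains (R peaks, pulse arrivals) are encoded on a uniform grid as
unit impulses at the nearest sample (exact half-sample ties round to the
earlier sample), convolved with a discrete Gaussian of σ = 1.25 samples
truncated at 4σ and renormalised to unit sum, then divided by the maximum
so the peak is exactly 1. σ is interpreted in samples of the common
analysis grid (125 Hz by default, i.e. 10 ms), one of the two readings the
source description admits; at the default grid the alternative reading
coincides.

## B-scan stacks and the subarea SNR

Stacks are stored in an open container (JSON metadata + little-endian
float32 frames, normalised to [0, 1]) with per-frame millisecond
timestamps, maximum raw intensity `max_raw`, and the scanner quality score
Q in dB. The display transform 255·I^¼ is provided for visualisation only;
analysis runs on the normalised intensities.

The per-frame noise level is modelled as `max_raw / 10^(Q/10)`
(shot-noise-limited detection; the quality score converted from dB to a
linear power ratio). With raw intensity = normalised intensity × max_raw,
the subarea SNR reduces to `mean(I) · 10^(Q/10)`; the raw-data scale
cancels, so re-normalising the same raw data rescales the SNR uniformly
and leaves the SNR-drop series — the quantity that is actually inverted —
unchanged. The drop reference is the maximum per-pixel SNR over every
window pixel of every frame of the series (an across-series peak, not
per-frame), and drops are clipped to 1 because the washout relation has no
solution above it.

## Rigid registration

Each frame is aligned to the pixelwise average of the first ten frames
with an in-plane rigid transform (rotation about the image centre, then
translation). Translations are estimated by subpixel phase correlation.
Rotations are found by a coarse-to-fine search (0.25° grid over ±1.5°,
refined at 0.05°), each candidate scored by the normalised cross-correlation
of the fully resolved frame (rotated, then shifted by its own
phase-correlation estimate) against the reference over the common support.
The angle search runs at native resolution: sub-degree rotations displace
pixels by well under a pixel at coarser pyramid levels, so downsampled
levels carry no rotation signal at these frame sizes. Out-of-support
regions are zero-filled, reproducing the dark borders characteristic of
strongly moving frames. On synthetic stacks with known motion (≤10 px,
≤1°) recovery is within 0.1 px and 0.17°, against a contract of 0.5 px and
0.2°.

## Washout inversion and pulse arrivals

`forward_washout` is sinc²(k0 n v t) with the removable singularity at
v = 0 set to 1. The inverse is multi-branch: branch 0 is the unique root in
the principal lobe [0, π); branch m ≥ 1 exists when the m-th side-lobe peak
(located by solving x cos x = sin x) exceeds the observed drop, and its
representative root is taken on the lobe's falling flank so velocity
increases strictly with the numerical solution index. Roots are bracketed
and bisected (Brent) to 1e-12 absolute tolerance in x, then scaled by
1/(k0 n t). Five branches are retained by default. Velocities are carried
in m/s internally; figures label mm/s, the scale on which the two
acquisition regimes yield typical values of order 10 and 50.

The flow profile is the per-frame maximal-branch velocity (no additional
analytic-envelope transform; an optional centred moving average is off by
default). Its gradient uses central differences on the actual, possibly
uneven, frame timestamps with one-sided endpoints. Pulse arrivals are the
gradient maxima within consecutive bins of one mean R-R interval anchored
at the first frame; bins with fewer than three frames emit nothing (a
maximum over fewer samples is dominated by endpoint artifacts), and exact
ties break to the earlier frame.

## HRT estimation and the one-cycle rule

Both trains are encoded on a common 125 Hz grid (8 ms lag resolution; the
OCT frame interval of 13–50 ms is the true resolution limit, so the grid is
configurable upward). The OCT arrival span defines the base window; the ECG
window is padded 10 s before and 1 s after it. The cross-correlation is
energy-normalised without mean subtraction — both signals are non-negative
bump trains with unit maxima — and computed at every integer-sample lag at
which the padded ECG window fully covers the shifted OCT support. The
offset is the argmax restricted to one cardiac cycle [−RR̄, 0] (ties to the
smallest |lag|), and HRT = −offset, so an ECG pattern leading by 136 ms
appears as an offset of −136 ms and an HRT of +136 ms. The exam is flagged
as an outlier when the unrestricted argmax leaves that interval.

Because both trains are near-periodic, the correlation is a comb with peaks
one R-R interval apart, separated in height only by R-R jitter decoherence
(~3 % of RR per beat against the 10 ms encoding width) and degraded by
pulse-arrival quantisation. At the 85 kHz regime (13.4 ms frames) the
unrestricted argmax identifies aliased 1.5·RR delays correctly in ~97 % of
simulated exams; at the 20 kHz regime (49 ms frames) the quantisation
rivals the jitter separation and the flag is materially less reliable. The
one-cycle restriction makes the reported HRT itself insensitive to this
ambiguity. A related caveat: for true delays near RR/2 the comb peak at
RR − HRT has smaller magnitude than the true one, and the smallest-|lag|
tie-break would prefer it under perfect periodicity; physiological jitter
resolves this in practice.

## Coefficient-of-variation report

CoV is the sample standard deviation (n−1) over the mean. Inter-subject:
CoV of per-subject mean HRTs. Intra-subject / intra-exam / intra-vessel:
mean ± SD of per-group CoVs over groups with at least two members (exams
within a subject, vessels within an exam, exams within a vessel). Levels
with no qualifying group are reported as not available rather than raising.
Flagged outlier exams are excluded from the statistics but retained in the
records output.

## Synthetic data generator

The generator is the package's ground-truth instrument; its defaults are
the study conditions: 7 s exams, 70 bpm with ±3 % uniform R-R jitter,
125 Hz ECG, true HRT 144 ms, and the two acquisition regimes
(20.4 frames/s with t = 44.8 µs; 74.4 frames/s with t = 11.2 µs, available
as presets). Choices made where realism had to be balanced against
testability:

* **ECG**: a parametric P-QRS-T template (sum of five Gaussians with a
  dominant R spike) — only R-peak timing matters downstream — sampled with
  ±0.5 ms timestamp jitter to exercise resampling, plus white noise at a
  configurable SNR (default 25 dB).
* **Flow waveform**: each beat launches a pulse at R + HRT with a logistic
  rise (10–90 % in under one frame interval, steepest at onset + half an
  interval) times an exponential decay (τ = 0.35 RR̄) toward a diastolic
  baseline of 25 % of the systolic peak. The default peak velocity is 80 %
  of the principal-lobe bound λ/(4 n t), so inversion is single-valued for
  the designed waveform; higher peaks exercise the multi-branch path but
  make the envelope itself ambiguous.
* **Frames**: layered bands with lateral modulation and band-limited
  speckle (grain smoothed to ~1 px, the PSF scale — fully white per-pixel
  texture would alias under resampling and carries no usable rotation
  signal), a circular vessel with hyperreflective walls, a shadow column
  beneath it, and a lumen following `lumen_level × SNR_drop(v(t))`. Two
  rendering details make the forward model exactly invertible: a static
  3×3 reference-scatterer patch inside the 7×7 window pins the peak-pixel
  reference SNR at the no-washout level, with the remaining window pixels
  compensated so the window mean equals `lumen_level × drop` exactly; and
  the per-frame quality score is set to 10·log10(1/noise_sd) so the
  subarea SNR computation sees the actual rendered noise floor.
* **Motion**: per-frame uniform rigid jitter (defaults 3 px, 0.3°;
  configurable to the 10 px / 1° test regime). The first ten frames are
  motion-free — the subject settling into fixation — so the first-ten-frame
  registration reference is sharp and recorded transforms are directly
  comparable to the registration output.
* **Cohorts**: per-subject mean HRTs ~ Normal(base, between_frac·base),
  per-exam HRTs ~ Normal(subject mean, within_frac·base); vessels within
  an exam share the exam's delay (synchronous arrival).

Everything is driven by `numpy.random.default_rng` seeded from the config,
so identical configs give byte-identical bundles.

What the generator does **not** emulate: real retinal anatomy, eye-motion
spectra, blinks, speckle statistics beyond a band-limited Gaussian texture,
Doppler-angle geometry, or transverse flow. Passing tests therefore
demonstrate that the analysis chain recovers what the forward model
encodes under realistic noise, timing and motion — not that it would meet
the same tolerances on clinical recordings.

## Problem sizes

Tests and the acceptance script run the same conditions at reduced image
sizes, chosen as the package's own test scale: 96×72 px frames for
signal-level work (the subarea analysis touches only a 7×7 window plus its
surroundings) and 200×150 px for registration, where the rotation lever
arm matters. HRT recovery uses 20 seeded 7 s exams split across both
frame-rate regimes; CoV recovery uses 20 replicates of a 5-subject ×
3-exam cohort; registration uses two 30-frame stacks with 10 px / 1°
motion. The tolerance for HRT recovery is one common-grid bin (8 ms) plus
one frame interval; the sharpest-rise detector carries a systematic bias
of about half a frame interval relative to the pulse onset, which sits
well inside that band and cancels in all CoV statistics.

## Known limitations

* The HRT carries the arrival-detection bias (~half a frame interval), so
  absolute values from different frame rates differ by a few ms.
* The outlier flag degrades at coarse frame rates (see above).
* Registration assumes motion is rigid and in-plane; out-of-plane motion
  is not modelled, matching the acquisition's physical limitation.
* Velocities are axial components in arbitrary calibration (no
  Doppler-angle correction); only their timing enters the HRT.
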