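# hrtoct

Heart-retina time (HRT) estimation from ECG-coupled time-resolved dynamic
optical coherence tomography.

## The problem

When the left ventricle contracts (the ECG R peak), a pressure pulse travels
down the arterial tree and reaches the retinal arterioles a fraction of a
cardiac cycle later. Time-resolved OCT B-scans of arterioles at the optic
nerve head see that pulse indirectly: axial blood motion during the detector
integration time washes out the interference fringes, so the vessel-lumen
SNR drops as flow accelerates. Coupling a microsecond-timestamped ECG to the
OCT timeline makes the lag between ventricular contraction and retinal pulse
arrival — the heart-retina time — measurable. HRT is a pulse-transit-time
style quantity and a candidate biomarker for cardiovascular health.

This package implements the full analysis chain for researchers working with
such coupled recordings, plus a forward-model synthetic-data generator so
every stage is testable without acquisition hardware.

## The model

Fringe washout relates the observed SNR drop of a vessel subarea to the
axial velocity component v:

    SNR_drop = sin(k0 Δz)² / (k0 Δz)²,   Δz = n v t,   k0 = 2π/λ

with λ the central wavelength (880 nm), n the ocular refractive index
(1.36) and t the integration time (44.8 µs at the 20 kHz A-scan rate,
11.2 µs at 85 kHz). The relation is many-to-one: each side lobe of sinc²
below the observed drop contributes a candidate velocity, indexed by the
numerical solution index (NSI). The pipeline:

1. resample the ECG to 125 Hz and detect R peaks (Engelse–Zeelenberg
   detector with an adaptive threshold);
2. rigidly register each B-scan to the average of the first ten frames;
3. extract the 7×7-pixel vessel subarea, compute its SNR
   (`mean intensity / (max_raw / 10^(Q_dB/10))`) and divide by the series'
   peak per-pixel SNR to get the drop;
4. invert the washout relation per frame, take the maximal-branch velocity
   envelope, differentiate it, and pick the sharpest rise per heart-rate
   bin as the pulse-arrival time;
5. encode both event trains as Gaussian-smoothed (σ = 1.25 samples),
   [0, 1]-normalised signals on a common 125 Hz grid and cross-correlate
   them (OCT as baseline, ECG padded 10 s before / 1 s after). The HRT is
   the additive inverse of the argmax lag within one cardiac cycle; an
   unrestricted argmax outside [−RR, 0] flags the exam as an outlier.

Cohort reproducibility is summarised with coefficients of variation at the
inter-subject, intra-subject, intra-exam and intra-vessel level.

## Worked example

Simulate one 7 s exam with a true HRT of 144 ms and analyse it:

```sh
cat > demo_cfg.json <<'EOF'
{"scan": {"width_px": 160, "height_px": 120}, "duration_s": 7.0,
 "true_hrt_ms": 144.0, "seed": 12}
EOF
hrtoct simulate demo_exam --config demo_cfg.json
hrtoct hrt demo_exam demo_out
```

which prints

```
wrote exam bundle to demo_exam
A1: HRT 160.0 ms (outlier=False)
```

`demo_out/results.json` holds the machine-readable result:

```json
{"A1": {"hrt_ms": 160.0, "offset_ms": -160.0, "argmax_offset_ms": -160.0,
        "is_outlier": false, "n_arrivals": 9}}
```

Reading: nine pulse arrivals were detected across the 7 s series; the
cross-correlation of the arrival train against the R-peak train peaks at an
offset of −160 ms (the ECG pattern leads the OCT pattern), so the estimated
HRT is 160 ms. The 16 ms excess over the simulated 144 ms is the expected
detection bias: the sharpest rise of a pulse sampled at ~20 frames/s is
located about half a frame interval after its true onset, and the common
grid quantises lags to 8 ms. The unrestricted argmax equals the restricted
one, so the delay is within one cardiac cycle and the exam is not an
outlier. `demo_out/` also contains the five-row signal panel (subarea SNR,
NSI-coloured velocity scatter, gradient with detected rises, ECG with R
peaks, overlaid trains) and the cross-correlation figure.

The same flow works for cohorts: `hrtoct simulate-cohort` writes a tree of
exam bundles and `hrtoct cohort-report` aggregates per-vessel HRTs into a
CoV report and a 50 ms histogram of cross-correlation offsets.

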