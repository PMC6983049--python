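# fabricmotion

Can accelerometers sewn into everyday clothing stand in for
body-worn sensors? Garment-mounted sensors are far easier to wear all
day, but fabric couples to the limb loosely: the clothing signal trails
the body signal by a fraction of a second, sits at a different
orientation, swings with the garment and overshoots in amplitude.
`fabricmotion` implements the analysis pipeline for quantifying that
gap from paired tri-axial recordings (50 Hz, units of g, one sensor
strapped to the body and one sewn to the garment over the same site):

1. **Synchronisation** — detect the start-of-day jump and tap markers,
   then estimate the residual inter-sensor lag as the integer shift k
   maximising the normalised cross-correlation
   r(k) = corr(body_t, clothing_{t+k}) and remove it by trimming.
2. **Orientation** — estimate each sensor's gravity direction ĝ from a
   quiet window and rotate it onto +y with Rodrigues' formula
   R = I + sinθ·K + (1−cosθ)·K², k = (ĝ×ŷ)/|ĝ×ŷ|, θ = ∠(ĝ, ŷ).
3. **Similarity** — per activity instance (30–40 s), Pearson's r per
   axis under five cumulative preprocessing variants (original,
   time-aligned, rotated, both, both + activity-wise re-alignment),
   aggregated as median ± variance across instances.
4. **Classification agreement** — classify both streams with a
   threshold decision tree on the y-axis acceleration and its 250 ms
   moving variance (walking/running, transition, sitting, standing)
   and tabulate a confusion matrix with the body-worn labels as
   reference.

A seeded synthetic generator produces paired streams with the same
statistical structure (gravity posture geometry, double-peak gait
waveform with 0.7 s walking / 0.3 s running strides, jump/tap markers,
and a clothing channel distorted by lag, rotation, swing, scaling and
noise), so the full pipeline runs and is validated without any
recordings. See `docs/methods.md` for the model and all defaults.

Audience: researchers in wearable sensing / digital health comparing
sensor placements, and anyone needing a tested reference implementation
of cross-correlation synchronisation and gravity alignment for
accelerometry.

## Worked example

Generate a synthetic day (ten minutes; the clothing channel carries a
38-sample lag, a 15° tilt, mild swing and noise), then align and run
the full pipeline:

```sh
$ fabricmotion synth --out demo --seed 1
wrote synthetic pair (30000 samples at 50 Hz) to demo

$ fabricmotion align demo/body.csv demo/clothing.csv --out demo/aligned
lag: 38 samples (0.76 s), peak r = 0.9939

$ fabricmotion run --seed 1 --out demo/run
global lag: 38 samples (0.76 s)
report written to demo/run/report.json
```

The estimated lag of 38 samples at 50 Hz is a 0.76 s delay — the
clothing sensor trails the leg by three quarters of a second. The
report's y-axis correlation summary for walking (median over three
instances) shows what each correction buys:

```
variant                        median_r
original                       0.4737
rotated                        0.5128
time_aligned                   0.9981
aligned_rotated                0.9992
aligned_rotated_activitywise   0.9992
```

Uncorrected, body and clothing agree weakly (r ≈ 0.47); removing the
time lag is the decisive step, and orientation correction adds the
rest. The classification agreement (body-worn labels as reference)
keeps every non-transition diagonal near 100%:

```
walking_running 100.0   sitting 99.9   standing 100.0   transition 90.6
```

i.e. the clothing-mounted stream, once synchronised and aligned,
supports the same activity classification as the body-worn stream, and
residual disagreement concentrates in the brief posture transitions.

Recorded data can be run through the identical pipeline by replacing
the config's `synth` block with an `inputs` block naming two CSV
streams and an activity log (`fabricmotion run --config my.yaml`).

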