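# dida — digital image disintegration analysis

`dida` turns a video of a fast-disintegrating tablet (FDT) in a small, dark
disintegration vessel into a quantitative disintegration profile, classifies
the behaviour it shows, and compares conditions statistically. It is aimed at
formulation and quality-control scientists who assay FDTs in biorelevant
medium volumes (tens of microlitres to a millilitre — far below the
pharmacopoeial bath volumes), where the camera, not a basket apparatus, is
the sensor.

## The measurement

The observable is the **mean grey value (MGV)**: the arithmetic mean pixel
intensity over a fixed region of interest (ROI) drawn around the white
formulation on the black vessel floor, computed per frame of a 10 frames/s
recording. Two companion recordings anchor the scale — the medium-only
vessel gives the background MGV (and the sensor noise floor), and an
intact-tablet recording gives the full-tablet MGV. The **% tablet
remaining** at time *t* is

```
R(t) = 100 · (MGV(t) − MGV_bg) / MGV₀,      MGV₀ = MGV_tablet − MGV_bg
```

deliberately unclipped: R > 100 % indicates swelling (gelling excipients
such as hypromellose absorb the medium and grow instead of breaking apart),
and small negative values are sensor noise around an empty vessel.

Profiles are summarized at 10 s, 30 s and 180 s (the FDA 30 s and European
Pharmacopoeia 3 min disintegration limits for FDTs), classified as
*instant*, *fast*, *prolonged*, *partial* (a residual plateau that never
crosses the completion threshold) or *swelling* (a sustained level above
105 %), and replicate groups are compared with a Welch two-sample t-test,
starred at P ≤ 0.05 / 0.01 / 0.001.

A built-in simulator renders synthetic assay recordings — a noisy 8-bit
disc whose area tracks a closed-form kinetics curve — so every stage of the
pipeline can be validated against known ground truth without laboratory
data.

## Worked example

Simulate a first-order disintegration that stalls at an 8 % residual
(incomplete disintegration), then analyze it end to end:

```python
from dida import KineticsModel, SimulationConfig, analyze_bundle, generate_assay

config = SimulationConfig(
    frame_size_px=(64, 64), tablet_center_px=(32.0, 32.0), tablet_radius_px=16.0,
    duration_s=250.0, noise_sd=2.0, n_replicates=3, seed=7,
    kinetics=KineticsModel(model="decay_to_plateau", rate_k_per_s=0.1, plateau_pct=8.0),
)
bundle = generate_assay(config)
analysis = analyze_bundle(bundle, timepoints_s=[10.0, 30.0, 180.0])
for s in analysis.summaries:
    print(f"{s.timepoint_s:5.0f} s: {s.mean_percent:5.1f} +/- {s.sd_percent:.1f} % remaining (n={s.n})")
print("category:", analysis.consensus_category)
print(f"noise floor: {analysis.noise_floor_pct:.2f} %")
```

prints

```
   10 s:  41.8 +/- 0.0 % remaining (n=3)
   30 s:  12.6 +/- 0.1 % remaining (n=3)
  180 s:   8.0 +/- 0.1 % remaining (n=3)
category: prolonged
noise floor: 0.05 %
```

At 10 s the tablet still reads 41.8 % (the analytic value is
8 + 92·e⁻¹ ≈ 41.8 %), by 3 min it has settled on the 8 % residual, and the
replicates agree to within a tenth of a percentage point — the per-pixel
noise of 2 grey levels averages down to a 0.05 % noise floor over the ROI.
The profile crosses the default 10 % completion threshold only after 30 s,
so the behaviour is classified *prolonged*; with a completion threshold of
5 % it would be *partial*, the signature of incomplete disintegration.

The same workflow is available from the shell:

```
dida simulate --preset decay --out bundle/
dida analyze --bundle bundle/ --out analysis/
dida compare cond_a/timepoint_summary.csv cond_b/timepoint_summary.csv --timepoint 180
dida report --analysis-dir analysis/
```

`analyze` writes one profile CSV per replicate
(`time_s,mgv,percent_remaining,flags`), a timepoint-summary CSV, a
classification JSON and a run log with the software version and a
configuration hash; `compare` prints `{t, df, p, stars}` for the Welch test
between two conditions at one timepoint.

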