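# navlab

Accuracy evaluation for augmented-reality (AR) surgical navigation in
laparoscopic liver surgery.

In image-guided laparoscopy, a CT-derived 3D liver model is overlaid onto the
live laparoscope video. Getting that overlay right requires chaining several
estimated transforms, each with its own error source:

* **hand-eye calibration** `T_C^M` — the fixed transform between the
  laparoscope camera `C` and the optically tracked marker body `M` mounted on
  it, solved from posed views of a calibration plate via the stacked linear
  system `[I ⊗ (R_O^M)⁻¹, 0; 0, (R_O^M)⁻¹] · [vec(R_C^M); t_C^M] =
  [vec(R_C^O); t_C^O + (R_O^M)⁻¹ t_O^M]` (least squares, rotation projected
  back to SO(3));
* **image-to-patient registration** `T_I^P` — the rigid transform between CT
  image space `I` and the tracked patient `P`, estimated by the classical
  centroid/cross-covariance SVD solution over landmark correspondences
  (cauterization marks annotated on the CT model vs. the same marks sampled
  on the liver with a tracked tool tip);
* the **AR reprojection chain** for each video frame,
  `T_I^C = M_I · (T_C^M)⁻¹ · (T_M^O)⁻¹ · T_P^O · (T_P^I)⁻¹`,
  with `M_I` the pinhole camera intrinsics and `O` the optical tracker frame.

Accuracy is quantified the standard way: **FLE** (fiducial localization
error — the 3D distance between a clinician's annotation of a landmark and
its user-independent ground-truth position) and **TRE** (target registration
error — the overlay error at marks *not* used for the registration, measured
in the image as a pixel offset and converted to millimetres at the
reprojected depth through the inverse intrinsics). Because E[TRE²] falls
roughly as FLE²/N with diminishing geometric returns, the package includes
the marker-subset resampling experiment: register with N = 3…10 randomly
drawn marks, repeatedly, and evaluate TRE on the held-out marks over all
frames, under three conditions — clinician annotations on the intraoperative
model, clinician annotations on the (pneumoperitoneum-deformed) preoperative
model, and inserted-fiducial ground truth.

No public in-vivo dataset exists for this protocol, so the package ships a
first-class synthetic generator: a liver-sized superellipsoid phantom with 15
labeled surface marks, a smooth nonrigid preoperative/intraoperative shape
difference, per-clinician annotation noise, breathing + jitter in tool-tip
sampling, fiducial-insertion displacement (compensated by a small rigid ICP),
and laparoscope trajectories keeping all marks in view. Every generator is a
pure function of (config, seed), and in the all-noise-off world the entire
chain closes to numerical zero — the pipeline's master integration test.

Intended users: researchers in image-guided surgery and surgical-navigation
accuracy who want a tested, reproducible reference implementation of the
calibration/registration/TRE machinery and a sandbox for protocol questions
("how many registration markers are worth acquiring?").

## Worked example

```python
from navlab import StudyConfig, run_study

report = run_study(StudyConfig(seed=1))
for cond, mean in sorted(report.summary["condition_mean_tre_mm"].items()):
    print(f"mean TRE [{cond}]: {mean:.2f} mm")
print(f"mean FLE: {report.summary['fle_mean_mm']:.2f} mm")
```

prints

```
mean TRE [fiducial]: 1.27 mm
mean TRE [intraop-user]: 10.09 mm
mean TRE [preop-user]: 22.83 mm
mean FLE: 16.77 mm
```

Reading the numbers: registering with user annotations on the deformed
preoperative model more than doubles the overlay error relative to the
intraoperative model (22.83 vs 10.09 mm) — the cost of pneumoperitoneum
deformation; removing the human annotation error entirely (inserted-fiducial
registration) drops TRE to the ~1 mm floor set by the 2-pixel centroid
annotation noise of the video frames. The mean FLE of 16.77 mm matches the
generator's annotation noise target (σ = 10.5 mm per axis gives an expected
mean error norm of 2σ√(2/π) ≈ 16.75 mm). `report.records` holds the
long-format TRE table; `run_study(cfg, output_dir=...)` additionally writes
CSV tables, a JSON summary and TRE-vs-N plots.

The same study is available from the shell:

```bash
navlab run-study --seed 1 --out results/
navlab report --results results/
```

plus `navlab simulate`, `navlab handeye solve`, `navlab register svd|icp` and
`navlab evaluate` for the individual stages.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full default study from scratch at the given seed (hand-eye
solve, per-trial registration experiments, TRE/FLE summaries) and writes the
results JSON to `--out`, with the complete study bundle (tables, summary,
plots) beside it.

## Scope notes

The package deliberately models a zero-distortion pinhole camera, rigid
registration only (no viscoelastic/nonrigid compensation), and descriptive
statistics plus a plain Welch two-sample comparison (no repeated-measures
ANOVA machinery). See `docs/methods.md` for the model assumptions, parameter
defaults and their rationale, and known limitations.
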