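# Methods

This note documents the models implemented in `navlab`, the assumptions they
make, the defaults and why, and what the synthetic world does and does not
establish.

## Coordinate frames and conventions

Five frames: `I` (CT image space), `P` (patient on the table), `O` (optical
tracker), `M` (laparoscope marker body), `C` (camera). A transform `T_A^B`
maps points from frame `A` to frame `B`; composition is checked on frame
labels and refuses mismatched chains — the sub/superscript notation is
error-prone enough in practice that silent composition is a bug source, not a
convenience. The image-to-patient registration is reported as `T_I^P`; the AR
chain consumes its inverse, written `(T_P^I)⁻¹` — both spellings denote the
same estimate.

Camera: +z forward, x right, y down, pixel origin top-left, pure pinhole.
No distortion model is fitted anywhere: synthetic frames are generated
distortion-free, so simulation and evaluation are self-consistent by
construction. 3D units are millimetres throughout; 2D units are pixels.

## Hand-eye calibration

The solver consumes pose pairs `(T_O^M, T_C^O)` from posed views of a
tracked calibration plate whose frame coincides with `O`. Each pose
contributes 12 rows of the stacked linear system

    [ I₃ ⊗ (R_O^M)⁻¹   0 ] [ vec(R_C^M) ]   [ vec(R_C^O)              ]
    [ 0      (R_O^M)⁻¹   ] [ t_C^M      ] = [ t_C^O + (R_O^M)⁻¹ t_O^M ]

with `vec` in column order. Rotation and translation unknowns are solved
*jointly* by dense QR-based least squares (the system is only 12N×12), and
the 9-vector rotation block is projected to the nearest proper rotation by
SVD with determinant correction. The reported residual is the RMS of the
stacked system at the raw, pre-projection solution.

Numerical choices and caveats:

* Because the plate frame is tied to the tracker frame, the stacked matrix is
  full rank even when every pose has the same rotation — one pose already
  determines the solution algebraically. A single-orientation calibration is
  nevertheless untrustworthy on real data (any systematic error along the
  unexercised rotations is invisible), so the solver additionally requires
  the marker rotations to span at least 0.5° of geodesic spread and raises a
  degenerate-motion error otherwise; `HandEyeCalibrator(check_diversity=False)`
  opts out explicitly.
* Whether a physical tracker reports `T_O^M` or its inverse is
  device-specific. Generator and solver here share one documented convention
  (`tracker_to_marker` maps O→M); users of real tracker logs must verify the
  direction themselves.

## Image-to-patient registration

Point-based rigid least squares in closed form: demean both point sets, SVD
of the cross-covariance, determinant correction against reflections. The
optimum is symmetric in which frame the residual is measured; the
implementation demeans in the image frame and reports FRE (RMS residual over
the points used) there. Degenerate inputs — fewer than 3 points, collinear
configurations (second singular value below 1e-9 of the first) — are
rejected rather than silently solved.

The model-to-model compensation for fiducial-insertion displacement is a
point-to-point ICP: nearest-neighbour matching (ties broken to the lowest
target index, for determinism), closed-form rigid re-fit, iterate until the
mean residual changes by < `tol` (default 1e-4 mm) or `max_iter` (default
100). The mean residual is non-increasing by construction; non-convergence
returns the best estimate with a warning rather than raising. No trimming by
default; a `trim_fraction` parameter is available for partially overlapping
clouds. This is a deliberately simple surrogate for the interactive
surface-to-surface alignment tools used in practice.

## TRE and the pixel→mm conversion

Per frame, every evaluable mark (observed in that frame and not used for the
registration) is reprojected through
`T_I^C = M_I (T_C^M)⁻¹ (T_M^O)⁻¹ T_P^O (T_P^I)⁻¹`, and the pixel offset to
the observed centroid is converted to millimetres by back-projecting both
pixels through `M_I⁻¹` and scaling to the camera-frame depth of the
*reprojected* point — the only depth the navigation system knows. This
equals `depth · ‖K⁻¹(Δu, Δv, 0)‖` exactly. Marks behind the camera are
skipped and flagged, never fatal. Note what this measures: the in-plane
component of the 3D error at the reprojected depth. Error along the viewing
ray is invisible to a monocular overlay, which is precisely why the protocol
reports this quantity; it is *not* an estimator of the full 3D TRE (for
isotropic error it sits at √(2/3) of it on average).

For validation against registration theory the package therefore also
provides `monte_carlo_tre3d`, which measures the true 3D displacement of
held-out marks under refitted registrations with isotropic fiducial noise.
Its mean agrees with the first-order closed-form expected-TRE prediction
E[TRE²] = (⟨FLE²⟩/N)(1 + ⅓ Σₖ dₖ²/fₖ²) to within a few percent — provided the
fiducial configuration is not near-degenerate: the formula is first-order and
blows up when the fiducial spread about a principal axis is comparable to the
noise itself, so the acceptance test draws subsets whose minimum axis spread
is at least 2σ.

## The marker-subset experiment

For each condition × user × N × repeat cell, N marks are drawn uniformly
without replacement from one rng stream per (condition, user, N) derived from
the master seed — fully reproducible, independent across repeats. The three
conditions differ in the image-side registration points and in the model
being reprojected: clinician annotations on the intraoperative model,
clinician annotations on the deformed preoperative model (reprojecting the
deformed marks — the wrong-shaped model is what the system would overlay), or
inserted-fiducial ground truth. The fiducial condition is user-independent
and runs once per (N, repeat). Marks in the registration subset are excluded
from TRE; among the rest, only marks with an observed centroid in a frame are
evaluated. Records are kept long-format (trial, condition, user, N, repeat,
frame, mark, TRE); σ in every summary is the sample standard deviation over
records, with single-record groups flagged rather than NaN'd. Rounding
(half-up, 1–2 decimals) happens only at presentation.

The statistics module is deliberately descriptive: grouped mean ± σ, per-N
deltas (mean(N) − mean(N+1)), and a Welch two-sample comparison. No
repeated-measures ANOVA or multiple-testing correction is attempted.

## The synthetic world

What the generator emulates, and the defaults:

| parameter | default | rationale |
|---|---|---|
| phantom | superellipsoid, half-axes 100×70×40 mm, exponent 4 | enclosed volume ≈ 1815 cm³, inside the porcine liver range 1593–2761 cm³; a plain ellipsoid of the same extents would fall below it |
| marks | 15, anterior surface, ≥ 25 mm apart | protocol's mark count; spacing keeps subsets well-conditioned |
| deformation magnitude | 25 mm mean mark displacement | pneumoperitoneum surrogate sized so the preop/intraop TRE gap is comfortably detectable (≈2× ratio); a label for "large visible deformation", not an estimate of porcine mechanics |
| deformation field | small random affine strain + 10 Gaussian RBF kernels, width 80 mm | smooth by construction; magnitude 0 is exactly the identity |
| annotation noise σ (intraop) | 10.5 mm per axis | targets mean FLE = 2σ√(2/π) ≈ 16.8 mm |
| preop/intraop σ ratio | 1.45 | inter-user variability scales with σ; 1.45 reproduces a ~45% higher preoperative spread |
| per-user bias | ‖bias‖ ≤ 3 mm | distinct systematic offsets per clinician |
| tool sampling | breathing 5 mm amplitude / 4 s period, jitter 0.5 mm, 50 samples over 2 full periods | integer periods make the breathing sinusoid average out exactly; jitter shrinks by √50 |
| fiducial insertion | 2° / 4 mm rigid + 1 mm smooth | small model-to-model displacement; the rigid part is recoverable by ICP, the smooth remainder is the "inaccuracy in the ground truth" a real protocol accepts |
| 2D centroid noise | 2 px | the manual annotation of mark centers in video frames; no published value exists — this is a free parameter and sets the fiducial-condition TRE floor (≈ depth·σ_px·√(π/2)/f ≈ 1.3 mm at the default geometry) |
| camera | fx = fy = 800 px, 960×540, orbit at ~400 mm within 20° of the anterior axis | keeps all 15 marks visible in every frame, as the protocol requires; frames failing visibility are re-drawn further out, bounded retries |

A positional error-scaling hook (annotation error growing away from the
surface boundary, which real annotation patterns suggest) is *not* enabled;
annotation error is Gaussian isotropic plus bias. OR-table tilt, insufflation
dynamics and breathing-gated CT are not modelled.

What a green test establishes — and does not. The zero-noise closure proves
the chain's algebra is exactly self-consistent (every TRE < 1e-6 mm through
hand-eye solve, registration and reprojection). The seeded default study
proves the qualitative orderings (preop > intraop > fiducial TRE; TRE falls
with N with diminishing deltas) follow from the assumed error structure. It
does **not** reproduce in-vivo TRE magnitudes: those depend on tissue
mechanics, tracking hardware and annotation behaviour that the generator only
parameterizes. The packaged per-marker FLE table (subjects A–C, marks a–o) is
the one set of externally printed values the package reproduces exactly
(subject means 29.4 / 31.6 / 28.5 mm, half-up to 1 decimal). That table's own
source reports an overall FLE of 16.81 ± 12.92 mm across 375 distances, which
is arithmetically inconsistent with its per-subject means (~29.8 mm grand
mean); the package reproduces the table arithmetic and leaves the discrepancy
documented, not resolved. Similarly, "inter-user variability" has no fixed
formula in the protocol literature; the implementation uses all pairwise
distances between users' annotations per mark, flagged as an interpretation.

## Scaled-down defaults

The full protocol (4 trials × 5 users × 8 marker counts × 10 repeats × 100
frames) produces 320,000 AR frames. The default `StudyConfig` scales this to
20 frames and 5 repeats (~200 registrations per condition per trial, ~300k
TRE records, under 10 s on one CPU); `full_scale=True` restores the full
counts. Structured logging echoes per-stage timings and the seeds in use; a
trial that fails is recorded in the report and the study continues.

## Known limitations

* Monocular pixel-based TRE under-reports depth error by construction (see
  above); stereo evaluation is out of scope.
* ICP is point-to-point with closest-point matching; a grossly wrong
  initialization (e.g. a 180° flip) can settle in a local minimum — flagged
  via the recorded residual sequence and convergence flag, not prevented.
* The deformation surrogate is geometric, not biomechanical; its magnitude
  parameter is a dial, not a prediction.
* Annotation error is stationary and isotropic per user; real annotation
  error is spatially structured.
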