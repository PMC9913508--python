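# Methods

## Problem setting

Neuronavigation platforms track surgical instruments relative to
preoperative imaging at 15–30 positions per second. If the tool tip is
logged throughout tumor resection, the volume it sweeps approximates the
resection cavity — provided line-of-sight to the optical tracker is
maintained and brain shift is small. `resectmap` implements this mapping
and the evaluation algebra needed to compare the tracked cavity with
preoperative tumor and intraoperative residual segmentations.

## The resection map

The map is a truncated signed distance field (TSDF) on an axis-aligned
region-of-interest (ROI) grid enclosing the tumor plus a margin
(default 10 mm).

* **State.** Per voxel: signed distance `d` in mm to the swept-volume
  surface, clamped to `[-τ, τ]`; and `first_carved_s`, the earliest
  timestamp at which the voxel became interior (NaN where never carved).
* **Update.** A sample at `p` with tool radius `r` applies
  `d(x) ← min(d(x), max(‖x−p‖ − r, −τ))` inside the narrow band
  (`‖x−p‖ < τ + r`); a pair of linked samples uses the distance to the
  segment between them (capsule). Updates are pointwise minima, so the
  field is monotonically non-increasing (resection only removes tissue),
  ingestion is independent of chunking (streaming equals batch,
  bit-exact), and the final field equals the clamped minimum over all
  primitives regardless of order.
* **Linking rule.** Consecutive samples are capsule-linked only when
  separated by ≤ `link_max_gap_s` (0.5 s) *and* ≤ `link_max_jump_mm`
  (10 mm). Re-acquisition after a longer gap carves an isolated sphere:
  connecting across a dropout would carve a fictitious tunnel through
  tissue the tool never traversed, a direct source of False Positive
  Tracking. Capsule timestamps attribute to the later sample;
  first-carve wins where capsules overlap, preserving
  earliest-resection semantics for replay.
* **Binarization and surface.** The tracked cavity is `d < 0` (strict:
  the zero level set is the cavity *surface*). Surfaces are extracted
  with marching cubes at level 0; time-colored surfaces look up
  `first_carved_s` of the nearest carved voxel per vertex.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `tool_radius_mm` | 1.5 | mm | effective aperture of bipolar/CUSA/pointer tips; *not observable from tracking data* — the single most consequential free parameter, configurable per instrument |
| `grid_spacing_mm` | 0.5 | mm | sub-millimeter mapping resolution |
| `band_mm` (τ) | 3.0 | mm | ≥ 2× radius: keeps the narrow band cheap while leaving enough field for smooth marching-cubes surfaces |
| `link_max_gap_s` | 0.5 | s | ≈ 10–15 missed frames at 15–30 Hz separates dropouts from normal motion |
| `link_max_jump_mm` | 10 | mm | implausible inter-frame motion at surgical tool speeds |
| brain-filter `margin_mm` | 1.0 | mm | one tool radius of tolerance so cortical-surface carving is not discarded by mask discretization |

## Tracking logs

Logs are self-describing TSV (`# time_s  x_mm  y_mm  z_mm  instrument`),
UTF-8, one sample per line, shortest-round-trip float formatting (so
write→parse is lossless). Timestamps are stream-relative seconds;
wall-clock epochs (> 1e8 s) are re-zeroed on parse. A thin adapter
accepts 4×4 tracker transforms and takes the translation column as the
tip position, matching TRANSFORM-stream semantics of navigation
middleware.

The cerebrum filter removes samples recorded outside the brain (tool
entering/leaving the field). It is evaluated on the mask lattice: a
sample is kept when its containing voxel lies within `margin_mm`
(exact Euclidean distance transform) of a cerebrum voxel. The filter is
idempotent and monotone in the margin.

## Evaluation algebra

All mask arithmetic happens on the finest grid among the inputs
(nearest-neighbor resampling only — binary semantics are never
interpolated). With preop tumor `P`, tracked cavity `C`, residual `R`
(clipped to `P`; the clipped-away volume is reported, since
intraoperative re-segmentation can drift outside the preoperative
contour): `resected = P \ R`, `TP = C ∩ resected`, `FP = C ∩ R`,
`FN = resected \ C`, `TN = R \ C`. Identities `TP+FP+TN+FN = |P|` and
`predicted residual = TN+FN = |P| − |C ∩ P|` hold exactly in voxel
counts (counts are carried alongside cm³ so tests can verify them
without float summation error).

Reported percentages: "Tumor Resected Based on Tool-Tip Tracking (%)" is
`|C ∩ P| / |P|` — the tracked coverage of the preoperative tumor,
including any false-positive sliver inside the residual; the stricter
TP-only percentage is reported separately. "False Positive Tracking (%)"
is `|FP| / |R|`, defined as 0 when the residual is empty. Phantom
metrics: coverage `|C ∩ lesion| / |lesion|`; overlap defaults to Dice,
with a directional variant (`|A ∩ B| / |A|`) available because the
phantom literature does not always state which is meant.

Reports round volumes and percentages to one decimal (the print
convention of clinical tables); JSON output preserves full precision.

## The synthetic-surgery simulator

The simulator emulates the features of clinical cases that drive
tracking accuracy, with ground truth recorded before any perturbation so
evaluation measures *mapping* error, not truth error.

* **Phantom.** Ellipsoidal tumor (default grid 0.5 mm) with 0–n
  spherical concavities bitten out of the surface (recurrent tumors are
  rarely convex), optional concentric cystic core occupying a set
  fraction of tumor volume, optional prior-resection cavity, inside an
  ellipsoidal cerebrum (tumor + 15 mm by default). Deterministic in the
  seed, bit for bit.
* **Plan.** Boustrophedon raster through the target volume: horizontal
  layers top-down at `raster_spacing_mm` (default = tool radius, which
  guarantees overlap of adjacent swept lines), alternating line
  directions, lines spanning the target extent, the deepest target plane
  always rastered. Samples lie on the raster polyline at uniform
  arc-length steps of `tool_speed / rate`; timestamps are uniform at the
  sampling rate (default 20 Hz, 5 mm/s). For partial resections the
  target is the upper `resect_fraction` of the tumor along the approach
  (raster) axis, with the cut plane raised by the tool radius so the
  *swept* fraction matches the request; deep tissue is removed last. A
  concentric (erosion-shell) ordering was rejected: straight raster
  lines through a hollow shell would re-carve the core it is supposed to
  spare.
* **Ground truth.** The swept volume is the ideal raster polyline
  voxelized as a union of capsules (voxel centers strictly within the
  tool radius — the same strict-interior convention as the SDF), on an
  ROI lattice index-aligned with the phantom grid so cropping and
  intersection are exact. `resected = swept ∩ tumor`,
  `residual = tumor \ resected`, a disjoint partition by construction.
* **Dropout.** Samples deleted inside explicit occlusion windows, or
  windows drawn from a two-state (visible/occluded) renewal process with
  exponential dwell times — episodic line-of-sight loss.
* **Jitter.** I.i.d. isotropic Gaussian offsets per sample
  (calibration/tracking error), σ per axis.
* **Brain shift.** A Gaussian-bump displacement field (magnitude `m`,
  length scale `L`), tapered to zero at the cerebrum boundary; a
  cyst-collapse mode points the field toward the drained cyst centroid.
  The intraoperative truth masks receive the full field (the tissue
  state at imaging time); each log position is displaced by the field
  scaled by its elapsed-time fraction, because shift accumulates during
  surgery — early samples sit in the near-preoperative frame, late ones
  in the shifted frame. This temporal mismatch is what produces False
  Positive Tracking (tracking apparently inside the shifted residual)
  alongside False Negative Tracking; displacing the whole log by the
  static field would cancel the effect and make FP structurally
  impossible. Mask warping uses the small-displacement inverse
  (`value at x ← value at x − u(x)`), adequate for the 2–10 mm magnitudes
  simulated. Magnitudes follow the neurosurgical literature's range; no
  biomechanical deformation model is attempted.

What the simulator does **not** model: tissue elasticity/biomechanics,
MRI intensities beyond a flat background for overlays, instrument shape
(the carving kernel is spherical), surgeon-specific motion, or
registration error other than isotropic jitter. Passing phantom tests
therefore demonstrates correctness of the mapping and evaluation
machinery under the stated motion/noise models — not clinical accuracy,
which depends on line-of-sight discipline and real brain-shift patterns.

## Phantom study configuration

The bundled batch (`run_phantom_batch`, also driven by
`scripts/acceptance.py`) uses 18 phantoms — ellipsoid radii drawn
uniformly from 17–23 × 14–18 × 11–17 mm (≈10–30 cm³), 0–2 lobes of depth
3–6 mm — each fully resected with continuous tracking at 20 Hz, 5 mm/s,
raster spacing 1.5 mm, carved at 0.5 mm, no dropout/jitter/shift. Per
case it reports lesion coverage and Dice overlap between the carved
cavity and the analytic swept-volume truth. Problem sizes (ROI grids
≈100–130 voxels per axis, 20k–60k samples per case) keep the whole batch
to a few minutes on one CPU.

## Numerical choices and edge cases

* All distances in float64; the incremental narrow-band update is
  bit-identical to a dense clamped min-distance evaluation (verified by
  an oracle test), because subgrid voxel-center coordinates are computed
  separably and min/clamp are exact.
* Nearest-neighbor index lookup uses `rint` (ties to even); target
  voxels whose centers fall more than half a voxel outside a source
  lattice resample to 0.
* `init_map` grids include voxel centers on both ROI faces (a 10 mm box
  at 0.5 mm spacing has 21 samples per axis) and extend past the box
  when the extent is not a spacing multiple.
* Samples whose narrow band misses the ROI entirely are no-ops; an
  unordered log is an error.
* Empty preoperative tumor, empty lesion, or both-empty overlap inputs
  raise (`percent of zero` is undefined) rather than returning 0.
* Mesh export stores vertices as float32 (the PLY/STL norm); the
  per-vertex `time_s` property is written into PLY and recovered on
  load. Map checkpoints are NRRD pairs (SDF + first-carved, NaN =
  never).

## Known limitations

* The effective tool radius is an assumption; clinical instruments
  remove tissue anisotropically and intermittently (e.g. CUSA on/off),
  so the carved cavity is an idealization of "volume traversed".
* The cerebrum filter cannot reject in-brain samples recorded while the
  instrument was idle or being exchanged; no heuristic beyond the
  brain mask is applied.
* Brain-shift compensation is out of scope: the simulator reproduces the
  *effect* of shift on the metrics, not a correction for it.
* Carving assumes an axis-aligned ROI lattice; volumes with rotated
  direction matrices are supported for I/O and geometry but the raster
  planner requires identity direction.
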