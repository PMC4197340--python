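# Methods

Units throughout: millimetres, milliseconds, degrees, newtons. All
randomness flows from explicit integer seeds; identical seeds give
byte-identical outputs.

## Anatomical coordinate frames

Frames are right-handed with X anterior, Y proximal, Z lateral (right
foot). The primary axis of each definition is taken exactly as stated;
the secondary axis is Gram–Schmidt-orthogonalised against it; the third
axis is the completing cross product.

* **Tibia** — origin at the centroid of the plafond boundary points;
  Y toward the shaft point; X perpendicular to both Y and the
  anteromedial–anterolateral plafond edge line, signed anterior. The
  anterior disambiguation uses the AM/AL edge midpoint relative to the
  plafond centroid, so swapping the AM and AL labels cannot flip the
  axis.
* **Talus** — origin at the centre of the circle circumscribing the
  trochlea tali; Z along the circle normal (lateral); X along the
  posterior→anterior trochlear edge direction. The circle is fit to the
  AM/AL edge midpoint, the PM/PL edge midpoint, and the mid-band
  trochlear surface samples: two midpoints alone underdetermine a
  circle, so the surface samples are required inputs. The fit is a
  least-squares plane followed by the algebraic (Kåsa) in-plane circle —
  closed form, deterministic, exact on noiseless circles of any radius.
* **Calcaneus** — origin midway between the most lateral point of the
  posterior articular surface and the most medial point of the middle
  articular surface; X is the anterior hint projected onto the fitted
  inferior-surface plane; Y is the inferior-plane normal projected onto
  the fitted lateral-surface plane, orthogonalised against X.

Landmarks are explicit inputs (JSON), never detected from geometry:
the intended workflow has an operator pick them on CT models, and the
phantom generator places them analytically. Degenerate configurations
(collinear fits, coincident landmarks, shaft point on the origin) raise
`DegenerateGeometryError`. Frame construction is rigidly equivariant to
1e−9, verified over 100 seeded placements per bone.

## Single-plane 3D–2D registration

**Camera.** Cone-beam: point source, flat detector `detector_distance`
down the +z optical axis, square pixels of `pixel_pitch` mm. The lab
frame is the camera frame, so "in-plane" means (x, y) and "out-of-plane"
means depth z. Default synthetic geometry: source-to-detector 1000 mm,
object plane ≈ 700 mm (magnification ≈ 1.43), 256×256 images at
1.2 mm/px (a desk-scale stand-in for a 512×512 clinical detector; the
`CameraModel.scaled` helper changes resolution without changing
geometry).

**Silhouettes.** `render_silhouette` projects every face and rasterizes
the filled silhouette (PIL polygon fill), with the boundary from
marching squares. Rendered *images* are anti-aliased by 4× supersampled
coverage so the apparent edge sits at the true projected contour to well
under a pixel. For the registration *cost*, meshes that declare convex
components (all phantom bones do) get an exact sub-pixel contour: the
cone-beam silhouette of a convex solid is the convex hull of its
projected vertices, and multi-part bones take the union of their
component hulls. General meshes fall back to the rasterized contour.

**Cost.** One-way chamfer: the Sobel gradient ridge of the image is
thinned to a skeleton, its Euclidean distance transform is computed on a
4× upsampled grid (values in native px), and the cost is the mean of
that field bilinearly sampled along the model contour. The edge
threshold is relative (0.25 × max gradient), making the cost invariant
to affine intensity rescaling. The manual contour-matching of the
original workflow is replaced by this automated local search; the cost
is a standard formalisation, not a claim about how a human matches.

**Optimization.** Nelder–Mead over six parameters (three extrinsic
x-y-z rotations in degrees applied on top of the initial rotation, three
translations), with seeded multi-start perturbations (default 5 starts,
σ = 1 mm/1°, ≤ 400 evaluations each) and a final fine polish
(quarter-step simplex) that collapses nearby micro-minima so repeated
runs agree far inside the reported repeatability. A registration is
flagged non-converged when the best cost exceeds 0.75 px (typical
aligned costs are ≈ 0.2 px at the default noise). Tracking initializes
frame k from the frame k−1 result (constant-position prediction); if the
best cost exceeds 0.45 px the tracker retries with a broadened
multi-start (2σ, +2 starts) before accepting, which stops slow drift
into silhouette-alias attractors. A failed frame (black image, frustum
violation, non-convergence) is flagged and the last good pose carries
forward, so isolated bad frames do not derail their neighbours.

**Error anatomy.** In-plane translations and the in-plane rotation are
constrained to ≈ 0.1–0.5 mm/deg. Depth is constrained only through
magnification: out-of-plane translation errors are an order of magnitude
larger, and out-of-plane tilts are the dominant rotation error
(1–2.5°). This asymmetry propagates to the joint angles: sagittal-plane
dorsi/plantarflexion is recovered to a few tenths of a degree, while
eversion and axial rotation carry a several-degree budget — the same
per-axis reliability ordering the fluoroscopic ankle literature reports.
Constant-position tracking assumes inter-frame motion within the
capture range (~10 mm/10°); the pre-contact free fall moves the foot
≈ 23 mm per 60 Hz frame, so tracked experiments start at the toe-contact
frame and pre-contact frames are registered independently when needed.

## Joint angles

Talocrural = talus in the tibial anatomical frame; subtalar = calcaneus
in the talar anatomical frame. Angles follow the Grood–Suntay joint
coordinate system: flexion about the parent-fixed mediolateral axis,
axial rotation about the child-fixed proximodistal axis,
eversion/inversion about the floating axis. With the frame conventions
above this is the intrinsic Z–X–Y Euler factorisation with
`dorsiflexion = +a`, `eversion = −b`, `external rotation = −c`; the
compose/decompose pair round-trips to 1e−9 for |angles| ≤ 45°, and a
`GimbalWarning` is raised within 2° of the floating-axis degeneracy.
Angles are reported relative to the static standing reference (the
reference posture reads 0°); zeroing is reversible, and whether the
original tables were reference-zeroed is not stated in the source — we
zero and say so. The 60 Hz series is linearly interpolated for period
changes (the periods span ~5–9 frames; higher-order interpolation is
unwarranted). Single-frame registration gaps are linearly interpolated;
longer gaps are flagged missing.

## Events and synchronization

Both streams are put on a common clock with t = 0 at toe contact.
Operational definitions (the source protocol states none, so these are
package-defined stand-ins, config-exposed and noted in output
metadata):

* **toe contact** — first time vertical GRF exceeds 10 N and stays above
  it for 20 ms, back-interpolated to the threshold crossing;
* **heel contact** — first time after toe contact the inferior-most
  transformed calcaneal vertex descends below 5 mm above the plate
  plane, interpolated between frames. A kinematic rule is unavoidable:
  a forefoot landing has no second force onset.

The analysis window is −33 ms to +250 ms around toe contact with a mark
at +150 ms; at 60 Hz the window start is exactly two frames before the
toe-contact frame. Every generated forefoot trial satisfies
window_start < toe < heel < +150 < window_end, enforced as an invariant.

## Statistics

Paired two-tailed t-test per variable (t = mean(d)/(sd(d)/√n), df = n−1),
trials averaged within subject before testing (config-switchable);
no multiple-testing correction across table rows, matching the source
analysis. Table presentation rounds to one decimal, half away from zero,
and the "mean difference" column is computed from the rounded summary
means. Reliability is ICC(3,1) — two-way mixed, consistency, single
measurement — the natural model when a single operator repeats the
analysis. Sample size for a paired design is the smallest n whose
noncentral-t power reaches the target (the n = 6 claim of the source
study is not reproduced because its effect size is unstated).

## Synthetic data

**Phantoms.** Parametric primitives, not anatomical shapes, chosen so
every downstream truth is analytic: a tibial shaft cylinder (radius
14 mm, length 50 mm — only the distal tibia is in a lateral ankle
field of view) with a medial-malleolus block; a talus whose trochlea is
an exact cylindrical band (radius 19 mm, width 28 mm, the default of
the 18–20 mm anatomical range) over a flat body with an anterior neck;
a calcaneal wedge (60×28×38 mm, inferior surface inclined 20° so it is
horizontal at neutral stance) with a sustentaculum-like medial process.
The malleolus, neck, flat bottom and medial process are not decoration:
a surface of revolution has a silhouette invariant to rotation about its
axis, and a z-symmetric box is first-order invariant to tilt about the
anterior axis, so without off-axis outline features the registration
problem would be genuinely ill-posed in exactly the rotations the joint
angles need. Vertex jitter (σ = 0.02 mm, seeded) roughens the surfaces;
landmarks are placed analytically.

**Motion scripts.** Per joint and axis, a PCHIP curve through control
points at −60, 0, t_heel, 150 and 300 ms whose values are the published
condition summaries: toe-contact angles (talocrural dorsiflexion −20.5°
barefoot / −17.9° shod, etc.), toe-to-heel-contact changes, and
heel-contact-to-150 ms changes, with a small proportional tail after
150 ms. The global trajectory is a free fall at the 10 cm drop's impact
velocity (1.4 mm/ms) until toe contact, then an 18 mm smoothstep sink
over 150 ms; the scene height is solved so the calcaneus clears the
plate by 14 mm at toe contact (the forefoot that actually touches is
not modelled). Geometric heel contact then lands near 80 ms in both
conditions. Ground-truth heel contact is computed from the scripted
poses at 1 ms sampling with the same inferior-vertex rule the detector
uses; the 60 Hz detector agrees within half a frame.

**GRF.** Zero before toe contact, then
`BW · ramp(t/25 ms) · (1 + (peak−1) · (t/45 ms) e^{1−t/45 ms})`: an
impact transient peaking at exactly the scripted multiple of body weight
(1.58 barefoot / 1.39 shod by default) at 45 ms, settling to one body
weight, plus additive Gaussian noise (σ = 3 N default).

**Cohorts.** Each subject s gets per-variable values
`b_s = μ_b + a_s + e_s/2`, `s_s = μ_s + a_s − e_s/2` with shared effect
`a_s ~ N(0, σ_a)` and paired difference `e_s ~ N(0, σ_d)`. σ_d is the
difference SD implied by the published two-tailed p-value
(σ_d = |Δ|√n / t⁻¹(1−p/2, n−1)), capped at the algebraic maximum
sd_b + sd_s (one published row implies an impossible σ_d ≈ 27°; the cap
keeps marginals faithful); σ_a then matches the published condition SD.
Cohorts are therefore study-shaped in means, SDs *and* significance
structure: the empirical power of the paired test on generated cohorts
matches a direct normal-theory Monte-Carlo of the same effect model
within sampling error. Trial-level measurement noise is white 0.25° per
frame per axis (motivated by the registration repeatability). The
cohort layer samples the scripted curves directly — it stands in for
the study's processed per-trial outcomes; the render→register path is
validated separately and closed end-to-end on single trials.

**What the generator does not emulate.** X-ray attenuation physics and
soft-tissue occlusion (silhouette-contrast renders only), anatomical
bone shape, shoe-sole geometry or material mechanics, ground-contact
dynamics after heel touchdown (the heel may sink a few mm "through" the
plate late in the window; events are unaffected), marker or CT
segmentation error, and left feet. Passing tests therefore demonstrate
the correctness of the measurement chain and its noise behaviour on
silhouette-faithful data — not performance on clinical images.

## Problem sizes

The validation experiments run desk-scale: 256×256 frames, three
repeated registrations of three frames × three bones for repeatability,
a 12–15-frame tracked landing × three repeats for the ICC, one trial
per condition (three frames each, all bones) for the end-to-end
condition-difference closure, and 150 generated cohorts for the power
cross-check. These sizes were chosen as the smallest at which the
statistics of interest are stable; all are parameters of the
corresponding `experiments` functions.

## Known limitations

* Depth (out-of-plane translation) is weakly identified by construction;
  its errors are reported, not suppressed.
* Non-sagittal joint angles inherit out-of-plane tilt error (several
  degrees at single frames); condition differences in eversion/axial
  rotation are correspondingly noisy.
* The chamfer cost can "converge" onto wrong edges from grossly wrong
  initializations (a false-positive mode shared by all one-way contour
  costs); initialization within a few mm/deg, or tracking, is assumed.
* Toe/heel-contact rules are package-defined operational definitions;
  both thresholds are configuration.
* The sample-size operation answers the generic paired-design question;
  it does not reproduce any specific published n.
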