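# Methods

This note records the models, conventions and numerical choices behind
`kinerisk`, and what its synthetic-data validation does and does not show.

## Coordinate conventions and data model

All positions are millimetres in a right-handed frame with X lateral
(subject's right), Y anterior, Z up; frames are 0-based and sampled at a
fixed rate (200 Hz default). A `MarkerFrameSeries` carries an explicit
per-sample missing flag — zeros are valid coordinates and never encode
occlusion. TRC is the primary interchange format (human-diffable text);
long-format CSV is equivalent; C3D is supported behind the same interface
when the optional `ezc3d` dependency is installed.

## The skeleton

The bundled model has 15 rigid segments — head, upper and lower trunk, and
paired upper arms, forearms, hands, thighs, shanks, feet — in a tree rooted
at the pelvis. Each segment's local frame is aligned with the global frame
in the neutral standing posture with its origin at the proximal joint
centre, and holds ≥3 non-collinear template markers in local coordinates.

The 42-marker label set is a reconstruction: published marker-site lists
for comparable full-body setups describe the sites in prose without an
itemised left/right breakdown, and 42 labels cannot give 15 segments three
*private* markers each (that needs 45). Adjacent segments therefore share
markers, and every shared marker is placed where sharing is geometrically
exact: at a joint centre (shoulder, elbow — invariant under any rotation of
the joint) or on the wrist flexion axis (invariant under wrist
flexion/extension). Template and muscle-attachment coordinates describe a
plausible 1.70 m reference body; they are fixtures, not anatomical ground
truth, so per-muscle lengthening percentages computed from synthetic
motions are illustrative rather than subject-representative.

## Preprocessing

Occlusion gaps are linearly interpolated per coordinate when no longer
than the configured limit (default 10 frames = 50 ms at 200 Hz); longer
gaps stay missing and are reported; edge gaps are held at the nearest valid
sample. Smoothing uses the symmetric five-point kernel (1, 3, 4, 3, 1)/12
applied to raw marker coordinates before pose fitting — derived angle and
length series are not re-smoothed. At the two samples nearest each series
edge the kernel is truncated and renormalized; this preserves length and
avoids extrapolation, at the cost of slightly less attenuation there (the
alternative — dropping edge frames — discards data; which variant the
original workflow used is unknowable from the published description). The
kernel leaves constants and interior linear trends unchanged and halves the
standard deviation of white noise (√(Σw²) = 1/2).

## Kinematics

Segment poses are fitted independently per frame by the SVD (Kabsch)
least-squares rigid alignment with a determinant guard against reflections;
frames with fewer than three usable markers are marked invalid rather than
failing the run. No inverse kinematics over the chain is attempted — joint
constraints are not enforced, which keeps the estimator simple and makes
its errors local.

Joint angles decompose `R_rel = R_parentᵀ R_child` in an intrinsic Cardan
sequence, default XYZ = flexion/extension about the lateral axis, then
abduction/adduction, then axial rotation; the sequence is configurable per
joint. Angles are reported in degrees, unwrapped over time (adjacent-frame
jumps >180° corrected by ±360°), and frames whose middle angle is within 1°
of ±90° carry a gimbal-proximity flag but still return values. ROM is
max − min over the analysed interval. Angular velocity uses central
differences (one-sided at the edges); the peak speed and the maximal
contiguous deceleration interval are reported for follow-through analyses.

Hip angles are thigh-relative-to-pelvis (parent-segment-relative
throughout); a global-frame alternative was considered and rejected because
it conflates pelvis motion with hip motion during one-leg support.

## Muscle model

A muscle is a straight-line polyline through ≥2 attachment points fixed in
segment-local frames; no wrapping surfaces, moment arms, forces or
activation — path geometry only, which is the level the risk criterion
needs. Rest length is the path length in the neutral anatomical standing
posture; it is the denominator of normalized lengthening, which therefore
equals exactly 100% at neutral and is invariant under uniform subject
scaling. Lengthening speed is the central-difference dL/dt converted to
m/s. Work patterns use a ±0.005 m/s dead band: above = lengthening
(eccentric proxy), below −dead-band = shortening (concentric proxy),
otherwise isometric. The dead band suppresses classification chatter from
millimetre-level noise at 200 Hz; the labels are kinematic proxies since no
EMG exists in the pipeline.

## Risk criteria

A muscle is **at risk** when its maximum instantaneous normalized
lengthening strictly exceeds the threshold (default 120% of rest length,
per the lesion-study criterion; "exactly 120.0%" is deliberately not
flagged). The criterion is applied to the per-trial maximum; group tables
aggregate per-subject values as mean ± SD.

**Impact-like eccentric loading** has no published detection rule, only two
cues — a "speedy increase" of lengthening speed within less than ~100 ms.
The implemented rule is: an event starts where the speed last sat at or
below the series median and ends at the local peak of the climb, provided
the climb from the median to `rise_factor ×` median (default 3×) takes at
most `rise_window` (default 100 ms) and the muscle lengthens throughout.
Both parameters are configurable; a series with non-positive median (e.g.
all-zero speed) yields no events by construction.

**Pitch phase segmentation** locates seven events: trial bounds, peak
lead-foot height (balance point), onset of the post-balance height minimum
(foot contact; onset = first frame within 0.2% of the height range above
the minimum), extrema of the shoulder axial-rotation angle after foot
contact (maximum external / internal rotation), and peak hand speed between
those extrema (ball release — a proxy, as no ball is modelled). Six phases
span consecutive events. The heuristics follow the standard qualitative
event definitions and are validated only against the synthetic generator,
not against real pitching data; degenerate inputs (monotone rotation,
non-increasing events) raise a segmentation error.

## Statistics

Group summaries are mean and sample SD (n−1). The independent t-test is
implemented from the (mean, sd, n) triplets — pooled variance by default,
matching the era's standard "independent t test", with Welch's form
available by flag; raw-sample input is routed through `describe`. p-values
are two-sided; significance defaults to α = 0.05; no multiple-testing
correction is applied (as none was applied in the source tables — a caveat
when scanning many variables). Published comparisons can be checked
directly from printed summaries because the formulas need nothing else.

## Synthetic data

The generator prescribes per-joint angle curves as PCHIP control points,
composes poses down the joint tree, and maps each marker once from its
owner segment; Gaussian marker noise and occlusion windows are applied
after the noise-free ground truth (angles, muscle lengths, event frames) is
recorded — the ground truth is computed from the prescribed poses directly,
never through marker fitting, so it is a true independent oracle. PCHIP
never overshoots its control points, and knot times are snapped onto the
frame grid, so a preset's prescribed excursion equals the sampled curve's
ROM exactly. Skill presets (instep kick 1.2 s, fan kick 1.6 s, axe kick
0.8 s, pitch 2.0 s, all 200 Hz) default their excursions to the published
group means (e.g. hip flexion/extension 129° instep, 146.3° fan, 162.2°
axe; knee 113°/108.9°/65.3°); the axe kick runs in roughly half the fan
kick's time, which reproduces the reported speed ordering qualitatively.
The pitch preset plants the lead foot with a deliberately sharp final
descent so that "foot contact" is well defined to within a frame or two.

Not emulated: soft-tissue artifact, marker mislabeling, non-Gaussian noise,
ball/environment objects, and inter-subject anthropometric variation beyond
uniform scaling. Passing round-trip tests therefore demonstrates the
correctness of the computational chain, not field accuracy on real capture
data.

## Validation choices and tolerances

- Zero-noise round trips (generator → markers → poses → angles/lengths) are
  checked with smoothing disabled: the input has no noise to remove, and
  the check targets reconstruction fidelity (errors come out near machine
  precision, ~1e-11). With smoothing enabled the filter biases fast curve
  peaks by a few tenths of a degree / up to ~2% of muscle length on the
  fastest kick — inherent to any low-pass filter at these speeds.
- Rigid-fit recovery of random transforms: residual < 1e-9 mm over 1000
  seeded cases; Cardan decompose–recompose: < 1e-9 away from gimbal lock;
  hinge muscle length vs the planar law-of-cosines: < 1e-6 mm.
- Under 2 mm marker noise the preset hip ROM stays within 2° (Monte-Carlo,
  seeded); fillable occlusions change ROM by < 0.5°.
- The null calibration runs 10,000 same-normal replicates at the study's
  group sizes (n=7 vs 13) and expects a rejection rate of 0.05 ± 0.01.

## Known limitations

Straight-line muscle paths underestimate lengths where real muscles wrap
bone (notably at large hip flexion); attachment coordinates are fixtures;
independent per-segment fits ignore joint constraints; pitch event
heuristics are generator-validated only; and shared wrist markers are only
exactly consistent for wrist flexion/extension (a limitation inherited from
reconciling 42 labels with 15 three-marker segments).
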