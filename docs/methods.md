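# Methods

This document specifies the measurement model, the conventions recorded in
every output, all tunable parameters, the synthetic validation phantom, and
the numerical choices and limitations of the implementation. Lengths are in
millimetres, angles in degrees throughout.

## 1. Measurement model

### 1.1 Resting pose (`frame.compute_resting_plane`)

The bone is posed as if laid on a flat table on its posterior condyles.
Candidate supporting planes are the convex-hull facets for which

- the center of mass projects within 3 mm of the facet (static stability),
- the hull's principal axis lies roughly in the plane (|n·ℓ| ≤ 0.5,
  excluding end-on balancing poses).

Each candidate facet plane is refined by up to two rounds of SVD plane
fitting to the mesh vertices within the 0.5 mm contact band, anchored at
the contact centroid (this removes the sensitivity of a single hull facet
to vertex jitter); refinement aborts if the support is nearly collinear.
A candidate is valid only if the center of mass projects inside the convex
hull of the contact points (1.5 mm margin) and the contacts contain a
*condylar pair*: two single-linkage clusters (5 mm gap) that are compact
(extent ≤ 18 mm), populated (≥ 3 points each) and separated by ≥ 15 mm.
Among valid candidates the pose with the **lowest center of mass** wins
(minimum potential energy, rounded to 0.1 mm; ties broken by larger patch
separation, then contact count). The plane normal, oriented into the bone,
is the anterior viewing axis.

### 1.2 Anatomical frame (`frame.build_frame`)

- **Shaft axis**: principal axis of the proximal portion of the mesh,
  oriented distal → proximal, then projected into the viewing plane
  (Gram–Schmidt); the raw 3-D axis is kept for audit.
- **Bicondylar axis**: through the two condylar contact centroids,
  orthogonalized against shaft and view axes, oriented medial → lateral.
- **Laterality**: the medial condyle's contact patch sits farther distal
  and is larger; if the asymmetry signal is below threshold the side is
  `unknown` (flagged) and may be supplied by the user. A user override that
  contradicts the heuristic is honored but flagged.
- QC: vertices more than 2 mm below the resting plane are flagged
  (`vertices_below_resting_plane`).

The orthonormal triad (bicondylar `t`, shaft `s`, view `h`) defines frame
coordinates used everywhere downstream.

### 1.3 Trochlear tracing (`trochlea`)

Slice planes perpendicular to the shaft axis sample the distal
`distal_fraction` of the proximodistal extent. Each slice yields an
anterior height profile `h(t)` (the most anterior surface point per
mediolateral station, `profile_spacing` apart). Slice spacing is floored
at the median mesh edge length: slicing finer than the mesh resolution
only duplicates profiles.

Per profile, after Gaussian smoothing (`smooth_sigma_mm`), every pair of
adjacent peaks with prominence ≥ `min_prominence_mm` flanking an interior
minimum is a *triple* (medial ridge, groove, lateral ridge). Triples are
linked distal → proximal by greedy nearest-neighbour matching with a
constant-velocity prediction: each open chain extrapolates its last step in
all three `t` coordinates, and a match requires the worst residual to stay
inside `link_gate_mm` (+ half the predicted step, so steep courses widen
their own gate; new chains boot with 1.5× the gate). A chain may skip
`max_link_gap` slices before closing. The winning chain is the longest
(ties by total ridge prominence) and must cover ≥ 4 slices over ≥ 2.5 mm,
otherwise measurement fails loudly (`GrooveDetectionError`).

Trace termination — both ridges dropping below the prominence threshold —
operationalizes facet convergence. The **patellar entry point** is the
midpoint of the medial and lateral proximal ridge endpoints. The groove
obliquity is the angle between the proximal-quarter groove chord and the
shaft axis in the viewing plane. The spur prominence reported per knee is
the maximum medial-ridge height above the groove floor over the proximal
third of the trace; it includes the baseline ridge relief, so spur size is
read as elevation relative to a cohort baseline, not as an absolute.

### 1.4 Clockface (`clockface`)

The clock center is placed on the shaft-axis line at the proximodistal
level of the groove's distal terminus; 12 o'clock points proximally along
the shaft midline. The lateralization angle θ is the unsigned angle
between the 12-o'clock ray and the center→entry ray, measured in the
viewing-plane projection (signed variant: positive = lateral). An entry
point within 1 mm of the center leaves the angle undefined and raises an
error.

Clock mapping (30° per hour): left knees `hour = (θ/30) mod 12`, right
knees `hour = (12 − θ/30) mod 12`, so lateral deviation reads 1–2–3
o'clock on the left and 11–10–9 o'clock on the right. Grades are
half-open bins on θ: `< 30` normal, `[30, 46)` mild, `[46, 60)` moderate,
`≥ 60` severe. The full convention is recorded in every output as
`clockface-v1:rest=posterior-condyles;center=shaft-line@groove-distal;12=shaft-proximal;30deg/hour`.

## 2. Pipeline parameters (`PipelineConfig`)

| parameter | default | meaning |
|---|---|---|
| `n_slices` | 120 | requested slice planes (clamped to mesh resolution) |
| `distal_fraction` | 0.6 | fraction of the proximodistal extent sliced |
| `profile_spacing` | 0.5 mm | mediolateral sampling step |
| `smooth_sigma_mm` | 1.0 mm | profile smoothing |
| `min_prominence_mm` | 0.75 mm | ridge prominence threshold |
| `link_gate_mm` | 6.0 mm | trace-linking residual gate |
| `max_link_gap` | 1 | slices a trace may skip |
| `grade_edges` | (30, 46, 60) | severity bin edges |

Pose-search constants (contact tolerance 0.5 mm, cluster gap 5 mm, patch
extent ≤ 18 mm, patch separation ≥ 15 mm) are anatomical absolutes for a
human distal femur and are deliberately not scale-free; meshes are
validated to lie in a 20–600 mm bounding-box range, with optional automatic
m/µm → mm rescaling.

## 3. Synthetic femur (`synth`)

The phantom is an implicit solid polygonized by marching cubes at
`mesh_pitch_mm`:

- a shaft capsule along +y, grazing the resting plane,
- two condylar ellipsoids exactly tangent to z = 0 (the medial one larger
  and shifted 3 mm distally, encoding laterality),
- an anterior block whose top face is a heightfield: a flat base carrying
  two Gaussian ridges (σ = 3 mm, amplitude `ridge_height_mm`) offset half a
  `groove_width_mm` either side of the groove centerline, minus a Gaussian
  groove dip, with amplitudes ramped over 1.5 mm at the course ends. A
  spur is an amplitude swell of the medial ridge near its proximal end.

The centerline runs from the distal terminus D on the midline to the entry
point E placed at exactly `theta_deg` on a 35 mm radius about the clock
center (optionally via a curved course with prescribed obliquity). Ridge
maxima of the terminal profile are solved numerically, so the stored
ground truth (entry point, ridge termini, axes, plane) is exact for the
pre-jitter surface; `GroundTruth.recompute_theta()` reproduces `theta_deg`
to machine precision. Right knees are exact mirror images. Vertex jitter
(`noise_mm`, seeded) is applied last. Cohorts draw θ from a truncated
normal on [0, 90] with per-knee meshing seeds derived deterministically
from the cohort seed.

Generator and pipeline share no geometry code; the pipeline never sees
ground truth.

### Realism limits of the phantom

- The heightfield applies the ridge/groove profile **mediolaterally at
  fixed shaft height**. Perpendicular to a course at angle θ the pattern is
  therefore only `groove_width · cos θ` wide: at very large angles
  (θ ≳ 79° at 1.4 mm pitch) the proximodistal span of the course
  (`35 · cos θ` mm) and the perpendicular groove width both collapse below
  mesh resolution and the groove is genuinely unresolvable. Such knees
  fail loudly and are excluded (counted in `n_failed`), which slightly
  biases noisy high-mean cohort statistics downward.
- Truncating the θ distribution to [0, 90] lowers the realized cohort mean
  below the nominal mean (≈ 1.4° at mean 56.6, SD 18.3).
- Condyles are ellipsoids and the trochlea is a separable heightfield;
  cartilage, osteophytes and segmentation artifacts are not modeled beyond
  isotropic vertex jitter.
- At 1.4 mm pitch the per-knee measurement carries a small positive bias
  (≈ +1.3°) from coarse sampling of the ridge maxima; at 1.0 mm pitch the
  per-knee error is within ±0.7° across θ ∈ [5°, 80°].

## 4. Numerical choices

- **Marching cubes** (scikit-image) with the z-grid offset by 0.317·pitch
  so flat faces never coincide with grid planes (exact node zero-crossings
  produce degenerate triangles); near-duplicate vertices are merged by
  rounding to 10⁻⁵ mm.
- **SVD plane refinement** of hull-facet candidates, anchored mid-band at
  the contact centroid, bounded to two iterations with a 0.95-cosine
  degeneracy guard.
- **Predictive trace linking** (constant-velocity extrapolation with a
  slope-scaled gate) rather than a fixed gate, so steep grooves at coarse
  pitch remain traceable without admitting cross-structure jumps; the gate
  tests the worst residual over groove and both ridge positions.
- **Resolution-adaptive slicing** floors slice spacing at the median mesh
  edge length; duplicated profiles would otherwise defeat the velocity
  estimate with staircase steps.
- **Statistics**: cohort SD uses the n−1 (sample) estimator; failed knees
  are excluded and counted, never imputed; all randomness flows from
  explicit seeds (`numpy.random.default_rng` / `SeedSequence`).

## 5. Limitations

- The method assumes a segmented **distal femur including enough shaft**
  (the shaft axis is estimated from the proximal 40 % of the mesh) and
  intact posterior condyles; severely eroded condyles break the resting
  pose definition.
- Laterality detection relies on condylar asymmetry; symmetric phantoms or
  pathological condyles yield `side = unknown`, in which case the angle and
  grade are still reported but the clock position requires a user-supplied
  side.
- Angles near 0° have an ill-conditioned clock direction (the entry ray is
  nearly parallel to 12 o'clock); angles are reported unsigned with a
  separate sign for medial deviation.
- Validation is synthetic. The phantom covers pose, noise, resolution,
  laterality, spur and obliquity variation, but not real cartilage/bone
  segmentation artifacts; absolute accuracy on clinical meshes should be
  established against expert measurements.
- Very severe dysplasia at coarse mesh resolution is excluded rather than
  guessed (see §3); use ≤ 1 mm pitch meshes when severe cases matter.
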