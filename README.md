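# trochlemetry

Quantification of proximal trochlear dysplasia from 3-D distal-femur surface
meshes, using a clockface description of where the patellar entry point of
the trochlear groove sits relative to the femoral shaft.

## The measurement

Trochlear dysplasia — a flattened or laterally displaced trochlear groove —
is a principal risk factor for patellofemoral instability, and its proximal
extent is poorly captured by single-slice radiographic indices. This package
implements a 3-D, whole-bone measurement:

1. **Resting pose.** The femur mesh is posed the way an anatomist would lay
   the bone on a table: resting on its two posterior condyles. The stable
   supporting plane is found by searching the convex hull for poses in which
   the center of mass is supported by two separate, compact condylar contact
   patches. Viewing direction is anterior (normal of that plane).
2. **Anatomical frame.** The shaft axis (pointing proximally), the
   bicondylar axis (medial to lateral) and the viewing axis form an
   orthonormal frame. Laterality is detected from condylar asymmetry and
   can be overridden.
3. **Trochlear tracing.** Planes perpendicular to the shaft axis cut the
   anterior surface into height profiles; in each profile the two trochlear
   ridges and the groove between them are detected as a
   ridge–minimum–ridge triple and linked across slices into continuous
   medial-ridge, lateral-ridge and groove traces. Where both ridges lose
   prominence the facets have converged: the **patellar entry point** is the
   midpoint of the two proximal ridge endpoints.
4. **Clockface.** An analog clock is centered on the shaft-axis line at the
   proximodistal level of the groove's distal terminus, 12 o'clock pointing
   proximally along the shaft midline. The angle between the 12-o'clock ray
   and the ray to the entry point is the **lateralization angle**; one clock
   hour spans 30°. Lateral deviation reads clockwise toward 1–2–3 o'clock
   in left knees and counter-clockwise toward 11–10–9 o'clock in right
   knees. Severity grades: `< 30°` normal, `[30°, 46°)` mild, `[46°, 60°)`
   moderate, `≥ 60°` severe.

Typical values: control knees cluster around 23° (just inside 1 o'clock);
dysplastic knees average about 57°, i.e. near 2 o'clock (left) or
10 o'clock (right). The package also reports groove obliquity and a
supratrochlear-spur prominence per knee.

Because patient meshes do not come with ground truth, validation uses a
**parametric synthetic femur**: an implicit-surface phantom (shaft capsule,
two condylar ellipsoids tangent to the resting plane, and an anterior
trochlear surface with two Gaussian ridges flanking a groove) whose entry
point is placed at an exact, known lateralization angle. Generator and
measurement pipeline share no code path beyond mesh I/O. See
[docs/methods.md](docs/methods.md) for the full model, all parameters and
the known limitations.

## Worked example

```python
from trochlemetry import SynthParams, generate, measure_mesh

mesh, truth = generate(SynthParams(theta_deg=56.6, seed=42))  # or load_mesh("knee.stl")
record, audit = measure_mesh(mesh)
print(record.side, record.lateralization_deg, record.clock_hour, record.grade)
```

Running `python examples/01_measure_single_knee.py` prints:

```
knee id              synth_left_theta56.6_seed42
side                 left
lateralization angle  56.14 deg   (ground truth 56.6)
clock position         1.87 o'clock
grade                moderate
groove obliquity      52.72 deg
spur prominence        6.58 mm
qc flags             -
```

The same works from the command line:

```bash
trochlemetry synth --theta 56.6 --seed 42 -o knee.stl --truth truth.json
trochlemetry measure knee.stl --out records.csv
trochlemetry cohort-synth --n 24 --theta-mean 56.6 --theta-sd 18.3 -o cohort/
trochlemetry measure cohort/*.stl --out cohort.csv
trochlemetry summarize cohort.csv
trochlemetry compare controls.csv cohort.csv
```

Every output records the measurement convention string and the resolved
configuration (`records.csv.meta.json`), and each knee carries QC flags;
knees that cannot be measured fail loudly and are reported as `failed`
rather than imputed.

More examples: [examples/](examples/) (single-knee audit trail, the clock
convention as a table, a two-group synthetic study).

## Layout

- `src/trochlemetry/` — library (`mesh_io`, `frame`, `trochlea`,
  `clockface`, `synth`, `cohort`, `config`) and the `trochlemetry` CLI.
- `tests/` — unit, property-based and acceptance tests.
- `examples/`, `docs/methods.md`, `scripts/acceptance.py`.
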