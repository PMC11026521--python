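# aaamorph

Automated morphometry of abdominal aortic aneurysm (AAA) surface models.

Before endovascular aneurysm repair (EVAR), a stent-graft is selected from
seven anatomical landmarks: the aortic neck diameter, the maximum aneurysm
diameter, the maximum right and left common iliac artery diameters, the
aortic neck length, the tortuosity of each common iliac artery, and the
angulation between the neck and the aneurysm.  Conventional measurement on
2D CT slices is slow and poorly reproducible (inter-observer variation can
exceed the clinical ±5 mm tolerance for diameters).  `aaamorph` measures
all seven landmarks directly on a triangulated 3D model of the
aorta-plus-thrombus lumen, driven by manually divided vessel centerlines —
the workflow used when measurements are scripted against a CAD kernel, here
implemented as a standalone geometric library.

## Method

The inputs for one case are: (1) the 3D aortic model (STL/PLY, mm), (2-4)
the neck, aneurysm, and right/left iliac centerlines, and (5) the start
planes of the two iliac arteries (JSON; schema in
`aaamorph.centerline`).

The core primitive is the **maximum-contour diameter search**.  A
centerline *c* is resampled at arc-length step *h* (default 1 mm) into
stations *(pᵢ, t̂ᵢ)*, where *t̂ᵢ* is the unit direction from *pᵢ* to its
consecutive point.  Each station defines a cutting plane (origin *pᵢ*,
normal *t̂ᵢ*); the plane–mesh intersection segments are chained into
contours, the longest contour is selected, and its maximum chord

&nbsp;&nbsp;&nbsp;&nbsp;d(pᵢ) = max_{a,b ∈ Cᵢ} ‖a − b‖

is measured.  The reported diameter is maxᵢ d(pᵢ).  From this primitive:

- **neck diameter** — a single plane at the neck centerline's arc-length
  midpoint;
- **aneurysm diameter** — the search over the aneurysm centerline;
- **iliac diameters** — the model is first cut at the iliac start plane
  (normal pointing into the iliac territory) so sac contours cannot shadow
  the branch, then the search runs along the iliac centerline;
- **neck length** — arc length of the neck centerline;
- **iliac tortuosity** — arc length / start-to-end chord of the iliac
  centerline (≥ 1, = 1 for a straight vessel);
- **neck angulation** — angle between the start-to-end chords of the neck
  and aneurysm centerlines.

Evaluation statistics are included for segmentation and method comparison:
Dice coefficient and symmetric 95th-percentile Hausdorff distance (HD95) on
NIfTI label volumes, Bland–Altman bias and limits of agreement
(bias ± 1.96·SD), ICC(2,1), and pairwise Pearson correlations.

Because clinical CT models cannot ship with the code, a **phantom
generator** builds bifurcated fusiform aneurysm surfaces (angulated neck,
cosine-bell sac, arc-shaped iliac branches) whose seven landmark values are
known in closed form, so the whole pipeline is validated against analytic
ground truth.

## Worked example

```bash
aaamorph phantom --out demo --seed 42
aaamorph measure --surface demo/model.stl --centerlines demo/centerlines.json \
                 --out demo/report.json
```

The default phantom has neck radius 12 mm, sac radius 28 mm, neck length
33 mm, 30° neck angulation, and iliac radii 9.5/8.5 mm on 75°/90° arcs.
`demo/report.json` then contains (values the pipeline actually printed):

```
neck_diameter_mm         24.0        (truth 24.0)
aneurysm_diameter_mm     56.000001   (truth 56.0)
right_iliac_diameter_mm  19.001197   (truth 19.0)
left_iliac_diameter_mm   17.001548   (truth 17.0)
neck_length_mm           32.998615   (truth 33.0)
right_tortuosity.ratio    1.072502   (truth 1.072523)
left_tortuosity.ratio     1.106759   (truth 1.106791)
neck_angulation_deg      30.0        (truth 30.0)
```

i.e. diameters within 0.01%, lengths within 0.005%, tortuosity ratios
within 3·10⁻⁵, and angulation exact to machine precision.  `demo/ledger.json`
holds the analytic truth for comparison.  Segmentation metrics and
agreement statistics are exposed as `aaamorph seg-eval` and
`aaamorph agree`.

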