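# Methods

## Measurement model

All measurements operate on a triangulated surface of the aorta-plus-
thrombus lumen in mm world coordinates, plus four manually divided
centerlines (aortic neck, aneurysm, right and left common iliac) and the
two iliac start planes.  The anatomical divisions — where the neck ends and
the sac begins, where each iliac starts — arrive through the centerlines;
the package deliberately does not try to detect them.

### Sectioning kernel

A cutting plane is intersected with the mesh per triangle: vertices are
classified by signed distance to the plane, and each straddling triangle
contributes one segment whose endpoints are linear interpolations along the
crossing edges.  Vertices within 1e-9 mm of the plane are assigned to the
positive side, which makes the classification deterministic and prevents a
vertex lying exactly on the plane from generating duplicate or degenerate
segments (zero-length segments below the chaining tolerance are dropped).

Segments are chained into contours by merging endpoints within 1e-6 mm
(endpoints produced by a shared mesh edge are bitwise-near identical, so
this tolerance is generous by many orders of magnitude).  Chains whose free
ends meet are closed contours; open chains — which arise on clipped meshes
whose rims the plane crosses — are retained and compete for selection by
their open length.  Contour selection is by polyline length (including the
closing segment for closed contours) with ties broken by lowest index, so
the pipeline is fully deterministic.

The maximum chord of a contour is the exact pairwise maximum distance.  For
contours above 32 points the convex hull of the in-plane projection is
taken first; the farthest pair is always a pair of hull vertices, so the
result is identical to brute force (property-tested to 1e-9).

Cutting planes are unbounded, as they are in CAD kernels.  A centerline
displaced sideways off the vessel can therefore still produce sections;
measurement failure is reported only when every station plane misses the
mesh entirely.

### Stations and landmark definitions

Station directions are forward differences to the consecutive resampled
point, with the terminus reusing its predecessor's direction; no tangent
smoothing is applied.  The default station spacing is 1.0 mm — sub-voxel
relative to the 2.5–5.0 mm slice thickness typical of the CT this anatomy
is modelled from, and cheap enough that the whole seven-landmark
measurement of a ~35k-face model takes well under a second.

The neck diameter uses a single plane at the neck's arc-length midpoint
(the midpoint is interpolated exactly on the resampled polyline).  The neck
length is the centerline arc length, not the straight start-to-end
distance: measured along the vessel it generalizes correctly to angulated
necks and coincides with the straight distance for straight ones.  The
angulation uses the start-to-end chords of the neck and aneurysm
centerlines (not fitted lines), clamped arccosine, reported in [0, 180]°.
Tortuosity is arc length over chord; a chord below 1e-6 mm (a closed loop)
is reported as a degenerate-centerline error rather than a ratio, since
curve/chord is unbounded there.

Iliac measurement first clips the model to the positive half-space of the
stored iliac start plane.  The plane orientation convention is part of the
input contract: *the normal points toward the iliac territory*.  Without
this cut, a plane perpendicular to the iliac near the bifurcation can slice
the sac or the contralateral branch and the "longest contour" rule would
pick the wrong structure.

A failed landmark (missing centerline, empty sections) is recorded as a
per-landmark error entry and the remaining landmarks are still measured —
batch-friendly behaviour for cohort processing.

## Phantom generator

The phantom emulates the anatomy the measurement is designed for, with
every landmark value known in closed form:

- **Trunk** — one swept tube over a continuous centerline: a neck arc of
  length `neck_length` followed by a straight aneurysm axis.  The neck arc
  turns by 2β where β = `neck_bend_deg`, so its chord makes exactly β with
  the aneurysm axis while the junction stays tangent-continuous; the ledger
  angulation is therefore β exactly.  The radius is `neck_radius` along the
  neck, then a cosine bell rising to `aneurysm_max_radius` at mid-sac and
  returning — the C¹ profile avoids sectioning artifacts at the junction
  and places an analytic apex at mid-sac.
- **Iliac branches** — circular arcs of `iliac_arc_deg` with fixed arc
  length `iliac_length` (so the bend radius is L/θ and the tortuosity ratio
  depends only on θ), bending outward in the x–z plane, laterally offset so
  each branch lies strictly on its own side of the sagittal plane.  The
  iliac start planes sit on the trunk axis with ±x normals; keeping the
  positive half-space isolates one branch exactly.  An optional focal bulge
  raises the mid-branch radius.  The measured iliac centerline starts 1 mm
  into the branch so the first station plane clears the trunk outlet rim.
- **Ledger** — neck and sac diameters are 2r; neck length is the arc
  length parameter; branch tortuosity is (RΔθ)/(2R sin(Δθ/2)) over the
  measured arc range, 1.0 for straight branches.

Tube meshes use parallel-transported ring frames (no twist, so bent necks
cannot self-intersect at these curvatures) with 72 circumferential segments
and 1 mm ring spacing by default.  Rings are perpendicular to the local
tangent, so a station plane recovers the circular cross-section up to the
inscribed-polygon chord factor cos(π/144) ≈ 0.99976 — the dominant,
sub-0.1% bias in diameter recovery.

Default parameters are scaled to a typical elective-repair cohort: neck
diameter 24 mm, maximum sac diameter 56 mm, iliac diameters 19/17 mm, neck
length 33 mm, 30° angulation, iliac tortuosity ratios ≈ 1.07/1.11.
Randomized phantoms draw neck radius 8–14 mm, sac radius 1.8–2.3× the neck
radius (capped at 30 mm), neck length 28–45 mm, neck bend 0–30°, sac length
80–100 mm, iliac radii 6–10 mm, and iliac arcs 0–90°.  The generator is a
pure function of its spec — the seed field is reserved for optional jitter
that defaults to none — so identical specs give byte-identical meshes.

What the phantoms do *not* emulate: wall irregularity and thrombus texture,
non-circular (elliptical/saccular) cross-sections, branch vessels, and
imaging artifacts.  Passing the recovery suite shows the geometry pipeline
is correct and stable; it does not certify accuracy on patient-specific
meshes with segmentation noise, where the surface itself is the dominant
error source.  The bifurcation junction is left unstitched (the branch
tubes hang from the trunk outlet), which is representative of the clipped,
non-watertight parts the pipeline must tolerate; all sections through the
trunk itself are closed.

## Metrics

Dice is computed on voxel counts per label; two empty masks give 1.0 with
an explicit warning (total agreement on absence), one empty mask gives 0.0.
HD95 uses boundary voxels (6-connectivity face adjacency; the outside of
the grid counts as background), physical-mm distances via nearest-neighbour
queries, the linear-interpolation percentile, and symmetrization by the
maximum of the two directed 95th percentiles.  Directionality, percentile
interpolation, and symmetrization are conventions pinned here for
reproducibility — other common choices (average of directed terms,
nearest-rank percentile) differ at the sub-voxel level.

Bland–Altman reports bias, sample SD (n−1), and limits of agreement
bias ± 1.96·SD of the paired differences; optional outlier removal drops
points outside the initial limits once and recomputes, keeping the
first-pass statistics alongside.  The ICC is fixed to the two-way
random-effects, absolute-agreement, single-rater form ICC(2,1) =
(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n), the matching design for
several observers rating the same subjects; a zero-variance table is
defined as 1.0 with a warning.  Pairwise observer agreement is exposed as
Pearson correlations of column pairs.

## Numerical choices and problem sizes

- On-plane tolerance 1e-9 mm (classification), chaining tolerance 1e-6 mm,
  contour-on-plane tolerance 1e-6 mm.
- Clipping at a plane interpolates crossing edges identically for both
  half-spaces, so the areas of the two parts sum exactly to the whole
  (tested to 1e-6 relative).
- The test suite and the acceptance script validate recovery on 20
  randomized phantoms at ~35k faces and ~200 stations each (≈10 s total on
  one core), 100 random contours against the brute-force chord oracle, and
  voxel metrics on grids up to 20³ against the all-pairs oracle; these
  sizes give the oracles exhaustive coverage while keeping runs fast.

## Known limitations

- Centerlines must be supplied; there is no automatic centerline extraction
  or anatomical-division detection.
- Lateral drift of a centerline is not detected (planes are unbounded);
  grossly wrong centerlines can yield plausible-looking diameters.
- The longest-contour rule can select a neighbouring structure if the
  iliac start planes do not separate the territories as the input contract
  requires.
- Angulation is reported as the raw chord angle in [0, 180]°; no clinical
  thresholding (e.g. at 60°) is applied.
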