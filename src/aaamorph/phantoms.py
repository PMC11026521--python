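"""Parametric vascular phantoms with analytic ground truth.

The phantom generator produces everything the measurement pipeline needs —
a triangulated aorta-like surface, the four named centerlines, and the two
iliac start planes — from a handful of geometric parameters, together with
a ledger of the landmark values those parameters imply in closed form.
Every measurement operation can therefore be validated against known truth
without any imaging data.

Phantom anatomy
---------------
* The aortic *trunk* is a single swept tube: an optionally angulated neck
  (a circular arc whose start-to-end chord makes ``neck_bend_deg`` with the
  aneurysm axis, with a tangent-continuous junction) followed by a straight
  aneurysm segment whose radius follows a cosine bell from the neck radius
  up to ``aneurysm_max_radius`` and back.
* Two *iliac* branches hang from the trunk outlet as circular arcs of
  ``iliac_arc_deg`` bending outward in the x-z plane, each with fixed arc
  length ``iliac_length``; an arc angle of 0 degrades to a straight branch.
  An optional focal bulge on a branch raises its mid-segment radius.
* The iliac start planes sit on the trunk axis at the outlet with normals
  pointing toward the respective iliac territory (+x right, -x left), so
  keeping the positive half-space isolates one branch.

Tube meshes use parallel-transported ring frames (no twist) and are open at
the neck inlet and iliac outlets.  The branch tubes are not stitched to the
trunk at the bifurcation; all cross-sections through the trunk itself are
closed contours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.spatial.distance import cdist

from .centerline import Centerline, CenterlineSet
from .errors import GeometryError, InputError
from .geometry_core import SectionPlane, TriangleSurface
from .landmarks import TortuosityResult
from .metrics import LabelVolume

#: arc-length offset (mm) of the iliac centerline start below the bifurcation,
#: keeping the first measurement plane clear of the trunk outlet rim
ILIAC_START_OFFSET = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one bifurcated fusiform aneurysm phantom (mm / degrees).

    Defaults are scaled to a typical elective-repair anatomy: neck diameter
    ~24 mm, maximum aneurysm diameter ~56 mm, iliac diameters ~17-19 mm,
    neck length ~33 mm.
    """

    neck_radius: float = 12.0
    neck_length: float = 33.0
    neck_bend_deg: float = 30.0
    aneurysm_max_radius: float = 28.0
    aneurysm_length: float = 90.0
    iliac_radii: tuple[float, float] = (9.5, 8.5)
    iliac_arc_deg: tuple[float, float] = (75.0, 90.0)
    iliac_length: float = 60.0
    iliac_bulge_radii: tuple[Optional[float], Optional[float]] = (None, None)
    circumferential_segments: int = 72
    axial_step: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        radii = [self.neck_radius, self.aneurysm_max_radius, *self.iliac_radii]
        radii += [r for r in self.iliac_bulge_radii if r is not None]
        if any(r <= 0 for r in radii):
            raise InputError("all phantom radii must be positive")
        if self.aneurysm_max_radius < self.neck_radius:
            raise InputError("aneurysm_max_radius must be >= neck_radius")
        if self.circumferential_segments < 16:
            raise InputError("need at least 16 circumferential segments")
        if self.neck_length <= 0 or self.aneurysm_length <= 0 or self.iliac_length <= 0:
            raise InputError("segment lengths must be positive")
        if self.axial_step <= 0:
            raise InputError("axial_step must be positive")
        if not 0 <= self.neck_bend_deg < 60:
            raise InputError("neck_bend_deg must be in [0, 60)")
        for side, (arc, bulge) in enumerate(zip(self.iliac_arc_deg, self.iliac_bulge_radii)):
            if not 0 <= arc <= 90:
                raise InputError("iliac arc angles must be in [0, 90] degrees")
            if bulge is not None and bulge < self.iliac_radii[side]:
                raise InputError("iliac bulge radius must be >= branch radius")


@dataclass
class GroundTruthLedger:
    """Landmark values implied analytically by a :class:`PhantomSpec`."""

    neck_diameter: float
    aneurysm_diameter: float
    right_iliac_diameter: float
    left_iliac_diameter: float
    neck_length: float
    right_tortuosity: TortuosityResult
    left_tortuosity: TortuosityResult
    neck_angulation: float

    def to_dict(self) -> dict:
        return {
            "neck_diameter_mm": self.neck_diameter,
            "aneurysm_diameter_mm": self.aneurysm_diameter,
            "right_iliac_diameter_mm": self.right_iliac_diameter,
            "left_iliac_diameter_mm": self.left_iliac_diameter,
            "neck_length_mm": self.neck_length,
            "right_tortuosity": {
                "curve_mm": self.right_tortuosity.curve_length,
                "line_mm": self.right_tortuosity.line_length,
                "ratio": self.right_tortuosity.ratio,
            },
            "left_tortuosity": {
                "curve_mm": self.left_tortuosity.curve_length,
                "line_mm": self.left_tortuosity.line_length,
                "ratio": self.left_tortuosity.ratio,
            },
            "neck_angulation_deg": self.neck_angulation,
        }


# ---------------------------------------------------------------------------
# swept-tube meshing
# ---------------------------------------------------------------------------


def _tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangents: central differences, one-sided at the ends."""
    t = np.empty_like(points)
    t[1:-1] = points[2:] - points[:-2]
    t[0] = points[1] - points[0]
    t[-1] = points[-1] - points[-2]
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def _transport_frames(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Parallel-transported orthonormal ring frames (no twist)."""
    n = np.empty_like(tangents)
    a = np.zeros(3)
    a[int(np.argmin(np.abs(tangents[0])))] = 1.0
    v = a - (a @ tangents[0]) * tangents[0]
    n[0] = v / np.linalg.norm(v)
    for i in range(1, len(tangents)):
        v = n[i - 1] - (n[i - 1] @ tangents[i]) * tangents[i]
        norm = np.linalg.norm(v)
        if norm < 1e-12:  # tangent flipped by ~90 degrees; caller validates
            raise GeometryError("cannot transport frame across sharp tangent change")
        n[i] = v / norm
    b = np.cross(tangents, n)
    return n, b


def make_tube_surface(
    centerline: Centerline,
    radius_profile: Callable[[float], float],
    segments: int,
) -> TriangleSurface:
    """Swept-tube triangulation around a centerline.

    ``radius_profile`` maps arc length from the centerline start (mm) to a
    positive tube radius (mm).  One ring of ``segments`` vertices is placed
    at every centerline point, oriented by parallel transport so the tube
    does not twist; both ends are left open.
    """
    if segments < 8:
        raise InputError(f"need at least 8 circumferential segments, got {segments}")
    pts = centerline.points
    seg_vec = np.diff(pts, axis=0)
    seg_dir = seg_vec / np.linalg.norm(seg_vec, axis=1, keepdims=True)
    if np.any(np.einsum("ij,ij->i", seg_dir[:-1], seg_dir[1:]) < 0):
        raise GeometryError("centerline tangent flips by more than 90 degrees")
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(seg_vec, axis=1))])
    radii = np.array([radius_profile(si) for si in s])
    if np.any(radii <= 0):
        raise GeometryError("radius profile must be positive everywhere")
    tangents = _tangents(pts)
    nrm, bnrm = _transport_frames(tangents)
    phi = 2 * np.pi * np.arange(segments) / segments
    ring = np.cos(phi)[:, None], np.sin(phi)[:, None]
    vertices = (
        pts[:, None, :]
        + radii[:, None, None] * (ring[0][None] * nrm[:, None, :] + ring[1][None] * bnrm[:, None, :])
    ).reshape(-1, 3)
    nr, ns = len(pts), segments
    j = np.arange(ns)
    j1 = (j + 1) % ns
    faces = []
    for i in range(nr - 1):
        a = i * ns + j
        b = i * ns + j1
        c = (i + 1) * ns + j1
        dd = (i + 1) * ns + j
        faces.append(np.column_stack([a, b, c]))
        faces.append(np.column_stack([a, c, dd]))
    return TriangleSurface(vertices, np.vstack(faces))


# ---------------------------------------------------------------------------
# bifurcated fusiform phantom
# ---------------------------------------------------------------------------


def _neck_arc_points(spec: PhantomSpec) -> np.ndarray:
    """Neck centerline from the proximal (renal) end down to the junction at
    the origin.  The arc turns by twice the bend angle so that its chord
    makes exactly ``neck_bend_deg`` with the (vertical) aneurysm axis while
    the junction stays tangent-continuous."""
    ln = spec.neck_length
    n = max(2, int(math.ceil(ln / spec.axial_step)) + 1)
    s = np.linspace(ln, 0.0, n)  # proximal -> junction
    beta = math.radians(spec.neck_bend_deg)
    if beta < 1e-12:
        return np.column_stack([np.zeros(n), np.zeros(n), s])
    k = 2 * beta / ln  # curvature: total turning 2*beta over the arc
    return np.column_stack([(1 - np.cos(k * s)) / k, np.zeros(n), np.sin(k * s) / k])


def _iliac_arc_points(
    spec: PhantomSpec, side: int, s_start: float, s_end: float, step: float
) -> np.ndarray:
    """Points along one iliac branch between arc lengths s_start..s_end.

    side: 0 = right (bends toward +x), 1 = left (toward -x).  The branch
    starts at the trunk outlet level z = -aneurysm_length, laterally offset
    so the whole tube stays strictly on its own side of the sagittal plane.
    """
    sign = 1.0 if side == 0 else -1.0
    r_tube = spec.iliac_bulge_radii[side] or spec.iliac_radii[side]
    x0 = sign * (r_tube + 2.0)
    z0 = -spec.aneurysm_length
    n = max(2, int(math.ceil((s_end - s_start) / step)) + 1)
    s = np.linspace(s_start, s_end, n)
    theta_tot = math.radians(spec.iliac_arc_deg[side])
    if theta_tot < 1e-9:  # straight branch
        return np.column_stack([np.full(n, x0), np.zeros(n), z0 - s])
    radius = spec.iliac_length / theta_tot
    th = s / radius
    x = x0 + sign * radius * (1 - np.cos(th))
    z = z0 - radius * np.sin(th)
    return np.column_stack([x, np.zeros(n), z])


def _trunk_radius_profile(spec: PhantomSpec) -> Callable[[float], float]:
    ln, la = spec.neck_length, spec.aneurysm_length
    rn, ra = spec.neck_radius, spec.aneurysm_max_radius

    def profile(s: float) -> float:
        if s <= ln:
            return rn
        t = min((s - ln) / la, 1.0)
        return rn + (ra - rn) * (1 - math.cos(2 * math.pi * t)) / 2.0

    return profile


def _iliac_radius_profile(spec: PhantomSpec, side: int) -> Callable[[float], float]:
    r = spec.iliac_radii[side]
    rb = spec.iliac_bulge_radii[side]
    li = spec.iliac_length
    if rb is None:
        return lambda s: r

    def profile(s: float) -> float:
        t = s / li
        if t < 0.25 or t > 0.75:
            return r
        return r + (rb - r) * (1 - math.cos(2 * math.pi * (t - 0.25) / 0.5)) / 2.0

    return profile


def _ledger_tortuosity(spec: PhantomSpec, side: int) -> TortuosityResult:
    """Closed-form tortuosity of a branch centerline.

    The measured centerline spans arc lengths [ILIAC_START_OFFSET,
    iliac_length] of the branch; for a circular arc of total angle theta the
    curve/chord ratio is (R dtheta) / (2 R sin(dtheta / 2))."""
    curve = spec.iliac_length - ILIAC_START_OFFSET
    theta_tot = math.radians(spec.iliac_arc_deg[side])
    if theta_tot < 1e-9:
        return TortuosityResult(curve, curve, 1.0)
    radius = spec.iliac_length / theta_tot
    dtheta = curve / radius
    line = 2 * radius * math.sin(dtheta / 2)
    return TortuosityResult(curve, line, curve / line)


def make_fusiform_phantom(
    spec: PhantomSpec,
) -> tuple[TriangleSurface, CenterlineSet, GroundTruthLedger]:
    """Build surface, centerlines, planes, and analytic ledger for a spec.

    The mesh is a pure function of the spec (the seed is reserved for
    optional jitter, which defaults to none), so identical specs give
    byte-identical meshes.
    """
    spec.validate()
    step = spec.axial_step

    # trunk: angulated neck arc + straight aneurysm, one continuous tube
    neck_pts = _neck_arc_points(spec)
    n_an = max(2, int(math.ceil(spec.aneurysm_length / step)) + 1)
    an_pts = np.column_stack(
        [np.zeros(n_an), np.zeros(n_an), np.linspace(0.0, -spec.aneurysm_length, n_an)]
    )
    trunk_pts = np.vstack([neck_pts[:-1], an_pts])  # drop duplicated junction
    trunk = make_tube_surface(
        Centerline(trunk_pts, name="trunk"),
        _trunk_radius_profile(spec),
        spec.circumferential_segments,
    )

    surfaces = [trunk]
    iliac_lines = []
    for side in (0, 1):
        tube_pts = _iliac_arc_points(spec, side, 0.0, spec.iliac_length, step)
        surfaces.append(
            make_tube_surface(
                Centerline(tube_pts, name=("right_iliac", "left_iliac")[side]),
                _iliac_radius_profile(spec, side),
                spec.circumferential_segments,
            )
        )
        line_pts = _iliac_arc_points(
            spec, side, ILIAC_START_OFFSET, spec.iliac_length, step
        )
        iliac_lines.append(
            Centerline(line_pts, name=("right_iliac", "left_iliac")[side])
        )

    offset = 0
    all_v, all_f = [], []
    for s in surfaces:
        all_v.append(s.vertices)
        all_f.append(s.faces + offset)
        offset += s.n_vertices
    surface = TriangleSurface(np.vstack(all_v), np.vstack(all_f))

    outlet = np.array([0.0, 0.0, -spec.aneurysm_length])
    centerlines = CenterlineSet(
        neck=Centerline(neck_pts, name="neck"),
        aneurysm=Centerline(an_pts, name="aneurysm"),
        right_iliac=iliac_lines[0],
        left_iliac=iliac_lines[1],
        right_plane=SectionPlane(outlet, np.array([1.0, 0.0, 0.0])),
        left_plane=SectionPlane(outlet, np.array([-1.0, 0.0, 0.0])),
    )

    ledger = GroundTruthLedger(
        neck_diameter=2 * spec.neck_radius,
        aneurysm_diameter=2 * spec.aneurysm_max_radius,
        right_iliac_diameter=2 * (spec.iliac_bulge_radii[0] or spec.iliac_radii[0]),
        left_iliac_diameter=2 * (spec.iliac_bulge_radii[1] or spec.iliac_radii[1]),
        neck_length=spec.neck_length,
        right_tortuosity=_ledger_tortuosity(spec, 0),
        left_tortuosity=_ledger_tortuosity(spec, 1),
        neck_angulation=spec.neck_bend_deg,
    )
    return surface, centerlines, ledger


def random_phantom_spec(rng: np.random.Generator) -> PhantomSpec:
    """A randomized but anatomically plausible phantom spec.

    Radii span 6-30 mm and iliac arc angles 0-90 degrees; the aneurysm is
    always at least 1.8x the neck radius so a fusiform sac exists.
    """
    neck_radius = rng.uniform(8.0, 14.0)
    return PhantomSpec(
        neck_radius=neck_radius,
        neck_length=rng.uniform(28.0, 45.0),
        neck_bend_deg=rng.uniform(0.0, 30.0),
        aneurysm_max_radius=min(30.0, neck_radius * rng.uniform(1.8, 2.3)),
        aneurysm_length=rng.uniform(80.0, 100.0),
        iliac_radii=(rng.uniform(6.0, 10.0), rng.uniform(6.0, 10.0)),
        iliac_arc_deg=(rng.uniform(0.0, 90.0), rng.uniform(0.0, 90.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# voxel mask fixtures for the overlap metrics
# ---------------------------------------------------------------------------


def _brute_force_boundary(mask: np.ndarray) -> np.ndarray:
    """Boundary voxel indices by explicit 6-neighbourhood check (oracle)."""
    out = []
    shape = mask.shape
    for idx in np.argwhere(mask):
        i, j, k = idx
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                out.append(idx)
                break
            if not mask[ni, nj, nk]:
                out.append(idx)
                break
    return np.array(out, dtype=float)


def brute_force_hd95(mask_a: np.ndarray, mask_b: np.ndarray, spacing) -> float:
    """All-pairs 95th-percentile Hausdorff oracle for small masks."""
    spacing = np.asarray(spacing, dtype=float)
    pa = _brute_force_boundary(mask_a) * spacing
    pb = _brute_force_boundary(mask_b) * spacing
    d = cdist(pa, pb)
    return float(max(np.percentile(d.min(axis=1), 95), np.percentile(d.min(axis=0), 95)))


def make_shifted_box_volumes(
    shape: tuple[int, int, int],
    box: tuple[int, int, int],
    shift: tuple[int, int, int],
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[LabelVolume, LabelVolume, float, float]:
    """Two binary box masks offset by ``shift`` voxels, with the exact Dice
    from the overlap count and the HD95 from the brute-force oracle."""
    shape = tuple(int(v) for v in shape)
    box = np.asarray(box, dtype=int)
    shift = np.asarray(shift, dtype=int)
    start_a = np.maximum(0, -shift)
    start_b = start_a + shift
    for name, start in (("box", start_a), ("shifted box", start_b)):
        if np.any(start < 0) or np.any(start + box > np.asarray(shape)):
            raise InputError(f"{name} does not fit inside the grid")
    va = np.zeros(shape, dtype=np.int16)
    vb = np.zeros(shape, dtype=np.int16)
    va[tuple(slice(s, s + b) for s, b in zip(start_a, box))] = 1
    vb[tuple(slice(s, s + b) for s, b in zip(start_b, box))] = 1
    n_box = int(np.prod(box))
    overlap = int(np.prod(np.maximum(0, box - np.abs(shift))))
    expected_dice = 2.0 * overlap / (2.0 * n_box)
    expected = (
        0.0
        if np.all(shift == 0)
        else brute_force_hd95(va.astype(bool), vb.astype(bool), spacing)
    )
    origin = np.zeros(3)
    return (
        LabelVolume(va, spacing, origin),
        LabelVolume(vb, spacing, origin),
        expected_dice,
        expected,
    )
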