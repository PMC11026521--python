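"""The seven-landmark automated measurement pipeline.

Given a triangulated aorta+thrombus surface and the four manually divided
centerlines (neck, aneurysm, right and left common iliac) plus the two
iliac start planes, this module measures the landmarks used for stent-graft
sizing before endovascular repair:

1. aortic neck diameter          — max chord of the section at the neck
                                   centerline's arc-length midpoint
2. aortic aneurysm diameter      — max diameter along the aneurysm centerline
3. right iliac artery diameter   — max diameter along the right iliac
                                   centerline after cutting at the start plane
4. left iliac artery diameter    — likewise on the left
5. aortic neck length            — arc length of the neck centerline
6. iliac tortuosity (right/left) — centerline arc length over start-to-end
                                   chord length (>= 1; 1 for a straight vessel)
7. aortic neck angulation        — angle between the start-to-end chords of
                                   the neck and aneurysm centerlines

The diameter search ("maximum contour" routine) sections the surface with a
plane at every resampled centerline station, selects the longest contour of
each section, and takes its maximum chord; the station with the largest
chord wins.  Stations whose section is empty are skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .centerline import (
    Centerline,
    CenterlineSet,
    Station,
    arc_length,
    chord_length,
    midpoint_station,
    resample_centerline,
    station_frames,
)
from .errors import (
    AAAMorphError,
    DegenerateCenterlineError,
    MeasurementFailureError,
    ValidationError,
)
from .geometry_core import (
    SectionPlane,
    TriangleSurface,
    contour_length,
    cut_surface_by_plane,
    longest_contour,
    max_contour_diameter,
    plane_section,
)


@dataclass
class MeasureConfig:
    """Tunable measurement parameters.

    resample_step
        Spacing (mm) of the measurement stations generated along each
        centerline.  1.0 mm is sub-voxel relative to typical CT slice
        thickness for this anatomy (2.5-5.0 mm).
    tol_chord
        Minimum start-to-end chord (mm) below which tortuosity and
        angulation are undefined.
    """

    resample_step: float = 1.0
    tol_chord: float = 1e-6

    def __post_init__(self) -> None:
        if self.resample_step <= 0:
            raise ValidationError("resample_step must be positive")


@dataclass
class DiameterResult:
    """A measured maximum diameter with the station where it occurred."""

    diameter: float
    station: Station
    contour_perimeter: float


@dataclass
class TortuosityResult:
    """Centerline arc length, chord length, and their ratio (>= 1)."""

    curve_length: float
    line_length: float
    ratio: float


@dataclass
class LandmarkReport:
    """All seven landmarks for one case, plus per-landmark errors."""

    neck_diameter: Optional[DiameterResult] = None
    aneurysm_diameter: Optional[DiameterResult] = None
    right_iliac_diameter: Optional[DiameterResult] = None
    left_iliac_diameter: Optional[DiameterResult] = None
    neck_length: Optional[float] = None
    right_tortuosity: Optional[TortuosityResult] = None
    left_tortuosity: Optional[TortuosityResult] = None
    neck_angulation: Optional[float] = None
    errors: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return not self.errors

    def to_json_dict(self) -> dict:
        """Report in the flat JSON layout used by the CLI."""

        def _dia(r: Optional[DiameterResult]):
            return None if r is None else r.diameter

        def _tor(r: Optional[TortuosityResult]):
            if r is None:
                return None
            return {"curve_mm": r.curve_length, "line_mm": r.line_length, "ratio": r.ratio}

        stations = {}
        for key in ("neck_diameter", "aneurysm_diameter", "right_iliac_diameter", "left_iliac_diameter"):
            r = getattr(self, key)
            if r is not None:
                stations[key] = {
                    "point_mm": r.station.point.tolist(),
                    "direction": r.station.direction.tolist(),
                    "contour_perimeter_mm": r.contour_perimeter,
                }
        return {
            "neck_diameter_mm": _dia(self.neck_diameter),
            "aneurysm_diameter_mm": _dia(self.aneurysm_diameter),
            "right_iliac_diameter_mm": _dia(self.right_iliac_diameter),
            "left_iliac_diameter_mm": _dia(self.left_iliac_diameter),
            "neck_length_mm": self.neck_length,
            "right_tortuosity": _tor(self.right_tortuosity),
            "left_tortuosity": _tor(self.left_tortuosity),
            "neck_angulation_deg": self.neck_angulation,
            "stations": stations,
            "errors": dict(self.errors),
            "provenance": dict(self.provenance),
        }

    def to_csv_row(self) -> dict:
        """One flat row per case for cohort tables."""
        d = self.to_json_dict()
        row = {k: d[k] for k in (
            "neck_diameter_mm", "aneurysm_diameter_mm", "right_iliac_diameter_mm",
            "left_iliac_diameter_mm", "neck_length_mm", "neck_angulation_deg",
        )}
        for side in ("right", "left"):
            t = d[f"{side}_tortuosity"]
            row[f"{side}_curve_mm"] = None if t is None else t["curve_mm"]
            row[f"{side}_line_mm"] = None if t is None else t["line_mm"]
            row[f"{side}_ratio"] = None if t is None else t["ratio"]
        row["n_errors"] = len(self.errors)
        return row


# ---------------------------------------------------------------------------
# individual landmark measurements
# ---------------------------------------------------------------------------


def _measure_station(surface: TriangleSurface, station: Station) -> Optional[tuple[float, float]]:
    """Section at one station; (max chord, perimeter) of the longest contour,
    or None when the plane misses the mesh."""
    contours = plane_section(surface, SectionPlane(station.point, station.direction))
    if not contours:
        return None
    best = longest_contour(contours)
    return max_contour_diameter(best), contour_length(best)


def max_diameter_along_centerline(
    surface: TriangleSurface, c: Centerline, step: float = 1.0
) -> DiameterResult:
    """Maximum-contour diameter search along a centerline.

    Sections the surface at every station of the resampled centerline and
    returns the station with the largest longest-contour max chord.
    """
    if step <= 0:
        raise ValidationError("station step must be positive")
    stations = station_frames(resample_centerline(c, step))
    best: Optional[DiameterResult] = None
    for st in stations:
        res = _measure_station(surface, st)
        if res is None:
            continue
        dia, perim = res
        if best is None or dia > best.diameter:
            best = DiameterResult(dia, st, perim)
    if best is None:
        raise MeasurementFailureError(
            f"centerline {c.name!r} does not traverse the surface (all sections empty)"
        )
    return best


def neck_diameter(
    surface: TriangleSurface, neck: Centerline, resample_step: float = 1.0
) -> DiameterResult:
    """Diameter at the arc-length midpoint of the aortic neck centerline.

    A single plane is placed at the midpoint station and the longest
    contour's maximum chord is returned.
    """
    st = midpoint_station(neck, resample_step)
    res = _measure_station(surface, st)
    if res is None:
        raise MeasurementFailureError("neck midpoint plane does not intersect the surface")
    dia, perim = res
    return DiameterResult(dia, st, perim)


def aneurysm_diameter(
    surface: TriangleSurface, aneurysm: Centerline, step: float = 1.0
) -> DiameterResult:
    """Maximum aneurysm diameter: the diameter search run over the aneurysm
    centerline."""
    return max_diameter_along_centerline(surface, aneurysm, step)


def iliac_diameter(
    surface: TriangleSurface,
    start_plane: SectionPlane,
    iliac: Centerline,
    step: float = 1.0,
) -> DiameterResult:
    """Maximum iliac diameter after separating the iliac territory.

    The surface is cut at the iliac start plane (whose normal points toward
    the iliac territory, i.e. the positive side is kept) and the diameter
    search runs along the iliac centerline on the cut sub-mesh, so contours
    of the aneurysm sac cannot shadow the iliac sections.
    """
    part = cut_surface_by_plane(surface, start_plane, keep="positive")
    return max_diameter_along_centerline(part, iliac, step)


def neck_length(neck: Centerline) -> float:
    """Aortic neck length: arc length of the neck centerline (mm).

    Measured along the vessel, which equals the straight distance for a
    straight neck and generalizes correctly for angulated necks.
    """
    return arc_length(neck)


def iliac_tortuosity(iliac: Centerline, tol_chord: float = 1e-6) -> TortuosityResult:
    """Tortuosity of a common iliac artery.

    curve length = centerline arc length, line length = start-to-end chord,
    ratio = curve / line.  The ratio is >= 1, with equality only for a
    straight (collinear) centerline.
    """
    line = chord_length(iliac)
    if line <= tol_chord:
        raise DegenerateCenterlineError(
            f"iliac centerline {iliac.name!r} start-to-end chord below {tol_chord} mm"
        )
    curve = arc_length(iliac)
    return TortuosityResult(curve, line, curve / line)


def neck_angulation(neck: Centerline, aneurysm: Centerline, tol_chord: float = 1e-6) -> float:
    """Angle (degrees, in [0, 180]) between the start-to-end chord of the
    neck centerline and the start-to-end chord of the aneurysm centerline."""
    u = neck.points[-1] - neck.points[0]
    w = aneurysm.points[-1] - aneurysm.points[0]
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu <= tol_chord or nw <= tol_chord:
        raise DegenerateCenterlineError("degenerate chord: angulation undefined")
    cosang = float(np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------


def measure_all(
    surface: TriangleSurface,
    inputs: CenterlineSet,
    config: MeasureConfig | None = None,
) -> LandmarkReport:
    """Measure all seven landmarks, recording per-landmark errors.

    A failure of one landmark (e.g. a missing or displaced centerline) is
    recorded in ``report.errors`` under the landmark's name instead of
    aborting the remaining measurements.
    """
    cfg = config or MeasureConfig()
    report = LandmarkReport()
    report.provenance = {"resample_step_mm": cfg.resample_step}

    def attempt(key: str, fn) -> None:
        try:
            setattr(report, key, fn())
        except AAAMorphError as exc:
            report.errors[key] = f"{type(exc).__name__}: {exc}"

    attempt("neck_diameter",
            lambda: neck_diameter(surface, inputs.require("neck"), cfg.resample_step))
    attempt("aneurysm_diameter",
            lambda: aneurysm_diameter(surface, inputs.require("aneurysm"), cfg.resample_step))
    attempt("right_iliac_diameter",
            lambda: iliac_diameter(surface, inputs.require("right_plane"),
                                   inputs.require("right_iliac"), cfg.resample_step))
    attempt("left_iliac_diameter",
            lambda: iliac_diameter(surface, inputs.require("left_plane"),
                                   inputs.require("left_iliac"), cfg.resample_step))
    attempt("neck_length", lambda: neck_length(inputs.require("neck")))
    attempt("right_tortuosity",
            lambda: iliac_tortuosity(inputs.require("right_iliac"), cfg.tol_chord))
    attempt("left_tortuosity",
            lambda: iliac_tortuosity(inputs.require("left_iliac"), cfg.tol_chord))
    attempt("neck_angulation",
            lambda: neck_angulation(inputs.require("neck"), inputs.require("aneurysm"),
                                    cfg.tol_chord))
    return report
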