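"""Centerline polylines, resampling, and station frames.

A centerline is the luminal midline of a vessel segment, given as an
ordered 3D polyline in mm.  Measurement *stations* — a point plus the unit
direction to its consecutive point — are generated along it and define the
cross-sectional cutting planes of the measurement algorithm.

Four named centerlines describe one aneurysm case: the aortic neck, the
aneurysm, and the right and left common iliac arteries, together with the
two start planes that separate the iliac territories from the aortic trunk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import SchemaError, ValidationError
from .geometry_core import SectionPlane

CENTERLINE_NAMES = ("neck", "aneurysm", "right_iliac", "left_iliac")


@dataclass
class Centerline:
    """Ordered 3D polyline in mm with a free-text name."""

    points: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 2:
            raise ValidationError(f"centerline {self.name!r} needs at least 2 points")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps < 1e-9):
            raise ValidationError(
                f"centerline {self.name!r} has consecutive points closer than 1e-9 mm"
            )

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Station:
    """A centerline point plus the local unit direction to the next point."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            if n < 1e-12:
                raise ValidationError("station direction has zero length")
            d = d / n
        self.direction = d


@dataclass
class CenterlineSet:
    """The manual inputs for one case: four centerlines and two iliac planes.

    Fields may be ``None`` when a case is incomplete; the measurement driver
    then reports a per-landmark error instead of aborting the whole case.
    """

    neck: Optional[Centerline]
    aneurysm: Optional[Centerline]
    right_iliac: Optional[Centerline]
    left_iliac: Optional[Centerline]
    right_plane: Optional[SectionPlane]
    left_plane: Optional[SectionPlane]

    def require(self, name: str):
        value = getattr(self, name)
        if value is None:
            raise ValidationError(f"centerline set is missing {name!r}")
        return value


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------
# Schema:
# {"units": "mm",
#  "centerlines": {"neck": [[x,y,z], ...], "aneurysm": [...],
#                  "right_iliac": [...], "left_iliac": [...]},
#  "planes": {"right_iliac": {"origin": [x,y,z], "normal": [x,y,z]},
#             "left_iliac":  {...}}}
# Plane normals need not be unit length in the file (normalized on load) and
# point toward the corresponding iliac territory.


def read_centerlines(path: str) -> CenterlineSet:
    """Load a :class:`CenterlineSet` from the JSON schema above."""
    with open(path) as fh:
        data = json.load(fh)
    if data.get("units") != "mm":
        raise ValidationError(f"centerline units must be 'mm', got {data.get('units')!r}")
    cls = data.get("centerlines")
    planes = data.get("planes")
    if not isinstance(cls, dict) or not isinstance(planes, dict):
        raise SchemaError("centerline JSON needs 'centerlines' and 'planes' objects")
    lines = {}
    for name in CENTERLINE_NAMES:
        if name not in cls:
            raise SchemaError(f"centerline JSON is missing centerline {name!r}")
        lines[name] = Centerline(np.asarray(cls[name], dtype=float), name=name)
    plane_objs = {}
    for name in ("right_iliac", "left_iliac"):
        if name not in planes:
            raise SchemaError(f"centerline JSON is missing plane {name!r}")
        p = planes[name]
        try:
            plane_objs[name] = SectionPlane(p["origin"], p["normal"])
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"plane {name!r} needs 'origin' and 'normal'") from exc
    return CenterlineSet(
        neck=lines["neck"],
        aneurysm=lines["aneurysm"],
        right_iliac=lines["right_iliac"],
        left_iliac=lines["left_iliac"],
        right_plane=plane_objs["right_iliac"],
        left_plane=plane_objs["left_iliac"],
    )


def write_centerlines(cs: CenterlineSet, path: str) -> None:
    """Write a complete :class:`CenterlineSet` back to the JSON schema."""
    for name in CENTERLINE_NAMES:
        cs.require(name)
    cs.require("right_plane")
    cs.require("left_plane")
    data = {
        "units": "mm",
        "centerlines": {name: getattr(cs, name).points.tolist() for name in CENTERLINE_NAMES},
        "planes": {
            "right_iliac": {
                "origin": cs.right_plane.origin.tolist(),
                "normal": cs.right_plane.normal.tolist(),
            },
            "left_iliac": {
                "origin": cs.left_plane.origin.tolist(),
                "normal": cs.left_plane.normal.tolist(),
            },
        },
    }
    with open(path, "w") as fh:
        json.dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# polyline measures
# ---------------------------------------------------------------------------


def arc_length(c: Centerline) -> float:
    """Length along the polyline (mm)."""
    return float(np.linalg.norm(np.diff(c.points, axis=0), axis=1).sum())


def chord_length(c: Centerline) -> float:
    """Straight-line distance from the first to the last point (mm)."""
    return float(np.linalg.norm(c.points[-1] - c.points[0]))


def _cumulative(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_at(points: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    return np.array([np.interp(s, cum, points[:, k]) for k in range(3)])


def resample_centerline(c: Centerline, step: float) -> Centerline:
    """Resample at arc-length multiples of ``step``, keeping the endpoint.

    First and last points coincide with the originals; arc length is
    preserved up to the usual O(step^2) chord shortening.
    """
    if step <= 0:
        raise ValidationError(f"resample step must be positive, got {step}")
    cum = _cumulative(c.points)
    total = cum[-1]
    s = np.arange(0.0, total, step)
    if total - s[-1] > 1e-9:
        s = np.append(s, total)
    else:
        s[-1] = total
    pts = np.column_stack([np.interp(s, cum, c.points[:, k]) for k in range(3)])
    # drop interpolated points that collapse onto a neighbour
    keep = np.concatenate([[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) >= 1e-9])
    pts = pts[keep]
    if len(pts) < 2:  # pathological: total length ~ 0 is excluded by invariants
        pts = c.points[[0, -1]]
    return Centerline(pts, name=c.name)


def station_frames(c: Centerline) -> list[Station]:
    """One station per point; the direction at point *i* is the unit vector
    to point *i+1*, and the last point reuses its predecessor's direction
    (forward-difference closure at the terminus)."""
    pts = c.points
    diffs = np.diff(pts, axis=0)
    dirs = diffs / np.linalg.norm(diffs, axis=1, keepdims=True)
    dirs = np.vstack([dirs, dirs[-1]])
    return [Station(p, d) for p, d in zip(pts, dirs)]


def midpoint_station(c: Centerline, resample_step: float = 1.0) -> Station:
    """The station at half the total arc length.

    The centerline is resampled at ``resample_step``, the half-arc-length
    point is interpolated exactly, and the direction runs from it to the
    next resampled point.
    """
    r = resample_centerline(c, resample_step)
    cum = _cumulative(r.points)
    half = cum[-1] / 2.0
    point = _point_at(r.points, cum, half)
    nxt_idx = int(np.searchsorted(cum, half + 1e-9))
    if nxt_idx >= len(r.points):
        nxt_idx = len(r.points) - 1
    direction = r.points[nxt_idx] - point
    if np.linalg.norm(direction) < 1e-12:
        direction = r.points[nxt_idx] - r.points[nxt_idx - 1]
    return Station(point, direction / np.linalg.norm(direction))
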