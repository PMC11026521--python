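"""Segmentation and method-comparison metrics.

Overlap and surface-distance metrics (Dice coefficient and 95th-percentile
Hausdorff distance) operate on integer label volumes in physical mm
coordinates; agreement statistics (Bland-Altman limits of agreement,
two-way random-effects ICC, pairwise Pearson correlations) operate on
paired or multi-observer measurement tables.

Pinned conventions
------------------
* HD95 is symmetric: the maximum of the two directed 95th-percentile
  boundary distances, with linear interpolation between order statistics
  for the percentile.
* Boundary voxels are labelled voxels with at least one face-adjacent
  (6-connectivity) non-labelled neighbour; voxels at the grid edge count
  as boundary.
* ICC is the two-way random-effects, absolute-agreement, single-rater form
  ICC(2,1).
* Dice of two empty masks is 1.0 (total agreement on absence) with an
  explicit warning; exactly one empty mask gives 0.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import GeometryError, InputError, UndefinedDistanceError


class EmptyLabelWarning(UserWarning):
    """Both masks empty for the requested label: metric defined by convention."""


@dataclass
class LabelVolume:
    """Integer label grid with voxel spacing and world origin (mm).

    Labels are non-negative integers; 0 is background.  By convention the
    aneurysm segmentation uses 1..4 for aorta, thrombus, calcification, and
    vessels.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise InputError("label volume must be a 3D grid")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise InputError("label volume must hold integers")
        if self.voxels.min(initial=0) < 0:
            raise InputError("labels must be non-negative")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise InputError("voxel spacing components must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def read_label_volume(path: str) -> LabelVolume:
    """Read a NIfTI label image; spacing and origin come from the affine."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise InputError(f"{path}: voxel values are not integer labels")
        data = rounded.astype(np.int32)
    affine = img.affine
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    origin = affine[:3, 3]
    return LabelVolume(data, spacing, origin)


def write_label_volume(vol: LabelVolume, path: str) -> None:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vol.spacing)
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.int16), affine), str(path))


def _check_same_grid(a: LabelVolume, b: LabelVolume) -> None:
    if a.shape != b.shape:
        raise GeometryError(f"grid shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, atol=1e-6):
        raise GeometryError("voxel spacing mismatch")
    if not np.allclose(a.origin, b.origin, atol=1e-6):
        raise GeometryError("grid origin mismatch")


# ---------------------------------------------------------------------------
# overlap / surface distance
# ---------------------------------------------------------------------------


def dice(a: LabelVolume, b: LabelVolume, label: int) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) for one label, in [0,1]."""
    _check_same_grid(a, b)
    ma = a.voxels == label
    mb = b.voxels == label
    na, nb = int(ma.sum()), int(mb.sum())
    if na == 0 and nb == 0:
        warnings.warn(
            f"label {label} empty in both volumes; Dice = 1.0 by convention",
            EmptyLabelWarning,
            stacklevel=2,
        )
        return 1.0
    if na == 0 or nb == 0:
        return 0.0
    inter = int(np.logical_and(ma, mb).sum())
    return 2.0 * inter / (na + nb)


def _boundary_points_mm(mask: np.ndarray, spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    """World coordinates (mm) of boundary voxels: labelled voxels with a
    face-adjacent non-labelled neighbour (grid edges count as outside)."""
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    boundary = mask & ~interior
    idx = np.argwhere(boundary)
    return idx * spacing + origin


def hd95(a: LabelVolume, b: LabelVolume, label: int) -> float:
    """Symmetric 95th-percentile Hausdorff distance (mm) for one label.

    Each directed term is the 95th percentile (linear interpolation) of the
    distances from every boundary voxel of one mask to the nearest boundary
    voxel of the other, in physical mm; the result is the maximum of the
    two directed terms.
    """
    _check_same_grid(a, b)
    ma = a.voxels == label
    mb = b.voxels == label
    if not ma.any() or not mb.any():
        raise UndefinedDistanceError(f"label {label} empty: surface distance undefined")
    pa = _boundary_points_mm(ma, a.spacing, a.origin)
    pb = _boundary_points_mm(mb, b.spacing, b.origin)
    d_ab, _ = cKDTree(pb).query(pa, k=1)
    d_ba, _ = cKDTree(pa).query(pb, k=1)
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------


@dataclass
class AgreementResult:
    """Bland-Altman summary: bias, SD of differences, and 95% limits of
    agreement (bias ± 1.96 SD)."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n_used: int
    outliers_removed: int = 0
    pre_removal: Optional["AgreementResult"] = None


def _ba_stats(d: np.ndarray) -> tuple[float, float, float, float]:
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def bland_altman(x, y, remove_outliers: bool = False) -> AgreementResult:
    """Bland-Altman agreement between two paired measurement series.

    Differences are d = x - y; bias is their mean, sd the sample standard
    deviation (n-1), and the limits of agreement bias ± 1.96 sd.  With
    ``remove_outliers`` points whose difference falls outside the initial
    limits are dropped once and the statistics recomputed; the first-pass
    result is kept in ``pre_removal``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise InputError(f"paired series length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 2:
        raise InputError("need at least 2 paired measurements")
    d = x - y
    bias, sd, lo, hi = _ba_stats(d)
    first = AgreementResult(bias, sd, lo, hi, n_used=len(d))
    if not remove_outliers:
        return first
    keep = (d >= lo) & (d <= hi)
    removed = int((~keep).sum())
    if removed == 0 or keep.sum() < 2:
        first.pre_removal = None
        return first
    bias2, sd2, lo2, hi2 = _ba_stats(d[keep])
    return AgreementResult(
        bias2, sd2, lo2, hi2,
        n_used=int(keep.sum()), outliers_removed=removed, pre_removal=first,
    )


def icc(ratings) -> float:
    """ICC(2,1): two-way random-effects, absolute-agreement, single rater.

    ``ratings`` is an (n subjects x k observers) table with no missing
    cells.  Computed from the two-way ANOVA mean squares as
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)`` and clamped to
    [-1, 1] for reporting.  A table with zero total variance is defined as
    1.0 (all raters and subjects identical) with a warning.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise InputError("ratings must be a 2D subjects-by-observers table")
    n, k = x.shape
    if n < 2 or k < 2:
        raise InputError(f"need >= 2 subjects and >= 2 observers, got {n}x{k}")
    if np.isnan(x).any():
        raise InputError("ratings table has missing cells")
    grand = x.mean()
    sst = float(((x - grand) ** 2).sum())
    if sst <= 1e-12 * max(1.0, abs(grand)) ** 2:
        warnings.warn("zero total variance: ICC = 1.0 by convention", UserWarning, stacklevel=2)
        return 1.0
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = float(k * ((row_means - grand) ** 2).sum())
    ssc = float(n * ((col_means - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-300:
        return 1.0
    return float(np.clip((msr - mse) / denom, -1.0, 1.0))


def pairwise_correlations(ratings) -> np.ndarray:
    """Pearson correlation matrix (k x k) of observer columns."""
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InputError("ratings must be an (n>=2) x (k>=2) table")
    if np.isnan(x).any():
        raise InputError("ratings table has missing cells")
    return np.corrcoef(x, rowvar=False)
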