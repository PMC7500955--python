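"""Top-view roundness and microtubule-wall integrity (fracture) detection.

Healthy centrioles are near-perfect cylinders: their nine wall peaks lie on
a circle.  Depletion of wall/inner-scaffold proteins produces ovoid or
opened centrioles and, in a fraction of cells, an outright fracture of the
microtubule wall.  This module quantifies both phenotypes from top views:

* *roundness* — minor/major axis ratio of the ellipse fitted to the
  detected wall peaks (1 for a perfect circle), with the peak-polygon
  circularity reported alongside;
* *wall integrity* — the largest angular arc with no wall signal; a
  centriole is flagged broken when the arc exceeds a threshold (default
  30 deg, i.e. at least one fully missing triplet).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import EllipseModel

from ._polar import angular_wall_trace, polar_transform, quadratic_peak_refine
from .calibration import ExpansionCalibration
from .errors import (
    DegenerateFitError,
    InsufficientPeaksError,
    NoSignalError,
)
from .radial_mapping import _tubulin_channel, _wall_peak_angles

__all__ = [
    "WallPeaks",
    "RoundnessResult",
    "WallIntegrityResult",
    "detect_wall_peaks",
    "compute_roundness",
    "assess_wall_integrity",
]


@dataclass(frozen=True)
class WallPeaks:
    """Detected tubulin wall peaks, sorted by angle about the center."""

    xs: np.ndarray  # px
    ys: np.ndarray  # px
    radii_px: np.ndarray
    thetas_deg: np.ndarray
    center: tuple[float, float]

    @property
    def n_detected(self) -> int:
        return len(self.xs)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.xs, self.ys])

    @classmethod
    def from_points(
        cls, points: np.ndarray, center: tuple[float, float] | None = None
    ) -> "WallPeaks":
        """Build from (x, y) coordinates (e.g. analytic test geometry)."""
        pts = np.asarray(points, dtype=float)
        if center is None:
            center = (float(pts[:, 1].mean()), float(pts[:, 0].mean()))
        dx = pts[:, 0] - center[1]
        dy = pts[:, 1] - center[0]
        thetas = np.rad2deg(np.arctan2(dy, dx)) % 360.0
        order = np.argsort(thetas)
        return cls(
            xs=pts[order, 0],
            ys=pts[order, 1],
            radii_px=np.hypot(dx, dy)[order],
            thetas_deg=thetas[order],
            center=center,
        )


@dataclass(frozen=True)
class RoundnessResult:
    roundness: float
    major_axis_px: float
    minor_axis_px: float
    major_axis_nm: float | None
    minor_axis_nm: float | None
    polygon_area: float
    polygon_perimeter: float
    circularity: float


@dataclass(frozen=True)
class WallIntegrityResult:
    broken: bool
    largest_gap_deg: float
    gap_location_deg: float


def detect_wall_peaks(
    image: np.ndarray,
    center: tuple[float, float],
    min_separation_deg: float = 20.0,
    prominence_frac: float = 0.2,
) -> WallPeaks:
    """Detect the per-triplet wall peaks of a top view.

    The angular wall trace (max-over-radius per 1 deg sector, smoothed) is
    searched for local maxima with prominence >= ``prominence_frac`` of
    the trace range and angular separation >= ``min_separation_deg``; each
    peak's radial position is then refined by quadratic interpolation of
    the radial profile along the peak direction.
    """
    angles, _, _ = _wall_peak_angles(
        image, center, min_separation_deg=min_separation_deg,
        prominence_frac=prominence_frac,
    )
    if len(angles) < 3:
        raise InsufficientPeaksError(f"only {len(angles)} wall peaks detected")
    tub = _tubulin_channel(image)
    radii_px, _, polar = polar_transform(tub, center, r_step=0.5, n_theta=720)
    radii = []
    for ang in angles:
        row = polar[int(round(ang * 2.0)) % 720]
        idx = int(np.argmax(row))
        radii.append(radii_px[0] + quadratic_peak_refine(row, idx) * 0.5)
    radii = np.asarray(radii)
    th = np.deg2rad(angles)
    return WallPeaks(
        xs=center[1] + radii * np.cos(th),
        ys=center[0] + radii * np.sin(th),
        radii_px=radii,
        thetas_deg=np.asarray(angles, dtype=float),
        center=center,
    )


def tilt_proxy(peaks: WallPeaks) -> float:
    """Ratio of wall-peak radial SD to mean radius.

    Oblique (tilted) views project the ring into an apparent ellipse and
    inflate this ratio; views with proxy >= 0.15 should not be scored for
    roundness ("perfectly imaged top views" admission rule).
    """
    return float(peaks.radii_px.std() / peaks.radii_px.mean())


def compute_roundness(
    peaks: WallPeaks,
    calib: ExpansionCalibration | None = None,
) -> RoundnessResult:
    """Least-squares ellipse fit to the wall peaks; roundness = minor/major.

    The polygon obtained by connecting consecutive peaks is summarized
    alongside by its circularity 4*pi*area/perimeter**2.
    """
    if peaks.n_detected < 5:
        raise InsufficientPeaksError(
            f"ellipse fit needs >= 5 peaks, got {peaks.n_detected}"
        )
    pts = peaks.points
    spread = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if spread[-1] < 1e-6 * spread[0]:
        raise DegenerateFitError("peaks are collinear")
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(pts)
        if not model:
            raise DegenerateFitError("ellipse fit failed")
        a, b = model.axis_lengths
    else:  # scikit-image < 0.26
        model = EllipseModel()
        if not model.estimate(pts):
            raise DegenerateFitError("ellipse fit failed")
        _, _, a, b, _ = model.params
    major, minor = max(a, b), min(a, b)

    # polygon metrics on the angle-sorted peak ring
    x, y = pts[:, 0], pts[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * abs(np.sum(x * y2 - x2 * y))
    perimeter = float(np.sum(np.hypot(x2 - x, y2 - y)))
    circularity = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else 0.0

    to_nm = calib.to_biological_nm if calib is not None else None
    return RoundnessResult(
        roundness=float(minor / major),
        major_axis_px=float(major),
        minor_axis_px=float(minor),
        major_axis_nm=to_nm(2.0 * major) if to_nm else None,
        minor_axis_nm=to_nm(2.0 * minor) if to_nm else None,
        polygon_area=float(area),
        polygon_perimeter=perimeter,
        circularity=float(circularity),
    )


def _circular_runs(missing: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of contiguous True runs on a circular boolean array."""
    n = len(missing)
    if missing.all():
        return [(0, n)]
    if not missing.any():
        return []
    # rotate so the array starts on a False
    start0 = int(np.argmin(missing))
    rolled = np.roll(missing, -start0)
    runs = []
    i = 0
    while i < n:
        if rolled[i]:
            j = i
            while j < n and rolled[j]:
                j += 1
            runs.append(((i + start0) % n, j - i))
            i = j
        else:
            i += 1
    return runs


def assess_wall_integrity(
    image: np.ndarray,
    center: tuple[float, float],
    gap_threshold_deg: float = 30.0,
    missing_frac: float = 0.15,
) -> WallIntegrityResult:
    """Largest angular arc with no wall signal, and the broken flag.

    Sectors whose max-over-radius wall intensity falls below
    ``missing_frac`` of the trace maximum (above background) are missing;
    the largest contiguous missing arc is refined by linear interpolation
    of the threshold crossings at its boundaries and compared with
    ``gap_threshold_deg``.
    """
    thetas, trace = angular_wall_trace(_tubulin_channel(image), center)
    n = len(trace)
    lo, hi = float(trace.min()), float(trace.max())
    if hi <= 0 or hi == lo:
        raise NoSignalError("no wall signal in the tubulin channel")
    thr = lo + missing_frac * (hi - lo)
    missing = trace < thr
    runs = _circular_runs(missing)
    if not runs:
        return WallIntegrityResult(broken=False, largest_gap_deg=0.0, gap_location_deg=0.0)

    step = 360.0 / n
    best_len, best_loc = 0.0, 0.0
    for start, length in runs:
        if length >= n:
            best_len, best_loc = 360.0, 0.0
            break
        # refine the entry crossing (before `start`) and exit crossing
        i_prev = (start - 1) % n
        f_in = (trace[i_prev] - thr) / max(trace[i_prev] - trace[start], 1e-12)
        end = (start + length) % n
        i_last = (start + length - 1) % n
        f_out = (thr - trace[i_last]) / max(trace[end] - trace[i_last], 1e-12)
        # entry crossing sits f_in before `start`, exit crossing f_out past i_last
        gap = (length - np.clip(f_in, 0, 1) + np.clip(f_out, 0, 1)) * step
        if gap > best_len:
            best_len = float(gap)
            best_loc = float((thetas[start] + gap / 2.0 - step / 2.0) % 360.0)
    return WallIntegrityResult(
        broken=bool(best_len > gap_threshold_deg),
        largest_gap_deg=best_len,
        gap_location_deg=best_loc,
    )
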