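"""Confocal-scale quantification: foci detection, per-cell dot counting,
centrosomal/centriolar intensities and control normalization.

These are the widefield/confocal procedures that accompany the nanoscale
measurements: counting the number of centriolar dots per cell (e.g.
protein/Centrin dot categories such as "2/2" or "2/4"), integrating the
centrosomal signal over a small fixed-area region, averaging a short line
profile over a centriole pair, and expressing intensities relative to the
mean of the control group (A.U.).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max

from .errors import GeometryError, InvalidInputError, NormalizationError

__all__ = [
    "Focus",
    "FociCountRecord",
    "NormalizedIntensity",
    "detect_foci",
    "count_dots_per_cell",
    "centrosomal_intensity",
    "centriolar_profile_intensity",
    "normalize_to_control",
]


@dataclass(frozen=True)
class Focus:
    y: float
    x: float
    peak_intensity: float
    channel: str


@dataclass(frozen=True)
class FociCountRecord:
    cell_id: int
    counts: dict  # channel -> int
    category: str  # joint label, e.g. "2/2"


@dataclass(frozen=True)
class NormalizedIntensity:
    raw: float
    relative_au: float


def detect_foci(
    image: np.ndarray,
    channel: str = "ch0",
    threshold_sd: float = 5.0,
    min_separation_px: int = 3,
    spot_sigma_px: float = 1.5,
) -> list[Focus]:
    """Detect diffraction-limited foci in a single-channel image.

    The image is band-pass filtered with a Laplacian of Gaussian at the
    spot scale; local maxima above ``background + threshold_sd * SD``
    (robust background statistics: median and MAD of the filtered image)
    and separated by at least ``min_separation_px`` are returned.  An
    empty list is a valid result.
    """
    if image.ndim != 2:
        raise InvalidInputError("detect_foci expects a single-channel 2-D image")
    img = image.astype(float)
    filt = -ndimage.gaussian_laplace(img, spot_sigma_px) * spot_sigma_px**2
    bg = float(np.median(filt))
    mad = float(np.median(np.abs(filt - bg)))
    sd = 1.4826 * mad if mad > 0 else float(filt.std())
    if sd == 0:
        return []
    coords = peak_local_max(
        filt,
        min_distance=min_separation_px,
        threshold_abs=bg + threshold_sd * sd,
        exclude_border=False,
    )
    return [
        Focus(y=float(r), x=float(c), peak_intensity=float(img[r, c]), channel=channel)
        for r, c in coords
    ]


def count_dots_per_cell(
    foci: dict[str, list[Focus]],
    cell_labels: np.ndarray,
) -> tuple[list[FociCountRecord], pd.DataFrame]:
    """Per-cell focus counts per channel plus the joint-category table.

    ``cell_labels`` is an integer label mask (0 = outside every cell);
    foci falling outside all cells are dropped.  The category of a cell
    joins the per-channel counts in the channel order given, e.g. "2/4".
    The table reports the percentage of cells per category (sums to 100).
    """
    channels = list(foci.keys())
    cell_ids = sorted(int(v) for v in np.unique(cell_labels) if v != 0)
    counts = {cid: {ch: 0 for ch in channels} for cid in cell_ids}
    n_dropped = 0
    for ch, flist in foci.items():
        for f in flist:
            r, c = int(round(f.y)), int(round(f.x))
            if not (0 <= r < cell_labels.shape[0] and 0 <= c < cell_labels.shape[1]):
                n_dropped += 1
                continue
            lab = int(cell_labels[r, c])
            if lab == 0:
                n_dropped += 1
                continue
            counts[lab][ch] += 1
    records = [
        FociCountRecord(
            cell_id=cid,
            counts=dict(counts[cid]),
            category="/".join(str(counts[cid][ch]) for ch in channels),
        )
        for cid in cell_ids
    ]
    cats = pd.Series([r.category for r in records])
    table = (100.0 * cats.value_counts(normalize=True)).rename("pct").reset_index()
    table = table.rename(columns={"index": "category"})
    table.attrs["n_dropped"] = n_dropped
    return records, table


def _disc_offsets(area_px: int) -> np.ndarray:
    """Offsets of the ``area_px`` pixels nearest the origin (a digital disc)."""
    r = int(np.ceil(np.sqrt(area_px))) + 1
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = (yy**2 + xx**2).ravel()
    order = np.lexsort((xx.ravel(), yy.ravel(), d2))
    sel = order[:area_px]
    return np.column_stack([yy.ravel()[sel], xx.ravel()[sel]])


def centrosomal_intensity(
    image: np.ndarray,
    center: tuple[float, float],
    area_px: int = 20,
    mode: str = "disc",
    background: float | None = None,
) -> float:
    """Integrated, background-subtracted intensity around a centrosome.

    ``mode='disc'`` (default) integrates over the ``area_px`` pixels
    nearest the center — a digital disc of exactly that area.
    ``mode='box'`` integrates an ``area_px`` x ``area_px`` square instead
    (the side-length reading of a "20 pixel" region).  The background
    defaults to the image median.
    """
    cy, cx = int(round(center[0])), int(round(center[1]))
    if mode == "disc":
        offs = _disc_offsets(area_px)
        ys, xs = offs[:, 0] + cy, offs[:, 1] + cx
    elif mode == "box":
        half = area_px // 2
        yy, xx = np.mgrid[-half : area_px - half, -half : area_px - half]
        ys, xs = yy.ravel() + cy, xx.ravel() + cx
    else:
        raise InvalidInputError(f"unknown mode {mode!r}")
    if ys.min() < 0 or xs.min() < 0 or ys.max() >= image.shape[0] or xs.max() >= image.shape[1]:
        raise GeometryError("measurement region clipped by the image border")
    bg = float(np.median(image)) if background is None else float(background)
    return float(image[ys, xs].sum() - bg * len(ys))


def centriolar_profile_intensity(
    image: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    n_points: int = 25,
    background: float | None = None,
) -> float:
    """Mean background-subtracted intensity of an interpolated line profile.

    ``p0`` and ``p1`` are (y, x) endpoints of the segment across the
    centriole pair; the profile is sampled at ``n_points`` evenly spaced
    positions (bilinear interpolation).
    """
    for p in (p0, p1):
        if not (0 <= p[0] <= image.shape[0] - 1 and 0 <= p[1] <= image.shape[1] - 1):
            raise GeometryError(f"segment endpoint {p} outside image")
    t = np.linspace(0.0, 1.0, n_points)
    ys = p0[0] + t * (p1[0] - p0[0])
    xs = p0[1] + t * (p1[1] - p0[1])
    values = ndimage.map_coordinates(image.astype(float), [ys, xs], order=1)
    bg = float(np.median(image)) if background is None else float(background)
    return float(values.mean() - bg)


def normalize_to_control(
    values: np.ndarray | list[float],
    control_values: np.ndarray | list[float],
) -> list[NormalizedIntensity]:
    """Divide every measurement by the mean of the control group (A.U.).

    Normalizing the control group by itself yields a group mean of
    exactly 1 by construction.
    """
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise NormalizationError("control group is empty")
    mean = float(control.mean())
    if mean == 0:
        raise NormalizationError("control mean is zero")
    return [NormalizedIntensity(raw=float(v), relative_au=float(v) / mean) for v in np.asarray(values, dtype=float)]
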