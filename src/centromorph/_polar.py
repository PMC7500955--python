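"""Shared polar-resampling helpers for top-view analyses."""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def polar_transform(
    image: np.ndarray,
    center: tuple[float, float],
    r_max: float | None = None,
    r_step: float = 0.5,
    n_theta: int = 360,
    theta_offset_deg: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample ``image`` on a polar grid about ``center`` (y, x in px).

    Returns ``(radii_px, thetas_deg, polar)`` with ``polar`` of shape
    ``(n_theta, n_r)``, bilinear interpolation, zero padding outside.
    """
    if r_max is None:
        r_max = min(image.shape) / 2.0 - 1.0
    radii = np.arange(0.0, r_max + r_step / 2.0, r_step)
    thetas = theta_offset_deg + np.arange(n_theta) * (360.0 / n_theta)
    th = np.deg2rad(thetas)[:, None]
    ys = center[0] + radii[None, :] * np.sin(th)
    xs = center[1] + radii[None, :] * np.cos(th)
    polar = ndimage.map_coordinates(
        image.astype(float), [ys, xs], order=1, mode="constant", cval=0.0
    )
    return radii, thetas, polar


def angular_wall_trace(
    image: np.ndarray,
    center: tuple[float, float],
    r_step: float = 0.5,
    n_theta: int = 360,
    smooth_px: float = 1.0,
    smooth_deg: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Max-over-radius wall intensity per angular sector.

    The image is lightly smoothed before resampling (suppresses shot noise
    without displacing the wall), then the per-sector maximum over radius is
    taken and circularly smoothed.  Returns ``(thetas_deg, trace)``.
    """
    smoothed = ndimage.gaussian_filter(image.astype(float), smooth_px)
    _, thetas, polar = polar_transform(smoothed, center, r_step=r_step, n_theta=n_theta)
    trace = polar.max(axis=1)
    if smooth_deg > 0:
        trace = ndimage.gaussian_filter1d(trace, smooth_deg * n_theta / 360.0, mode="wrap")
    return thetas, trace


def quadratic_peak_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample peak position by a 3-point parabola around index ``i``.

    Returns the refined index (float).  Falls back to ``i`` at the array
    edges or when the parabola degenerates.
    """
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0 or abs(denom) < 1e-300:
        return float(i)
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(i) + float(np.clip(shift, -1.0, 1.0))
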