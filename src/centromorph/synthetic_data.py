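"""Synthetic expanded-centriole image generator with ground-truth manifests.

The generator renders the structures the analysis modules assume:

* **top views** — the nine microtubule-triplet wall elements of a centriole
  seen down its long axis, as Gaussian blobs equally spaced on an ellipse,
  with the protein-of-interest shell rendered at a configurable radial
  offset toward the lumen;
* **lateral views** — the centriole barrel seen from the side, as two
  parallel wall lines, with the protein band covering a configurable
  fraction of the tubulin length;
* **multi-cell foci fields** — diffraction-limited spots for dot counting
  and intensity-normalization fixtures;
* **decorated-microtubule line profiles** — 1-D periodic bump trains for
  the periodicity estimator.

All geometry is specified in biological nanometres and converted to
expanded-space pixels through an :class:`~centromorph.calibration.ExpansionCalibration`,
mimicking U-ExM acquisition (the gel expands the specimen ~4.2x; the
microscope samples the expanded gel at 35 nm pixels).  Images are blurred
with a Gaussian PSF, Poisson-sampled and given additive Gaussian read
noise.  Every emitted image carries a manifest record of the parameters
actually drawn, so every analysis stage can be verified by parameter
recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .calibration import ExpansionCalibration
from .errors import GeometryError, InvalidInputError, PackingError
from .presets import (
    _draw_scalar_or_range,
    _draw_truncated_normal,
    calibration_from_preset,
    load_preset,
)

__all__ = [
    "CentrioleSpec",
    "ImagingSpec",
    "DecorationProfileSpec",
    "GroundTruthManifest",
    "generate_top_view",
    "generate_lateral_view",
    "generate_cell_field",
    "generate_decoration_profile",
    "sample_centriole_spec",
    "imaging_from_preset",
    "generate_preset_batch",
    "integrity_fixture",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CentrioleSpec:
    """Per-image ground-truth geometry of one synthetic centriole.

    All lengths are biological nanometres.  ``protein_offset_nm`` is signed:
    positive moves the protein shell toward the lumen (interior to the
    wall), matching the sign convention of the radial mapping stage.
    """

    view: str  # "top" | "lateral"
    wall_radius_nm: float = 110.0
    n_triplets: int = 9
    wall_sigma_nm: float = 8.0
    tubulin_length_nm: float = 450.0
    protein_offset_nm: float = 0.0
    protein_coverage_frac: float = 0.5
    protein_position_frac: float = 0.25
    ellipse_ratio: float = 1.0
    break_arc_deg: float = 0.0
    break_center_deg: float = 0.0
    break_axial_range_frac: tuple[float, float] = (0.0, 1.0)
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.view not in {"top", "lateral"}:
            raise InvalidInputError(f"view must be 'top' or 'lateral', got {self.view!r}")
        if self.n_triplets < 3:
            raise InvalidInputError("n_triplets must be >= 3")
        if self.wall_radius_nm <= 0:
            raise InvalidInputError("wall_radius_nm must be positive")
        if not (0.0 <= self.protein_coverage_frac <= 1.0):
            raise InvalidInputError("protein_coverage_frac must be in [0, 1]")
        if not (0.0 <= self.protein_position_frac <= 1.0):
            raise InvalidInputError("protein_position_frac must be in [0, 1]")
        if self.protein_position_frac + self.protein_coverage_frac > 1.0 + 1e-9:
            raise InvalidInputError("protein band must lie within the tubulin extent")
        if not (0.0 < self.ellipse_ratio <= 1.0):
            raise InvalidInputError("ellipse_ratio must be in (0, 1]")
        if not (0.0 <= self.break_arc_deg < 360.0):
            raise InvalidInputError("break_arc_deg must be in [0, 360)")


@dataclass(frozen=True)
class ImagingSpec:
    """Acquisition model: Gaussian PSF, Poisson shot noise, Gaussian read noise.

    ``psf_fwhm_nm`` is in expanded-space nm (the PSF is a property of the
    microscope, not of the specimen).  ``photon_scale`` is the expected
    photon count at the peak of an isolated structure element.
    """

    psf_fwhm_nm: float = 140.0
    photon_scale: float = 500.0
    read_noise_sd: float = 3.0
    background: float = 10.0
    calib: ExpansionCalibration = field(
        default_factory=lambda: ExpansionCalibration(gel_size_mm=50.0)
    )
    seed: int | None = None
    apply_noise: bool = True
    fov_px: int | None = None  # None -> auto-sized field of view

    def __post_init__(self) -> None:
        if self.psf_fwhm_nm <= 0:
            raise InvalidInputError("psf_fwhm_nm must be positive")
        if self.photon_scale <= 0:
            raise InvalidInputError("photon_scale must be positive")
        if self.read_noise_sd < 0:
            raise InvalidInputError("read_noise_sd must be non-negative")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_fwhm_nm * FWHM_TO_SIGMA / self.calib.pixel_nm

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class DecorationProfileSpec:
    """1-D decorated-microtubule profile: Gaussian bumps every ``period_nm``."""

    period_nm: float = 8.5
    n_repeats: int = 20
    bump_fwhm_nm: float = 4.0
    noise_sd: float = 0.05
    sample_step_nm: float = 0.25
    pad_nm: float = 12.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.period_nm <= 0:
            raise InvalidInputError("period_nm must be positive")
        if self.n_repeats < 1:
            raise InvalidInputError("n_repeats must be >= 1")
        if self.sample_step_nm > self.period_nm / 4.0:
            raise InvalidInputError(
                "sample_step_nm must be <= period_nm / 4 (Nyquist margin)"
            )


# --------------------------------------------------------------------------
# manifest
# --------------------------------------------------------------------------


class GroundTruthManifest:
    """Ordered collection of per-image ground-truth records.

    Records are plain dicts (JSON-serializable).  The manifest round-trips
    losslessly through JSON lines; a CSV mirror is written for convenience.
    """

    def __init__(self, records: list[dict] | None = None):
        self.records: list[dict] = list(records) if records else []

    def append(self, record: dict) -> None:
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "GroundTruthManifest":
        records = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    records.append(json.loads(line))
        return cls(records)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _spec_record(spec: CentrioleSpec, imaging: ImagingSpec, **extra) -> dict:
    rec = dataclasses.asdict(spec)
    rec["break_axial_range_frac"] = list(spec.break_axial_range_frac)
    rec.update(
        psf_fwhm_nm=imaging.psf_fwhm_nm,
        photon_scale=imaging.photon_scale,
        read_noise_sd=imaging.read_noise_sd,
        background=imaging.background,
        seed=imaging.seed,
        x_factor=imaging.calib.x_factor,
        pixel_nm=imaging.calib.pixel_nm,
    )
    # derived truths
    rec["true_delta_nm"] = spec.protein_offset_nm
    rec["true_tubulin_length_nm"] = spec.tubulin_length_nm
    rec["true_protein_length_nm"] = spec.protein_coverage_frac * spec.tubulin_length_nm
    rec["true_coverage_pct"] = 100.0 * spec.protein_coverage_frac
    rec["true_position_pct"] = 100.0 * (
        spec.protein_position_frac + spec.protein_coverage_frac / 2.0
    )
    rec["true_roundness"] = spec.ellipse_ratio
    rec["broken"] = spec.break_arc_deg > 0.0
    rec.update(extra)
    return rec


# --------------------------------------------------------------------------
# top view
# --------------------------------------------------------------------------


def _auto_fov(extent_px: float, sigma_px: float, minimum: int = 32) -> int:
    size = int(np.ceil(2.0 * (extent_px + 4.0 * sigma_px) + 8.0))
    return max(size, minimum)


def _blob_image(
    shape: tuple[int, int],
    centers: np.ndarray,
    amplitude: float,
    sigma_px: float,
) -> np.ndarray:
    """Sum of isotropic Gaussian blobs at ``centers`` ((y, x) pairs, px)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape, dtype=float)
    inv = 1.0 / (2.0 * sigma_px**2)
    for cy, cx in centers:
        img += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) * inv)
    return amplitude * img


def _apply_noise(image: np.ndarray, imaging: ImagingSpec, rng: np.random.Generator) -> np.ndarray:
    if not imaging.apply_noise:
        return image
    noisy = rng.poisson(np.clip(image, 0.0, None)).astype(float)
    if imaging.read_noise_sd > 0:
        noisy += rng.normal(0.0, imaging.read_noise_sd, size=image.shape)
    return noisy


def _ring_blob_centers(
    spec: CentrioleSpec, radius_offset_nm: float, calib: ExpansionCalibration,
    center: tuple[float, float],
) -> np.ndarray:
    """Wall-element centers ((y, x) px) on the (possibly broken) ellipse.

    The ellipse has mean radius ``wall_radius_nm - radius_offset_nm`` and
    minor/major ratio ``ellipse_ratio``; elements whose angular position
    falls inside the break window are removed (the physical fracture takes
    the wall elements with it).
    """
    r_mean = spec.wall_radius_nm - radius_offset_nm
    if r_mean <= 0:
        raise GeometryError("protein shell radius must stay positive")
    a_nm = 2.0 * r_mean / (1.0 + spec.ellipse_ratio)
    b_nm = spec.ellipse_ratio * a_nm
    a_px = calib.biological_to_px(a_nm)
    b_px = calib.biological_to_px(b_nm)
    t = np.deg2rad(spec.orientation_deg) + 2.0 * np.pi * np.arange(spec.n_triplets) / spec.n_triplets
    x_loc = a_px * np.cos(t)
    y_loc = b_px * np.sin(t)
    if spec.break_arc_deg > 0:
        theta = np.rad2deg(np.arctan2(y_loc, x_loc)) % 360.0
        gap = (theta - (spec.break_center_deg - spec.break_arc_deg / 2.0)) % 360.0
        keep = gap > spec.break_arc_deg
    else:
        keep = np.ones_like(t, dtype=bool)
    cy, cx = center
    return np.column_stack([cy + y_loc[keep], cx + x_loc[keep]])


def generate_top_view(
    spec: CentrioleSpec,
    imaging: ImagingSpec,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Render one two-channel (tubulin, protein) top view.

    The tubulin channel shows ``n_triplets`` Gaussian wall elements equally
    spaced on an ellipse of mean radius ``wall_radius_nm``; the protein
    channel shows the same geometry ``protein_offset_nm`` closer to the
    lumen.  Returns the (2, H, W) photon-count image and the manifest
    record.
    """
    if spec.view != "top":
        raise InvalidInputError("generate_top_view requires spec.view == 'top'")
    calib = imaging.calib
    rng = imaging.rng() if rng is None else rng

    wall_sigma_px = calib.biological_to_px(spec.wall_sigma_nm)
    sigma_tot = float(np.hypot(wall_sigma_px, imaging.psf_sigma_px))
    a_px = calib.biological_to_px(2.0 * spec.wall_radius_nm / (1.0 + spec.ellipse_ratio))
    if imaging.fov_px is None:
        fov = _auto_fov(a_px, sigma_tot)
    else:
        fov = imaging.fov_px
        if fov < 2.0 * (a_px + 3.0 * imaging.psf_sigma_px):
            raise GeometryError(
                f"field of view {fov} px too small for ring radius {a_px:.1f} px"
            )
    center = ((fov - 1) / 2.0, (fov - 1) / 2.0)

    channels = []
    for offset in (0.0, spec.protein_offset_nm):
        centers = _ring_blob_centers(spec, offset, calib, center)
        chan = imaging.background + _blob_image(
            (fov, fov), centers, imaging.photon_scale, sigma_tot
        )
        channels.append(_apply_noise(chan, imaging, rng))
    image = np.stack(channels)

    record = _spec_record(
        spec, imaging, center_px=list(center), fov_px=fov, channel_order=["tubulin", "protein"]
    )
    return image, record


# --------------------------------------------------------------------------
# lateral view
# --------------------------------------------------------------------------


def _smooth_box(x: np.ndarray, lo: float, hi: float, sigma: float) -> np.ndarray:
    """Top-hat on [lo, hi] convolved with a Gaussian of SD ``sigma`` (exact)."""
    from scipy.special import erf

    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((x - lo) / s) - erf((x - hi) / s))


def generate_lateral_view(
    spec: CentrioleSpec,
    imaging: ImagingSpec,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Render one two-channel lateral view (barrel seen from the side).

    The tubulin channel is two parallel wall lines separated by the
    wall-to-wall diameter (scaled by ``ellipse_ratio``, i.e. the barrel is
    viewed along the minor axis when elliptical) running the drawn tubulin
    length; the protein channel is a band covering
    ``protein_coverage_frac`` of that length starting at
    ``protein_position_frac`` (proximal end at position 0).
    """
    if spec.view != "lateral":
        raise InvalidInputError("generate_lateral_view requires spec.view == 'lateral'")
    calib = imaging.calib
    rng = imaging.rng() if rng is None else rng

    wall_sigma_px = calib.biological_to_px(spec.wall_sigma_nm)
    sigma_tot = float(np.hypot(wall_sigma_px, imaging.psf_sigma_px))
    L_px = calib.biological_to_px(spec.tubulin_length_nm)
    R_px = calib.biological_to_px(spec.wall_radius_nm * spec.ellipse_ratio)

    half_diag = np.hypot(L_px / 2.0, R_px)
    if imaging.fov_px is None:
        fov = _auto_fov(half_diag, sigma_tot)
    else:
        fov = imaging.fov_px
        if fov < 2.0 * (half_diag + 3.0 * imaging.psf_sigma_px):
            raise GeometryError(
                f"field of view {fov} px too small for barrel half-diagonal "
                f"{half_diag:.1f} px"
            )
    center = ((fov - 1) / 2.0, (fov - 1) / 2.0)

    yy, xx = np.mgrid[0:fov, 0:fov].astype(float)
    phi = np.deg2rad(spec.orientation_deg)
    u = np.array([np.cos(phi), np.sin(phi)])  # long axis (x, y)
    xr = (xx - center[1]) * u[0] + (yy - center[0]) * u[1]
    yr = -(xx - center[1]) * u[1] + (yy - center[0]) * u[0]

    walls = np.exp(-((yr - R_px) ** 2) / (2 * sigma_tot**2)) + np.exp(
        -((yr + R_px) ** 2) / (2 * sigma_tot**2)
    )
    tub = imaging.photon_scale * _smooth_box(xr, -L_px / 2.0, L_px / 2.0, sigma_tot) * walls

    band_lo = -L_px / 2.0 + spec.protein_position_frac * L_px
    band_hi = band_lo + spec.protein_coverage_frac * L_px
    Rp_px = calib.biological_to_px(
        max(spec.wall_radius_nm * spec.ellipse_ratio - spec.protein_offset_nm, 1.0)
    )
    p_walls = np.exp(-((yr - Rp_px) ** 2) / (2 * sigma_tot**2)) + np.exp(
        -((yr + Rp_px) ** 2) / (2 * sigma_tot**2)
    )
    prot = imaging.photon_scale * _smooth_box(xr, band_lo, band_hi, sigma_tot) * p_walls

    image = np.stack(
        [
            _apply_noise(imaging.background + tub, imaging, rng),
            _apply_noise(imaging.background + prot, imaging, rng),
        ]
    )
    record = _spec_record(
        spec, imaging, center_px=list(center), fov_px=fov, channel_order=["tubulin", "protein"]
    )
    return image, record


# --------------------------------------------------------------------------
# multi-cell foci fields
# --------------------------------------------------------------------------


def generate_cell_field(
    n_cells: int,
    foci_per_cell: int | dict | Callable[[np.random.Generator], int],
    intensity_ratio: float = 1.0,
    imaging: ImagingSpec | None = None,
    n_treated: int = 0,
    channels: Sequence[str] = ("ch0",),
    cell_size_px: int = 48,
    min_separation_px: int = 6,
    amplitude_jitter_sd: float = 0.15,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render a field of cells, each containing diffraction-limited foci.

    Cells are laid out on a grid of ``cell_size_px`` tiles; the label mask
    assigns each tile to one cell (labels 1..n_cells).  The first
    ``n_treated`` cells are "treated": their focal peak intensity is scaled
    by ``intensity_ratio``.  ``foci_per_cell`` may be an integer, a
    ``{channel: int-or-callable}`` mapping, or a callable drawing a count.

    Returns ``(image (C, H, W), cell label mask, truth table)`` where the
    truth table has one row per cell with per-channel counts, the treated
    flag and the drawn intensity scale.
    """
    if n_cells < 1:
        raise InvalidInputError("n_cells must be >= 1")
    imaging = imaging if imaging is not None else ImagingSpec()
    rng = imaging.rng() if rng is None else rng

    ncols = int(np.ceil(np.sqrt(n_cells)))
    nrows = int(np.ceil(n_cells / ncols))
    H, W = nrows * cell_size_px, ncols * cell_size_px
    labels = np.zeros((H, W), dtype=int)
    sigma = imaging.psf_sigma_px

    def _count_for(channel: str) -> int:
        spec = foci_per_cell
        if isinstance(spec, dict):
            spec = spec[channel]
        if callable(spec):
            return int(spec(rng))
        return int(spec)

    margin = max(min_separation_px, int(np.ceil(3 * sigma)) + 1)
    if cell_size_px - 2 * margin <= 0:
        raise PackingError("cell too small for the requested spot size")

    image = np.full((len(channels), H, W), float(imaging.background))
    rows = []
    for cell in range(n_cells):
        r, c = divmod(cell, ncols)
        y0, x0 = r * cell_size_px, c * cell_size_px
        labels[y0 : y0 + cell_size_px, x0 : x0 + cell_size_px] = cell + 1
        treated = cell < n_treated
        scale = intensity_ratio if treated else 1.0
        jitter = _draw_truncated_normal(rng, 1.0, amplitude_jitter_sd, low=0.1)
        row = {"cell_id": cell + 1, "treated": treated, "intensity_scale": scale * jitter}
        placed: list[tuple[float, float]] = []
        for ci, channel in enumerate(channels):
            k = _count_for(channel)
            row[f"n_foci_{channel}"] = k
            for _ in range(k):
                for attempt in range(200):
                    fy = rng.uniform(y0 + margin, y0 + cell_size_px - margin)
                    fx = rng.uniform(x0 + margin, x0 + cell_size_px - margin)
                    if all(
                        np.hypot(fy - py, fx - px) >= min_separation_px
                        for py, px in placed
                    ):
                        break
                else:
                    raise PackingError(
                        f"could not place {k} foci with separation "
                        f"{min_separation_px} px in a {cell_size_px} px cell"
                    )
                placed.append((fy, fx))
                amp = imaging.photon_scale * scale * jitter
                yy, xx = np.mgrid[y0 : y0 + cell_size_px, x0 : x0 + cell_size_px]
                image[ci, y0 : y0 + cell_size_px, x0 : x0 + cell_size_px] += amp * np.exp(
                    -((yy - fy) ** 2 + (xx - fx) ** 2) / (2 * sigma**2)
                )
        rows.append(row)

    for ci in range(len(channels)):
        image[ci] = _apply_noise(image[ci], imaging, rng)
    return image, labels, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# decoration profiles
# --------------------------------------------------------------------------


def generate_decoration_profile(
    spec: DecorationProfileSpec,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """1-D bump train: Gaussian bumps every ``period_nm``, plus noise.

    Returns ``(positions_nm, intensity, truth)``.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    length = spec.n_repeats * spec.period_nm + 2.0 * spec.pad_nm
    positions = np.arange(0.0, length, spec.sample_step_nm)
    centers = spec.pad_nm + (np.arange(spec.n_repeats) + 0.5) * spec.period_nm
    sigma = spec.bump_fwhm_nm * FWHM_TO_SIGMA
    intensity = np.zeros_like(positions)
    for c in centers:
        intensity += np.exp(-((positions - c) ** 2) / (2 * sigma**2))
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=positions.shape)
    truth = {
        "period_nm": spec.period_nm,
        "n_repeats": spec.n_repeats,
        "bump_fwhm_nm": spec.bump_fwhm_nm,
        "noise_sd": spec.noise_sd,
        "sample_step_nm": spec.sample_step_nm,
        "seed": spec.seed,
    }
    return positions, intensity, truth


# --------------------------------------------------------------------------
# preset sampling and batch generation
# --------------------------------------------------------------------------


def sample_centriole_spec(
    preset: dict,
    channel: str,
    view: str,
    rng: np.random.Generator,
    force_break: bool | None = None,
    force_round: bool = False,
) -> CentrioleSpec:
    """Draw one per-image :class:`CentrioleSpec` from a preset.

    Lengths and coverages are drawn from truncated normals (truncated at
    zero / the unit interval); the radial offset is drawn from a normal
    around the preset offset; ellipticity may be a scalar or a uniform
    range; breaks occur with the preset prevalence unless ``force_break``
    pins them.  ``force_round`` overrides the ellipse draw with a circle
    (used by the wall-integrity fixture so the break phenotype is rendered
    in isolation).
    """
    cent = preset["centriole"]
    chan = preset["channels"][channel]

    length = _draw_truncated_normal(
        rng, cent["tubulin_length_nm"]["mean"], cent["tubulin_length_nm"]["sd"], low=50.0
    )
    cov = _draw_truncated_normal(
        rng, chan["coverage"]["mean"], chan["coverage"]["sd"], low=0.01, high=1.0
    )
    pos_rule = chan.get("position", "centered")
    if pos_rule == "proximal":
        pos = min(0.2, 1.0 - cov)
    else:
        pos = (1.0 - cov) / 2.0
    offset = float(rng.normal(chan["offset_nm"], chan.get("offset_sd_nm", 0.0)))
    ellipse = 1.0 if force_round else _draw_scalar_or_range(rng, cent.get("ellipse_ratio", 1.0))
    prevalence = float(cent.get("break_prevalence", 0.0))
    broken = bool(rng.random() < prevalence) if force_break is None else force_break
    arc = float(cent.get("break_arc_deg", 60.0)) if broken else 0.0
    return CentrioleSpec(
        view=view,
        wall_radius_nm=float(cent.get("wall_radius_nm", 110.0)),
        n_triplets=int(cent.get("n_triplets", 9)),
        wall_sigma_nm=float(cent.get("wall_sigma_nm", 8.0)),
        tubulin_length_nm=length,
        protein_offset_nm=offset,
        protein_coverage_frac=cov,
        protein_position_frac=pos,
        ellipse_ratio=ellipse,
        break_arc_deg=arc,
        break_center_deg=float(rng.uniform(0.0, 360.0)) if broken else 0.0,
        orientation_deg=float(rng.uniform(0.0, 360.0)),
    )


def imaging_from_preset(
    preset: dict, seed: int | None = None, apply_noise: bool = True
) -> ImagingSpec:
    img = preset.get("imaging", {})
    return ImagingSpec(
        psf_fwhm_nm=float(img.get("psf_fwhm_nm", 140.0)),
        photon_scale=float(img.get("photon_scale", 500.0)),
        read_noise_sd=float(img.get("read_noise_sd", 3.0)),
        background=float(img.get("background", 10.0)),
        calib=calibration_from_preset(preset),
        seed=seed,
        apply_noise=apply_noise,
    )


def generate_preset_batch(
    preset: str | dict,
    channel: str,
    view: str,
    n: int,
    seed: int = 0,
    apply_noise: bool = True,
    force_round: bool = False,
) -> tuple[list[np.ndarray], GroundTruthManifest]:
    """Generate ``n`` images from a named preset with one master seed.

    Per-image substreams are spawned deterministically from the master
    seed, so the batch is bit-reproducible and individual images do not
    share noise.
    """
    preset = load_preset(preset) if not isinstance(preset, dict) else preset
    imaging = imaging_from_preset(preset, seed=seed, apply_noise=apply_noise)
    render = generate_top_view if view == "top" else generate_lateral_view
    manifest = GroundTruthManifest()
    images = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n)):
        rng = np.random.default_rng(child)
        spec = sample_centriole_spec(preset, channel, view, rng, force_round=force_round)
        image, record = render(spec, imaging, rng=rng)
        record["image_id"] = i
        record["channel"] = channel
        record["preset"] = preset.get("name", "custom")
        images.append(image)
        manifest.append(record)
    return images, manifest


def integrity_fixture(
    n: int = 150,
    n_broken: int = 15,
    seed: int = 0,
    preset: str | dict = "hs-siwdr90",
    channel: str = "POC5",
    break_arc_deg: float = 60.0,
) -> tuple[list[np.ndarray], GroundTruthManifest]:
    """Fixed-count wall-integrity fixture: exactly ``n_broken`` of ``n`` top
    views carry a rendered break of ``break_arc_deg``.

    Walls are rendered round (the ellipticity phenotype is generated
    separately) so the detector's flagged fraction reflects breaks only.
    """
    preset = load_preset(preset) if not isinstance(preset, dict) else preset
    imaging = imaging_from_preset(preset, seed=seed)
    master = np.random.default_rng(np.random.SeedSequence(seed))
    broken_ids = set(master.permutation(n)[:n_broken].tolist())
    manifest = GroundTruthManifest()
    images = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n)):
        rng = np.random.default_rng(child)
        spec = sample_centriole_spec(
            preset, channel, "top", rng, force_break=(i in broken_ids), force_round=True
        )
        if i in broken_ids and spec.break_arc_deg != break_arc_deg:
            spec = dataclasses.replace(spec, break_arc_deg=break_arc_deg)
        image, record = generate_top_view(spec, imaging, rng=rng)
        record["image_id"] = i
        record["channel"] = channel
        record["preset"] = preset.get("name", "custom")
        images.append(image)
        manifest.append(record)
    return images, manifest
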