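"""Expansion-factor calibration and pixel/physical unit conversions.

Ultrastructure expansion microscopy (U-ExM) embeds the specimen in a
swellable gel that expands roughly 4.2-fold.  Every distance measured on an
image is therefore an *expanded-space* distance and must be divided by the
gel's expansion factor to recover the biological scale.  The expansion
factor of a gel is measured as its expanded size divided by the size of the
seeding coverslip (12 mm by convention).

All downstream modules express their outputs in biological nanometres via
an :class:`ExpansionCalibration`.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .errors import InvalidCalibrationError, InvalidInputError

__all__ = [
    "ExpansionCalibration",
    "expansion_factor",
    "to_biological_nm",
    "biological_to_px",
]


def _round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (4.425 -> 4.43), not banker's."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def expansion_factor(gel_size_mm: float, coverslip_mm: float = 12.0) -> float:
    """Dimensionless gel expansion factor: expanded gel size / coverslip size.

    Parameters
    ----------
    gel_size_mm :
        Measured size of the expanded gel, in mm (caliper measurement).
    coverslip_mm :
        Size of the coverslip the sample was seeded on, in mm (default 12).

    Returns
    -------
    float
        The expansion factor at full precision.  Use
        :meth:`ExpansionCalibration.x_factor_reported` for the 2-decimal
        half-up rounded value used in reports.
    """
    if gel_size_mm <= 0 or coverslip_mm <= 0:
        raise InvalidCalibrationError(
            f"gel and coverslip sizes must be positive, got "
            f"{gel_size_mm} / {coverslip_mm} mm"
        )
    return gel_size_mm / coverslip_mm


@dataclass(frozen=True)
class ExpansionCalibration:
    """Per-gel calibration converting image pixels to biological nanometres.

    Attributes
    ----------
    gel_size_mm :
        Measured expanded gel size (mm).
    coverslip_mm :
        Seeding coverslip size (mm), 12 by convention.
    pixel_nm :
        x, y pixel size in expanded-space nm (default 35).
    z_step_nm :
        Axial step in expanded-space nm (default 120).
    """

    gel_size_mm: float
    coverslip_mm: float = 12.0
    pixel_nm: float = 35.0
    z_step_nm: float = 120.0

    def __post_init__(self) -> None:
        expansion_factor(self.gel_size_mm, self.coverslip_mm)  # validates
        if self.pixel_nm <= 0 or self.z_step_nm <= 0:
            raise InvalidCalibrationError(
                f"pixel_nm and z_step_nm must be positive, got "
                f"{self.pixel_nm} / {self.z_step_nm}"
            )

    @property
    def x_factor(self) -> float:
        """Expansion factor at full precision."""
        return expansion_factor(self.gel_size_mm, self.coverslip_mm)

    @property
    def x_factor_reported(self) -> float:
        """Expansion factor rounded half-up to 2 decimals, for reports."""
        return _round_half_up(self.x_factor, 2)

    @property
    def bio_pixel_nm(self) -> float:
        """Biological-scale size of one pixel (pixel_nm / x_factor)."""
        return self.pixel_nm / self.x_factor

    # -- conversions ------------------------------------------------------

    def to_biological_nm(self, distance_px: float) -> float:
        """Convert an in-image distance (pixels) to biological nm."""
        return to_biological_nm(distance_px, self)

    def biological_to_px(self, distance_nm: float) -> float:
        """Convert a biological-scale distance (nm) to image pixels."""
        return biological_to_px(distance_nm, self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExpansionCalibration":
        """Build from a calibration block of a run config (YAML/JSON)."""
        return cls(
            gel_size_mm=float(d["gel_size_mm"]),
            coverslip_mm=float(d.get("coverslip_mm", 12.0)),
            pixel_nm=float(d.get("pixel_nm", 35.0)),
            z_step_nm=float(d.get("z_step_nm", 120.0)),
        )

    def to_dict(self) -> dict:
        return {
            "gel_size_mm": self.gel_size_mm,
            "coverslip_mm": self.coverslip_mm,
            "pixel_nm": self.pixel_nm,
            "z_step_nm": self.z_step_nm,
        }


def to_biological_nm(distance_px: float, calib: ExpansionCalibration) -> float:
    """Convert a pixel distance to biological nm: px * pixel_nm / x_factor."""
    if distance_px < 0:
        raise InvalidInputError(f"distance must be non-negative, got {distance_px}")
    return distance_px * calib.pixel_nm / calib.x_factor


def biological_to_px(distance_nm: float, calib: ExpansionCalibration) -> float:
    """Convert a biological-scale distance (nm) to image pixels."""
    if distance_nm < 0:
        raise InvalidInputError(f"distance must be non-negative, got {distance_nm}")
    return distance_nm * calib.x_factor / calib.pixel_nm
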