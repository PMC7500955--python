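"""Named phenotype presets for the synthetic expanded-centriole generator.

A preset bundles, for one experimental condition, the geometry of the
centriole (wall radius, nine triplets, tubulin length distribution,
ellipticity, break prevalence), the per-channel protein shell parameters
(radial offset toward the lumen, longitudinal coverage and band position)
and the imaging model (PSF, photon scale, noise).  Presets ship as YAML
files inside the package; ``load_preset`` also accepts a path to a user
YAML file with the same schema.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from ..calibration import ExpansionCalibration

__all__ = ["available_presets", "load_preset"]

_PRESET_PKG = "centromorph.presets"


def available_presets() -> list[str]:
    """Names of the presets bundled with the package."""
    names = []
    for entry in resources.files(_PRESET_PKG).iterdir():
        if entry.name.endswith(".yaml"):
            names.append(entry.name[: -len(".yaml")])
    return sorted(names)


def load_preset(name_or_path: str | Path) -> dict:
    """Load a preset by bundled name (case-insensitive) or YAML path."""
    p = Path(str(name_or_path))
    if p.suffix in {".yaml", ".yml"} and p.exists():
        with open(p) as fh:
            return yaml.safe_load(fh)
    name = str(name_or_path).lower()
    candidate = resources.files(_PRESET_PKG) / f"{name}.yaml"
    if not candidate.is_file():
        raise KeyError(
            f"unknown preset {name_or_path!r}; available: {available_presets()}"
        )
    return yaml.safe_load(candidate.read_text())


def calibration_from_preset(preset: dict) -> ExpansionCalibration:
    return ExpansionCalibration.from_dict(preset.get("calibration", {"gel_size_mm": 50.0}))


def _draw_truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    low: float = 0.0,
    high: float = np.inf,
) -> float:
    """Draw from N(mean, sd) truncated to (low, high) by redrawing."""
    if sd == 0:
        return float(np.clip(mean, low, high))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low < x < high:
            return float(x)
    return float(np.clip(mean, low, high))


def _draw_scalar_or_range(rng: np.random.Generator, value) -> float:
    if isinstance(value, dict):
        return float(rng.uniform(value["min"], value["max"]))
    return float(value)
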