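"""TIFF and manifest I/O for simulated and acquired images."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .calibration import ExpansionCalibration
from .synthetic_data import GroundTruthManifest

__all__ = ["save_image", "load_image", "save_batch", "load_batch"]


def save_image(
    path: str | Path,
    image: np.ndarray,
    calib: ExpansionCalibration | None = None,
    metadata: dict | None = None,
) -> None:
    """Write a (C, H, W) image as multichannel TIFF.

    The pixel size (expanded-space nm) and calibration are stored in the
    image description as JSON so measurements can be re-scaled on load.
    Channel order is (tubulin, protein) for simulated centrioles.
    """
    desc = dict(metadata or {})
    if calib is not None:
        desc["calibration"] = calib.to_dict()
    tifffile.imwrite(
        str(path),
        np.asarray(image, dtype=np.float32),
        description=json.dumps(desc),
        photometric="minisblack",
    )


def load_image(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an image written by :func:`save_image`; returns (array, metadata)."""
    with tifffile.TiffFile(str(path)) as tf:
        image = tf.asarray()
        desc = tf.pages[0].description
    try:
        metadata = json.loads(desc) if desc else {}
    except json.JSONDecodeError:
        metadata = {}
    return image, metadata


def save_batch(
    outdir: str | Path,
    images: list[np.ndarray],
    manifest: GroundTruthManifest,
    calib: ExpansionCalibration | None = None,
    stem: str = "image",
) -> list[Path]:
    """Write a batch as numbered TIFFs plus JSONL and CSV manifests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, image in enumerate(images):
        p = outdir / f"{stem}_{i:04d}.tif"
        save_image(p, image, calib=calib, metadata={"image_id": i})
        paths.append(p)
    manifest.to_jsonl(outdir / "manifest.jsonl")
    manifest.to_csv(outdir / "manifest.csv")
    return paths


def load_batch(indir: str | Path, stem: str = "image") -> tuple[list[np.ndarray], GroundTruthManifest | None]:
    """Read back a directory written by :func:`save_batch`."""
    indir = Path(indir)
    images = [load_image(p)[0] for p in sorted(indir.glob(f"{stem}_*.tif"))]
    mpath = indir / "manifest.jsonl"
    manifest = GroundTruthManifest.from_jsonl(mpath) if mpath.exists() else None
    return images, manifest
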