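"""File I/O: calibrated images with pixel-size sidecars, annotation JSON
and ground-truth JSON.

Annotation schema (all coordinates nm, image frame, y down)::

    {
      "edge":  [[x, y], ...],          # pore-edge polyline (closed)
      "outer": [[x, y], ...],          # outer rim-band boundary (closed)
      "inner": [[x, y], ...],          # inner rim-band boundary (closed)
      "regions": [{"label": "pore" | "non_pore", "vertices": [[x, y], ...]}]
    }
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .detect import ProjectionImage
from .errors import ValidationError
from .geometry import Polyline, PoreAnnotation, RoiPolygon
from .scene import GroundTruth, ParticleTruth

logger = logging.getLogger(__name__)

SIDECAR_SUFFIX = ".pixelsize.json"


def write_image(image: ProjectionImage, path) -> Path:
    """Write an 8-bit single-channel TIFF plus a pixel-size sidecar JSON.

    The pixel size also goes into the TIFF resolution tags (pixels per cm).
    """
    path = Path(path)
    px_per_cm = 1e7 / image.pixel_size
    tifffile.imwrite(
        path,
        image.intensities,
        photometric="minisblack",
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )
    sidecar = path.with_suffix(path.suffix + SIDECAR_SUFFIX)
    sidecar.write_text(json.dumps({"pixel_size_nm": image.pixel_size}) + "\n")
    return path


def read_image(path, pixel_size: float | None = None) -> ProjectionImage:
    """Read an 8-bit TIFF/PNG.  The pixel size comes from the sidecar JSON
    unless given explicitly; an explicit value wins and any mismatch with
    the sidecar is logged."""
    path = Path(path)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse trivial channel axes
        arr = arr[..., 0]
    sidecar = path.with_suffix(path.suffix + SIDECAR_SUFFIX)
    sidecar_px = None
    if sidecar.exists():
        sidecar_px = float(json.loads(sidecar.read_text())["pixel_size_nm"])
    if pixel_size is None:
        pixel_size = sidecar_px
    elif sidecar_px is not None and not np.isclose(pixel_size, sidecar_px):
        logger.warning(
            "pixel size %.4g nm/px overrides sidecar value %.4g nm/px for %s",
            pixel_size, sidecar_px, path.name,
        )
    if pixel_size is None:
        raise ValidationError(
            f"pixel_size: no sidecar found for {path.name} and none supplied"
        )
    return ProjectionImage(intensities=arr, pixel_size=float(pixel_size))


def _poly_to_list(p: Polyline) -> list:
    return [[float(x), float(y)] for x, y in p.vertices]


def write_annotation(path, ann: PoreAnnotation, regions=()) -> Path:
    path = Path(path)
    doc = {
        "edge": _poly_to_list(ann.edge),
        "outer": _poly_to_list(ann.outer),
        "inner": _poly_to_list(ann.inner),
        "regions": [
            {"label": r.label, "vertices": _poly_to_list(r.boundary)}
            for r in regions
        ],
    }
    path.write_text(json.dumps(doc) + "\n")
    return path


def read_annotation(path) -> tuple[PoreAnnotation, list[RoiPolygon]]:
    doc = json.loads(Path(path).read_text())
    for key in ("edge", "outer", "inner"):
        if key not in doc:
            raise ValidationError(f"annotation JSON missing required key {key!r}")
    ann = PoreAnnotation(
        edge=Polyline(np.array(doc["edge"]), closed=True),
        outer=Polyline(np.array(doc["outer"]), closed=True),
        inner=Polyline(np.array(doc["inner"]), closed=True),
    )
    regions = [
        RoiPolygon(
            boundary=Polyline(np.array(r["vertices"]), closed=True),
            label=r["label"],
        )
        for r in doc.get("regions", ())
    ]
    return ann, regions


def write_ground_truth(path, truth: GroundTruth, offset: float = 0.0) -> Path:
    """Serialize ground truth, shifting projected coordinates by ``offset``
    (lab frame is vesicle-centered; image frame origin is the top-left
    pixel corner)."""
    path = Path(path)
    doc = {
        "true_circumference_nm": truth.true_circumference,
        "tilt_rad": truth.tilt,
        "coordinate_offset_nm": offset,
        "projected_rim": [
            [float(x + offset), float(y + offset)]
            for x, y in truth.projected_rim.vertices
        ],
        "particles": [
            {
                "x_nm": float(p.position_2d[0] + offset),
                "y_nm": float(p.position_2d[1] + offset),
                "class": p.particle_class,
                "distance_to_rim_nm": p.distance_to_rim,
                "diameter_nm": p.diameter,
            }
            for p in truth.particles_2d
        ],
    }
    path.write_text(json.dumps(doc) + "\n")
    return path


def read_ground_truth(path) -> GroundTruth:
    """Read ground truth back; coordinates stay in the frame they were
    written in (image frame when an offset was applied)."""
    doc = json.loads(Path(path).read_text())
    particles = tuple(
        ParticleTruth(
            position_2d=np.array([p["x_nm"], p["y_nm"]]),
            particle_class=p["class"],
            distance_to_rim=float(p["distance_to_rim_nm"]),
            diameter=float(p["diameter_nm"]),
        )
        for p in doc["particles"]
    )
    return GroundTruth(
        true_circumference=float(doc["true_circumference_nm"]),
        projected_rim=Polyline(np.array(doc["projected_rim"]), closed=True),
        particles_2d=particles,
        tilt=float(doc["tilt_rad"]),
    )
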