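"""End-to-end pipeline: simulate -> detect -> measure -> report.

``run_simulate`` renders a cohort of porated vesicles with ground-truth
annotations; ``run_measure`` detects particles in calibrated images, joins
them with annotations and emits tidy CSV tables (densities, per-pore
records, edge distances, rank tests) plus a regression summary;
``run_report`` condenses a measurement directory into a human-readable
summary.  Identical config + seed give byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely.geometry as sgeom
import yaml

from . import io as prio
from .detect import DetectionParams, detect_particles, total_cluster_area
from .errors import PairedInputError, ValidationError
from .geometry import (
    Polyline,
    PoreAnnotation,
    RoiPolygon,
    circularity,
    classify_orientation,
    min_edge_distance,
    point_in_polygon,
    pore_perimeter,
)
from .scene import (
    DEFAULT_MARGIN,
    Orientation,
    PlacementParams,
    VesicleModel,
    image_offset,
    make_scene,
    place_background_particles,
    place_rim_particles,
    project_scene,
    render_image,
    rim_circle_points,
)
from .stats import (
    PoreRecord,
    density_vs_circumference_regression,
    mann_whitney,
    region_density,
)

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = (".tif", ".tiff", ".png")


def _range_field(name, lo, hi):
    if lo > hi:
        raise ValidationError(f"{name}: range ({lo}, {hi}) is reversed")
    return (float(lo), float(hi))


@dataclass
class RunConfig:
    """Full parameterization of a simulated + measured cohort."""

    seed: int = 0
    n_vesicles: int = 10
    radius_range: tuple = (50.0, 150.0)
    membrane_thickness: float = 5.0
    pore_half_angle_range: tuple = (0.25, 0.6)
    tilt_range: tuple = (0.0, 0.0)
    linear_density: float = 1.0 / 6.0
    labeling_efficiency: float = 1.0
    rim_jitter_sd: float = 0.3
    background_area_density: float = 0.0
    count_mode: str = "poisson"
    rim_exclusion_nm: float = 5.0
    particle_diameter_mean: float = 1.3
    particle_diameter_sd: float = 0.0
    pixel_size: float = 0.2
    noise_sd: float = 0.0
    margin: float = DEFAULT_MARGIN
    rim_band_nm: float = 5.0
    band_low: int = 30
    band_high: int = 50
    min_area: float = 0.32
    connectivity: int = 8
    include_below_band: bool = False
    en_face_cutoff: float = 0.9
    normalization: float = 1.0
    nonpore_margin_nm: float = 2.0

    def __post_init__(self) -> None:
        if self.n_vesicles < 1:
            raise ValidationError("n_vesicles: must be at least 1")
        self.radius_range = _range_field("radius_range", *self.radius_range)
        self.pore_half_angle_range = _range_field(
            "pore_half_angle_range", *self.pore_half_angle_range
        )
        self.tilt_range = _range_field("tilt_range", *self.tilt_range)
        # construct once to surface invariant violations early
        DetectionParams(
            band_low=self.band_low,
            band_high=self.band_high,
            min_area=self.min_area,
            connectivity=self.connectivity,
        )

    def detection_params(self) -> DetectionParams:
        return DetectionParams(
            band_low=self.band_low,
            band_high=self.band_high,
            min_area=self.min_area,
            connectivity=self.connectivity,
            include_below_band=self.include_below_band,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"config: unknown keys {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc = {k: (list(v) if isinstance(v, tuple) else v) for k, v in doc.items()}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def _project_offset_circle(vesicle, orientation, radial_offset, shift):
    """Project a circle concentric with the rim and shift to image frame."""
    pts3 = rim_circle_points(vesicle, radial_offset=radial_offset)
    M = orientation.rotation_matrix()
    v2 = (pts3 @ M.T)[:, :2] + shift
    return Polyline(v2, closed=True)


def _nonpore_sector(vesicle, outer: Polyline, shift, margin_nm, sweep_deg=330.0):
    """Annular-sector region inside the vesicle projection that excludes the
    pore neighbourhood.  Simple by construction (sweep < 360 degrees)."""
    center = np.array([shift, shift])
    r_in = float(np.max(np.linalg.norm(outer.vertices - center, axis=1))) + margin_nm
    r_out = 0.95 * vesicle.radius
    if r_in >= r_out:
        logger.warning("pore occupies most of the projection; shrinking non-pore sector")
        r_in = 0.8 * r_out
    half_gap = math.radians((360.0 - sweep_deg) / 2.0)
    ang = np.linspace(half_gap, 2.0 * np.pi - half_gap, 180)
    arc_out = center + r_out * np.column_stack([np.cos(ang), np.sin(ang)])
    arc_in = center + r_in * np.column_stack([np.cos(ang[::-1]), np.sin(ang[::-1])])
    return RoiPolygon(
        boundary=Polyline(np.vstack([arc_out, arc_in]), closed=True),
        label="non_pore",
    )


def _build_annotation(vesicle, orientation, config, shift):
    band = min(config.rim_band_nm, vesicle.rim_radius)  # keep inner radius > 0
    edge = _project_offset_circle(vesicle, orientation, 0.0, shift)
    outer = _project_offset_circle(vesicle, orientation, band / 2.0, shift)
    inner = _project_offset_circle(vesicle, orientation, -band / 2.0, shift)
    ann = PoreAnnotation(edge=edge, outer=outer, inner=inner)
    regions = [
        RoiPolygon(boundary=Polyline(outer.vertices.copy(), closed=True), label="pore"),
        _nonpore_sector(vesicle, outer, shift, config.nonpore_margin_nm),
    ]
    return ann, regions


def run_simulate(config: RunConfig, out_dir) -> pd.DataFrame:
    """Render a cohort of scenes with annotations and ground truth.

    Writes one TIFF (+ pixel-size sidecar), one annotation JSON and one
    ground-truth JSON per vesicle, a manifest CSV and a config echo.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    rows = []
    for i in range(config.n_vesicles):
        radius = float(master.uniform(*config.radius_range))
        half_angle = float(master.uniform(*config.pore_half_angle_range))
        tilt = float(master.uniform(*config.tilt_range))
        azimuth = float(master.uniform(0.0, 2.0 * np.pi))
        placement_seed = int(master.integers(2 ** 31))

        vesicle = VesicleModel(
            radius=radius,
            membrane_thickness=config.membrane_thickness,
            pore_half_angle=half_angle,
        )
        orientation = Orientation(tilt=tilt, azimuth=azimuth)
        scene = make_scene(vesicle, orientation)
        params = PlacementParams(
            linear_density=config.linear_density,
            labeling_efficiency=config.labeling_efficiency,
            rim_jitter_sd=config.rim_jitter_sd,
            background_area_density=config.background_area_density,
            seed=placement_seed,
            count_mode=config.count_mode,
            rim_exclusion_nm=config.rim_exclusion_nm,
            diameter_mean=config.particle_diameter_mean,
            diameter_sd=config.particle_diameter_sd,
        )
        if config.linear_density > 0:
            scene = place_rim_particles(scene, params)
        if config.background_area_density > 0:
            scene = place_background_particles(scene, params)

        truth = project_scene(scene)
        image = render_image(
            scene, config.pixel_size, noise_sd=config.noise_sd,
            seed=placement_seed, margin=config.margin,
        )
        shift = image_offset(vesicle, config.margin)
        ann, regions = _build_annotation(vesicle, orientation, config, shift)

        stem = f"vesicle_{i:03d}"
        tif = prio.write_image(image, out_dir / f"{stem}.tif")
        ann_path = prio.write_annotation(out_dir / f"{stem}.annotation.json", ann, regions)
        truth_path = prio.write_ground_truth(
            out_dir / f"{stem}.truth.json", truth, offset=shift
        )
        rows.append(
            {
                "image_id": stem,
                "image": tif.name,
                "annotation": ann_path.name,
                "truth": truth_path.name,
                "seed": placement_seed,
                "radius_nm": radius,
                "pore_half_angle_rad": half_angle,
                "tilt_rad": tilt,
                "pore_diameter_nm": vesicle.pore_diameter,
                "true_circumference_nm": truth.true_circumference,
                "n_rim_particles": len(scene.rim_particles),
                "n_background_particles": len(scene.background_particles),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    config.to_yaml(out_dir / "config.yaml")
    return manifest


def _pair_inputs(in_dir: Path):
    images = sorted(
        p for p in in_dir.iterdir()
        if p.suffix.lower() in IMAGE_SUFFIXES
    )
    pairs, orphan_images = [], []
    for img in images:
        ann = img.with_name(img.stem + ".annotation.json")
        if ann.exists():
            pairs.append((img, ann))
        else:
            orphan_images.append(img.name)
    ann_files = {p.name for p in in_dir.glob("*.annotation.json")}
    used = {a.name for _, a in pairs}
    orphan_anns = sorted(ann_files - used)
    if not pairs or orphan_images or orphan_anns:
        if not pairs and not orphan_images and not orphan_anns:
            raise PairedInputError(f"no images or annotations found in {in_dir}")
        if orphan_images or orphan_anns:
            raise PairedInputError(
                "unpaired inputs — images without annotations: "
                f"{orphan_images}; annotations without images: {orphan_anns}"
            )
    return pairs


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_measure(
    in_dir,
    out_dir,
    config: RunConfig | None = None,
    pixel_size: float | None = None,
) -> dict:
    """Measure a directory of image/annotation pairs.

    Emits densities.csv, pores.csv, distances.csv, tests.csv, summary.json
    and run.log.  Returns the summary dict.
    """
    if config is None:
        config = RunConfig()
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = _pair_inputs(in_dir)
    det_params = config.detection_params()

    density_rows, pore_rows, distance_rows, log_lines = [], [], [], []
    pore_records = []
    log_lines.append(
        f"detection band [{det_params.band_low}, {det_params.band_high}] "
        f"min_area {det_params.min_area} nm^2 connectivity {det_params.connectivity}"
    )
    log_lines.append(f"seed {config.seed}")

    for img_path, ann_path in pairs:
        image = prio.read_image(img_path, pixel_size=pixel_size)
        ann, regions = prio.read_annotation(ann_path)
        clusters = detect_particles(image, det_params)
        stem = img_path.stem

        circ = circularity(ann.edge)
        tilt_class = classify_orientation(circ, en_face_cutoff=config.en_face_cutoff)

        outer_poly = RoiPolygon(
            boundary=Polyline(ann.outer.vertices.copy(), closed=True), label="pore"
        )
        inner_shape = sgeom.Polygon(ann.inner.vertices)
        rim_clusters = [
            c
            for c in clusters
            if point_in_polygon(c.centroid, outer_poly)
            and not inner_shape.contains(sgeom.Point(c.centroid))
        ]
        perimeter = pore_perimeter(ann)
        record = PoreRecord(
            pore_id=stem,
            perimeter=perimeter,
            particle_area=total_cluster_area(rim_clusters),
            particle_count=len(rim_clusters),
            tilt_class=tilt_class,
        )
        pore_records.append(record)
        pore_rows.append(
            {
                "pore_id": stem,
                "perimeter_nm": record.perimeter,
                "particle_area_nm2": record.particle_area,
                "particle_count": record.particle_count,
                "spacing_nm": record.spacing,
                "circularity": circ,
                "tilt_class": tilt_class,
            }
        )
        for region in regions:
            rec = region_density(clusters, region, normalization=config.normalization)
            density_rows.append(
                {
                    "image_id": stem,
                    "region_label": rec.region_label,
                    "cluster_area_nm2": rec.cluster_area,
                    "region_area_nm2": rec.region_area,
                    "density": rec.density,
                }
            )
        for c in rim_clusters:
            distance_rows.append(
                {
                    "image_id": stem,
                    "centroid_x_nm": c.centroid[0],
                    "centroid_y_nm": c.centroid[1],
                    "area_nm2": c.area,
                    "distance_nm": min_edge_distance(c.centroid, ann.edge),
                }
            )
        log_lines.append(
            f"{img_path.name} sha256 {_sha256(img_path)} "
            f"clusters {len(clusters)} rim_clusters {len(rim_clusters)}"
        )

    densities = pd.DataFrame(
        density_rows,
        columns=["image_id", "region_label", "cluster_area_nm2",
                 "region_area_nm2", "density"],
    )
    pores = pd.DataFrame(
        pore_rows,
        columns=["pore_id", "perimeter_nm", "particle_area_nm2",
                 "particle_count", "spacing_nm", "circularity", "tilt_class"],
    )
    distances = pd.DataFrame(
        distance_rows,
        columns=["image_id", "centroid_x_nm", "centroid_y_nm",
                 "area_nm2", "distance_nm"],
    )

    test_rows = []
    pore_d = densities.loc[densities.region_label == "pore", "density"].to_numpy()
    nonpore_d = densities.loc[densities.region_label == "non_pore", "density"].to_numpy()
    if len(pore_d) >= 1 and len(nonpore_d) >= 1:
        res = mann_whitney(pore_d, nonpore_d)
        test_rows.append(
            {
                "comparison": "pore_vs_non_pore_density",
                "u_statistic": res.u_statistic,
                "p_value": res.p_value,
                "method": res.method,
                "n1": res.n1,
                "n2": res.n2,
            }
        )
    tests = pd.DataFrame(
        test_rows,
        columns=["comparison", "u_statistic", "p_value", "method", "n1", "n2"],
    )

    summary: dict = {"n_images": len(pairs), "seed": config.seed}
    counted = [r for r in pore_records if r.particle_count > 0]
    if counted:
        total_perim = sum(r.perimeter for r in counted)
        total_count = sum(r.particle_count for r in counted)
        summary["pooled_spacing_nm"] = total_perim / total_count
        summary["mean_spacing_nm"] = float(
            np.mean([r.spacing for r in counted])
        )
    if len(pore_records) >= 3 and np.ptp([r.perimeter for r in pore_records]) > 0:
        reg = density_vs_circumference_regression(pore_records)
        summary["regression"] = {
            "slope_nm": reg.slope,
            "intercept_nm2": reg.intercept,
            "r_squared": reg.r_squared,
            "n": reg.n,
            "slope_through_origin_nm": reg.slope_through_origin,
        }

    densities.to_csv(out_dir / "densities.csv", index=False)
    pores.to_csv(out_dir / "pores.csv", index=False)
    distances.to_csv(out_dir / "distances.csv", index=False)
    tests.to_csv(out_dir / "tests.csv", index=False)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


def run_report(measure_dir, plot: bool = False) -> str:
    """Summarize a measurement directory as plain text; optionally save a
    particle-area-vs-perimeter scatter plot."""
    measure_dir = Path(measure_dir)
    pores = pd.read_csv(measure_dir / "pores.csv")
    tests = pd.read_csv(measure_dir / "tests.csv")
    summary = json.loads((measure_dir / "summary.json").read_text())
    lines = [f"images analyzed: {summary.get('n_images', len(pores))}"]
    if len(pores):
        lines.append(
            f"pores: {len(pores)}; mean perimeter "
            f"{pores.perimeter_nm.mean():.1f} nm; mean particle count "
            f"{pores.particle_count.mean():.1f}"
        )
    if "pooled_spacing_nm" in summary:
        lines.append(f"pooled interparticle spacing: {summary['pooled_spacing_nm']:.2f} nm")
    if "regression" in summary:
        reg = summary["regression"]
        lines.append(
            "area vs perimeter regression: slope "
            f"{reg['slope_nm']:.3f} nm, intercept {reg['intercept_nm2']:.2f} nm^2, "
            f"R^2 {reg['r_squared']:.3f} (n = {reg['n']})"
        )
    for _, row in tests.iterrows():
        lines.append(
            f"{row.comparison}: U = {row.u_statistic:.1f}, "
            f"p = {row.p_value:.4g} ({row.method}, n1 = {row.n1}, n2 = {row.n2})"
        )
    text = "\n".join(lines)
    if plot and len(pores):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(pores.perimeter_nm, pores.particle_area_nm2, s=18)
        ax.set_xlabel("pore perimeter (nm)")
        ax.set_ylabel("total particle area (nm$^2$)")
        ax.set_xlim(left=0)
        ax.set_ylim(bottom=0)
        fig.tight_layout()
        fig.savefig(measure_dir / "area_vs_perimeter.png", dpi=150)
        plt.close(fig)
    (measure_dir / "report.txt").write_text(text + "\n")
    return text
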