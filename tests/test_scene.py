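import math

import numpy as np
import pytest

from porerim.detect import DetectionParams, detect_particles
from porerim.errors import ParameterError, ValidationError
from porerim.geometry import polyline_length
from porerim.scene import (
    EXTERIOR_INTENSITY,
    GOLD_INTENSITY,
    Orientation,
    Particle3D,
    PlacementParams,
    VesicleModel,
    eligible_background_area,
    image_offset,
    make_scene,
    place_background_particles,
    place_rim_particles,
    project_scene,
    render_image,
)

from conftest import disk_pixel_count, ellipse_perimeter_quad


def circ_vesicle(circumference=120.0, radius=100.0):
    """Vesicle whose rim circumference is exactly the requested value."""
    half_angle = math.asin(circumference / (2 * math.pi * radius))
    return VesicleModel(radius=radius, pore_half_angle=half_angle)


class TestValidation:
    def test_rim_radius_definition(self):
        v = VesicleModel(radius=100.0, pore_half_angle=0.2)
        assert v.rim_radius == pytest.approx(100 * math.sin(0.2))
        assert v.rim_radius == pytest.approx(19.87, abs=0.01)

    def test_degenerate_pore_rejected(self):
        with pytest.raises(ValidationError, match="pore_half_angle"):
            VesicleModel(radius=100.0, pore_half_angle=0.0)

    def test_bad_radius_and_thickness(self):
        with pytest.raises(ValidationError, match="radius"):
            VesicleModel(radius=-5.0)
        with pytest.raises(ValidationError, match="membrane_thickness"):
            VesicleModel(radius=4.0, membrane_thickness=4.0)

    def test_edge_on_accepted_and_flagged(self):
        o = Orientation(tilt=np.pi / 2)
        assert o.is_edge_on
        scene = make_scene(VesicleModel(radius=50.0), o)
        assert scene.orientation.is_edge_on

    def test_tilt_out_of_range(self):
        with pytest.raises(ValidationError, match="tilt"):
            Orientation(tilt=2.0)

    def test_particle_validation(self):
        with pytest.raises(ValidationError, match="diameter"):
            Particle3D(position=np.zeros(3), diameter=0.0, particle_class="rim")
        with pytest.raises(ValidationError, match="particle_class"):
            Particle3D(position=np.zeros(3), diameter=1.0, particle_class="gold")

    def test_placement_params_validation(self):
        with pytest.raises(ValidationError, match="linear_density"):
            PlacementParams(linear_density=-1.0)
        with pytest.raises(ValidationError, match="labeling_efficiency"):
            PlacementParams(labeling_efficiency=1.5)


class TestRimPlacement:
    def test_zero_density_zero_particles(self):
        scene = make_scene(circ_vesicle(), Orientation())
        scene = place_rim_particles(scene, PlacementParams(linear_density=0.0))
        assert len(scene.particles) == 0

    def test_fixed_count_mode(self):
        scene = make_scene(circ_vesicle(120.0), Orientation())
        p = PlacementParams(linear_density=1 / 6, count_mode="fixed", seed=1)
        scene = place_rim_particles(scene, p)
        assert len(scene.rim_particles) == 20

    def test_sanity_cap(self):
        scene = make_scene(circ_vesicle(), Orientation())
        with pytest.raises(ParameterError):
            place_rim_particles(scene, PlacementParams(linear_density=1e5))

    def test_poisson_mean_monte_carlo(self):
        # lambda * p * C = 20; sample mean over 500 seeds within 3 SE
        scene = make_scene(circ_vesicle(120.0), Orientation())
        counts = [
            len(place_rim_particles(scene, PlacementParams(
                linear_density=1 / 6, seed=s)).rim_particles)
            for s in range(500)
        ]
        se = math.sqrt(20.0 / 500)
        assert abs(np.mean(counts) - 20.0) <= 3 * se

    def test_labeling_efficiency_thins_mean(self):
        # lambda=1/6, p=0.8, C=120 -> mean 16 over 1000 seeds
        scene = make_scene(circ_vesicle(120.0), Orientation())
        counts = [
            len(place_rim_particles(scene, PlacementParams(
                linear_density=1 / 6, labeling_efficiency=0.8,
                seed=s)).rim_particles)
            for s in range(1000)
        ]
        se = math.sqrt(16.0 / 1000)
        assert abs(np.mean(counts) - 16.0) <= 3 * se

    def test_deterministic_given_seed(self):
        scene = make_scene(circ_vesicle(), Orientation())
        p = PlacementParams(linear_density=1 / 6, seed=42)
        s1 = place_rim_particles(scene, p)
        s2 = place_rim_particles(scene, p)
        assert len(s1.particles) == len(s2.particles)
        for a, b in zip(s1.particles, s2.particles):
            assert np.array_equal(a.position, b.position)

    def test_particles_on_membrane_sphere(self):
        v = circ_vesicle()
        scene = place_rim_particles(
            make_scene(v, Orientation()),
            PlacementParams(linear_density=1.0, seed=3),
        )
        for p in scene.particles:
            r = np.linalg.norm(p.position)
            assert v.radius - v.membrane_thickness <= r <= v.radius + 1e-9


class TestBackgroundPlacement:
    def test_zero_density(self):
        scene = make_scene(circ_vesicle(), Orientation())
        scene = place_background_particles(scene, PlacementParams())
        assert len(scene.particles) == 0

    def test_full_sphere_expected_count(self):
        # vanishing pore + no exclusion band: eligible area -> 4*pi*R^2
        v = VesicleModel(radius=50.0, pore_half_angle=1e-6)
        assert eligible_background_area(v, 0.0) == pytest.approx(
            4 * np.pi * 50.0 ** 2, rel=1e-9
        )
        rho = 0.001
        expected = 4 * np.pi * 2500.0 * rho
        counts = [
            len(place_background_particles(
                make_scene(v, Orientation()),
                PlacementParams(background_area_density=rho,
                                rim_exclusion_nm=0.0, seed=s)).particles)
            for s in range(300)
        ]
        se = math.sqrt(expected / 300)
        assert abs(np.mean(counts) - expected) <= 3 * se

    def test_exclusion_band_brute_force(self):
        # no background particle within 5 nm of the rim (3D check on truth)
        v = VesicleModel(radius=60.0, pore_half_angle=0.5)
        scene = place_background_particles(
            make_scene(v, Orientation(tilt=0.3)),
            PlacementParams(background_area_density=0.01, rim_exclusion_nm=5.0,
                            seed=11),
        )
        assert len(scene.particles) > 50
        # brute-force distance oracle against a dense rim sampling
        phi = np.linspace(0, 2 * np.pi, 20_000, endpoint=False)
        rim = np.column_stack([
            v.rim_radius * np.cos(phi),
            v.rim_radius * np.sin(phi),
            np.full_like(phi, v.rim_height),
        ])
        chord = 2 * v.radius * math.sin(5.0 / (2 * v.radius))  # geodesic 5 nm
        for p in scene.particles:
            d = np.linalg.norm(rim - p.position, axis=1).min()
            assert d >= chord - 1e-6

    def test_outside_pore_cap(self):
        v = VesicleModel(radius=60.0, pore_half_angle=0.5)
        scene = place_background_particles(
            make_scene(v, Orientation()),
            PlacementParams(background_area_density=0.01, seed=4),
        )
        for p in scene.particles:
            polar = math.acos(p.position[2] / v.radius)
            assert polar > v.pore_half_angle


class TestProjection:
    def test_en_face_rim_is_circle(self):
        v = VesicleModel(radius=100.0, pore_half_angle=0.2)
        gt = project_scene(make_scene(v, Orientation(tilt=0.0)))
        radii = np.linalg.norm(gt.projected_rim.vertices, axis=1)
        assert np.allclose(radii, v.rim_radius, atol=1e-9)

    def test_tilted_semi_minor_axis(self):
        v = circ_vesicle(2 * np.pi * 10.0)  # rim radius 10
        gt = project_scene(make_scene(v, Orientation(tilt=np.pi / 3)))
        verts = gt.projected_rim.vertices - gt.projected_rim.vertices.mean(axis=0)
        cov = np.cov(verts.T)
        semi = np.sqrt(2 * np.sort(np.linalg.eigvalsh(cov))[::-1])
        assert semi[0] == pytest.approx(10.0, rel=1e-2)
        assert semi[1] == pytest.approx(5.0, rel=1e-2)

    def test_projected_rim_length_matches_ellipse_integral(self):
        v = circ_vesicle(2 * np.pi * 10.0)
        gt = project_scene(make_scene(v, Orientation(tilt=np.pi / 3)))
        expected = ellipse_perimeter_quad(10.0, 5.0)
        assert polyline_length(gt.projected_rim) == pytest.approx(expected, rel=1e-3)
        assert polyline_length(gt.projected_rim) == pytest.approx(48.44, abs=0.05)

    def test_true_circumference_identity(self):
        v = VesicleModel(radius=123.4, pore_half_angle=0.37)
        gt = project_scene(make_scene(v, Orientation(tilt=0.5)))
        expected = np.pi * 2 * 123.4 * math.sin(0.37)
        assert abs(gt.true_circumference - expected) / expected < 1e-9

    def test_rim_particle_truth_distance_bounded(self):
        params = PlacementParams(linear_density=0.5, rim_jitter_sd=0.4, seed=9)
        scene = place_rim_particles(
            make_scene(VesicleModel(radius=80.0), Orientation(tilt=0.2)), params
        )
        gt = project_scene(scene)
        bound = 3 * params.rim_jitter_sd + params.diameter_mean
        for p in gt.particles_2d:
            assert p.distance_to_rim <= bound


class TestRender:
    def test_empty_scene_background(self):
        scene = make_scene(VesicleModel(radius=40.0), Orientation())
        img = render_image(scene, 0.5)
        # darkest feature is the membrane shell; no gold band pixels at all
        assert img.intensities.max() == EXTERIOR_INTENSITY
        assert not np.any((img.intensities >= 30) & (img.intensities <= 50))

    def test_single_particle_pixel_count(self):
        v = VesicleModel(radius=40.0)
        scene = make_scene(v, Orientation())
        # particle at the rim, en face
        pos = np.array([v.rim_radius, 0.0, v.rim_height])
        scene = scene.__class__(
            vesicle=v, orientation=scene.orientation,
            particles=(Particle3D(position=pos, diameter=1.3,
                                  particle_class="rim"),),
        )
        px = 0.2
        img = render_image(scene, px)
        n_gold = int(np.sum(img.intensities == GOLD_INTENSITY))
        half = image_offset(v)
        n_px = img.shape[0]
        oracle = disk_pixel_count(pos[0] + half, pos[1] + half, 0.65, px, n_px)
        assert n_gold == oracle
        assert n_gold == pytest.approx(np.pi * 0.65 ** 2 / px ** 2, abs=5)

    def test_determinism_with_noise(self):
        scene = place_rim_particles(
            make_scene(VesicleModel(radius=50.0), Orientation(tilt=0.4)),
            PlacementParams(linear_density=0.2, seed=5),
        )
        a = render_image(scene, 0.4, noise_sd=8.0, seed=17)
        b = render_image(scene, 0.4, noise_sd=8.0, seed=17)
        assert np.array_equal(a.intensities, b.intensities)
        c = render_image(scene, 0.4, noise_sd=8.0, seed=18)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_coarse_pixel_warning(self, caplog):
        v = VesicleModel(radius=40.0)
        scene = place_rim_particles(
            make_scene(v, Orientation()),
            PlacementParams(linear_density=0.05, seed=2),
        )
        with caplog.at_level("WARNING", logger="porerim.scene"):
            render_image(scene, 2.0)
        assert any("covers < 1 pixel" in r.message for r in caplog.records)

    def test_noise_free_detection_recall(self):
        # well separated rim particles: every one detected, nothing else
        v = VesicleModel(radius=60.0, pore_half_angle=0.5)
        phi = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        particles = tuple(
            Particle3D(
                position=np.array([
                    v.rim_radius * np.cos(a), v.rim_radius * np.sin(a),
                    v.rim_height,
                ]),
                diameter=1.3,
                particle_class="rim",
            )
            for a in phi
        )
        scene = make_scene(v, Orientation())
        scene = scene.__class__(vesicle=v, orientation=scene.orientation,
                                particles=particles)
        img = render_image(scene, 0.2)
        clusters = detect_particles(img, DetectionParams())
        assert len(clusters) == 8
        half = image_offset(v)
        gt = project_scene(scene)
        truth = np.array([p.position_2d for p in gt.particles_2d]) + half
        for c in clusters:
            assert np.min(np.linalg.norm(truth - c.centroid, axis=1)) < 0.15
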