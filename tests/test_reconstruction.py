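import dataclasses

import numpy as np
import pytest

from carmplan.frustum import Frustum, backproject_pixel, project_point
from carmplan.geometry import Ray, apply, compose
from carmplan.reconstruction import (
    Annotation,
    DegenerateRaysError,
    Trajectory3D,
    annotation_ray,
    trajectory_from_views,
    triangulate,
)
from carmplan.simulate import orbit_frustums
from conftest import random_transform


def brute_force_closest_point(rays, center, half_width, resolution):
    """Independent oracle: coarse-to-fine grid search of the ray-distance
    objective down to `resolution` mm."""

    def cost(pts):
        total = np.zeros(pts.shape[0])
        for r in rays:
            P = np.eye(3) - np.outer(r.direction, r.direction)
            total += np.sum(((pts - r.origin) @ P.T) ** 2, axis=1)
        return total

    best = np.asarray(center, float)
    width = half_width
    while width > resolution / 2:
        axes = [np.linspace(best[i] - width, best[i] + width, 11) for i in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        best = grid[np.argmin(cost(grid))]
        width /= 5.0
    return best


class TestTriangulate:
    def test_two_orthogonal_rays_exact(self):
        p = np.array([10.0, -5.0, 30.0])
        rays = [Ray(p - [50, 0, 0], [1, 0, 0]), Ray(p - [0, 50, 0], [0, 1, 0])]
        rec = triangulate(rays)
        np.testing.assert_allclose(rec.x_star, p, atol=1e-12)
        assert rec.residual == pytest.approx(0.0, abs=1e-12)
        assert rec.n_rays == 2

    def test_parallel_rays_degenerate(self):
        rays = [Ray([0, 0, 0], [0, 0, 1]), Ray([5, 0, 0], [0, 0, 1])]
        with pytest.raises(DegenerateRaysError):
            triangulate(rays)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            triangulate([Ray([0, 0, 0], [0, 0, 1])])

    def test_noisy_four_rays_match_grid_search_oracle(self, rng):
        truth = np.array([4.0, -6.0, 12.0])
        rays = []
        for _ in range(4):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            perp = np.cross(d, rng.normal(size=3))
            perp /= np.linalg.norm(perp)
            origin = truth - 300.0 * d + 0.5 * rng.normal() * perp
            rays.append(Ray(origin, d))
        rec = triangulate(rays)
        oracle = brute_force_closest_point(rays, truth, half_width=3.0, resolution=0.01)
        assert np.linalg.norm(rec.x_star - oracle) < 0.01
        assert rec.residual > 0

    def test_two_rays_equal_midpoint_of_common_perpendicular(self, rng):
        """Classical closed form: midpoint of the shortest segment between
        two skew lines."""
        for _ in range(10):
            o1, o2 = rng.uniform(-50, 50, 3), rng.uniform(-50, 50, 3)
            d1, d2 = rng.normal(size=3), rng.normal(size=3)
            d1, d2 = d1 / np.linalg.norm(d1), d2 / np.linalg.norm(d2)
            if np.linalg.norm(np.cross(d1, d2)) < 0.1:
                continue
            # closed-form parameters of the mutual perpendicular feet
            w = o1 - o2
            a, b, c = d1 @ d1, d1 @ d2, d2 @ d2
            d_, e_ = d1 @ w, d2 @ w
            s = (b * e_ - c * d_) / (a * c - b * b)
            t = (a * e_ - b * d_) / (a * c - b * b)
            midpoint = ((o1 + s * d1) + (o2 + t * d2)) / 2.0
            rec = triangulate([Ray(o1, d1), Ray(o2, d2)])
            np.testing.assert_allclose(rec.x_star, midpoint, atol=1e-9)

    def test_reprojection_consistency(self, two_view_frustums, rng):
        p = np.array([8.0, 3.0, -12.0])
        anns = []
        for fr in two_view_frustums:
            px = project_point(fr, p) + rng.normal(0, 1.0, 2)
            anns.append(Annotation(fr.frustum_id, px))
        rays = [annotation_ray(fr, a) for fr, a in zip(two_view_frustums, anns)]
        rec = triangulate(rays)
        for fr, a in zip(two_view_frustums, anns):
            depth = (rec.x_star - fr.source_center) @ fr.principal_axis
            bound = rec.residual * (fr.intrinsics.focal_length / depth) / fr.intrinsics.pixel_spacing
            err = np.linalg.norm(project_point(fr, rec.x_star) - a.pixel)
            # the paraxial bound picks up a small obliquity factor off-axis
            assert err <= 1.005 * bound + 1e-6

    def test_rigid_invariance(self, two_view_frustums, rng):
        p = np.array([8.0, 3.0, -12.0])
        rays = [backproject_pixel(fr, project_point(fr, p)) for fr in two_view_frustums]
        rec = triangulate(rays)
        G = random_transform(rng)
        moved = [
            dataclasses.replace(fr, source_pose=compose(G, fr.source_pose))
            for fr in two_view_frustums
        ]
        rays2 = [
            backproject_pixel(fr2, backproject_px)
            for fr2, backproject_px in zip(
                moved, [project_point(fr, p) for fr in two_view_frustums]
            )
        ]
        rec2 = triangulate(rays2)
        np.testing.assert_allclose(rec2.x_star, apply(G, rec.x_star), atol=1e-9)


class TestAnnotationRay:
    def test_principal_point_gives_principal_axis(self):
        fr = Frustum()
        ray = annotation_ray(fr, Annotation("", fr.intrinsics.principal_point))
        np.testing.assert_allclose(ray.direction, [0, 0, 1], atol=1e-12)

    def test_round_trip_unit_norm(self, two_view_frustums, rng):
        fr = two_view_frustums[1]
        p = rng.uniform(-40, 40, 3)
        ann = Annotation(fr.frustum_id, project_point(fr, p))
        ray = annotation_ray(fr, ann)
        assert np.linalg.norm(ray.direction) == pytest.approx(1.0, abs=1e-12)
        v = p - ray.origin
        assert np.linalg.norm(v - (v @ ray.direction) * ray.direction) < 1e-9


class TestTrajectoryFromViews:
    def _project_line(self, fr, a, b):
        return project_point(fr, a), project_point(fr, b)

    def test_noiseless_two_views_60deg(self):
        frs = orbit_frustums([0, 0, 0], [0.0, 60.0])
        entry = np.array([6.0, -9.0, -35.0])
        exit_ = np.array([-4.0, 7.0, 38.0])
        ea, xa = self._project_line(frs[0], entry, exit_)
        eb, xb = self._project_line(frs[1], entry, exit_)
        traj = trajectory_from_views(ea, xa, frs[0], eb, xb, frs[1])
        truth = (exit_ - entry) / np.linalg.norm(exit_ - entry)
        angle = np.degrees(np.arccos(np.clip(traj.direction @ truth, -1, 1)))
        assert angle < 1e-9
        assert traj.distance_to_point(entry) < 1e-9
        assert traj.distance_to_point(exit_) < 1e-9

    def test_identical_views_degenerate(self, two_view_frustums):
        fr = two_view_frustums[0]
        entry, exit_ = np.array([6.0, -9.0, -35.0]), np.array([-4.0, 7.0, 38.0])
        ea, xa = self._project_line(fr, entry, exit_)
        with pytest.raises(DegenerateRaysError):
            trajectory_from_views(ea, xa, fr, ea, xa, fr)

    def test_direction_oriented_entry_to_exit(self, two_view_frustums):
        entry, exit_ = np.array([6.0, -9.0, -35.0]), np.array([-4.0, 7.0, 38.0])
        ea, xa = self._project_line(two_view_frustums[0], entry, exit_)
        eb, xb = self._project_line(two_view_frustums[1], entry, exit_)
        traj = trajectory_from_views(ea, xa, two_view_frustums[0], eb, xb, two_view_frustums[1])
        assert traj.direction @ (exit_ - entry) > 0

    def test_noisy_monte_carlo_bounded(self, two_view_frustums, rng):
        entry, exit_ = np.array([6.0, -9.0, -35.0]), np.array([-4.0, 7.0, 38.0])
        truth = (exit_ - entry) / np.linalg.norm(exit_ - entry)
        angles, dists = [], []
        for _ in range(50):
            pxs = []
            for fr in two_view_frustums:
                pxs.append(project_point(fr, entry) + rng.normal(0, 1.0, 2))
                pxs.append(project_point(fr, exit_) + rng.normal(0, 1.0, 2))
            traj = trajectory_from_views(
                pxs[0], pxs[1], two_view_frustums[0], pxs[2], pxs[3], two_view_frustums[1]
            )
            angles.append(np.degrees(np.arccos(np.clip(abs(traj.direction @ truth), 0, 1))))
            dists.append(traj.distance_to_point(entry))
        # 1 px ~ 0.18 mm at the isocenter; 90 deg separation keeps errors small
        assert np.mean(angles) < 2.0 and np.max(dists) < 3.0
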