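"""Geometry invariants of the periodic substrates."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from dexsy.substrates import (EXTRACELLULAR, PlacementError,
                              build_cylinder_substrate,
                              build_sphere_substrate, first_intersection,
                              load_substrate, locate, save_substrate)


def _min_image(d, box):
    return d - box * np.round(d / box)


class TestCylinderSubstrate:
    def test_default_build_is_valid_and_deterministic(self):
        sub = build_cylinder_substrate(seed=3)
        assert sub.n_cylinders == 100
        assert np.all(sub.radii > 0)
        d = _min_image(sub.centers[:, None] - sub.centers[None, :],
                       sub.lattice_size)
        dist = np.linalg.norm(d, axis=-1)
        np.fill_diagonal(dist, np.inf)
        assert np.all(dist >= sub.radii[:, None] + sub.radii[None, :])
        again = build_cylinder_substrate(seed=3)
        np.testing.assert_array_equal(sub.centers, again.centers)
        np.testing.assert_array_equal(sub.radii, again.radii)

    def test_radii_follow_the_gamma_distribution(self):
        # moments over many builds match shape*scale within 1%
        shape, scale = 5.3316, 1.0242e-7
        draws = np.concatenate([
            build_cylinder_substrate(seed=s).radii for s in range(20)])
        rng = np.random.default_rng(0)
        big = rng.gamma(shape, scale, 100_000)
        assert abs(big.mean() - shape * scale) / (shape * scale) < 0.01
        # the placed radii are an unbiased subsample of that distribution
        assert abs(draws.mean() - shape * scale) / (shape * scale) < 0.05

    def test_single_cylinder_is_trivially_placed(self):
        sub = build_cylinder_substrate(n_cylinders=1, seed=0)
        assert sub.n_cylinders == 1

    def test_unpackable_density_raises_with_achieved_fraction(self):
        with pytest.raises(PlacementError, match="area fraction"):
            build_cylinder_substrate(gamma_scale=1e-6, n_cylinders=100,
                                     lattice_size=1.65e-5, seed=0,
                                     max_attempts=50, max_redraws=2)


class TestSphereSubstrate:
    def test_box_side_from_packing_arithmetic(self):
        sub = build_sphere_substrate(seed=1)
        # n (4/3) pi r^3 / phi, cube root
        expected = (500 * 4 / 3 * np.pi * 2.5e-6**3 / 0.62) ** (1 / 3)
        assert sub.box_side == pytest.approx(expected, rel=1e-12)
        assert sub.box_side == pytest.approx(3.75e-5, rel=0.02)
        assert sub.radius == 2.5e-6

    def test_no_overlap_under_periodic_wrap(self):
        sub = build_sphere_substrate(seed=1)
        tree = cKDTree(sub.centers % sub.box_side, boxsize=sub.box_side)
        assert len(tree.query_pairs(2 * sub.radius)) == 0

    def test_single_sphere_box_side(self):
        sub = build_sphere_substrate(n_spheres=1, diameter=5e-6,
                                     packing_fraction=0.1, seed=0)
        v = 4 / 3 * np.pi * 2.5e-6**3
        assert sub.box_side == pytest.approx((v / 0.1) ** (1 / 3))

    def test_volume_fraction_by_uniform_sampling(self):
        sub = build_sphere_substrate(seed=2)
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, sub.box_side, (100_000, 3))
        tree = cKDTree(sub.centers % sub.box_side, boxsize=sub.box_side)
        dist, _ = tree.query(pts)
        assert (dist < sub.radius).mean() == pytest.approx(0.62, abs=0.01)

    def test_invalid_packing_fraction_rejected(self):
        with pytest.raises(ValueError):
            build_sphere_substrate(packing_fraction=0.7)


class TestLocate:
    def test_sphere_center_and_far_point(self):
        sub = build_sphere_substrate(seed=1)
        assert locate(sub, sub.centers[17]) == 17
        # a point on a sphere surface +2r along x from center 0 may be in
        # another sphere; craft a guaranteed-extracellular point instead
        rng = np.random.default_rng(3)
        from scipy.spatial import cKDTree
        tree = cKDTree(sub.centers % sub.box_side, boxsize=sub.box_side)
        while True:
            p = rng.uniform(0, sub.box_side, 3)
            if tree.query(p)[0] > sub.radius * 1.05:
                break
        assert locate(sub, p) == EXTRACELLULAR

    def test_periodic_translation_invariance(self):
        sub = build_sphere_substrate(seed=1)
        rng = np.random.default_rng(4)
        for _ in range(50):
            p = rng.uniform(0, sub.box_side, 3)
            shift = rng.integers(-2, 3, 3) * sub.box_side
            assert locate(sub, p) == locate(sub, p + shift)
        cyl = build_cylinder_substrate(seed=1)
        for _ in range(50):
            p = rng.uniform(0, cyl.lattice_size, 3)
            shift = np.append(rng.integers(-2, 3, 2) * cyl.lattice_size,
                              rng.normal() * 1e-5)
            assert locate(cyl, p) == locate(cyl, p + shift)


class TestFirstIntersection:
    def test_radial_exit_at_one_radius(self):
        sub = build_sphere_substrate(seed=1)
        c = sub.centers[0]
        hit = first_intersection(sub, c, c + [2 * sub.radius, 0, 0])
        pos, normal, idx = hit
        assert idx == 0
        assert np.linalg.norm(pos - c) == pytest.approx(sub.radius)
        np.testing.assert_allclose(normal, [1, 0, 0], atol=1e-12)

    def test_no_intersection_for_short_extracellular_segment(self):
        sub = build_sphere_substrate(seed=1)
        tree = cKDTree(sub.centers % sub.box_side, boxsize=sub.box_side)
        rng = np.random.default_rng(5)
        found = 0
        while found < 5:
            p = rng.uniform(0, sub.box_side, 3)
            gap = tree.query(p)[0] - sub.radius
            if gap > 1e-7:
                d = rng.normal(size=3)
                d *= 0.5 * gap / np.linalg.norm(d)
                assert first_intersection(sub, p, p + d) is None
                found += 1

    @pytest.mark.parametrize("kind", ["spheres", "cylinders"])
    def test_agrees_with_brute_force_quadratic(self, kind):
        # oracle: per-object quadratic roots with explicit min-image, no
        # acceleration structure
        if kind == "spheres":
            sub = build_sphere_substrate(seed=6)
            box, centers = sub.box_side, sub.centers
            radii = np.full(len(centers), sub.radius)
            ndim = 3
        else:
            sub = build_cylinder_substrate(seed=6)
            box, centers, radii = sub.lattice_size, sub.centers, sub.radii
            ndim = 2
        rng = np.random.default_rng(8)
        for _ in range(2000):
            p0 = rng.uniform(0, box, 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            seg = 0.6e-6 * d
            hit = first_intersection(sub, p0, p0 + seg)
            # brute force over every object
            best = (np.inf, None)
            u = seg[:ndim] / np.linalg.norm(seg[:ndim]) \
                if np.linalg.norm(seg[:ndim]) > 0 else None
            if u is not None:
                seg_len = np.linalg.norm(seg[:ndim])
                for k in range(len(centers)):
                    m = _min_image(centers[k] - p0[:ndim], box)
                    b = m @ u
                    disc = b * b - (m @ m - radii[k] ** 2)
                    if disc < 0:
                        continue
                    sq = np.sqrt(disc)
                    for s in (b - sq, b + sq):
                        if 0 < s <= seg_len and s < best[0]:
                            best = (s, k)
            if hit is None:
                assert best[1] is None
            else:
                assert best[1] == hit[2]
                s_hit = np.linalg.norm((hit[0] - p0)[:ndim])
                assert s_hit == pytest.approx(best[0], rel=1e-9)


def test_serialization_roundtrip(tmp_path):
    for build, name in [(build_sphere_substrate, "s"),
                        (build_cylinder_substrate, "c")]:
        sub = build(seed=9)
        path = tmp_path / f"{name}.txt"
        save_substrate(sub, path)
        back = load_substrate(path)
        np.testing.assert_allclose(back.centers, sub.centers)
        assert type(back) is type(sub)
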