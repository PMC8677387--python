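import numpy as np
import pytest
from scipy import ndimage

from liverseg.registration import BoundaryPointSet, extract_surface_points
from liverseg.void_filling import (
    VoidFillConfig,
    dual_contour,
    fill_voids,
    make_well_composed,
    octree_decompose,
    parity_label,
    prune_redundant_points,
    voxelize_points,
)
from liverseg.volume_io import Mask

BALL6 = ndimage.generate_binary_structure(3, 1)
SPHERE_R, SPHERE_N = 20.0, 56
SPHERE_VOLUME = 4.0 / 3.0 * np.pi * SPHERE_R**3


def exterior_flood_fill(shell):
    """Brute-force oracle: background reachable from the volume border."""
    lab, _ = ndimage.label(~shell, structure=BALL6)
    border = np.unique(
        np.r_[lab[0].ravel(), lab[-1].ravel(), lab[:, 0].ravel(),
              lab[:, -1].ravel(), lab[:, :, 0].ravel(), lab[:, :, -1].ravel()]
    )
    return np.isin(lab, border[border > 0])


def analytic_shell(radius=12.0, n=32, thickness=1.0):
    g = np.indices((n, n, n)) - n / 2
    r = np.sqrt((g**2).sum(0))
    return np.abs(r - radius) <= thickness


class TestVoxelizePoints:
    def test_single_point_no_dilation(self):
        out = voxelize_points(BoundaryPointSet(points=[[4, 4, 4]]), (9, 9, 9), dilation=0)
        assert out.voxel_count == 1

    def test_single_point_l1_ball(self):
        out = voxelize_points(BoundaryPointSet(points=[[4, 4, 4]]), (9, 9, 9), dilation=1)
        assert out.voxel_count == 7

    def test_sphere_cloud_connects_after_dilation(self, sphere_points):
        shell = voxelize_points(sphere_points, (SPHERE_N,) * 3, dilation=1)
        _, n = ndimage.label(shell.data, structure=BALL6)
        assert n == 1

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            voxelize_points(BoundaryPointSet(points=[[9, 0, 0]]), (9, 9, 9))


class TestOctree:
    def test_leaves_partition_bounding_cube(self):
        shell = Mask(analytic_shell().astype(np.uint8))
        oc = octree_decompose(shell)
        total = sum(leaf.size**3 for leaf in oc.leaves)
        assert total == oc.root.size**3

    def test_empty_corner_stays_coarse(self):
        data = np.zeros((32, 32, 32), dtype=np.uint8)
        data[20:24, 20:24, 20:24] = 1
        oc = octree_decompose(Mask(data))
        coarse = [l for l in oc.leaves if l.size > 1 and not l.intersects_shell]
        assert any(l.origin == (0, 0, 0) for l in coarse)

    def test_shell_voxels_live_in_max_depth_leaves(self):
        data = np.zeros((16, 16, 16), dtype=np.uint8)
        data[5, 6, 7] = 1
        oc = octree_decompose(Mask(data))
        hits = [l for l in oc.leaves if l.intersects_shell]
        assert all(l.size == oc.leaf_size_at_max_depth for l in hits)
        (leaf,) = hits
        assert leaf.origin == (5, 6, 7)

    def test_empty_shell_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            octree_decompose(Mask(np.zeros((8, 8, 8), dtype=np.uint8)))


class TestParityLabel:
    def test_closed_shell_matches_flood_fill_oracle(self):
        shell = analytic_shell()
        mask = Mask(shell.astype(np.uint8))
        oc = octree_decompose(mask)
        labels = parity_label(oc, mask)
        oracle = (~exterior_flood_fill(shell)).astype(np.int8)
        assert np.array_equal(labels, oracle)

    def test_empty_label_field_when_shell_mask_blank(self):
        shell = analytic_shell()
        oc = octree_decompose(Mask(shell.astype(np.uint8)))
        blank = Mask(np.zeros_like(shell, dtype=np.uint8))
        assert parity_label(oc, blank).sum() == 0

    def test_open_shell_still_produces_cavity_free_solid(self):
        shell = analytic_shell()
        g = np.indices(shell.shape) - 16
        r = np.sqrt((g**2).sum(0))
        cap = (g[2] / np.maximum(r, 1e-9)) > np.cos(np.radians(30))
        open_shell = shell & ~cap
        mask = Mask(open_shell.astype(np.uint8))
        oc = octree_decompose(mask)
        labels = parity_label(oc, mask)
        ext = exterior_flood_fill(labels.astype(bool))
        assert np.array_equal(ext, ~labels.astype(bool))  # no cavities


class TestDualContour:
    def test_cube_mesh_watertight_genus_zero(self):
        labels = np.zeros((16, 16, 16), np.int8)
        labels[4:12, 4:12, 4:12] = 1
        oc = octree_decompose(Mask((labels > 0).astype(np.uint8)))
        mesh = dual_contour(oc, labels)
        assert mesh.watertight
        assert mesh.euler_characteristic == 2

    def test_sphere_mesh_volume_within_ten_percent(self):
        n, r = 40, 14.0
        g = np.indices((n, n, n)) - n / 2
        labels = ((g**2).sum(0) <= r * r).astype(np.int8)
        oc = octree_decompose(Mask(labels.astype(np.uint8)))
        mesh = dual_contour(oc, labels)
        assert mesh.watertight
        assert abs(mesh.enclosed_volume - 4 / 3 * np.pi * r**3) < 0.1 * 4 / 3 * np.pi * r**3

    def test_two_blobs_give_two_components(self):
        labels = np.zeros((24, 24, 24), np.int8)
        labels[3:8, 3:8, 3:8] = 1
        labels[14:20, 14:20, 14:20] = 1
        oc = octree_decompose(Mask((labels > 0).astype(np.uint8)))
        mesh = dual_contour(oc, labels)
        assert mesh.as_trimesh.body_count == 2

    def test_no_interface_rejected(self):
        labels = np.zeros((8, 8, 8), np.int8)
        labels[3, 3, 3] = 1
        oc = octree_decompose(Mask((labels > 0).astype(np.uint8)))
        with pytest.raises(ValueError, match="sign change"):
            dual_contour(oc, np.zeros((8, 8, 8), np.int8))

    def test_well_composed_repair_only_adds_voxels(self):
        rng = np.random.default_rng(0)
        labels = (rng.random((12, 12, 12)) > 0.6).astype(np.int8)
        repaired = make_well_composed(labels)
        assert (repaired >= labels).all()


class TestFillVoids:
    def test_complete_sphere_cloud(self, sphere_points):
        mesh, solid = fill_voids(sphere_points, (SPHERE_N,) * 3)
        assert mesh.watertight
        assert mesh.euler_characteristic == 2
        g = np.indices((SPHERE_N,) * 3) - SPHERE_N / 2
        ball = (g**2).sum(0) <= SPHERE_R**2
        s = solid.data.astype(bool)
        voe = 100 * (1 - (s & ball).sum() / (s | ball).sum())
        assert voe < 10.0

    def test_capped_sphere_watertight_and_volume_preserved(self, capped_sphere_points):
        mesh, solid = fill_voids(capped_sphere_points, (SPHERE_N,) * 3)
        assert mesh.watertight
        assert mesh.euler_characteristic == 2
        assert abs(solid.voxel_count - SPHERE_VOLUME) < 0.15 * SPHERE_VOLUME
        # cavity-free: exterior flood fill reaches every background voxel
        ext = exterior_flood_fill(solid.data.astype(bool))
        assert np.array_equal(ext, solid.data == 0)

    def test_solid_contains_its_own_erosion(self, sphere_points):
        _, solid = fill_voids(sphere_points, (SPHERE_N,) * 3)
        er = ndimage.binary_erosion(solid.data.astype(bool), structure=BALL6)
        assert (solid.data.astype(bool) | er).sum() == solid.voxel_count

    def test_idempotent_within_two_percent(self, sphere_points):
        _, solid = fill_voids(sphere_points, (SPHERE_N,) * 3)
        surface = extract_surface_points(solid)
        _, solid2 = fill_voids(surface, (SPHERE_N,) * 3)
        change = abs(int(solid2.voxel_count) - int(solid.voxel_count)) / solid.voxel_count
        assert change < 0.02

    def test_degenerate_cloud_rejected(self):
        flat = BoundaryPointSet(points=[[1, 1, 1], [1, 2, 1], [1, 3, 1], [1, 4, 1]])
        with pytest.raises(ValueError, match="non-coplanar"):
            fill_voids(flat, (8, 8, 8))


class TestPrune:
    def test_on_surface_points_kept_and_outlier_removed(self, sphere_points):
        mesh, _ = fill_voids(sphere_points, (SPHERE_N,) * 3)
        vert_vox = np.round(mesh.vertices).astype(int)
        vert_vox = np.unique(np.clip(vert_vox, 0, SPHERE_N - 1), axis=0)
        outlier = np.array([[1, 1, 1]])
        pts = BoundaryPointSet(points=np.vstack([vert_vox, outlier]))
        kept = prune_redundant_points(pts, mesh, delta=2.0)
        assert len(kept) <= len(pts)
        assert not any((p == outlier[0]).all() for p in kept.points)
        assert len(kept) == len(vert_vox)  # all on-surface points survive
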