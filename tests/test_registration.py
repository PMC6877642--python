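"""Transform fitting, voxel snapping, volume weighting and SDEF export."""

import numpy as np
import pytest

from inhaledose.materials import material
from inhaledose.nuclides import lookup
from inhaledose.phantom import VoxelPhantom
from inhaledose.registration import (
    AffineTransform,
    SourceEnsemble,
    apply_and_snap,
    export_sdef,
    fit_lung_transform,
    volume_weight_sources,
)

GOLDEN_SDEF = (
    "c  decay sources for Cs-137 (photon)\n"
    "SDEF PAR=2 POS=d1 ERG=d2\n"
    "SI1 L 1.5 2.5 3.5 4.5 5.5 6.5 7.5 8.5 9.5\n"
    "SP1 0.25 0.5 0.25\n"
    "SI2 L 0.2835 0.6616 0.0045 0.0318 0.0322 0.0363 0.0364 0.0373\n"
    "SP2 6.24525e-06 0.916329 0.00979858 0.0214277 0.0391943 "
    "0.00376869 0.00721434 0.00226121\n"
)


def toy_phantom(mask_slice=(slice(4, 8), slice(4, 8), slice(4, 8)), n=12):
    """Minimal phantom: a lung cube inside air."""
    ids = np.zeros((n, n, n), dtype=np.uint16)
    ids[mask_slice] = 7
    return VoxelPhantom(
        ids,
        1.0,
        np.zeros(3),
        {0: "air", 7: "lung"},
        {0: material("air"), 7: material("lung_respiratory")},
    )


class TestFitTransform:
    def test_identity_for_coincident_boxes(self, rng):
        ph = toy_phantom()
        cloud = rng.uniform(4, 8, size=(200, 3))
        cloud[0] = [4, 4, 4]
        cloud[1] = [8, 8, 8]
        tr = fit_lung_transform(cloud, ph)
        assert tr.scale == pytest.approx(1.0)
        assert np.allclose(tr.translation, 0.0, atol=1e-9)

    def test_half_size_cloud_scales_by_two(self, rng):
        ph = toy_phantom()
        cloud = rng.uniform(0, 2, size=(100, 3))
        cloud[0] = [0, 0, 0]
        cloud[1] = [2, 2, 2]
        tr = fit_lung_transform(cloud, ph)
        assert tr.scale == pytest.approx(2.0)
        assert np.allclose(tr.apply(np.array([[1.0, 1.0, 1.0]])), [[6.0, 6.0, 6.0]])

    def test_rotation_orthonormal(self, rng):
        tr = fit_lung_transform(rng.uniform(0, 5, (50, 3)), toy_phantom())
        assert np.allclose(tr.rotation @ tr.rotation.T, np.eye(3), atol=1e-9)

    def test_degenerate_cloud_rejected(self, rng):
        flat = rng.uniform(0, 5, (50, 3))
        flat[:, 2] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            fit_lung_transform(flat, toy_phantom())

    def test_too_few_particles(self, rng):
        with pytest.raises(ValueError, match="at least 10"):
            fit_lung_transform(rng.uniform(0, 5, (5, 3)), toy_phantom())

    def test_invertibility(self, rng):
        ph = toy_phantom()
        cloud = rng.uniform(0, 2, (100, 3))
        tr = fit_lung_transform(cloud, ph)
        assert np.allclose(tr.inverse_apply(tr.apply(cloud)), cloud, atol=1e-6)


class TestApplyAndSnap:
    def test_inside_unchanged(self):
        ph = toy_phantom()
        tr = AffineTransform(1.0, np.eye(3), np.zeros(3))
        pos = np.array([[5.5, 5.5, 5.5]])
        out, rep = apply_and_snap(pos, tr, ph)
        assert out.tolist() == [[5, 5, 5]]
        assert rep["already_inside"] == 1

    def test_face_neighbour_snapped(self):
        ph = toy_phantom()
        tr = AffineTransform(1.0, np.eye(3), np.zeros(3))
        out, rep = apply_and_snap(np.array([[3.5, 5.5, 5.5]]), tr, ph)
        assert out.tolist() == [[4, 5, 5]]
        assert rep["snapped"] == 1

    def test_snap_matches_brute_force(self, rng):
        ph = toy_phantom()
        tr = AffineTransform(1.0, np.eye(3), np.zeros(3))
        pos = rng.uniform(0.5, 11.5, (200, 3))
        out, rep = apply_and_snap(pos, tr, ph, max_snap_voxels=100, max_unplaced_fraction=1.0)
        mask_idx = np.argwhere(ph.respiratory_mask())
        for p, o in zip(np.floor(pos).astype(int), out):
            d2 = ((mask_idx - p) ** 2).sum(axis=1)
            assert ((o - p) ** 2).sum() == d2.min()

    def test_far_cloud_fails(self, rng):
        ph = toy_phantom()
        tr = AffineTransform(1.0, np.eye(3), np.zeros(3))
        pos = np.tile([[0.5, 0.5, 0.5]], (100, 1))
        with pytest.raises(ValueError, match="registration failure"):
            apply_and_snap(pos, tr, ph, max_snap_voxels=1.0)

    def test_all_outputs_inside_mask(self, rng):
        ph = toy_phantom()
        tr = AffineTransform(1.0, np.eye(3), np.zeros(3))
        pos = rng.uniform(2, 10, (500, 3))
        out, _ = apply_and_snap(pos, tr, ph, max_snap_voxels=20, max_unplaced_fraction=1.0)
        mask = ph.respiratory_mask()
        assert mask[out[:, 0], out[:, 1], out[:, 2]].all()


class TestVolumeWeights:
    def test_monodisperse_equal_weights(self):
        ph = toy_phantom()
        idx = np.tile([[5, 5, 5]], (10, 1))
        src = volume_weight_sources(np.full(10, 2.0), idx, ph)
        assert np.allclose(src.weights, src.weights[0])

    def test_weight_ratio_is_volume_ratio(self):
        ph = toy_phantom()
        idx = np.tile([[5, 5, 5]], (2, 1))
        src = volume_weight_sources(np.array([1.0, 2.0]), idx, ph, n_bins=4096)
        assert src.weights[1] / src.weights[0] == pytest.approx(8.0, rel=0.01)

    def test_binning_error_bound(self, rng):
        ph = toy_phantom()
        d = (rng.uniform(1, 8, 2000)) ** (1 / 3)  # uniform volumes
        idx = np.tile([[5, 5, 5]], (2000, 1))
        for n_bins in (8, 32, 128):
            src = volume_weight_sources(d, idx, ph, n_bins=n_bins)
            vol = np.pi / 6 * d**3
            rel = abs(src.weights.sum() - vol.sum()) / vol.sum()
            assert rel <= 1.0 / n_bins

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            volume_weight_sources(np.array([]), np.empty((0, 3)), toy_phantom())

    def test_literal_duplication_same_expectation(self):
        ph = toy_phantom()
        idx = np.tile([[5, 5, 5]], (3, 1))
        d = np.array([1.0, 1.0, 2.0])
        w = volume_weight_sources(d, idx, ph, n_bins=512)
        lit = volume_weight_sources(d, idx, ph, n_bins=512, literal_duplication=True)
        # per-particle total weight proportions agree between the two modes
        assert lit.weights.sum() / lit.weights[0] == pytest.approx(
            w.weights.sum() / w.weights[0], rel=0.15
        )


class TestSdefExport:
    def test_single_line_source(self):
        nuc = lookup("Cs-137")
        src = SourceEnsemble(np.array([[1, 1, 1]]), np.array([[1.5, 1.5, 1.5]]), np.array([2.0]))
        text = export_sdef(src, nuc, "photon")
        assert "SP1 1\n" in text

    def test_energy_probabilities_sum_to_one(self):
        nuc = lookup("Cs-137")
        src = SourceEnsemble(np.array([[1, 1, 1]]), np.array([[1.5, 1.5, 1.5]]), np.array([1.0]))
        text = export_sdef(src, nuc, "photon")
        sp2 = [float(v) for v in text.splitlines()[-1].split()[1:]]
        assert sum(sp2) == pytest.approx(1.0, abs=1e-4)

    def test_golden_fixture(self):
        nuc = lookup("Cs-137")
        idx = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        pos = idx + 0.5
        src = SourceEnsemble(idx, pos, np.array([1.0, 2.0, 1.0]), nuc, np.array([0.5, 1.0, 0.5]))
        assert export_sdef(src, nuc, "photon") == GOLDEN_SDEF

    def test_unsupported_kind(self):
        src = SourceEnsemble(np.array([[1, 1, 1]]), np.array([[1.5, 1.5, 1.5]]), np.array([1.0]))
        with pytest.raises(ValueError, match="unsupported"):
            export_sdef(src, lookup("Pu-239/240"), "alpha")
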