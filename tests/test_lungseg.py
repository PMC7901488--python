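"""Lung segmentation: thresholding, morphology vs BFS oracles, cropping."""

from collections import deque

import numpy as np
import pytest

from mediseg.ct_io import BinaryMask3D, CTVolume
from mediseg.losses import dice_coefficient
from mediseg.lungseg import (
    LungSegParams,
    crop_to_lungs,
    extract_lung_mask,
    invert_mask,
    largest_connected_component,
    lung_bounding_box,
    remove_border_connected,
    threshold_ct,
)
from mediseg.phantom import PhantomSpec, generate_phantom


def _vol(arr):
    return CTVolume(voxels=np.asarray(arr, dtype=np.float32))


def _mask(arr):
    return BinaryMask3D(voxels=np.asarray(arr, dtype=np.uint8))


# ---------------------------------------------------------------------------
# independent breadth-first-search oracles


def _neighbors(connectivity):
    offs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if di == dj == dk == 0:
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if order <= connectivity:
                    offs.append((di, dj, dk))
    return offs


def _bfs_components(mask, connectivity):
    """Flood-fill labelling: list of voxel-index sets, scan order."""
    mask = np.asarray(mask)
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    offs = _neighbors(connectivity)
    for idx in np.ndindex(*mask.shape):
        if not mask[idx] or seen[idx]:
            continue
        comp = set()
        q = deque([idx])
        seen[idx] = True
        while q:
            i, j, k = q.popleft()
            comp.add((i, j, k))
            for di, dj, dk in offs:
                ni, nj, nk = i + di, j + dj, k + dk
                if (0 <= ni < mask.shape[0] and 0 <= nj < mask.shape[1]
                        and 0 <= nk < mask.shape[2]
                        and mask[ni, nj, nk] and not seen[ni, nj, nk]):
                    seen[ni, nj, nk] = True
                    q.append((ni, nj, nk))
        comps.append(comp)
    return comps


def _oracle_largest(mask, connectivity):
    comps = _bfs_components(mask, connectivity)
    best = max(comps, key=len)  # first-seen wins ties: max keeps earliest
    out = np.zeros(mask.shape, dtype=np.uint8)
    for idx in best:
        out[idx] = 1
    return out


def _oracle_remove_border(mask, connectivity):
    out = np.asarray(mask).astype(np.uint8).copy()
    for comp in _bfs_components(mask, connectivity):
        touches = any(
            0 in (i, j, k) or i == mask.shape[0] - 1 or j == mask.shape[1] - 1
            or k == mask.shape[2] - 1
            for i, j, k in comp
        )
        if touches:
            for idx in comp:
                out[idx] = 0
    return out


# ---------------------------------------------------------------------------


def test_threshold_boundary_values():
    v = _vol(np.array([-1000, -500, -300, 0, 100], dtype=np.float32).reshape(1, 1, 5))
    m = threshold_ct(v, -300)
    assert m.voxels.ravel().tolist() == [0, 0, 0, 1, 1]


def test_threshold_all_air_is_empty():
    assert threshold_ct(_vol(np.full((4, 4, 4), -1000.0))).count() == 0


def test_invert_is_involution_and_partitions(rng):
    m = _mask(rng.random((6, 6, 6)) > 0.5)
    inv = invert_mask(m)
    assert np.array_equal(invert_mask(inv).voxels, m.voxels)
    assert m.count() + inv.count() == m.voxels.size
    assert invert_mask(_mask(np.ones((3, 3, 3)))).count() == 0


class TestLargestComponent:
    def test_keeps_bigger_blob(self):
        a = np.zeros((8, 8, 8), dtype=np.uint8)
        a[1:2, 1:6, 1] = 1   # 5 voxels
        a[5, 5, 4:7] = 1     # 3 voxels
        out = largest_connected_component(_mask(a))
        assert out.count() == 5
        assert np.all(out.voxels[1, 1:6, 1] == 1)

    def test_single_blob_idempotent(self):
        a = np.zeros((6, 6, 6), dtype=np.uint8)
        a[2:4, 2:4, 2:4] = 1
        out = largest_connected_component(_mask(a))
        assert np.array_equal(out.voxels, a)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="no foreground"):
            largest_connected_component(_mask(np.zeros((4, 4, 4))))

    @pytest.mark.parametrize("connectivity", [1, 3])
    def test_agrees_with_bfs_oracle(self, connectivity):
        rng = np.random.default_rng(42)
        for _ in range(25):
            a = (rng.random((16, 16, 16)) > 0.72).astype(np.uint8)
            if not a.any():
                continue
            ours = largest_connected_component(_mask(a), connectivity).voxels
            oracle = _oracle_largest(a, connectivity)
            assert np.array_equal(ours, oracle)


class TestRemoveBorderConnected:
    def test_border_blob_removed_interior_kept(self):
        a = np.zeros((8, 8, 8), dtype=np.uint8)
        a[0, 0:3, 0:3] = 1       # touches slice 0
        a[4:6, 4:6, 4:6] = 1     # interior
        out = remove_border_connected(_mask(a))
        assert out.count() == 8
        assert np.all(out.voxels[4:6, 4:6, 4:6] == 1)

    def test_all_foreground_becomes_empty(self):
        assert remove_border_connected(_mask(np.ones((5, 5, 5)))).count() == 0

    @pytest.mark.parametrize("connectivity", [1, 3])
    def test_agrees_with_boundary_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(7)
        for _ in range(25):
            a = (rng.random((16, 16, 16)) > 0.72).astype(np.uint8)
            ours = remove_border_connected(_mask(a), connectivity).voxels
            oracle = _oracle_remove_border(a, connectivity)
            assert np.array_equal(ours, oracle)


class TestExtractLungMask:
    def test_noiseless_phantom_recovered_exactly(self, noiseless_phantom):
        m = extract_lung_mask(noiseless_phantom.image)
        assert dice_coefficient(m, noiseless_phantom.lung_mask_truth) == 1.0

    def test_noisy_phantom_dice_above_090(self):
        spec = PhantomSpec(volume_shape=(96, 96, 48), noise_sd=50.0, seed=21)
        s = generate_phantom(spec)
        m = extract_lung_mask(s.image)
        assert dice_coefficient(m, s.lung_mask_truth) >= 0.90

    def test_solid_body_without_lungs_raises(self):
        v = _vol(np.full((32, 32, 32), 40.0))
        with pytest.raises(ValueError, match="interior air"):
            extract_lung_mask(v)

    def test_lung_mask_subset_of_air_and_disjoint_from_tissue(self, noiseless_phantom):
        vol = noiseless_phantom.image
        lung = extract_lung_mask(vol)
        tissue = threshold_ct(vol)
        air = invert_mask(tissue)
        assert np.all(air.voxels[lung.voxels > 0] == 1)
        assert not np.any(lung.voxels & tissue.voxels)

    def test_deterministic(self, noiseless_phantom):
        a = extract_lung_mask(noiseless_phantom.image)
        b = extract_lung_mask(noiseless_phantom.image)
        assert np.array_equal(a.voxels, b.voxels)


class TestCropToLungs:
    def test_bounding_box_arithmetic(self):
        a = np.zeros((40, 40, 20), dtype=np.uint8)
        a[10:21, 8:31, 2:15] = 1
        vol = _vol(np.zeros((40, 40, 20)))
        out = crop_to_lungs(vol, _mask(a), (0, 0, 0))
        assert out.voxels.shape == (11, 23, 13)

    def test_margin_clamps_to_volume(self):
        a = np.zeros((16, 16, 16), dtype=np.uint8)
        a[6:10, 6:10, 6:10] = 1
        vol = _vol(np.arange(16 ** 3, dtype=np.float32).reshape(16, 16, 16))
        out = crop_to_lungs(vol, _mask(a), (100, 100, 100))
        assert np.array_equal(out.voxels, vol.voxels)

    def test_lesion_contained_in_crop(self, noiseless_phantom):
        s = noiseless_phantom
        lung = extract_lung_mask(s.image)
        box = lung_bounding_box(lung)
        inside = np.zeros(s.image.voxels.shape, dtype=bool)
        inside[box[0], box[1], box[2]] = True
        assert np.all(inside[s.lesion_mask.voxels > 0])

    def test_world_coordinates_preserved(self, small_phantom):
        s = small_phantom
        lung = extract_lung_mask(s.image)
        out = crop_to_lungs(s.image, lung, (1, 1, 1))
        box = lung_bounding_box(lung, (1, 1, 1))
        # voxel (0,0,0) of the crop == voxel box.start of the original
        start = np.array([b.start for b in box] + [1.0])
        assert np.allclose(out.affine @ [0, 0, 0, 1], s.image.affine @ start)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            crop_to_lungs(_vol(np.zeros((8, 8, 8))), _mask(np.zeros((8, 8, 8))))

    def test_gray_value_support_shrinks(self, noiseless_phantom):
        s = noiseless_phantom
        lung = extract_lung_mask(s.image)
        cropped = crop_to_lungs(s.image, lung)
        assert set(np.unique(cropped.voxels)) <= set(np.unique(s.image.voxels))
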