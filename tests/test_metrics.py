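"""Agreement metrics against independent brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage

from aceval import (classify_mu, contour_agreement, delineate_btv, dice,
                    mu_similarity, peak_distance, pet_similarity,
                    proximity_sphere, regional_differences, shape_deviation)
from aceval.image import FWHM_TO_SIGMA
from aceval.metrics import CLASS_AIR, CLASS_BONE, CLASS_TISSUE

from conftest import as_mask, centered_volume, sphere_data


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_dice(a: np.ndarray, b: np.ndarray) -> float:
    a, b = set(map(tuple, np.argwhere(a))), set(map(tuple, np.argwhere(b)))
    if not a and not b:
        return 1.0
    return 2.0 * len(a & b) / (len(a) + len(b))


def oracle_hausdorff(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """Max of directed max surface distances by exhaustive pairwise search."""
    def surface(m):
        er = ndimage.binary_erosion(m, border_value=0)
        return np.argwhere(m & ~er) * np.asarray(spacing)
    pa, pb = surface(a), surface(b)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def oracle_ssim(x: np.ndarray, y: np.ndarray, data_range: float,
                sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03) -> np.ndarray:
    """SSIM map from the definition: Gaussian-weighted local moments."""
    filt = lambda im: ndimage.gaussian_filter(im, sigma, truncate=3.5, mode="reflect")
    ux, uy = filt(x), filt(y)
    uxx, uyy, uxy = filt(x * x), filt(y * y), filt(x * y)
    vx, vy, cxy = uxx - ux * ux, uyy - uy * uy, uxy - ux * uy
    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    return ((2 * ux * uy + c1) * (2 * cxy + c2)) / \
           ((ux ** 2 + uy ** 2 + c1) * (vx + vy + c2))


def oracle_smooth(binary: np.ndarray, fwhm_mm: float, spacing) -> np.ndarray:
    """Gaussian smoothing by explicit truncated-kernel convolution."""
    out = binary.astype(float)
    for axis in range(3):
        sigma = fwhm_mm * FWHM_TO_SIGMA / spacing[axis]
        radius = int(4.0 * sigma + 0.5)
        t = np.arange(-radius, radius + 1)
        kernel = np.exp(-0.5 * (t / sigma) ** 2)
        kernel /= kernel.sum()
        padded = np.pad(out, [(radius, radius) if ax == axis else (0, 0)
                              for ax in range(3)], mode="symmetric")
        out = ndimage.convolve1d(padded, kernel, axis=axis, mode="constant")
        sl = [slice(radius, -radius) if ax == axis else slice(None) for ax in range(3)]
        out = out[tuple(sl)]
    return out


# ---------------------------------------------------------------------------
# classify_mu
# ---------------------------------------------------------------------------

class TestClassifyMu:
    @pytest.mark.parametrize("mu, expected", [
        (0.0, CLASS_AIR), (0.049, CLASS_AIR),
        (0.05, CLASS_TISSUE), (0.096, CLASS_TISSUE), (0.1, CLASS_TISSUE),
        (0.101, CLASS_BONE), (0.151, CLASS_BONE),
    ])
    def test_class_bounds(self, mu, expected):
        vol = centered_volume(np.full((4, 4, 4), mu))
        cm = classify_mu(vol, as_mask(np.ones((4, 4, 4)), label="head"))
        assert (cm.labels.data == expected).all()

    def test_negative_mu_rejected_with_count(self):
        data = np.zeros((4, 4, 4)); data[:2, 0, 0] = -0.1
        with pytest.raises(ValueError, match="2 negative"):
            classify_mu(centered_volume(data), as_mask(np.ones((4, 4, 4)), label="head"))

    def test_phantom_truth_reproduces_label_map(self, noiseless_phantom):
        ph = noiseless_phantom
        cm = classify_mu(ph.mu_map, ph.head_mask)
        inside = ph.head_mask.data
        assert np.array_equal(cm.labels.data[inside], ph.labels.data[inside])

    def test_fov_restriction(self, noiseless_phantom):
        ph = noiseless_phantom
        half = np.zeros(ph.labels.shape); half[:32] = 1
        fov = as_mask(half, spacing=ph.labels.spacing, label="fov")
        cm = classify_mu(ph.mu_map, ph.head_mask, fov=fov)
        assert (cm.labels.data[32:] == -1).all()


# ---------------------------------------------------------------------------
# dice
# ---------------------------------------------------------------------------

class TestDice:
    def test_identical_nonempty(self, rng):
        m = as_mask(rng.random((6, 6, 6)) > 0.5)
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4, 4)); a[0] = 1
        b = np.zeros((4, 4, 4)); b[2] = 1
        assert dice(as_mask(a), as_mask(b)) == 0.0

    def test_hand_counted_overlap(self):
        a = np.zeros((4, 4, 4)); a.ravel()[:8] = 1
        b = np.zeros((4, 4, 4)); b.ravel()[4:12] = 1
        assert dice(as_mask(a), as_mask(b)) == 0.5

    def test_both_empty_is_one(self):
        z = as_mask(np.zeros((3, 3, 3)))
        assert dice(z, z) == 1.0

    def test_matches_brute_force_and_symmetry(self, rng):
        for _ in range(5):
            a = rng.random((8, 8, 8)) > 0.6
            b = rng.random((8, 8, 8)) > 0.6
            ma, mb = as_mask(a), as_mask(b)
            assert dice(ma, mb) == pytest.approx(oracle_dice(a, b), abs=1e-12)
            assert dice(ma, mb) == dice(mb, ma)


# ---------------------------------------------------------------------------
# proximity sphere
# ---------------------------------------------------------------------------

def _btv_from_mask(mask_data, spacing=(1.0, 1.0, 1.0)):
    """Build a BTVResult whose TBR is 2 inside the mask."""
    pet = np.where(mask_data, 4.0, 1.0)
    brain = np.ones_like(pet)
    return delineate_btv(centered_volume(pet, spacing), 2.0,
                         as_mask(brain, spacing=spacing, label="brain"))


class TestProximitySphere:
    def test_radius_boundary(self):
        data = np.zeros((121, 5, 5)); data[60, 2, 2] = 1
        btv = _btv_from_mask(data)
        prox = proximity_sphere(btv, radius_mm=50.0)
        x = prox.coordinate_grids()[0][:, 0, 0]
        center = 60
        on_axis = prox.data[:, 2, 2]
        assert on_axis[center + 49]          # 49 mm away: in
        assert on_axis[center + 50]          # 50.0 mm: in (<= radius)
        assert not on_axis[center + 51]      # 51 mm: out

    def test_two_distant_components_give_two_spheres(self):
        data = np.zeros((241, 31, 31))
        data[15, 15, 15] = 1
        data[215, 15, 15] = 1   # 200 mm apart
        btv = _btv_from_mask(data)
        prox = proximity_sphere(btv, radius_mm=12.0)
        expected = 2 * 4 / 3 * np.pi * 12.0 ** 3
        assert prox.n_voxels == pytest.approx(expected, rel=0.05)

    def test_tiny_radius_keeps_only_peak_voxels(self):
        data = np.zeros((21, 21, 21)); data[10, 10, 10] = 1
        btv = _btv_from_mask(data)
        prox = proximity_sphere(btv, radius_mm=0.01)
        assert prox.n_voxels == 1
        assert prox.data[10, 10, 10]

    def test_empty_btv_rejected(self):
        btv = _btv_from_mask(np.zeros((5, 5, 5)))
        with pytest.raises(ValueError, match="nonempty"):
            proximity_sphere(btv)


# ---------------------------------------------------------------------------
# mu / PET similarity
# ---------------------------------------------------------------------------

class TestMuSimilarity:
    def test_identical_maps(self, rng):
        vol = centered_volume(rng.random((16, 16, 16)) * 0.15)
        head = as_mask(np.ones((16, 16, 16)), label="head")
        out = mu_similarity(vol, vol, head)
        assert out["mae"] == 0.0
        assert out["ssim"] == pytest.approx(1.0)

    def test_constant_shift_mae(self, rng):
        a = centered_volume(rng.random((16, 16, 16)) * 0.1)
        b = a.with_data(a.data + 0.01)
        head = as_mask(np.ones((16, 16, 16)), label="head")
        assert mu_similarity(a, b, head)["mae"] == pytest.approx(0.01)

    def test_ssim_matches_direct_formula(self, rng):
        x = rng.random((16, 16, 16))
        y = x + rng.normal(0, 0.1, (16, 16, 16))
        a, b = centered_volume(x), centered_volume(y)
        head_data = np.ones((16, 16, 16), dtype=bool)
        head = as_mask(head_data, label="head")
        got = mu_similarity(a, b, head)["ssim"]
        want = oracle_ssim(x, y, data_range=float(x.max())).mean()
        assert got == pytest.approx(want, abs=1e-6)


class TestPetSimilarity:
    def test_identical_images_psnr_is_infinite(self, rng):
        pet = centered_volume(rng.random((12, 12, 12)) * 10)
        brain = as_mask(np.ones((12, 12, 12)), label="brain")
        out = pet_similarity(pet, pet, brain)
        assert out["mae"] == 0.0 and out["ssim"] == pytest.approx(1.0)
        assert np.isinf(out["psnr"])

    def test_constant_offset_closed_form(self, rng):
        a = centered_volume(rng.random((12, 12, 12)) * 10)
        c = 0.5
        b = a.with_data(a.data + c)
        brain = as_mask(np.ones((12, 12, 12)), label="brain")
        out = pet_similarity(a, b, brain)
        r = a.data.max()
        assert out["mae"] == pytest.approx(c)
        assert out["psnr"] == pytest.approx(10 * np.log10(r ** 2 / c ** 2))

    def test_matches_direct_formula_on_random_pair(self, rng):
        x = rng.random((16, 16, 16)) * 10
        y = x * (1 + rng.normal(0, 0.05, x.shape))
        brain_data = np.ones((16, 16, 16), dtype=bool)
        out = pet_similarity(centered_volume(x), centered_volume(y),
                             as_mask(brain_data, label="brain"))
        assert out["mae"] == pytest.approx(np.abs(x - y).mean(), abs=1e-9)
        assert out["ssim"] == pytest.approx(
            oracle_ssim(x, y, data_range=float(x.max())).mean(), abs=1e-6)
        mse = ((x - y) ** 2).mean()
        assert out["psnr"] == pytest.approx(10 * np.log10(x.max() ** 2 / mse), abs=1e-9)


# ---------------------------------------------------------------------------
# contour agreement
# ---------------------------------------------------------------------------

class TestContourAgreement:
    def test_identical_masks(self):
        m = as_mask(sphere_data((16, 16, 16), (1, 1, 1), (0, 0, 0), 5.0))
        out = contour_agreement(m, m)
        assert out["dice"] == 1.0 and out["hausdorff_mm"] == 0.0

    def test_one_voxel_translation_is_one_mm(self):
        a = np.zeros((16, 16, 16), dtype=bool); a[5:9, 5:9, 5:9] = True
        b = np.roll(a, 1, axis=0)
        out = contour_agreement(as_mask(a), as_mask(b))
        assert out["hausdorff_mm"] == pytest.approx(1.0)

    def test_isolated_distant_voxel_sets_hausdorff(self):
        a = np.zeros((40, 8, 8), dtype=bool); a[2:5, 2:5, 2:5] = True
        b = a.copy(); b[33, 3, 3] = True   # 30 mm from the nearest a-surface
        out = contour_agreement(as_mask(a), as_mask(b))
        assert out["hausdorff_mm"] == pytest.approx(
            oracle_hausdorff(a, b, (1, 1, 1)))
        assert 29.0 <= out["hausdorff_mm"] <= 31.0

    def test_matches_brute_force_on_random_blobs(self, rng):
        for _ in range(4):
            a = ndimage.binary_dilation(rng.random((12, 12, 12)) > 0.95)
            b = ndimage.binary_dilation(rng.random((12, 12, 12)) > 0.95)
            if not (a.any() and b.any()):
                continue
            out = contour_agreement(as_mask(a, spacing=(1.0, 1.5, 2.0)),
                                    as_mask(b, spacing=(1.0, 1.5, 2.0)))
            assert out["hausdorff_mm"] == pytest.approx(
                oracle_hausdorff(a, b, (1.0, 1.5, 2.0)), abs=1e-9)

    def test_empty_test_mask_rejected(self):
        a = as_mask(np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="undefined"):
            contour_agreement(a, as_mask(np.zeros((4, 4, 4))))


# ---------------------------------------------------------------------------
# shape deviation
# ---------------------------------------------------------------------------

class TestShapeDeviation:
    def test_identical_masks_give_zero(self):
        m = as_mask(sphere_data((24, 24, 24), (1, 1, 1), (0, 0, 0), 8.0))
        assert shape_deviation(m, m) == 0.0

    def test_one_voxel_shell_of_40mm_sphere_is_discounted(self):
        sphere = sphere_data((52, 52, 52), (1, 1, 1), (0, 0, 0), 20.0)
        dilated = ndimage.binary_dilation(sphere)
        out = shape_deviation(as_mask(sphere), as_mask(dilated))
        assert out == 0.0

    def test_disjoint_six_mm_blob_is_flagged_but_bounded(self):
        sphere = sphere_data((64, 64, 64), (1, 1, 1), (-10, 0, 0), 15.0)
        blob = sphere_data((64, 64, 64), (1, 1, 1), (20, 0, 0), 6.0)
        out = shape_deviation(as_mask(sphere), as_mask(sphere | blob))
        blob_ml = blob.sum() * 0.001
        assert 0.0 < out <= blob_ml
        assert blob_ml == pytest.approx(0.905, abs=0.02)

    def test_symmetric_in_arguments(self, rng):
        a = as_mask(sphere_data((24, 24, 24), (1, 1, 1), (0, 0, 0), 7.0))
        b = as_mask(sphere_data((24, 24, 24), (1, 1, 1), (3, 1, 0), 6.0))
        assert shape_deviation(a, b) == shape_deviation(b, a)

    def test_never_exceeds_symmetric_difference(self, rng):
        for _ in range(3):
            a = sphere_data((32, 32, 32), (1, 1, 1),
                            tuple(rng.uniform(-4, 4, 3)), rng.uniform(5, 10))
            b = sphere_data((32, 32, 32), (1, 1, 1),
                            tuple(rng.uniform(-4, 4, 3)), rng.uniform(5, 10))
            dev = shape_deviation(as_mask(a), as_mask(b))
            assert dev <= (a ^ b).sum() * 0.001 + 1e-12

    def test_matches_brute_force_smoothing(self, rng):
        a = sphere_data((16, 16, 16), (1, 1, 1), (0, 0, 0), 5.0)
        b = sphere_data((16, 16, 16), (1, 1, 1), (2, 1, 0), 4.0)
        got = shape_deviation(as_mask(a), as_mask(b))
        smoothed = oracle_smooth(a ^ b, 4.0, (1, 1, 1))
        want = (smoothed >= 1.0 - 1e-2).sum() * 0.001
        assert got == pytest.approx(want, abs=1e-9)


# ---------------------------------------------------------------------------
# peak distance
# ---------------------------------------------------------------------------

class TestPeakDistance:
    def test_identical_peaks(self):
        data = np.zeros((9, 9, 9)); data[4, 4, 4] = 1
        btv = _btv_from_mask(data)
        out = peak_distance(btv, btv)
        assert out["distance_mm"] == 0.0 and out["within_criterion"]

    def test_ten_mm_exactly_fails_strict_criterion(self):
        a = np.zeros((25, 9, 9)); a[7, 4, 4] = 1
        b = np.zeros((25, 9, 9)); b[17, 4, 4] = 1
        out = peak_distance(_btv_from_mask(a), _btv_from_mask(b))
        assert out["distance_mm"] == pytest.approx(10.0)
        assert not out["within_criterion"]

    def test_bias_flipping_between_near_equal_hot_spots(self):
        """Two hot spots 30 mm apart; a small test-side boost flips the max."""
        pet = np.full((41, 11, 11), 1.0)
        pet[5, 5, 5] = 4.00
        pet[35, 5, 5] = 3.98
        brain = as_mask(np.ones((41, 11, 11)), label="brain")
        ref = delineate_btv(centered_volume(pet), 2.0, brain)
        biased = pet.copy(); biased[35, 5, 5] *= 1.02
        test = delineate_btv(centered_volume(biased), 2.0, brain)
        out = peak_distance(ref, test)
        assert out["distance_mm"] == pytest.approx(30.0)
        assert not out["within_criterion"]

    def test_empty_btv_rejected(self):
        good = _btv_from_mask(np.ones((3, 3, 3)))
        empty = _btv_from_mask(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="nonempty"):
            peak_distance(good, empty)


# ---------------------------------------------------------------------------
# regional differences
# ---------------------------------------------------------------------------

class TestRegionalDifferences:
    def _regions(self, shape=(8, 8, 8)):
        labels = np.zeros(shape, dtype=int)
        labels[:4] = 1; labels[4:] = 2
        return centered_volume(labels)

    def test_identity_gives_zero_everywhere(self, rng):
        pet = centered_volume(rng.random((8, 8, 8)) + 1)
        out = regional_differences(pet, pet, self._regions())
        assert out == {1: 0.0, 2: 0.0}

    def test_uniform_scaling_gives_uniform_percent(self, rng):
        pet = centered_volume(rng.random((8, 8, 8)) + 1)
        test = pet.with_data(pet.data * 1.05)
        out = regional_differences(pet, test, self._regions())
        assert out[1] == pytest.approx(5.0) and out[2] == pytest.approx(5.0)

    def test_matches_brute_force_per_region_means(self, rng):
        ref = rng.random((8, 8, 8)) + 1
        test = ref * (1 + rng.normal(0, 0.1, ref.shape))
        regions = self._regions()
        out = regional_differences(centered_volume(ref), centered_volume(test), regions)
        for label in (1, 2):
            sel = regions.data == label
            want = 100 * (test[sel].mean() - ref[sel].mean()) / ref[sel].mean()
            assert out[label] == pytest.approx(want, abs=1e-9)

    def test_zero_reference_region_skipped_with_warning(self):
        ref = np.zeros((8, 8, 8)); ref[4:] = 2.0
        test = np.ones((8, 8, 8))
        with pytest.warns(UserWarning, match="region 1"):
            out = regional_differences(centered_volume(ref), centered_volume(test),
                                       self._regions())
        assert 1 not in out and 2 in out
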