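"""Image normalisation, patch decomposition and sampling."""

import numpy as np
import pytest

from datarep.exceptions import InvalidInputError
from datarep.patching import (
    MaskedImage,
    extract_patches,
    normalize_image,
    read_masked_image,
    sample_patches,
    write_masked_image,
)


def make_image(pixels, mask=None):
    pixels = np.asarray(pixels, dtype=float)
    if mask is None:
        mask = np.ones_like(pixels)
    return MaskedImage(pixels=pixels, mask=mask)


class TestNormalize:
    def test_minmax_over_foreground(self):
        img = make_image([[10, 20, 30]])
        out = normalize_image(img)
        assert np.allclose(out.pixels, [[0, 0.5, 1]])

    def test_idempotent(self):
        img = normalize_image(make_image(np.random.default_rng(0).uniform(5, 9, (8, 8))))
        again = normalize_image(img)
        assert np.allclose(img.pixels, again.pixels)

    def test_background_excluded_from_scaling_and_zeroed(self):
        pixels = np.array([[500.0, 10.0], [20.0, 30.0]])
        mask = np.array([[0, 1], [1, 1]])
        out = normalize_image(MaskedImage(pixels=pixels, mask=mask))
        assert out.pixels[0, 0] == 0.0
        assert out.pixels[1, 1] == 1.0

    def test_constant_foreground_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant foreground"):
            out = normalize_image(make_image([[7.0, 7.0]]))
        assert np.all(out.pixels == 0)

    def test_empty_mask_rejected(self):
        img = MaskedImage(pixels=np.ones((4, 4)), mask=np.zeros((4, 4)))
        with pytest.raises(InvalidInputError):
            normalize_image(img)

    def test_nonbinary_mask_rejected(self):
        with pytest.raises(InvalidInputError):
            MaskedImage(pixels=np.ones((2, 2)), mask=np.full((2, 2), 2))


class TestExtract:
    def test_full_foreground_count_matches_window_arithmetic(self):
        img = make_image(np.random.default_rng(1).random((256, 256)))
        ps = extract_patches(img, k=15)
        assert len(ps) == (256 - 15 + 1) ** 2 == 58564

    def test_all_background_yields_empty_set(self):
        img = MaskedImage(pixels=np.ones((32, 32)), mask=np.zeros((32, 32)))
        assert len(extract_patches(img, k=5)) == 0

    def test_single_foreground_center(self):
        mask = np.zeros((5, 5))
        mask[2, 2] = 1
        ps = extract_patches(MaskedImage(pixels=np.arange(25.0).reshape(5, 5),
                                         mask=mask), k=3)
        assert len(ps) == 1
        assert tuple(ps.centers[0]) == (2, 2)

    def test_even_patch_size_rejected(self):
        with pytest.raises(InvalidInputError):
            extract_patches(make_image(np.ones((10, 10))), k=4)

    def test_patch_larger_than_image_rejected(self):
        with pytest.raises(InvalidInputError):
            extract_patches(make_image(np.ones((8, 8))), k=9)

    def test_border_centers_excluded(self):
        img = make_image(np.ones((9, 9)))
        ps = extract_patches(img, k=5)
        assert ps.centers.min() >= 2
        assert ps.centers.max() <= 6
        assert len(ps) <= img.mask.sum()

    def test_row_major_flattening_round_trips(self):
        pixels = np.arange(49.0).reshape(7, 7)
        ps = extract_patches(make_image(pixels), k=3)
        i = 5
        r, c = ps.centers[i]
        window = pixels[r - 1 : r + 2, c - 1 : c + 2]
        assert np.array_equal(ps.unflatten(i), window.astype(np.float32))


class TestSample:
    @pytest.fixture()
    def patchset(self):
        return extract_patches(make_image(np.random.default_rng(2).random((40, 40))), k=5)

    def test_full_sample_is_permutation(self, patchset):
        out = sample_patches(patchset, len(patchset), seed=3)
        assert sorted(map(tuple, out.centers)) == sorted(map(tuple, patchset.centers))

    def test_deterministic_given_seed(self, patchset):
        a = sample_patches(patchset, 1, seed=9)
        b = sample_patches(patchset, 1, seed=9)
        assert np.array_equal(a.centers, b.centers)

    def test_oversized_request_warns_and_returns_all(self, patchset):
        with pytest.warns(UserWarning, match="returning all"):
            out = sample_patches(patchset, len(patchset) + 5, seed=0)
        assert len(out) == len(patchset)

    def test_empty_patchset_rejected(self):
        from datarep.patching import PatchSet

        empty = PatchSet(patches=np.empty((0, 9)), centers=np.empty((0, 2)), k=3)
        with pytest.raises(InvalidInputError):
            sample_patches(empty, 1, seed=0)

    def test_disjoint_seeds_rarely_overlap(self):
        """Hypergeometric expectation: two 100-draws from 58,564 patches
        share ~0.17 patches on average; >=10 overlaps is essentially
        impossible."""
        big = extract_patches(make_image(np.random.default_rng(4).random((256, 256))), k=15)
        a = sample_patches(big, 100, seed=1)
        b = sample_patches(big, 100, seed=2)
        overlap = len(set(map(tuple, a.centers)) & set(map(tuple, b.centers)))
        assert overlap <= 10


class TestIO:
    @pytest.mark.parametrize("suffix", [".png", ".nii"])
    def test_round_trip_preserves_normalised_content(self, tmp_path, suffix):
        rng = np.random.default_rng(5)
        mask = np.zeros((24, 24))
        mask[4:20, 6:18] = 1
        img = MaskedImage(pixels=rng.uniform(100, 900, (24, 24)), mask=mask,
                          subject_id="s", scanner_id="sc")
        ip, mp = tmp_path / f"img{suffix}", tmp_path / f"mask{suffix}"
        write_masked_image(img, ip, mp)
        back = read_masked_image(ip, mp)
        assert np.array_equal(back.mask, img.mask)
        a = normalize_image(img).pixels
        b = normalize_image(back).pixels
        assert np.allclose(a, b, atol=2e-4)

    def test_geometry_mismatch_rejected(self, tmp_path):
        img = MaskedImage(pixels=np.ones((8, 8)), mask=np.ones((8, 8)))
        other = MaskedImage(pixels=np.ones((9, 9)), mask=np.ones((9, 9)))
        write_masked_image(img, tmp_path / "a.png", tmp_path / "a_m.png")
        write_masked_image(other, tmp_path / "b.png", tmp_path / "b_m.png")
        with pytest.raises(InvalidInputError, match="geometry"):
            read_masked_image(tmp_path / "a.png", tmp_path / "b_m.png")

    def test_missing_file_named_in_error(self, tmp_path):
        with pytest.raises(InvalidInputError, match="nope.png"):
            read_masked_image(tmp_path / "nope.png", tmp_path / "nope_m.png")
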