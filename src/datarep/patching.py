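"""Masked grayscale images and their decomposition into patch features.

A scan enters the pipeline as a 2-D intensity grid with a binary
foreground mask (for brain MRI: the skull-stripped brain).  Because MRI
intensities are relative, each scan is min-max normalised over its own
foreground before patching.  The scan is then decomposed, at stride 1,
into k-by-k patches whose *middle pixel* lies inside the mask; patches
whose centre is background carry no information about the tissue under
study and are discarded.  Flattened row-major patch vectors are the
feature representation used by both the domain classifier and the
tissue classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import InvalidInputError

__all__ = [
    "MaskedImage",
    "PatchSet",
    "normalize_image",
    "extract_patches",
    "sample_patches",
    "read_masked_image",
    "write_masked_image",
]


@dataclass
class MaskedImage:
    """A 2-D grayscale image with a binary foreground mask.

    ``spacing`` is the physical pixel size in mm (row, col); the default
    geometry is 256 x 256 at 1.0 x 1.0 mm.
    """

    pixels: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    subject_id: str = ""
    scanner_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        mask = np.asarray(self.mask)
        if self.pixels.ndim != 2:
            raise InvalidInputError(
                f"pixels must be 2-D, got shape {self.pixels.shape}"
            )
        if mask.shape != self.pixels.shape:
            raise InvalidInputError(
                f"mask shape {mask.shape} does not match pixels {self.pixels.shape}"
            )
        unique = np.unique(mask)
        if not np.all(np.isin(unique, (0, 1, False, True))):
            raise InvalidInputError("mask must be strictly binary (0/1)")
        self.mask = mask.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class PatchSet:
    """Flattened k x k patches plus the (row, col) of each centre pixel.

    Patch features are held in single precision; intensities are
    normalised to [0, 1] so float32 resolution is ample.
    """

    patches: np.ndarray  # (n, k*k) row-major flattened intensities
    centers: np.ndarray  # (n, 2) centre coordinates, 0-based
    k: int
    subject_id: str = ""
    scanner_id: str = ""

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float32)
        self.centers = np.asarray(self.centers, dtype=int)
        if self.patches.ndim != 2 or self.patches.shape[1] != self.k * self.k:
            raise InvalidInputError(
                f"patches must be (n, {self.k * self.k}), got {self.patches.shape}"
            )
        if self.centers.shape != (len(self.patches), 2):
            raise InvalidInputError("centers must be (n, 2)")

    def __len__(self) -> int:
        return len(self.patches)

    def unflatten(self, i: int) -> np.ndarray:
        """Recover the 2-D k x k patch from its row-major flat vector."""
        return self.patches[i].reshape(self.k, self.k)


def normalize_image(img: MaskedImage) -> MaskedImage:
    """Min-max rescale foreground intensities to [0, 1]; background to 0.

    Only pixels under the mask enter the min/max, so arbitrary background
    values cannot distort the scaling.  Idempotent.  A constant
    foreground maps to all zeros with a warning.
    """
    if not img.mask.any():
        raise InvalidInputError("mask has no foreground pixels")
    fg = img.pixels[img.mask]
    lo, hi = float(fg.min()), float(fg.max())
    out = np.zeros_like(img.pixels, dtype=float)
    if hi > lo:
        out[img.mask] = (fg - lo) / (hi - lo)
    else:
        warnings.warn(
            "constant foreground intensity; normalized image is all zeros",
            stacklevel=2,
        )
    return replace(img, pixels=out)


def extract_patches(img: MaskedImage, k: int = 15) -> PatchSet:
    """All stride-1 k x k patches whose middle pixel is foreground.

    ``k`` must be odd so a middle pixel exists.  Patches that would
    extend past the image border are excluded rather than padded.
    An empty mask yields an empty PatchSet, not an error.
    """
    k = int(k)
    if k % 2 == 0 or k < 1:
        raise InvalidInputError(f"patch size k must be odd and positive, got {k}")
    h, w = img.shape
    if k > min(h, w):
        raise InvalidInputError(f"patch size {k} exceeds image dimensions {img.shape}")
    half = k // 2
    windows = np.lib.stride_tricks.sliding_window_view(img.pixels, (k, k))
    # Centre of window at (i, j) is pixel (i + half, j + half).
    center_mask = img.mask[half : h - half, half : w - half]
    idx = np.argwhere(center_mask)
    patches = windows[idx[:, 0], idx[:, 1]].reshape(len(idx), k * k)
    centers = idx + half
    return PatchSet(
        patches=patches,
        centers=centers,
        k=k,
        subject_id=img.subject_id,
        scanner_id=img.scanner_id,
    )


def sample_patches(ps: PatchSet, n: int, seed: int) -> PatchSet:
    """Uniform sample of ``n`` patches without replacement.

    Deterministic given ``seed``.  Requests beyond availability return
    all patches (in random order) with a warning.
    """
    if len(ps) == 0:
        raise InvalidInputError("cannot sample from an empty PatchSet")
    if n < 1:
        raise InvalidInputError(f"sample size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    if n >= len(ps):
        if n > len(ps):
            warnings.warn(
                f"requested {n} patches but only {len(ps)} available; "
                "returning all",
                stacklevel=2,
            )
        idx = rng.permutation(len(ps))
    else:
        idx = rng.choice(len(ps), size=n, replace=False)
    return PatchSet(
        patches=ps.patches[idx],
        centers=ps.centers[idx],
        k=ps.k,
        subject_id=ps.subject_id,
        scanner_id=ps.scanner_id,
    )


# ---------------------------------------------------------------------------
# File I/O: NIfTI via nibabel, PNG (grayscale) via imageio.  Masks travel as
# sidecar files with identical geometry.

def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _read_array(path: Path) -> np.ndarray:
    if _is_nifti(path):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise InvalidInputError(
                f"{path}: expected a single 2-D slice, got shape {data.shape}"
            )
        return np.asarray(data, dtype=float)
    import imageio.v3 as iio

    data = np.asarray(iio.imread(path), dtype=float)
    if data.ndim == 3:  # collapse grayscale-as-RGB
        data = data.mean(axis=2)
    return data


def read_masked_image(
    image_path, mask_path, subject_id: str = "", scanner_id: str = ""
) -> MaskedImage:
    """Load an image and its sidecar mask (NIfTI or PNG) as a MaskedImage."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    for p in (image_path, mask_path):
        if not p.exists():
            raise InvalidInputError(f"file not found: {p}")
    pixels = _read_array(image_path)
    mask = _read_array(mask_path)
    if mask.shape != pixels.shape:
        raise InvalidInputError(
            f"mask geometry {mask.shape} ({mask_path}) does not match "
            f"image {pixels.shape} ({image_path})"
        )
    return MaskedImage(
        pixels=pixels,
        mask=(mask > 0).astype(np.uint8),
        subject_id=subject_id,
        scanner_id=scanner_id,
    )


def write_masked_image(img: MaskedImage, image_path, mask_path) -> None:
    """Write an image/mask pair; format chosen from the file suffix.

    PNG output is quantised to 16 bits over the image's own intensity
    range; NIfTI keeps float32 values.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    if _is_nifti(image_path):
        import nibabel as nib

        affine = np.diag([img.spacing[0], img.spacing[1], 1.0, 1.0])
        nib.save(
            nib.Nifti1Image(img.pixels.astype(np.float32), affine), str(image_path)
        )
        nib.save(
            nib.Nifti1Image(img.mask.astype(np.uint8), affine), str(mask_path)
        )
    else:
        import imageio.v3 as iio

        lo, hi = float(img.pixels.min()), float(img.pixels.max())
        scale = (img.pixels - lo) / (hi - lo) if hi > lo else np.zeros_like(img.pixels)
        iio.imwrite(image_path, (scale * 65535).astype(np.uint16))
        iio.imwrite(mask_path, (img.mask * 65535).astype(np.uint16))
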