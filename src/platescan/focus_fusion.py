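"""Extended-depth-of-field fusion of per-well z-stacks.

Each well yields a handful of images focused at different heights; no
single frame has the whole droplet sharp.  Fusion aligns the frames
(integer-pixel translation — the stage settles between moves, so there
is no rotation and negligible sub-pixel drift), scores per-pixel
sharpness with a local absolute-Laplacian energy, and blends the frames
in a Laplacian pyramid weighted by Gaussian-smoothed sharpness maps.
The multiresolution blend avoids the seams a per-pixel argmax would
leave; the result takes every region from its sharpest source frame,
so features come out as clear as — but never clearer than — the parent
images.

Weighting uses contrast only.  Droplet micrographs are near-monochrome
and evenly exposed, so the saturation and well-exposedness terms of
general exposure fusion would only add noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageStack",
    "align_stack",
    "crop_to_overlap",
    "contrast_weights",
    "fuse_stack",
    "fuse_images",
    "fuse_manifest",
]

EPS = 1e-6

# ITU-R BT.601 luma coefficients
_LUMA = np.array([0.299, 0.587, 0.114])


def _luminance(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        return img.astype(float)
    return img.astype(float) @ _LUMA


def align_stack(
    images: list[np.ndarray], max_shift: int = 20
) -> list[tuple[int, int]]:
    """Integer (dx, dy) translation of each image relative to the middle one.

    The middle image is the reference (shift (0, 0)); every other image
    gets the shift within ±max_shift that maximizes the cross-correlation
    of the standardized (zero-mean, unit-variance) frames, computed by
    FFT.  A shift landing on the search boundary triggers a warning:
    max_shift was probably too small.
    """
    if not images:
        raise ValueError("empty stack")
    shapes = {im.shape for im in images}
    if len(shapes) > 1:
        raise ValueError(f"images differ in shape: {sorted(shapes)}")
    ref_idx = len(images) // 2
    ref = _standardize(_luminance(images[ref_idx]))
    f_ref = np.fft.rfft2(ref)
    shifts: list[tuple[int, int]] = []
    h, w = ref.shape
    for i, im in enumerate(images):
        if i == ref_idx:
            shifts.append((0, 0))
            continue
        mov = _standardize(_luminance(im))
        # corr[d] = sum_m ref[m] * mov[m + d]; peak at the translation of
        # mov relative to ref
        corr = np.fft.irfft2(np.fft.rfft2(mov) * np.conj(f_ref), s=ref.shape)
        dy, dx = _windowed_argmax(corr, max_shift)
        if max(abs(dy), abs(dx)) == max_shift:
            warnings.warn(
                f"image {i}: alignment shift ({dx}, {dy}) hit the ±{max_shift} "
                "search boundary; consider a larger max_shift",
                stacklevel=2,
            )
        shifts.append((dx, dy))
    return shifts


def _standardize(img: np.ndarray) -> np.ndarray:
    sd = img.std()
    return (img - img.mean()) / (sd if sd > 0 else 1.0)


def _windowed_argmax(corr: np.ndarray, max_shift: int) -> tuple[int, int]:
    """Argmax of a circular correlation surface over shifts in ±max_shift."""
    h, w = corr.shape
    ms_y = min(max_shift, (h - 1) // 2)
    ms_x = min(max_shift, (w - 1) // 2)
    offsets_y = np.r_[0 : ms_y + 1, -ms_y:0] if ms_y else np.array([0])
    offsets_x = np.r_[0 : ms_x + 1, -ms_x:0] if ms_x else np.array([0])
    window = corr[np.ix_(offsets_y % h, offsets_x % w)]
    iy, ix = np.unravel_index(np.argmax(window), window.shape)
    return int(offsets_y[iy]), int(offsets_x[ix])


def crop_to_overlap(
    images: list[np.ndarray], shifts: list[tuple[int, int]]
) -> list[np.ndarray]:
    """Undo the per-image shifts and crop all images to the common overlap.

    ``shifts[i] = (dx, dy)`` means image i shows the scene translated by
    (dx, dy) pixels relative to the reference; the aligned image i at
    reference pixel (y, x) is image_i[y + dy, x + dx].
    """
    h, w = images[0].shape[:2]
    dys = [dy for _, dy in shifts]
    dxs = [dx for dx, _ in shifts]
    y0, y1 = max(0, *(-d for d in dys)), min(h, *(h - d for d in dys))
    x0, x1 = max(0, *(-d for d in dxs)), min(w, *(w - d for d in dxs))
    if y1 <= y0 or x1 <= x0:
        raise ValueError("alignment shifts leave no common overlap")
    return [
        im[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
        for im, (dx, dy) in zip(images, shifts)
    ]


@dataclass
class ImageStack:
    """Aligned images of one well with their z-offsets and shifts."""

    images: list[np.ndarray]
    z_offsets: list[float] = field(default_factory=list)
    shifts: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("stack must contain at least one image")
        shapes = {im.shape for im in self.images}
        if len(shapes) > 1:
            raise ValueError("stack images must share shape and channel count")
        if not self.z_offsets:
            self.z_offsets = [0.0] * len(self.images)
        if not self.shifts:
            self.shifts = [(0, 0)] * len(self.images)

    @classmethod
    def from_images(
        cls,
        images: list[np.ndarray],
        z_offsets: list[float] | None = None,
        max_shift: int = 20,
    ) -> "ImageStack":
        """Align raw frames and crop them to their common overlap."""
        shifts = align_stack(images, max_shift=max_shift)
        aligned = crop_to_overlap(images, shifts)
        return cls(images=aligned, z_offsets=z_offsets or [], shifts=shifts)


def contrast_weights(
    images: list[np.ndarray], window: int = 5
) -> list[np.ndarray]:
    """Per-pixel focus weights: local absolute-Laplacian energy, normalized.

    Defocus blur suppresses high spatial frequencies, so the Laplacian
    magnitude averaged over a small window ranks which frame is sharpest
    at each pixel.  A small epsilon keeps featureless regions defined:
    there the weights degrade to uniform 1/n.  Weights sum to 1 across
    the stack at every pixel.
    """
    raw = []
    for im in images:
        lap = ndimage.laplace(_luminance(im))
        raw.append(ndimage.uniform_filter(np.abs(lap), size=window) + EPS)
    total = np.sum(raw, axis=0)
    return [r / total for r in raw]


def _auto_levels(shape: tuple[int, ...]) -> int:
    return max(1, int(np.floor(np.log2(min(shape[:2])))) - 3)


def _reduce(img: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_filter(img, sigma=1.0, mode="reflect")[::2, ::2]


def _expand(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=float)
    out[::2, ::2] = img
    return ndimage.gaussian_filter(out, sigma=1.0, mode="reflect") * 4.0


def _gaussian_pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [img.astype(float)]
    for _ in range(levels):
        pyr.append(_reduce(pyr[-1]))
    return pyr


def _laplacian_pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    gauss = _gaussian_pyramid(img, levels)
    pyr = [g - _expand(gauss[i + 1], g.shape) for i, g in enumerate(gauss[:-1])]
    pyr.append(gauss[-1])
    return pyr


def _collapse(pyr: list[np.ndarray]) -> np.ndarray:
    img = pyr[-1]
    for lap in reversed(pyr[:-1]):
        img = lap + _expand(img, lap.shape)
    return img


def fuse_stack(
    stack: ImageStack,
    weights: list[np.ndarray] | None = None,
    levels: int | None = None,
) -> np.ndarray:
    """Blend an aligned stack into one extended-depth-of-field image.

    Each image's Laplacian pyramid is mixed level by level using the
    Gaussian pyramid of its weight map (re-normalized per level), then
    collapsed.  Color images are blended channel-wise with the shared
    luminance weights.  Output is float, clipped to the input intensity
    range; deterministic.
    """
    images = stack.images
    if weights is None:
        weights = contrast_weights(images)
    if len(weights) != len(images):
        raise ValueError("one weight map per image required")
    for w_map, im in zip(weights, images):
        if w_map.shape != im.shape[:2]:
            raise ValueError("weight map shape must match image shape")
    if len(images) == 1:
        return images[0].astype(float)
    if levels is None:
        levels = _auto_levels(images[0].shape)

    w_pyrs = [_gaussian_pyramid(w, levels) for w in weights]
    # re-normalize the smoothed weights at every level
    w_sums = [np.sum([wp[l] for wp in w_pyrs], axis=0) for l in range(levels + 1)]

    channels = 1 if images[0].ndim == 2 else images[0].shape[2]
    fused_channels = []
    for ch in range(channels):
        planes = [im.astype(float) if im.ndim == 2 else im[..., ch].astype(float) for im in images]
        l_pyrs = [_laplacian_pyramid(p, levels) for p in planes]
        blended = [
            np.sum([wp[l] * lp[l] for wp, lp in zip(w_pyrs, l_pyrs)], axis=0)
            / np.maximum(w_sums[l], EPS)
            for l in range(levels + 1)
        ]
        fused_channels.append(_collapse(blended))
    fused = fused_channels[0] if channels == 1 else np.stack(fused_channels, axis=-1)
    lo = min(float(im.min()) for im in images)
    hi = max(float(im.max()) for im in images)
    return np.clip(fused, lo, hi)


def fuse_images(
    images: list[np.ndarray],
    z_offsets: list[float] | None = None,
    max_shift: int = 20,
    window: int = 5,
    levels: int | None = None,
) -> np.ndarray:
    """Align, weight and fuse raw frames in one call."""
    stack = ImageStack.from_images(images, z_offsets=z_offsets, max_shift=max_shift)
    return fuse_stack(stack, weights=contrast_weights(stack.images, window=window), levels=levels)


def fuse_manifest(
    manifest,
    out_dir: str | Path,
    image_format: str = "png",
    max_shift: int = 20,
    index_csv: bool = True,
) -> list[Path]:
    """Fuse every stack of a segmentation manifest to <well>.<format> files.

    Sentinel images are excluded — they carry no in-focus content.
    Returns the written paths; also writes an index CSV mapping wells to
    output files unless disabled.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    rows = []
    for s in manifest.stacks:
        frames = [iio.imread(r.path) for r in s.images]
        fused = fuse_images(frames, max_shift=max_shift)
        out = out_dir / f"{s.well}.{image_format}"
        iio.imwrite(out, np.round(fused).astype(np.uint8))
        written.append(out)
        rows.append({"well": s.well, "n_images": len(frames), "file": out.name})
    if index_csv:
        import pandas as pd

        pd.DataFrame(rows, columns=["well", "n_images", "file"]).to_csv(
            out_dir / "index.csv", index=False
        )
    return written
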