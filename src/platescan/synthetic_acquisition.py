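"""Seeded synthetic acquisitions for testing without the instrument.

Generates what the camera would have written to its SD card: one JPEG
per z-level per well, numbered in acquisition order, plus the
deliberately defocused sentinel closing each well.  Scenes are drawn
crystallization-droplet-like — a droplet edge, a few angular crystal
polygons, precipitate specks, a soft illumination gradient and sensor
noise — with enough high-frequency content that Gaussian defocus blur
measurably shrinks both the Laplacian energy and the compressed JPEG
size, which is the physical signature segmentation relies on.

Defocus follows a linear model: blur sigma (px) grows with the distance
of the stage z from the well's true best-focus height, which is
jittered per well within ±dz of the calibrated plane — the drop-height
variability that motivates capturing a z-stack in the first place.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from platescan.plate_geometry import PlateSpec
from platescan.scan_planner import ScanConfig, well_order

__all__ = [
    "SceneParams",
    "DefocusModel",
    "GroundTruthImage",
    "GroundTruth",
    "render_scene",
    "simulate_acquisition",
]

JPEG_QUALITY = 85


@dataclass(frozen=True)
class SceneParams:
    """Knobs for the synthetic droplet scene renderer.

    The default 640x360 frame keeps the 16:9 aspect of a 1080p camera
    at a size where a full plate simulates in seconds.
    """

    seed: int = 0
    width: int = 640
    height: int = 360
    n_droplet_arcs: int = 3
    n_crystals: int = 4
    n_specks: int = 120
    gradient_amplitude: float = 40.0
    noise_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("scene must be at least 64x64 pixels")
        for name in ("n_droplet_arcs", "n_crystals", "n_specks"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class DefocusModel:
    """Linear defocus: sigma = k * |z - z_best| + sigma0 (px, z in mm)."""

    k: float = 8.0
    sigma0: float = 0.5

    def sigma(self, z: float, z_best: float) -> float:
        return self.k * abs(z - z_best) + self.sigma0


@dataclass(frozen=True)
class GroundTruthImage:
    """Provenance of one emitted file."""

    filename: str
    well: str
    z_index: int | None  # None for the sentinel
    sentinel: bool
    sigma: float
    seq: int


@dataclass
class GroundTruth:
    """Everything the simulator knows that segmentation must recover."""

    plate: str
    n_z: int
    order: str
    seed: int
    jpeg_quality: int
    images: list[GroundTruthImage] = field(default_factory=list)
    z_best: dict[str, float] = field(default_factory=dict)

    def stacks(self) -> list[tuple[str, list[str], str | None]]:
        """Per-well (well, data filenames, sentinel filename) in scan order."""
        by_well: dict[str, dict] = {}
        order: list[str] = []
        for im in self.images:
            if im.well not in by_well:
                by_well[im.well] = {"data": [], "sentinel": None}
                order.append(im.well)
            if im.sentinel:
                by_well[im.well]["sentinel"] = im.filename
            else:
                by_well[im.well]["data"].append(im.filename)
        return [(w, by_well[w]["data"], by_well[w]["sentinel"]) for w in order]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "plate": self.plate,
            "n_z": self.n_z,
            "order": self.order,
            "seed": self.seed,
            "jpeg_quality": self.jpeg_quality,
            "z_best": self.z_best,
            "images": [asdict(im) for im in self.images],
        }
        Path(path).write_text(json.dumps(doc, indent=2))


def render_scene(params: SceneParams) -> np.ndarray:
    """Render the in-focus droplet scene for one well (uint8 grayscale).

    Deterministic for a given seed.  Edges everywhere — the droplet
    rim, crystal facets and point-like precipitate — give the scene the
    high-frequency energy that defocus will visibly drain.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    # soft illumination gradient
    theta = rng.uniform(0, 2 * np.pi)
    ramp = (np.cos(theta) * xx / w + np.sin(theta) * yy / h)
    img = 120.0 + params.gradient_amplitude * (ramp - ramp.mean())

    cx, cy = w / 2 + rng.uniform(-20, 20), h / 2 + rng.uniform(-15, 15)
    radius = 0.38 * min(h, w)
    rr = np.hypot(xx - cx, yy - cy)

    # droplet rim: bright ring arcs with slight radius jitter
    ang = np.arctan2(yy - cy, xx - cx)
    for _ in range(params.n_droplet_arcs):
        a0 = rng.uniform(-np.pi, np.pi)
        span = rng.uniform(1.0, 2.5)
        r_i = radius * rng.uniform(0.92, 1.05)
        in_arc = (np.mod(ang - a0, 2 * np.pi) < span) & (np.abs(rr - r_i) < 1.5)
        img[in_arc] += 80.0

    # crystals: bright convex polygons with darker outlines
    for _ in range(params.n_crystals):
        px = cx + rng.uniform(-0.5, 0.5) * radius
        py = cy + rng.uniform(-0.5, 0.5) * radius
        n_vert = rng.integers(3, 7)
        angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
        radii = rng.uniform(6, 22, n_vert)
        vx, vy = px + radii * np.cos(angles), py + radii * np.sin(angles)
        mask = _polygon_mask(h, w, vx, vy)
        img[mask] += rng.uniform(30, 70)
        edge = mask ^ ndimage.binary_erosion(mask, iterations=1)
        img[edge] -= 90.0

    # precipitate: single-pixel specks
    if params.n_specks:
        sy = rng.integers(0, h, params.n_specks)
        sx = rng.integers(0, w, params.n_specks)
        img[sy, sx] += rng.uniform(-70, 70, params.n_specks)

    img += rng.normal(0.0, params.noise_sigma, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def _polygon_mask(h: int, w: int, vx: np.ndarray, vy: np.ndarray) -> np.ndarray:
    from skimage.draw import polygon

    rr_p, cc_p = polygon(vy, vx, shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr_p, cc_p] = True
    return mask


def _encode_jpeg(img: np.ndarray, quality: int = JPEG_QUALITY) -> bytes:
    buf = io.BytesIO()
    Image.fromarray(img).save(buf, format="JPEG", quality=quality)
    return buf.getvalue()


def blurred(img: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian defocus approximation, preserving uint8 range."""
    if sigma <= 0:
        return img
    return np.clip(
        ndimage.gaussian_filter(img.astype(float), sigma=sigma), 0, 255
    ).astype(np.uint8)


def simulate_acquisition(
    spec: PlateSpec,
    config: ScanConfig,
    params: SceneParams,
    out_dir: str | Path,
    missing_prob: float = 0.0,
    defocus: DefocusModel | None = None,
) -> GroundTruth:
    """Write the JPEG series a plate scan would produce, plus ground truth.

    For each well in scan order and each z level (top to bottom) the
    well's scene is rendered, blurred per the defocus model and written
    as ``img_<seq>.jpg`` at quality 85.  The sentinel closes each well
    with sigma ``max(6*k*dz, 8)`` px — far outside the data range, so
    its JPEG is reliably the smallest of the well.  Each data image is
    independently dropped with probability ``missing_prob`` (the camera
    missing a frame); sentinels are never dropped.  Sequence numbers
    count all triggers, so dropped frames leave gaps, exactly as a
    camera that skipped a write would.

    Also writes ``ground_truth.json`` next to the images.
    """
    if not (0.0 <= missing_prob <= 0.2):
        raise ValueError("missing_prob must be in [0, 0.2]")
    defocus = defocus or DefocusModel()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)

    truth = GroundTruth(
        plate=spec.name,
        n_z=config.n_z,
        order=config.order,
        seed=params.seed,
        jpeg_quality=JPEG_QUALITY,
    )
    sigma_sentinel = max(6.0 * defocus.k * config.dz, 8.0)
    half = (config.n_z - 1) / 2.0
    seq = 0
    for k, (row, col) in enumerate(well_order(spec, config.order)):
        well = spec.well_label(row, col)
        scene_seed = int(rng.integers(0, 2**31 - 1))
        scene = render_scene(
            SceneParams(
                seed=scene_seed,
                width=params.width,
                height=params.height,
                n_droplet_arcs=params.n_droplet_arcs,
                n_crystals=params.n_crystals,
                n_specks=params.n_specks,
                gradient_amplitude=params.gradient_amplitude,
                noise_sigma=params.noise_sigma,
            )
        )
        z_best = float(rng.uniform(-config.dz, config.dz))
        truth.z_best[well] = z_best

        min_data_size = None
        for i in range(config.n_z):
            z = config.dz * (half - i)  # relative to the calibrated focus
            sigma = defocus.sigma(z, z_best)
            seq += 1
            dropped = bool(rng.random() < missing_prob)
            if dropped:
                continue
            data = _encode_jpeg(blurred(scene, sigma))
            name = f"img_{seq:04d}.jpg"
            (out_dir / name).write_bytes(data)
            truth.images.append(
                GroundTruthImage(
                    filename=name, well=well, z_index=i, sentinel=False,
                    sigma=sigma, seq=seq,
                )
            )
            min_data_size = min(min_data_size or len(data), len(data))

        if config.sentinel:
            seq += 1
            sigma = sigma_sentinel
            data = _encode_jpeg(blurred(scene, sigma))
            # guarantee the size signature: blur harder until the sentinel
            # is clearly the smallest file of its well
            while min_data_size is not None and len(data) >= 0.75 * min_data_size:
                sigma *= 1.5
                data = _encode_jpeg(blurred(scene, sigma))
            name = f"img_{seq:04d}.jpg"
            (out_dir / name).write_bytes(data)
            truth.images.append(
                GroundTruthImage(
                    filename=name, well=well, z_index=None, sentinel=True,
                    sigma=sigma, seq=seq,
                )
            )

    truth.to_json(out_dir / "ground_truth.json")
    return truth
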