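"""Synthetic annotated lesion images.

The generator emulates the statistical structure of half-face acne
photograph datasets without any download: a long-tailed per-image lesion
count (geometric-like, mode at 1, truncated to 1..C_max), cone-like spots
(radial intensity peak with linear falloff, reddish against a skin-tone
background) each tightly enclosed by one rectangular box with the apex at
the box center, a smooth illumination gradient, and additive pixel noise.
Boxes may overlap when spots are near each other; spot centers are kept at
least one radius apart so the ground-truth count stays well defined.

Two presets bracket the difficulty range studied here: ``easy`` (counts
1..10, well-separated spots, mild illumination variation) and ``hard``
(counts 51..65, dense spots, strong illumination variation) — the hard
preset reproduces the regime where count estimation breaks down at very
high lesion density.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from PIL import Image

from .annotations import AnnotatedImage, LesionBox, write_voc_xml
from .grading import DEFAULT_C_MAX, GradingScheme, severity_from_count

__all__ = [
    "SyntheticSpec",
    "sample_count",
    "generate_image",
    "generate_images",
    "generate_dataset",
    "peak_count_oracle",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic lesion-image distribution.

    ``count_geom_p`` is the success probability of the truncated geometric
    count sampler (smaller = longer tail); ``count_range`` further restricts
    the support.  ``sep_factor`` scales the minimum center-to-center
    distance in units of the larger spot's radius.  Intensities are 8-bit.
    """

    image_size: int = 96
    c_max: int = DEFAULT_C_MAX
    count_geom_p: float = 0.1
    count_range: tuple[int, int] = (1, DEFAULT_C_MAX)
    radius_range: tuple[float, float] = (4.0, 6.0)
    spot_delta: tuple[float, float, float] = (70.0, 25.0, 20.0)  # peak RGB boost
    background: tuple[float, float, float] = (196.0, 160.0, 140.0)
    background_jitter: float = 12.0  # per-image uniform tone shift
    illumination_amplitude: float = 10.0  # linear ramp, +/- this many levels
    noise_sd: float = 3.0
    sep_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_range[0] < 2.0:
            raise ValueError("spot radius must be >= 2 px")
        lo, hi = self.count_range
        if not 1 <= lo <= hi <= self.c_max:
            raise ValueError("count_range must lie within [1, c_max]")


def easy_spec(**kw) -> SyntheticSpec:
    """Low-density preset: counts 1..10, non-overlapping boxes."""
    defaults = dict(count_range=(1, 10), sep_factor=2.3)
    defaults.update(kw)
    return SyntheticSpec(**defaults)


def hard_spec(**kw) -> SyntheticSpec:
    """High-density preset (counts > 50): crowded spots, strong illumination."""
    defaults = dict(
        count_range=(51, DEFAULT_C_MAX),
        radius_range=(3.0, 5.0),
        sep_factor=1.0,
        illumination_amplitude=30.0,
        noise_sd=6.0,
    )
    defaults.update(kw)
    return SyntheticSpec(**defaults)


def sample_count(spec: SyntheticSpec, rng: np.random.Generator) -> int:
    """Draw a lesion count from the truncated geometric distribution.

    The geometric shape gives the long tail observed in real data (most
    images carry few lesions, mode at the lower end of the support);
    rejection keeps the draw inside ``count_range``.
    """
    lo, hi = spec.count_range
    while True:
        c = lo - 1 + rng.geometric(spec.count_geom_p)
        if c <= hi:
            return int(c)


def _place_centers(
    count: int, radius: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample spot centers with minimum separation; spots stay
    fully inside the image."""
    size = spec.image_size
    centers = np.empty((count, 2))
    for i in range(count):
        r = radius[i]
        placed = False
        for _ in range(2000):
            c = rng.uniform(r + 1, size - r - 1, size=2)
            if i == 0:
                placed = True
            else:
                d = np.hypot(*(centers[:i] - c).T)
                min_sep = spec.sep_factor * np.maximum(radius[:i], r)
                placed = bool(np.all(d >= min_sep))
            if placed:
                centers[i] = c
                break
        if not placed:
            raise ValueError(
                f"cannot place {count} spots of radius ~{r:.0f} in a "
                f"{size}x{size} image at separation factor {spec.sep_factor}"
            )
    return centers


def generate_image(
    spec: SyntheticSpec,
    count: int,
    rng: np.random.Generator,
    image_id: str = "synthetic",
    scheme: GradingScheme | None = None,
) -> AnnotatedImage:
    """Render exactly ``count`` cone-like spots and their tight boxes.

    Each spot adds a reddish radial cone (peak at the center, linear
    falloff to zero at its radius) to the skin-tone background; its box is
    the enclosing square, so the apex sits at the box center.  If placement
    fails at the sampled radii, the radii are reduced once before erroring.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    scheme = scheme or GradingScheme()
    size = spec.image_size
    r_lo, r_hi = spec.radius_range
    radius = rng.uniform(r_lo, r_hi, size=count)
    try:
        centers = _place_centers(count, radius, spec, rng)
    except ValueError:
        radius = np.full(count, max(2.0, r_lo * 0.6))
        centers = _place_centers(count, radius, spec, rng)

    base = np.asarray(spec.background) + rng.uniform(
        -spec.background_jitter, spec.background_jitter, size=3
    )
    img = np.broadcast_to(base, (size, size, 3)).astype(np.float64).copy()
    # smooth illumination: linear ramp in a random direction
    theta = rng.uniform(0.0, 2.0 * np.pi)
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1)
    ramp = (xx - 0.5) * np.cos(theta) + (yy - 0.5) * np.sin(theta)
    img += (spec.illumination_amplitude * 2.0 * ramp)[:, :, None]

    boxes = []
    for (cy, cx), r in zip(centers[:, ::-1], radius):
        x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
        y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
        ys, xs = np.mgrid[y0:y1, x0:x1]
        cone = np.clip(1.0 - np.hypot(xs - cx, ys - cy) / r, 0.0, None)
        img[y0:y1, x0:x1] += cone[:, :, None] * np.asarray(spec.spot_delta)
        # pixel-aligned tight enclosure (rounded outward); keeps the apex at
        # the box center within half a pixel and makes VOC I/O exact
        boxes.append(
            LesionBox(
                xmin=float(np.clip(np.floor(cx - r), 0, size)),
                ymin=float(np.clip(np.floor(cy - r), 0, size)),
                xmax=float(np.clip(np.ceil(cx + r), 0, size)),
                ymax=float(np.clip(np.ceil(cy + r), 0, size)),
            )
        )
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    out = AnnotatedImage(
        image_id=image_id,
        width=size,
        height=size,
        boxes=boxes,
        pixels=pixels,
        count=count,
    )
    if count <= scheme.c_max:
        out.with_severity(scheme)
    return out


def generate_images(
    n_images: int,
    spec: SyntheticSpec | None = None,
    seed: int = 0,
    scheme: GradingScheme | None = None,
    id_prefix: str = "syn",
) -> list[AnnotatedImage]:
    """In-memory dataset: ``n_images`` annotated images, deterministic in seed."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_images):
        count = sample_count(spec, rng)
        out.append(
            generate_image(spec, count, rng, image_id=f"{id_prefix}_{i:05d}", scheme=scheme)
        )
    return out


def generate_dataset(
    n_images: int,
    spec: SyntheticSpec | None = None,
    seed: int = 0,
    out_dir: str | Path = "synthetic_dataset",
    scheme: GradingScheme | None = None,
) -> Path:
    """Write PNG images, VOC XML annotations and a YAML manifest to disk."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    imgs = generate_images(n_images, spec, seed, scheme)
    records = []
    for img in imgs:
        png = out_dir / "images" / f"{img.image_id}.png"
        xml = out_dir / "annotations" / f"{img.image_id}.xml"
        Image.fromarray(img.pixels).save(png)
        write_voc_xml(img, xml)
        records.append(
            {
                "id": img.image_id,
                "image": str(png.relative_to(out_dir)),
                "annotation": str(xml.relative_to(out_dir)),
                "count": int(img.count),
                "severity": img.severity.name if img.severity else None,
            }
        )
    manifest = {"seed": seed, "n_images": n_images, "items": records}
    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out_dir


def peak_count_oracle(img: AnnotatedImage, min_distance: int = 4) -> int:
    """Count lesions by local brightness maxima — a model-free check that
    the rendered images carry the count signal.

    Works on low-density images with non-overlapping spots; dense or
    overlapping spots merge peaks and break the count.
    """
    from scipy import ndimage

    red = img.pixels[:, :, 0].astype(float) - img.pixels[:, :, 1].astype(float)
    smooth = ndimage.gaussian_filter(red, sigma=1.5)
    footprint = np.ones((2 * min_distance + 1, 2 * min_distance + 1))
    local_max = ndimage.maximum_filter(smooth, footprint=footprint) == smooth
    threshold = smooth.mean() + 0.35 * (smooth.max() - smooth.mean())
    return int(np.count_nonzero(local_max & (smooth > threshold)))
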