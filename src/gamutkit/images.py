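"""Image ingestion and corpus iteration with fixed byte conventions.

Byte value v maps to (v + 0.5) / 256 (and 16-bit analogously), so ingested
channel values always lie strictly inside (0, 1) and the inverse logistic
map downstream can never hit an infinity.  No color management is applied:
monotone in-camera transfer curves are part of what the covariance analysis
is designed to tolerate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .exceptions import DomainError, InputFormatError

__all__ = [
    "CorpusSpec",
    "read_image",
    "write_image",
    "iterate_corpus",
]

_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


@dataclass(frozen=True)
class CorpusSpec:
    """A set of images plus optional row-band cropping and subsampling.

    ``paths`` may be image files or a directory.  If the crop fractions are
    positive, the top and bottom row bands are yielded as separate regions
    (e.g. 0.25/0.25 splits 256-row frames into 64-row sky and ground bands).
    ``max_pixels_per_image`` caps the per-region sample by seeded uniform
    subsampling; the statistics are within sampling error of the full frame.
    """

    paths: tuple
    crop_top_fraction: float = 0.0
    crop_bottom_fraction: float = 0.0
    max_pixels_per_image: int = 100_000
    seed: int = 0

    def __post_init__(self):
        for f in (self.crop_top_fraction, self.crop_bottom_fraction):
            if not 0.0 <= f <= 0.5:
                raise DomainError("crop fractions must lie in [0, 0.5]")
        if self.max_pixels_per_image < 1000:
            raise DomainError("pixel cap must be at least 1000")
        paths = self.paths
        if isinstance(paths, (str, Path)):
            paths = (paths,)
        object.__setattr__(self, "paths", tuple(str(p) for p in paths))


def read_image(path) -> np.ndarray:
    """Read a PNG/JPEG into an (H, W, 3) float array strictly inside (0, 1).

    8-bit values map as (v + 0.5) / 256, 16-bit as (v + 0.5) / 65536.
    Grayscale images are promoted by channel replication (with a warning);
    an alpha channel is dropped.
    """
    try:
        raw = iio.imread(path)
    except Exception as exc:
        raise InputFormatError(f"could not read image {path!s}: {exc}") from exc
    if raw.dtype == np.uint8:
        arr = (raw.astype(np.float64) + 0.5) / 256.0
    elif raw.dtype == np.uint16:
        arr = (raw.astype(np.float64) + 0.5) / 65536.0
    else:
        raise InputFormatError(f"unsupported pixel type {raw.dtype} in {path!s}")
    if arr.ndim == 2:
        warnings.warn(f"{path!s} is grayscale; replicating to three channels")
        arr = np.stack([arr, arr, arr], axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise InputFormatError(f"unexpected image shape {raw.shape} in {path!s}")
    return arr


def write_image(path, rgb: np.ndarray) -> None:
    """Quantize a float RGB field to 8 bits and write it.

    Uses v -> round(256 v - 0.5), the exact inverse of the ingestion
    convention, so write-then-read round trips to within half a byte step.
    """
    rgb = np.asarray(rgb, dtype=float)
    bytes_ = np.clip(np.round(256.0 * rgb - 0.5), 0, 255).astype(np.uint8)
    iio.imwrite(path, bytes_)


def _expand_paths(paths) -> list:
    files = []
    for p in paths:
        p = Path(p)
        if p.is_dir():
            files.extend(
                q for q in p.iterdir() if q.suffix.lower() in _IMAGE_SUFFIXES
            )
        else:
            files.append(p)
    return sorted(set(files))


def _subsample(pixels: np.ndarray, cap: int, rng) -> np.ndarray:
    if pixels.shape[0] <= cap:
        return pixels
    idx = rng.choice(pixels.shape[0], size=cap, replace=False)
    return pixels[np.sort(idx)]


def iterate_corpus(spec: CorpusSpec):
    """Yield (image id, region label, pixel array) over a corpus.

    Regions are ``"full"`` plus, when crop fractions are set, ``"top"`` and
    ``"bottom"`` row bands.  Iteration order is the sorted file list and the
    per-image subsampling is seeded by (spec.seed, image index), so a given
    spec always yields identical samples.
    """
    files = _expand_paths(spec.paths)
    if not files:
        raise InputFormatError("corpus contains no readable images")
    for i, path in enumerate(files):
        arr = read_image(path)
        h = arr.shape[0]
        rng = np.random.default_rng([spec.seed, i])
        regions = [("full", arr)]
        if spec.crop_top_fraction > 0:
            regions.append(("top", arr[: int(round(h * spec.crop_top_fraction))]))
        if spec.crop_bottom_fraction > 0:
            regions.append(
                ("bottom", arr[h - int(round(h * spec.crop_bottom_fraction)) :])
            )
        for label, region in regions:
            pixels = region.reshape(-1, 3)
            yield path.stem, label, _subsample(
                pixels, spec.max_pixels_per_image, rng
            )
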