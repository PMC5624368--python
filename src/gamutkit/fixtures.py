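"""Synthetic image corpora with prescribed gamut signatures.

Stands in for natural-image databases: each image is filled with samples
from the six-parameter gamut generator (optionally smoothed in the physical
domain to emulate spatial coherence), quantized to 8 bits and written as
PNG.  A two-region mode stacks an "aerial" band with its own signature over
a "ground" band, emulating the sky/foreground banding of landscape corpora.
A JSON manifest records every parameter and seed, so a fixture regenerates
bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .exceptions import DomainError
from .gamut_gen import GamutParams
from .homomorphic import omega, opponent_inverse
from .images import write_image

__all__ = ["FixtureSpec", "make_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Layout and statistics of a synthetic corpus.

    ``signature`` drives the whole frame; if ``signature_top`` is given, the
    upper ``top_fraction`` of rows uses it instead (two-region landscape
    mode).  ``spatial_smoothing`` is a Gaussian blur radius in pixels
    applied in the physical domain, before the logistic squashing, so the
    per-pixel marginals keep (approximately) their family.
    """

    n_images: int
    width: int
    height: int
    signature: GamutParams
    signature_top: GamutParams | None = None
    top_fraction: float = 0.25
    spatial_smoothing: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_images < 1:
            raise DomainError("need at least one image")
        if self.width < 16 or self.height < 16:
            raise DomainError("fixture images must be at least 16x16")
        if not 0.0 < self.top_fraction < 1.0:
            raise DomainError("top_fraction must lie in (0, 1)")
        if self.spatial_smoothing < 0:
            raise DomainError("smoothing radius must be nonnegative")


def _physical_field(params: GamutParams, shape, rng) -> np.ndarray:
    deviates = params.mus + params.sigmas * rng.standard_normal((*shape, 3))
    return opponent_inverse(deviates)


def make_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Write the fixture images plus a manifest; returns the manifest.

    Image i is generated from np.random.default_rng([seed, i]), so any
    single image can be regenerated without producing the others.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h, w = spec.height, spec.width
    top_rows = int(round(h * spec.top_fraction)) if spec.signature_top else 0
    files = []
    for i in range(spec.n_images):
        rng = np.random.default_rng([spec.seed, i])
        physical = _physical_field(spec.signature, (h, w), rng)
        if spec.signature_top is not None:
            physical[:top_rows] = _physical_field(
                spec.signature_top, (top_rows, w), rng
            )
        if spec.spatial_smoothing > 0:
            for c in range(3):
                physical[..., c] = ndimage.gaussian_filter(
                    physical[..., c], spec.spatial_smoothing
                )
        name = f"fixture_{i:04d}.png"
        write_image(out / name, omega(physical))
        files.append(name)

    def params_dict(p):
        return None if p is None else {
            "mu_lambda": p.mu_lambda,
            "mu_theta": p.mu_theta,
            "mu_xi": p.mu_xi,
            "sigma_lambda": p.sigma_lambda,
            "sigma_theta": p.sigma_theta,
            "sigma_xi": p.sigma_xi,
        }

    manifest = {
        "n_images": spec.n_images,
        "width": w,
        "height": h,
        "signature": params_dict(spec.signature),
        "signature_top": params_dict(spec.signature_top),
        "top_fraction": spec.top_fraction,
        "spatial_smoothing": spec.spatial_smoothing,
        "seed": spec.seed,
        "per_image_seed": "default_rng([seed, image_index])",
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
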