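"""Toy generative model of reflectance spectra and its three-bin statistics.

Random reflectance spectra are built from a stationary Gaussian articulation
process g on the visible range (length normalized to 1), with a Lorentzian
power spectrum

    S(f) proportional to 1 / (f**2 + f_c**2),   f_c = 1 / (2 pi tau),

so that the articulation power falls off as the inverse square of the
frequency over the resolved band and the autocorrelation length is tau (in
units of the range width).  A smoothness cutoff f_max truncates the spectrum
at high frequencies: measured reflectance spectra carry no articulation at
very fine spectral scales, and the cutoff keeps realizations smooth between
grid samples.  The process is standardized to zero mean and unit variance and
squashed into (0, 1):

    reflectance(l) = Omega(shift + scale * g(l)).

Binning each spectrum into equal thirds yields an RGB triple per spectrum
(the bins stand in for the parts-of-daylight bands).  Ensembles of such
triples reproduce the covariance structure of natural images: correlation
decreasing with bin separation, a dominant achromatic eigenvector, and
second/third eigenvectors near the opponent axes.

In the large-``scale`` limit the squashed spectra degenerate to random
telegraph waves; their binned RGB values accumulate on the six cube edges
reachable by single spectral transitions (black-red, red-yellow,
yellow-white, white-cyan, cyan-blue, blue-black) -- the boundary colors of a
single spectral edge -- while the six green/magenta edges stay unpopulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError
from .gamut_stats import CovarianceSummary, summarize
from .homomorphic import clamp_observations, omega, to_physical

__all__ = [
    "SpectralModelParams",
    "ToySpectrum",
    "TelegraphResult",
    "GOETHE_EDGES",
    "OTHER_EDGES",
    "sample_articulation",
    "sample_spectrum",
    "sample_spectra",
    "telegraph_params",
    "bin_rgb",
    "model_ensemble",
    "telegraph_limit_check",
]

_CUBE_VERTICES = {
    "black": (0, 0, 0),
    "red": (1, 0, 0),
    "green": (0, 1, 0),
    "blue": (0, 0, 1),
    "yellow": (1, 1, 0),
    "cyan": (0, 1, 1),
    "magenta": (1, 0, 1),
    "white": (1, 1, 1),
}

#: Edges reachable by spectra with a single 0/1 transition: the boundary
#: ("edge color") gamut.  The first channel is the first (short-wave) bin.
GOETHE_EDGES = (
    ("black", "red"),
    ("red", "yellow"),
    ("yellow", "white"),
    ("white", "cyan"),
    ("cyan", "blue"),
    ("blue", "black"),
)

#: The remaining six cube edges (through the green and magenta corners).
OTHER_EDGES = (
    ("black", "green"),
    ("green", "yellow"),
    ("green", "cyan"),
    ("red", "magenta"),
    ("blue", "magenta"),
    ("magenta", "white"),
)


@dataclass(frozen=True)
class SpectralModelParams:
    """Parameters of the articulation process and its squashing.

    tau
        Autocorrelation length in units of the visible-range width
        (default: one bin width, 1/3).
    shift, scale
        Location and amplitude applied before the logistic squashing.
    n_wavelengths
        Grid size over the range; must be divisible by 3.
    f_max
        Smoothness cutoff in cycles per range width.  The default (8.0)
        leaves roughly a decade of inverse-square rolloff above f_c while
        keeping realizations smooth at the sub-bin scale.
    oversample
        The process is synthesized on an ``oversample``-times longer
        periodic domain and cropped, so the crop is effectively
        non-periodic.
    """

    tau: float = 1.0 / 3.0
    shift: float = 0.0
    scale: float = 1.0
    n_wavelengths: int = 96
    f_max: float = 8.0
    oversample: int = 4
    seed: int | None = None

    def __post_init__(self):
        if self.tau <= 0:
            raise DomainError("tau must be positive")
        if self.scale < 0:
            raise DomainError("scale must be nonnegative")
        if self.n_wavelengths < 3 or self.n_wavelengths % 3 != 0:
            raise DomainError("n_wavelengths must be a positive multiple of 3")
        if self.f_max <= 0:
            raise DomainError("f_max must be positive")
        if self.oversample < 1:
            raise DomainError("oversample must be at least 1")

    @property
    def f_c(self) -> float:
        return 1.0 / (2.0 * np.pi * self.tau)

    @property
    def grid(self) -> np.ndarray:
        """Sample positions in range units, midpoint convention."""
        n = self.n_wavelengths
        return (np.arange(n) + 0.5) / n


@dataclass(frozen=True)
class ToySpectrum:
    """A single random reflectance spectrum on the normalized range."""

    values: np.ndarray
    grid: np.ndarray


@dataclass(frozen=True)
class TelegraphResult:
    """Edge occupancy of binned RGB samples in the telegraph-wave limit."""

    fraction_goethe: float
    goethe_counts: dict
    other_counts: dict
    edge_tol: float
    n: int


def sample_articulation(
    params: SpectralModelParams, n_spectra: int, seed=None
) -> np.ndarray:
    """Standardized articulation processes, shape (n_spectra, n_wavelengths).

    Spectral synthesis: independent complex-normal Fourier coefficients with
    amplitude sqrt(S(f)), inverse FFT on the oversampled periodic domain,
    crop to the unit range, and divide by the theoretical standard deviation
    (exact, not per-realization, so the process stays stationary Gaussian
    with unit variance).
    """
    if n_spectra < 1:
        raise DomainError("n_spectra must be at least 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_wavelengths
    m = params.oversample * n
    freqs = np.fft.rfftfreq(m, d=1.0 / n)  # cycles per range width
    psd = 1.0 / (freqs**2 + params.f_c**2)
    psd[freqs > params.f_max] = 0.0
    amp = np.sqrt(psd)
    n_freq = amp.size
    re = rng.standard_normal((n_spectra, n_freq))
    im = rng.standard_normal((n_spectra, n_freq))
    coeff = amp * (re + 1j * im)
    coeff[:, 0] = amp[0] * re[:, 0]  # DC must be real
    if m % 2 == 0:
        coeff[:, -1] = 0.0  # drop the Nyquist bin
    g = np.fft.irfft(coeff, n=m)[:, :n]
    var = (psd[0] + 4.0 * psd[1:-1].sum()) / m**2 if m % 2 == 0 else (
        psd[0] + 4.0 * psd[1:].sum()
    ) / m**2
    return g / np.sqrt(var)


def sample_spectra(
    params: SpectralModelParams, n_spectra: int, seed=None
) -> np.ndarray:
    """Random reflectance spectra, shape (n_spectra, n_wavelengths)."""
    g = sample_articulation(params, n_spectra, seed=seed)
    reflectance = omega(params.shift + params.scale * g)
    # keep the open-interval invariant even where omega saturates in float
    return np.clip(reflectance, 1e-15, 1.0 - 1e-15)


def telegraph_params(seed=None) -> SpectralModelParams:
    """Parameters of the telegraph-wave (edge-color) limit.

    Near-binary spectra require a large squashing amplitude, and the
    single-transition regime requires the articulation to vary slowly
    compared with the visible window: a zero-mean stationary process whose
    correlation falls to 1/e within one bin necessarily crosses zero more
    than once per window (Rice's formula bounds the crossing rate from below
    by the decorrelation it must achieve), and multi-transition spectra land
    inside the cube rather than on its edges.  The preset therefore uses a
    correlation length of ten window widths with amplitude 50; binned
    samples then concentrate on the six single-transition edges with the
    green/magenta edges essentially unpopulated.
    """
    return SpectralModelParams(tau=10.0, shift=0.0, scale=50.0, seed=seed)


def sample_spectrum(params: SpectralModelParams) -> ToySpectrum:
    """A single random reflectance spectrum (seeded by the params)."""
    values = sample_spectra(params, 1)[0]
    return ToySpectrum(values=values, grid=params.grid)


def bin_rgb(spectrum) -> np.ndarray:
    """Mean reflectance over each third of the grid.

    Accepts a :class:`ToySpectrum`, a single spectrum array, or a batch with
    spectra along the last axis.  The first output channel is the first
    (lowest-wavelength) bin.
    """
    values = getattr(spectrum, "values", spectrum)
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    if n % 3 != 0:
        raise DomainError("spectrum length must be divisible by 3")
    return values.reshape(*values.shape[:-1], 3, n // 3).mean(axis=-1)


def model_ensemble(params: SpectralModelParams, n: int, seed=None):
    """n random spectra binned to RGB, plus their physical-domain summary.

    Returns ``(rgb, CovarianceSummary)``; the summary is computed on the
    clamped, logistically unmapped (physical-domain) triples.
    """
    if n < 100:
        raise DomainError("ensemble statistics need at least 100 spectra")
    rgb = bin_rgb(sample_spectra(params, n, seed=seed))
    physical = to_physical(clamp_observations(rgb))
    summary: CovarianceSummary = summarize(physical)
    return rgb, summary


def _edge_endpoints(edges):
    return [
        (np.array(_CUBE_VERTICES[a], float), np.array(_CUBE_VERTICES[b], float))
        for a, b in edges
    ]


def _distance_to_segment(points, a, b):
    ab = b - a
    t = np.clip((points - a) @ ab / (ab @ ab), 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(points - closest, axis=1)


def telegraph_limit_check(
    params: SpectralModelParams,
    n: int,
    edge_tol: float = 0.05,
    seed=None,
) -> TelegraphResult:
    """Edge occupancy of the binned RGB gamut in the near-binary limit.

    Requires ``scale >= 5`` so that the squashed spectra are effectively
    two-valued.  Each sample is attributed to every edge within ``edge_tol``
    (Euclidean distance to the segment); ``fraction_goethe`` is the fraction
    of samples within tolerance of at least one of the six single-transition
    edges.
    """
    if params.scale < 5:
        raise DomainError("telegraph limit requires scale >= 5")
    rgb = bin_rgb(sample_spectra(params, n, seed=seed))
    goethe = _edge_endpoints(GOETHE_EDGES)
    other = _edge_endpoints(OTHER_EDGES)
    goethe_d = np.stack([_distance_to_segment(rgb, a, b) for a, b in goethe])
    other_d = np.stack([_distance_to_segment(rgb, a, b) for a, b in other])
    near_goethe = (goethe_d <= edge_tol).any(axis=0)
    goethe_counts = {
        "-".join(e): int((goethe_d[i] <= edge_tol).sum())
        for i, e in enumerate(GOETHE_EDGES)
    }
    # Six cube corners lie on the single-transition hexagon, so a sample
    # near one of them is also within tolerance of the two green/magenta
    # edges meeting there; occupancy of the other six edges counts only
    # samples that are not near any single-transition edge.
    other_counts = {
        "-".join(e): int(((other_d[i] <= edge_tol) & ~near_goethe).sum())
        for i, e in enumerate(OTHER_EDGES)
    }
    return TelegraphResult(
        fraction_goethe=float(near_goethe.mean()),
        goethe_counts=goethe_counts,
        other_counts=other_counts,
        edge_tol=edge_tol,
        n=int(rgb.shape[0]),
    )
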