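"""Six-parameter generative model of color gamuts.

Opponent-channel values are drawn as independent normals in the physical
domain,

    lambda ~ N(mu_lambda, sigma_lambda),
    theta  ~ N(mu_theta,  sigma_theta),
    xi     ~ N(mu_xi,     sigma_xi),

mapped to physical channel values by the inverse opponent transform and
squashed into (0, 1) by the logistic map.  Six numbers thus parameterize a
full RGB gamut: mu_lambda sets the overall level, sigma_lambda the monochrome
contrast, (mu_theta, sigma_theta) the red-blue location and spread, and
(mu_xi, sigma_xi) the green-purple location and spread.

Two presets are provided.  The "sublunar" preset uses the median spreads
observed across natural-image corpora (1.07, 0.47, 0.13): strongly
correlated channels dominated by gray contrast.  The "alien" preset uses
equal spreads chosen to flatten the RGB histograms (matching the physical
channel variance to that of the logistic distribution omega maps to
uniform), producing only weakly correlated channels and colors that do not
occur in natural terrain.

The distortion experiment quantifies why uncalibrated imagery is still
usable: per-channel gamma and gain distortions of realistic (highly
correlated) samples barely change the values' correlation with the
undistorted truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError
from .gamut_stats import GamutSignature
from .homomorphic import CLAMP_DELTA, GUARD_DELTA, omega, opponent_inverse

__all__ = [
    "GamutParams",
    "DistortionParams",
    "DistortionResult",
    "ALIEN_SIGMA",
    "sample_gamut",
    "alien_preset",
    "sublunar_preset",
    "render_swatch",
    "distortion_experiment",
]

#: Equal opponent-channel spread that best flattens the RGB histograms.
#: omega is the CDF of the logistic(0, 1/2) distribution, whose variance is
#: pi^2/12, so a physical channel is flattened when its variance is pi^2/12.
#: Equal opponent deviates of variance s^2 produce physical channel
#: variances of (22/9, 25/9, 22/9) s^2 through the (non-orthogonal) inverse
#: opponent transform; matching the mean channel variance pi^2/12 gives
#: s = pi/sqrt(12 * 23/9) ~ 0.567.
ALIEN_SIGMA = float(np.pi / np.sqrt(12.0 * 23.0 / 9.0))


@dataclass(frozen=True)
class GamutParams:
    """Location and spread of the three opponent channels (physical domain)."""

    mu_lambda: float = 0.0
    mu_theta: float = 0.0
    mu_xi: float = 0.0
    sigma_lambda: float = 1.0
    sigma_theta: float = 0.5
    sigma_xi: float = 0.1

    def __post_init__(self):
        if min(self.sigma_lambda, self.sigma_theta, self.sigma_xi) < 0:
            raise DomainError("sigmas must be nonnegative")

    @property
    def mus(self) -> np.ndarray:
        return np.array([self.mu_lambda, self.mu_theta, self.mu_xi])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([self.sigma_lambda, self.sigma_theta, self.sigma_xi])

    def to_signature(self) -> GamutSignature:
        return GamutSignature(*self.mus, *self.sigmas)

    @classmethod
    def from_signature(cls, signature: GamutSignature) -> "GamutParams":
        return cls(*signature.mus, *signature.sigmas)


@dataclass(frozen=True)
class DistortionParams:
    """Per-channel gamma/gain distortion ensemble for the robustness test."""

    gamma_range: tuple = (0.5, 1.5)
    gain_range: tuple = (0.5, 1.5)
    n_draws: int = 1000
    n_samples: int = 10_000
    seed: int | None = None

    def __post_init__(self):
        for lo, hi in (self.gamma_range, self.gain_range):
            if lo <= 0 or hi < lo:
                raise DomainError("ranges must be positive intervals")
        if self.n_draws < 1 or self.n_samples < 2:
            raise DomainError("need at least 1 draw and 2 samples")


@dataclass(frozen=True)
class DistortionResult:
    median: float
    q1: float
    q3: float
    correlations: np.ndarray


def sample_gamut(params: GamutParams, n: int, seed=None) -> np.ndarray:
    """Draw n RGB triples from the six-parameter gamut model.

    Returns an (n, 3) array with every entry strictly inside (0, 1).
    Reproducible for a fixed seed.
    """
    if n < 1:
        raise DomainError("n must be at least 1")
    rng = np.random.default_rng(seed)
    deviates = params.mus + params.sigmas * rng.standard_normal((int(n), 3))
    # omega saturates to exactly 0/1 in double precision for |x| > ~19;
    # guard so the open-interval invariant holds for any parameter widths
    return np.clip(omega(opponent_inverse(deviates)), GUARD_DELTA, 1.0 - GUARD_DELTA)


def alien_preset() -> GamutParams:
    """Equal spreads flattening the RGB histograms; weakly correlated
    channels (the residual red-blue correlation ~0.18 is structural: equal
    opponent spreads cannot zero it)."""
    return GamutParams(
        0.0, 0.0, 0.0, ALIEN_SIGMA, ALIEN_SIGMA, ALIEN_SIGMA
    )


def sublunar_preset() -> GamutParams:
    """Median natural-corpus spreads: gray-dominated, correlated channels."""
    return GamutParams(0.0, 0.0, 0.0, 1.07, 0.47, 0.13)


def render_swatch(
    samples: np.ndarray, width: int, height: int, cell: int = 8
) -> np.ndarray:
    """Render samples as a (height x width) grid of square color cells.

    Fills row-major and quantizes with v -> round(256 v - 0.5), the inverse
    of the (v + 0.5)/256 byte-ingestion convention.  Returns an 8-bit image
    array of shape (height*cell, width*cell, 3).
    """
    samples = np.asarray(samples, dtype=float).reshape(-1, 3)
    if width < 1 or height < 1 or cell < 1:
        raise DomainError("width, height and cell must be positive")
    if samples.shape[0] < width * height:
        raise DomainError(
            f"need {width * height} samples for a {width}x{height} grid, "
            f"got {samples.shape[0]}"
        )
    grid = samples[: width * height].reshape(height, width, 3)
    bytes_ = np.clip(np.round(256.0 * grid - 0.5), 0, 255).astype(np.uint8)
    return np.repeat(np.repeat(bytes_, cell, axis=0), cell, axis=1)


def distortion_experiment(
    cov_physical: np.ndarray,
    means: np.ndarray,
    dp: DistortionParams,
) -> DistortionResult:
    """Correlation between distorted and true channel values.

    Draws Gaussian physical-domain triples with the given mean and
    covariance, squashes them to "true" RGB values, and for each distortion
    draw applies an independent per-channel gain A ~ U(gain_range) and gamma
    g ~ U(gamma_range) as (A v)**g, clipped to the ingestion interval.  Each
    draw contributes the Pearson correlation between distorted and true
    values within each of the three channels (each channel suffers its own
    monotone distortion); the result reports the median and quartiles of the
    pooled per-channel coefficients.
    """
    cov = np.asarray(cov_physical, dtype=float)
    means = np.asarray(means, dtype=float).reshape(3)
    if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
        raise DomainError("covariance must be symmetric 3x3")
    evals = np.linalg.eigvalsh(cov)
    if evals.min() < -1e-10 * max(evals.max(), 1.0):
        raise DomainError("covariance must be positive semidefinite")
    rng = np.random.default_rng(dp.seed)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(3) * max(evals.max(), 1.0))
    physical = means + rng.standard_normal((dp.n_samples, 3)) @ chol.T
    true = omega(physical)
    true_centered = true - true.mean(axis=0)
    true_norm = np.sqrt(np.sum(true_centered**2, axis=0))
    corrs = np.empty((dp.n_draws, 3))
    for k in range(dp.n_draws):
        gamma = rng.uniform(*dp.gamma_range, size=3)
        gain = rng.uniform(*dp.gain_range, size=3)
        distorted = np.clip(
            (gain * true) ** gamma, CLAMP_DELTA, 1.0 - CLAMP_DELTA
        )
        d_centered = distorted - distorted.mean(axis=0)
        corrs[k] = np.sum(d_centered * true_centered, axis=0) / (
            np.sqrt(np.sum(d_centered**2, axis=0)) * true_norm
        )
    corrs = corrs.reshape(-1)
    q1, med, q3 = np.percentile(corrs, [25, 50, 75])
    return DistortionResult(
        median=float(med), q1=float(q1), q3=float(q3), correlations=corrs
    )
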