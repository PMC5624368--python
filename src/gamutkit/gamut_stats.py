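"""Covariance and eigenstructure of channel triples; gamut signatures.

Natural RGB triples are highly correlated across channels.  In a narrow,
statistically translation-invariant spectral window the channel covariance is
expected to take the near-singular form

    C = [[1, 1-e1, 1-e2], [1-e1, 1, 1-e3], [1-e2, 1-e3, 1]],

with small e_i growing monotonically with spectral separation (e1 ~ e3,
e2 larger).  Its eigenvectors approach the fixed opponent axes
(1,1,1)/sqrt3, (1,0,-1)/sqrt2, (-1,2,-1)/sqrt6, and in the symmetric case
e1 = e3 = e, e2 = 2e the eigenvalues scale as 1 : 2e/3 : 2e/9, giving the
dominance statistic

    Z = lambda_1 / (lambda_2 + lambda_3) = 9 / (8 e).

This module provides the empirical summary (mean, covariance, sorted
eigenpairs, Z), the analytic model covariance, the stereographic eigenframe
used to compare empirical eigendirections against the opponent axes, the
six-parameter gamut signature, and the cross-corpus regression of the
green-purple spread on the red-blue spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError, DomainError
from .homomorphic import (
    GUARD_DELTA,
    clamp_observations,
    opponent_forward,
    to_physical,
)

__all__ = [
    "CovarianceSummary",
    "ModelCovariance",
    "ModelEigen",
    "EigenFrame",
    "GamutSignature",
    "PsiFit",
    "OPPONENT_AXES",
    "REFERENCE_PHYSICAL_COV",
    "summarize",
    "model_covariance",
    "model_eigen",
    "stereographic_frame",
    "gamut_signature",
    "psi_regression",
]

#: Fiducial opponent axes as unit column vectors:
#: white-black, red-blue, green-purple.
OPPONENT_AXES = np.column_stack(
    [
        np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0),
        np.array([1.0, 0.0, -1.0]) / np.sqrt(2.0),
        np.array([-1.0, 2.0, -1.0]) / np.sqrt(6.0),
    ]
)

#: Physical-domain channel covariance of a typical natural scene (a pebble
#: field), scaled so the largest entry is 100.  Used as the reference input
#: ensemble of the distortion-robustness simulation.
REFERENCE_PHYSICAL_COV = np.array(
    [[92.0, 90.0, 89.0], [90.0, 95.0, 96.0], [89.0, 96.0, 100.0]]
)


@dataclass(frozen=True)
class CovarianceSummary:
    """Mean, covariance, sorted eigenpairs and Z of a sample of triples."""

    mean: np.ndarray
    cov: np.ndarray
    cov_normalized: np.ndarray
    norm_constant: float
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # matching columns, sign-normalized
    z: float
    n: int

    @property
    def correlation(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.cov))
        return self.cov / np.outer(sd, sd)


@dataclass(frozen=True)
class ModelCovariance:
    """Unit-diagonal analytic covariance with off-diagonals 1 - e_i."""

    eps1: float
    eps2: float
    eps3: float

    def __post_init__(self):
        for e in (self.eps1, self.eps2, self.eps3):
            if not 0.0 < e < 1.0:
                raise DomainError("epsilon parameters must lie in (0, 1)")

    @property
    def matrix(self) -> np.ndarray:
        e1, e2, e3 = self.eps1, self.eps2, self.eps3
        return np.array(
            [
                [1.0, 1.0 - e1, 1.0 - e2],
                [1.0 - e1, 1.0, 1.0 - e3],
                [1.0 - e2, 1.0 - e3, 1.0],
            ]
        )


@dataclass(frozen=True)
class ModelEigen:
    """Exact eigenstructure of the symmetric model covariance."""

    eps: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    z: float


@dataclass(frozen=True)
class EigenFrame:
    """Eigendirections stereographically projected from the white point.

    The sphere of directions is projected from the antipode of the
    achromatic pole (1,1,1)/sqrt3 onto the equatorial plane, with in-plane
    axes along the red-blue and green-purple opponent directions.  The pole
    maps to the origin and directions orthogonal to it map onto the unit
    circle.
    """

    projected_points: np.ndarray  # (k, 2)
    reference_axes: np.ndarray = field(
        default_factory=lambda: OPPONENT_AXES.copy()
    )


@dataclass(frozen=True)
class GamutSignature:
    """Six-parameter signature: opponent-channel means and spreads."""

    mu_lambda: float
    mu_theta: float
    mu_xi: float
    sigma_lambda: float
    sigma_theta: float
    sigma_xi: float

    def __post_init__(self):
        if min(self.sigma_lambda, self.sigma_theta, self.sigma_xi) < 0:
            raise DomainError("signature sigmas must be nonnegative")

    @property
    def mus(self) -> np.ndarray:
        return np.array([self.mu_lambda, self.mu_theta, self.mu_xi])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([self.sigma_lambda, self.sigma_theta, self.sigma_xi])


@dataclass(frozen=True)
class PsiFit:
    """Log-log regression of sigma_Xi on sigma_Theta across gamuts.

    ``power`` is the fitted exponent and ``psi`` the prefactor in
    sigma_Xi = psi * sigma_Theta ** power (psi = exp of the log-log
    intercept).  ``psi_linear`` is the alternative through-origin linear
    slope sum(x y) / sum(x^2).
    """

    psi: float
    power: float
    r2: float
    psi_linear: float
    n: int


def _as_triples(samples) -> np.ndarray:
    arr = np.asarray(samples, dtype=float)
    if arr.ndim >= 2 and arr.shape[-1] == 3:
        return arr.reshape(-1, 3)
    raise DomainError("samples must have a trailing axis of 3 channels")


def summarize(samples, normalize_to: float = 100.0) -> CovarianceSummary:
    """Mean/covariance/eigen summary of a sample of channel triples.

    Covariance is the unbiased (n-1) estimate.  Eigenvalues are sorted
    descending; each eigenvector is sign-normalized so its largest-magnitude
    component is positive (eigendirections are axes, so the sign is a pure
    convention).  ``cov_normalized`` rescales the covariance so its largest
    entry equals ``normalize_to`` (100 for channel covariances, 1000 for
    opponent covariances, by convention).
    """
    arr = _as_triples(samples)
    n = arr.shape[0]
    if n < 4:
        raise DegenerateInputError("need at least 4 triples")
    mean = arr.mean(axis=0)
    cov = np.cov(arr, rowvar=False)
    if not np.all(np.isfinite(cov)) or np.trace(cov) <= 0:
        raise DegenerateInputError("sample has no variance")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    for j in range(3):
        k = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    tail = evals[1] + evals[2]
    if tail <= 0:
        raise DegenerateInputError("covariance is rank deficient")
    scale = normalize_to / np.abs(cov).max()
    return CovarianceSummary(
        mean=mean,
        cov=cov,
        cov_normalized=cov * scale,
        norm_constant=float(normalize_to),
        eigenvalues=evals,
        eigenvectors=evecs,
        z=float(evals[0] / tail),
        n=n,
    )


def model_covariance(eps1: float, eps2: float, eps3: float) -> ModelCovariance:
    """Analytic channel covariance for given epsilon parameters."""
    return ModelCovariance(eps1, eps2, eps3)


def model_eigen(eps: float) -> ModelEigen:
    """Eigenstructure of the symmetric model (e1 = e3 = eps, e2 = 2 eps).

    (1,0,-1)/sqrt2 is an exact eigenvector with eigenvalue exactly 2 eps for
    every eps; as eps -> 0 the normalized eigenvalues approach
    (1, 2 eps/3, 2 eps/9), the second/third ratio approaches 3, and
    Z -> 9/(8 eps).
    """
    if not 0.0 < eps < 0.5:
        raise DomainError("eps must lie in (0, 0.5)")
    matrix = model_covariance(eps, 2.0 * eps, eps).matrix
    evals, evecs = np.linalg.eigh(matrix)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    for j in range(3):
        k = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    z = float(evals[0] / (evals[1] + evals[2]))
    return ModelEigen(eps=eps, eigenvalues=evals, eigenvectors=evecs, z=z)


def stereographic_frame(summary) -> EigenFrame:
    """Project eigendirections stereographically from the white point.

    Accepts a :class:`CovarianceSummary` (or a bare (3, k) array of column
    directions).  Each direction is first flipped into the hemisphere facing
    the achromatic pole; equatorial directions (orthogonal to the pole) are
    flipped to a nonnegative first coordinate instead.
    """
    vectors = getattr(summary, "eigenvectors", summary)
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim == 1:
        vectors = vectors[:, None]
    if vectors.shape[0] != 3:
        raise DomainError("directions must be 3-vectors (columns)")
    pole = OPPONENT_AXES[:, 0]
    e2 = OPPONENT_AXES[:, 1]
    e3 = OPPONENT_AXES[:, 2]
    points = np.empty((vectors.shape[1], 2))
    for j in range(vectors.shape[1]):
        u = vectors[:, j]
        norm = np.linalg.norm(u)
        if norm == 0 or not np.all(np.isfinite(u)):
            raise DomainError("cannot project a zero direction")
        u = u / norm
        cos_pole = float(u @ pole)
        tol = 1e-12
        if cos_pole < -tol:
            u, cos_pole = -u, -cos_pole
        elif abs(cos_pole) <= tol and u[0] < 0:
            u = -u
        points[j] = np.array([u @ e2, u @ e3]) / (1.0 + cos_pole)
    return EigenFrame(projected_points=points)


def gamut_signature(field) -> GamutSignature:
    """Six-parameter signature of an RGB field.

    Pipeline: guard clamp -> inverse logistic map to the physical domain ->
    opponent transform -> per-channel mean and standard deviation
    (population convention matches the generator's parameters; the n vs n-1
    distinction is negligible at typical pixel counts).  The clamp only
    protects against exact 0/1: byte-ingested images already live inside
    [1/512, 511/512], and winsorizing float fields at 1/512 would bias the
    estimated spreads of high-contrast gamuts by more than their sampling
    error.
    """
    arr = _as_triples(field)
    if arr.shape[0] < 1:
        raise DegenerateInputError("empty field")
    opp = opponent_forward(to_physical(clamp_observations(arr, GUARD_DELTA)))
    mu = opp.mean(axis=0)
    sigma = opp.std(axis=0)
    return GamutSignature(
        mu_lambda=float(mu[0]),
        mu_theta=float(mu[1]),
        mu_xi=float(mu[2]),
        sigma_lambda=float(sigma[0]),
        sigma_theta=float(sigma[1]),
        sigma_xi=float(sigma[2]),
    )


def psi_regression(signatures) -> PsiFit:
    """Fit sigma_Xi = psi * sigma_Theta ** power across gamut signatures.

    Ordinary least squares of ln sigma_Xi on ln sigma_Theta.  A power near 1
    means the green-purple spread is simply proportional to the red-blue
    spread; the proportionality constant is characteristic of natural
    (daylight-scattering) environments.
    """
    sig_theta = np.array([s.sigma_theta for s in signatures], dtype=float)
    sig_xi = np.array([s.sigma_xi for s in signatures], dtype=float)
    if sig_theta.size < 3:
        raise DegenerateInputError("need at least 3 signatures")
    if np.any(sig_theta <= 0) or np.any(sig_xi <= 0):
        raise DegenerateInputError("signatures must have positive sigmas")
    x = np.log(sig_theta)
    y = np.log(sig_xi)
    if np.allclose(x, x[0]):
        raise DegenerateInputError("sigma_theta values are all equal")
    fit = stats.linregress(x, y)
    psi_linear = float(np.sum(sig_theta * sig_xi) / np.sum(sig_theta**2))
    return PsiFit(
        psi=float(np.exp(fit.intercept)),
        power=float(fit.slope),
        r2=float(fit.rvalue**2),
        psi_linear=psi_linear,
        n=int(sig_theta.size),
    )
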