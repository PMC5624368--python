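"""Homomorphic maps between observation and physical domains.

Camera channel values live on the open unit interval, while the physical
quantities that generate them (log ratios of absorption to scattering
cross-sections, log radiances, exposure) live on the whole real line and
combine additively.  The logistic map

    Omega(x) = (1 + tanh x) / 2

and its inverse carry values between the two domains, so that statistics can
be collected in the observation domain and analyzed in the (approximately
Gaussian) physical domain.  On top of the physical channels (rho, chi, beta)
the fixed opponent transform T produces the decorrelated channels

    Lambda = (rho + chi + beta) / 3     (white-black, the channel mean)
    Theta  = (rho - beta) / 2           (red-blue, spectral slope)
    Xi     = (-rho + 2 chi - beta) / 4  (green-purple, spectral curvature)

The Kubelka-Munk relation between the absorption/scattering ratio of a thick
turbid layer and its diffuse reflectance is included as the canonical
physical instance of such a sigmoidal observation map.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DomainError

__all__ = [
    "T",
    "T_INV",
    "CLAMP_DELTA",
    "GUARD_DELTA",
    "omega",
    "omega_inv",
    "clamp_observations",
    "to_physical",
    "to_observation",
    "opponent_forward",
    "opponent_inverse",
    "km_reflectance",
    "km_xi",
    "km_histogram",
]

#: Opponent transform: rows send (rho, chi, beta) to (Lambda, Theta, Xi).
T = np.array(
    [[4.0, 4.0, 4.0], [6.0, 0.0, -6.0], [-3.0, 6.0, -3.0]]
) / 12.0

#: Exact inverse of :data:`T`.
T_INV = np.array(
    [[3.0, 3.0, -2.0], [3.0, 0.0, 4.0], [3.0, -3.0, -2.0]]
) / 3.0

#: Ingestion clamp half-width.  Observation values are restricted to
#: [delta, 1-delta] before the inverse logistic map; 1/512 is half an 8-bit
#: quantization step under the (v+0.5)/256 byte convention, so byte images
#: never clip and the infinities of omega_inv at 0 and 1 are unreachable.
CLAMP_DELTA = 1.0 / 512.0

#: Guard clamp for float-valued fields: keeps values strictly inside (0, 1)
#: at double precision (so omega_inv stays finite) without winsorizing
#: genuine tail values the way the ingestion clamp would.
GUARD_DELTA = 1e-15


def omega(x):
    """Logistic squashing map from the real line onto (0, 1).

    Strictly increasing, with ``omega(0) == 0.5`` and the symmetry
    ``omega(-x) == 1 - omega(x)``.
    """
    return 0.5 * (1.0 + np.tanh(x))


def omega_inv(y):
    """Inverse of :func:`omega`; defined only on the open interval (0, 1).

    Raises
    ------
    DomainError
        If any value lies at or outside the endpoints.  Endpoint values
        signal a missing ingestion clamp upstream.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise DomainError(
            "omega_inv requires values strictly inside (0, 1); "
            "clamp observations first"
        )
    return np.arctanh(2.0 * y - 1.0)


def clamp_observations(values, delta: float = CLAMP_DELTA):
    """Clamp observation-domain values into [delta, 1 - delta]."""
    return np.clip(np.asarray(values, dtype=float), delta, 1.0 - delta)


def to_physical(field, clamp: bool = False):
    """Map observation-domain channel values to the physical domain.

    With ``clamp=True`` the ingestion clamp is applied first (used by
    pipelines that accept raw, possibly saturated data).
    """
    field = np.asarray(field, dtype=float)
    if clamp:
        field = clamp_observations(field)
    return omega_inv(field)


def to_observation(field):
    """Map physical-domain values back to the observation domain."""
    return omega(np.asarray(field, dtype=float))


def _apply_matrix(matrix, field):
    field = np.asarray(field, dtype=float)
    if field.shape[-1] != 3:
        raise DomainError("opponent transforms require a trailing axis of 3")
    return field @ matrix.T


def opponent_forward(physical):
    """(rho, chi, beta) -> (Lambda, Theta, Xi), any leading shape."""
    return _apply_matrix(T, physical)


def opponent_inverse(opponent):
    """(Lambda, Theta, Xi) -> (rho, chi, beta), any leading shape."""
    return _apply_matrix(T_INV, opponent)


def km_reflectance(xi):
    """Diffuse reflectance of an infinitely thick turbid layer.

    ``xi`` is the ratio of the specific absorption cross-section K to the
    specific scattering cross-section S.  Returns the root of
    ``(1 - R)**2 / (2 R) = xi`` lying in (0, 1]:

        R = 1 + xi - sqrt(xi**2 + 2 xi)

    Monotone decreasing, with R(0) = 1 and R -> 0 as xi -> infinity.
    """
    xi = np.asarray(xi, dtype=float)
    if np.any(xi < 0.0):
        raise DomainError("Kubelka-Munk ratio K/S must be nonnegative")
    return 1.0 + xi - np.sqrt(xi * xi + 2.0 * xi)


def km_xi(reflectance):
    """Inverse of :func:`km_reflectance`: ``(1 - R)**2 / (2 R)`` on (0, 1]."""
    r = np.asarray(reflectance, dtype=float)
    if np.any(r <= 0.0) or np.any(r > 1.0):
        raise DomainError("reflectance must lie in (0, 1]")
    return (1.0 - r) ** 2 / (2.0 * r)


def km_histogram(mu: float, sigma: float, n: int, seed=None, bins: int = 50):
    """Push a log-normal cross-section prior through the sigmoid.

    Draws ``n`` values from Normal(mu, sigma) in the physical (log) domain,
    maps them through :func:`omega`, and bins the resulting reflectances on a
    fixed grid over (0, 1).  Depending on (mu, sigma) the observation-domain
    histogram is unimodal and skewed, or bimodal with peaks at the ends --
    even though the physical-domain distribution is always normal.

    Returns ``(bin_edges, counts)`` with ``len(counts) == bins``.
    """
    if sigma <= 0:
        raise DomainError("sigma must be positive")
    if n < 1:
        raise DomainError("n must be at least 1")
    rng = np.random.default_rng(seed)
    values = omega(rng.normal(mu, sigma, size=int(n)))
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts
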