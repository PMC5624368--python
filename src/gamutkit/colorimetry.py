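"""Colorimetry of the object-color solid and the optimal three-band basis.

A daylight illuminant attenuated by all possible 0-1 reflectance functions
produces a convex, centrally symmetric region of tristimulus space -- the
object-color solid, a zonotope whose generators are the per-wavelength
tristimulus increments of the illuminant.  Splitting the visible range into
three bands by two cuts yields three band tristimulus vectors; the unique
pair of cuts maximizing the volume of the parallelepiped they span defines a
canonical RGB basis ("parts of daylight").  For CIE illuminant D65 and the
CIE 1964 supplementary standard observer the optimal cuts fall near 482.65 nm
and 565.43 nm.

Volume ratios are invariant under any nonsingular linear recoding of
tristimulus space, so the optimization is colorimetrically well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DomainError, InputFormatError, OptimizationError

__all__ = [
    "SpectralTable",
    "BandPartition",
    "RGBBasis",
    "ColorSolidGenerators",
    "DEFAULT_GRID",
    "load_spectral_table",
    "load_d65",
    "load_cmf_1964",
    "band_tristimulus",
    "optimize_cuts",
    "color_solid_generators",
    "zonotope_volume",
    "volume_fraction",
    "rgb_matching_functions",
]

#: Default working grid: (min nm, max nm, step nm).  The standard tables are
#: smooth at their native 5 nm sampling, so linear interpolation onto a 1 nm
#: grid is adequate; the band edges are refined to sub-nm precision by
#: splitting the straddling grid interval, not by refining the grid.
DEFAULT_GRID = (380.0, 700.0, 1.0)

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class SpectralTable:
    """Wavelength-sampled function(s): an illuminant or a CMF triple.

    ``values`` has shape (n,) or (n, 1) for an illuminant (relative power)
    or (n, 3) for colour-matching functions.
    """

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise InputFormatError("need at least two wavelength samples")
        if np.any(np.diff(wl) <= 0):
            raise InputFormatError("wavelength grid must be strictly increasing")
        if vals.shape[0] != wl.size:
            raise InputFormatError("values and wavelengths must align")
        if not np.all(np.isfinite(vals)):
            raise InputFormatError("spectral values must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    def value_at(self, wavelength):
        """Linear interpolation at one or more wavelengths."""
        wavelength = np.asarray(wavelength, dtype=float)
        if self.values.ndim == 1:
            return np.interp(wavelength, self.wavelengths, self.values)
        cols = [
            np.interp(wavelength, self.wavelengths, self.values[:, j])
            for j in range(self.values.shape[1])
        ]
        return np.stack(cols, axis=-1)


@dataclass(frozen=True)
class BandPartition:
    """Two cut wavelengths splitting a range into three spectral bands."""

    cut_low: float
    cut_high: float

    def __post_init__(self):
        if not self.cut_low < self.cut_high:
            raise DomainError("cut_low must be below cut_high")

    def validate_range(self, wl_min: float, wl_max: float) -> None:
        if not (wl_min < self.cut_low and self.cut_high < wl_max):
            raise DomainError(
                f"cuts ({self.cut_low}, {self.cut_high}) must lie strictly "
                f"inside the grid range ({wl_min}, {wl_max})"
            )


@dataclass(frozen=True)
class RGBBasis:
    """Tristimulus vectors of the three bands, as matrix columns.

    Columns follow the band order (short, middle, long wavelengths).
    """

    matrix: np.ndarray
    partition: BandPartition | None = None

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.matrix))


@dataclass(frozen=True)
class ColorSolidGenerators:
    """Per-interval tristimulus increments of an illuminant.

    The object-color solid is the zonotope generated by these vectors; their
    sum is the full tristimulus of the illuminant.
    """

    vectors: np.ndarray  # (m, 3)

    def __post_init__(self):
        vecs = np.asarray(self.vectors, dtype=float)
        if vecs.ndim != 2 or vecs.shape[1] != 3:
            raise DomainError("generators must be an (m, 3) array")
        if not np.all(np.isfinite(vecs)):
            raise DomainError("generators must be finite")
        object.__setattr__(self, "vectors", vecs)

    def __len__(self) -> int:
        return self.vectors.shape[0]


def _read_numeric_csv(path) -> np.ndarray:
    from io import StringIO

    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(str(path)).read_text()
    try:
        df = pd.read_csv(StringIO(text), comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InputFormatError(f"could not read {path!s}: {exc}") from exc
    # Accept headerless files: if the header row itself parses as numbers,
    # re-read without a header.
    try:
        [float(c) for c in df.columns]
    except (TypeError, ValueError):
        pass
    else:
        df = pd.read_csv(StringIO(text), comment="#", header=None)
    arr = df.to_numpy()
    if arr.size == 0:
        raise InputFormatError(f"{path!s} contains no data rows")
    try:
        arr = arr.astype(float)
    except (TypeError, ValueError) as exc:
        raise InputFormatError(f"{path!s} has non-numeric entries") from exc
    return arr


def load_spectral_table(path, kind: str, grid=DEFAULT_GRID) -> SpectralTable:
    """Load a CSV table and resample it onto a uniform wavelength grid.

    Parameters
    ----------
    path
        CSV with a wavelength column followed by 1 (illuminant) or 3 (CMF)
        value columns.  A header row is optional.
    kind
        ``"illuminant"`` or ``"cmf"``.
    grid
        ``(min_nm, max_nm, step_nm)`` working grid; the file must cover it.
    """
    if kind not in ("illuminant", "cmf"):
        raise InputFormatError(f"unknown table kind {kind!r}")
    arr = _read_numeric_csv(path)
    expected = 2 if kind == "illuminant" else 4
    if arr.ndim != 2 or arr.shape[1] != expected:
        raise InputFormatError(
            f"{kind} table must have {expected} columns "
            f"(wavelength + values); got shape {arr.shape}"
        )
    wl = arr[:, 0]
    vals = arr[:, 1] if kind == "illuminant" else arr[:, 1:4]
    if np.any(np.diff(wl) <= 0):
        raise InputFormatError("wavelengths must be strictly increasing")
    if kind == "illuminant" and np.any(vals < 0):
        raise InputFormatError("illuminant power must be nonnegative")
    lo, hi, step = grid
    if wl[0] > lo or wl[-1] < hi:
        raise InputFormatError(
            f"table covers ({wl[0]}, {wl[-1]}) nm but the working grid "
            f"requires ({lo}, {hi}) nm"
        )
    n = int(round((hi - lo) / step)) + 1
    new_wl = lo + step * np.arange(n)
    table = SpectralTable(wl, vals)
    return SpectralTable(new_wl, table.value_at(new_wl))


def _data_path(name: str):
    return resources.files("gamutkit").joinpath("data", "cie", name)


def load_d65(grid=DEFAULT_GRID) -> SpectralTable:
    """Vendored CIE illuminant D65 relative spectral power table."""
    return load_spectral_table(_data_path("illuminant_d65.csv"), "illuminant", grid)


def load_cmf_1964(grid=DEFAULT_GRID) -> SpectralTable:
    """Vendored CIE 1964 supplementary (10 degree) observer CMF table."""
    return load_spectral_table(_data_path("cmf_cie1964.csv"), "cmf", grid)


class _BandIntegrator:
    """Cumulative trapezoidal integral of illuminant x CMF.

    Precomputes the cumulative integral at every grid node so that the
    integral up to an arbitrary (off-grid) wavelength is an O(1) lookup plus
    a linearly split partial trapezoid.  This is what makes the exhaustive
    coarse cut search and the golden-section refinement cheap.
    """

    def __init__(self, illuminant: SpectralTable, cmf: SpectralTable):
        if illuminant.n_channels != 1:
            raise InputFormatError("illuminant table must have one channel")
        if cmf.n_channels != 3:
            raise InputFormatError("CMF table must have three channels")
        if illuminant.wavelengths.shape != cmf.wavelengths.shape or not np.allclose(
            illuminant.wavelengths, cmf.wavelengths
        ):
            raise InputFormatError("tables must share the same wavelength grid")
        self.wl = illuminant.wavelengths
        power = illuminant.values.reshape(-1)
        self.f = power[:, None] * cmf.values  # integrand, (n, 3)
        dl = np.diff(self.wl)[:, None]
        pieces = 0.5 * (self.f[1:] + self.f[:-1]) * dl
        self.cum = np.vstack([np.zeros(3), np.cumsum(pieces, axis=0)])
        self.illuminant = illuminant
        self.cmf = cmf

    @property
    def total(self) -> np.ndarray:
        return self.cum[-1]

    def integral_to(self, wavelength):
        """Integral of the integrand from the grid start to ``wavelength``."""
        c = np.atleast_1d(np.asarray(wavelength, dtype=float))
        if np.any(c < self.wl[0]) or np.any(c > self.wl[-1]):
            raise DomainError("wavelength outside the working grid")
        idx = np.searchsorted(self.wl, c, side="right") - 1
        idx = np.clip(idx, 0, len(self.wl) - 2)
        lam0 = self.wl[idx]
        frac = (c - lam0)[:, None]
        wl_span = (self.wl[idx + 1] - lam0)[:, None]
        f0 = self.f[idx]
        fc = f0 + (self.f[idx + 1] - f0) * (frac / wl_span)
        partial = 0.5 * (f0 + fc) * frac
        out = self.cum[idx] + partial
        return out[0] if np.isscalar(wavelength) else out


def band_tristimulus(
    illuminant: SpectralTable, cmf: SpectralTable, partition: BandPartition
) -> RGBBasis:
    """Tristimulus vectors of the three spectral bands of a partition.

    Each column is the trapezoidal integral of illuminant x CMF over one
    band; cuts between grid nodes split the straddling interval linearly.
    The three columns sum to the full-range tristimulus by construction.
    """
    integ = _BandIntegrator(illuminant, cmf)
    partition.validate_range(integ.wl[0], integ.wl[-1])
    f_low = integ.integral_to(partition.cut_low)
    f_high = integ.integral_to(partition.cut_high)
    cols = np.column_stack([f_low, f_high - f_low, integ.total - f_high])
    return RGBBasis(cols, partition)


def _det_of_cuts(integ: _BandIntegrator, cut_low, cut_high) -> float:
    f_low = integ.integral_to(cut_low)
    f_high = integ.integral_to(cut_high)
    m = np.column_stack([f_low, f_high - f_low, integ.total - f_high])
    return float(np.linalg.det(m))


def _golden_max(func, lo, hi, tol):
    """Deterministic golden-section maximization on [lo, hi]."""
    a, b = float(lo), float(hi)
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = func(c), func(d)
    while (b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = func(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = func(d)
    return 0.5 * (a + b)


def optimize_cuts(
    illuminant: SpectralTable,
    cmf: SpectralTable,
    coarse_step: float = 1.0,
    refine_tol: float = 0.01,
):
    """Find the cut pair maximizing the band-parallelepiped volume.

    Exhaustive search over all cut pairs on a coarse wavelength grid
    (vectorized through cumulative integrals), followed by coordinate-wise
    golden-section refinement of each cut to ``refine_tol`` nanometres.
    Entirely deterministic; coarse ties resolve to the lexicographically
    smallest pair.

    Returns
    -------
    (BandPartition, float)
        The optimal partition and the achieved |det| of the band basis.
    """
    integ = _BandIntegrator(illuminant, cmf)
    wl_min, wl_max = integ.wl[0], integ.wl[-1]
    if coarse_step <= 0 or refine_tol <= 0:
        raise DomainError("steps and tolerances must be positive")
    candidates = np.arange(wl_min + coarse_step, wl_max - coarse_step / 2, coarse_step)
    if candidates.size < 2:
        raise OptimizationError("grid too coarse to place two interior cuts")

    fvals = integ.integral_to(candidates)  # (m, 3)
    first = fvals  # band 1 for cut_low = candidates[i]
    last = integ.total[None, :] - fvals  # band 3 for cut_high = candidates[j]
    # det(first_i, f_j - f_i, last_j) over all pairs i < j
    cross = np.cross(fvals[None, :, :] - fvals[:, None, :], last[None, :, :])
    dets = np.abs(np.einsum("ik,ijk->ij", first, cross))
    i_idx, j_idx = np.triu_indices(candidates.size, k=1)
    pair_dets = dets[i_idx, j_idx]
    best = int(np.argmax(pair_dets))  # first occurrence = smallest lex pair
    if pair_dets[best] <= 0:
        raise OptimizationError(
            "objective vanishes for every cut pair; illuminant is degenerate"
        )
    cut_low = float(candidates[i_idx[best]])
    cut_high = float(candidates[j_idx[best]])

    # Coordinate-wise refinement; brackets of one coarse step around the
    # incumbent, iterated until both coordinates move by less than tol.
    for _ in range(60):
        new_low = _golden_max(
            lambda c: abs(_det_of_cuts(integ, c, cut_high)),
            max(wl_min, cut_low - coarse_step),
            min(cut_high, cut_low + coarse_step),
            refine_tol,
        )
        new_high = _golden_max(
            lambda c: abs(_det_of_cuts(integ, new_low, c)),
            max(new_low, cut_high - coarse_step),
            min(wl_max, cut_high + coarse_step),
            refine_tol,
        )
        moved = max(abs(new_low - cut_low), abs(new_high - cut_high))
        cut_low, cut_high = new_low, new_high
        if moved < refine_tol:
            break
    partition = BandPartition(cut_low, cut_high)
    return partition, abs(_det_of_cuts(integ, cut_low, cut_high))


def color_solid_generators(
    illuminant: SpectralTable, cmf: SpectralTable
) -> ColorSolidGenerators:
    """Zonotope generators: one tristimulus increment per grid interval.

    The increment of interval [l_i, l_{i+1}] is its trapezoidal contribution
    to the full tristimulus, so the generators sum exactly to the band
    tristimulus total and the band basis is a subset-sum parallelepiped of
    the solid.
    """
    integ = _BandIntegrator(illuminant, cmf)
    dl = np.diff(integ.wl)[:, None]
    return ColorSolidGenerators(0.5 * (integ.f[1:] + integ.f[:-1]) * dl)


def zonotope_volume(generators: ColorSolidGenerators, coarsen: int | None = None):
    """Volume of the 3-D zonotope spanned by the generators.

    Uses the exact formula: the sum of |det| over all generator triples.
    ``coarsen`` merges runs of that many consecutive generators (by summing
    them) before the O(m^3) triple sum; nearby per-wavelength increments are
    nearly parallel, so this is a cheap, accurate approximation for fine
    grids.
    """
    vecs = np.asarray(generators.vectors, dtype=float)
    if coarsen is not None and coarsen > 1:
        m = vecs.shape[0]
        pad = (-m) % coarsen
        if pad:
            vecs = np.vstack([vecs, np.zeros((pad, 3))])
        vecs = vecs.reshape(-1, coarsen, 3).sum(axis=1)
    m = vecs.shape[0]
    if m < 3:
        raise DomainError("zonotope volume needs at least 3 generators")
    total = 0.0
    # pairwise cross products once; then one dot per leading index
    for i in range(m - 2):
        # dets[j, k] = det(v_i, v_{i+1+j}, v_{i+2+k}); valid pairs need k >= j
        crosses = np.cross(vecs[i + 1 : -1, None, :], vecs[None, i + 2 :, :])
        dets = crosses @ vecs[i]
        rows, cols = np.triu_indices(m - i - 2)
        total += float(np.abs(dets[rows, cols]).sum())
    return total


def volume_fraction(
    illuminant: SpectralTable,
    cmf: SpectralTable,
    partition: BandPartition,
    coarsen: int | None = None,
) -> float:
    """Fraction of the object-color solid filled by the band parallelepiped.

    Invariant under any shared nonsingular linear recoding of tristimulus
    space (both volumes pick up the same |det| factor).
    """
    basis = band_tristimulus(illuminant, cmf, partition)
    gens = color_solid_generators(illuminant, cmf)
    return abs(basis.det) / zonotope_volume(gens, coarsen=coarsen)


def rgb_matching_functions(cmf: SpectralTable, basis: RGBBasis) -> SpectralTable:
    """Re-express the CMFs in the band RGB basis.

    Applies the basis inverse to the CMF triple at every wavelength, so that
    integrating illuminant x new functions over the three bands of the
    basis's own partition returns the identity matrix.
    """
    matrix = np.asarray(basis.matrix, dtype=float)
    if abs(np.linalg.det(matrix)) < 1e-300:
        raise DomainError("basis matrix is singular")
    new_vals = np.linalg.solve(matrix, cmf.values.T).T
    return SpectralTable(cmf.wavelengths, new_vals)
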