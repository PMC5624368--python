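import io

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from gamutkit import colorimetry as cm
from gamutkit.exceptions import DomainError, InputFormatError


class TestLoading:
    def test_d65_is_normalized_at_560(self, d65):
        assert d65.value_at(560.0) == pytest.approx(100.0, abs=1e-9)

    def test_cmf_nonnegative_over_working_range(self, cmf1964):
        assert cmf1964.values.shape[1] == 3
        assert np.all(cmf1964.values >= 0.0)

    def test_decreasing_wavelengths_rejected(self):
        bad = io.StringIO("wavelength_nm,relative_power\n500,1.0\n490,1.0\n")
        with pytest.raises(InputFormatError):
            cm.load_spectral_table(bad, "illuminant")

    def test_wrong_column_count_rejected(self):
        bad = io.StringIO("wl,a,b\n380,1,1\n700,1,1\n")
        with pytest.raises(InputFormatError):
            cm.load_spectral_table(bad, "illuminant")

    def test_insufficient_coverage_rejected(self):
        bad = io.StringIO("wl,p\n400,1\n650,1\n")
        with pytest.raises(InputFormatError):
            cm.load_spectral_table(bad, "illuminant")

    def test_headerless_file_accepted(self):
        table = cm.load_spectral_table(
            io.StringIO("300,1.0\n800,1.0\n"), "illuminant"
        )
        assert table.wavelengths[0] == 380.0
        assert table.values[0] == 1.0


class TestBandTristimulus:
    @pytest.mark.parametrize("cuts", [(483.0, 565.0), (482.65, 565.43), (450.7, 612.2)])
    def test_bands_sum_to_full_tristimulus(self, d65, cmf1964, cuts):
        basis = cm.band_tristimulus(d65, cmf1964, cm.BandPartition(*cuts))
        full = cm.color_solid_generators(d65, cmf1964).vectors.sum(axis=0)
        np.testing.assert_allclose(basis.matrix.sum(axis=1), full, rtol=1e-12)

    def test_boxcar_bands_are_diagonal(self, boxcar_tables):
        ill, cmf, areas = boxcar_tables
        basis = cm.band_tristimulus(ill, cmf, cm.BandPartition(30.0, 60.0))
        np.testing.assert_allclose(basis.matrix, np.diag(areas), atol=1e-12)

    def test_matches_independent_quadrature(self, d65, cmf1964):
        """Cross-check against trapezoid quadrature on a cut-refined grid."""
        cuts = cm.BandPartition(483.0, 565.43)
        basis = cm.band_tristimulus(d65, cmf1964, cuts)
        wl = d65.wavelengths
        product = d65.values[:, None] * cmf1964.values
        fine = np.unique(np.concatenate([wl, [cuts.cut_low, cuts.cut_high]]))
        prod_fine = np.stack(
            [np.interp(fine, wl, product[:, j]) for j in range(3)], axis=1
        )
        edges = [wl[0], cuts.cut_low, cuts.cut_high, wl[-1]]
        for b in range(3):
            mask = (fine >= edges[b]) & (fine <= edges[b + 1])
            expected = np.trapezoid(prod_fine[mask], fine[mask], axis=0)
            np.testing.assert_allclose(basis.matrix[:, b], expected, rtol=1e-9)

    def test_cut_outside_grid_rejected(self, d65, cmf1964):
        with pytest.raises(DomainError):
            cm.band_tristimulus(d65, cmf1964, cm.BandPartition(300.0, 565.0))


class TestOptimizeCuts:
    def test_daylight_cuts_near_printed_loci(self, d65, cmf1964):
        partition, det = cm.optimize_cuts(d65, cmf1964)
        assert partition.cut_low == pytest.approx(482.65, abs=0.5)
        assert partition.cut_high == pytest.approx(565.43, abs=0.5)
        assert det > 0

    def test_boxcar_recovers_boundaries(self, boxcar_tables):
        ill, cmf, _ = boxcar_tables
        partition, _ = cm.optimize_cuts(ill, cmf, coarse_step=1.0, refine_tol=0.01)
        assert partition.cut_low == pytest.approx(30.0, abs=0.02)
        assert partition.cut_high == pytest.approx(60.0, abs=0.02)

    def test_optimum_beats_arbitrary_partition(self, d65, cmf1964):
        partition, det = cm.optimize_cuts(d65, cmf1964)
        other = cm.band_tristimulus(d65, cmf1964, cm.BandPartition(450.0, 600.0))
        assert det >= abs(other.det)

    def test_deterministic_bit_identical(self, d65, cmf1964):
        p1, d1 = cm.optimize_cuts(d65, cmf1964)
        p2, d2 = cm.optimize_cuts(d65, cmf1964)
        assert (p1.cut_low, p1.cut_high, d1) == (p2.cut_low, p2.cut_high, d2)

    def test_degenerate_illuminant_rejected(self):
        wl = np.arange(91, dtype=float)
        ill = cm.SpectralTable(wl, np.zeros(91))
        cmf = cm.SpectralTable(wl, np.ones((91, 3)))
        with pytest.raises(cm.OptimizationError):
            cm.optimize_cuts(ill, cmf)


def _hull_volume(vectors: np.ndarray) -> float:
    """Brute-force oracle: hull of all 2^n subset sums of the generators."""
    n = vectors.shape[0]
    signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)
    return float(ConvexHull(signs @ vectors).volume)


class TestZonotopeVolume:
    def test_orthonormal_generators_give_unit_cube(self):
        gens = cm.ColorSolidGenerators(np.eye(3))
        assert cm.zonotope_volume(gens) == pytest.approx(1.0, rel=1e-12)

    def test_homogeneity_of_degree_three(self):
        rng = np.random.default_rng(4)
        vecs = rng.normal(size=(7, 3))
        v1 = cm.zonotope_volume(cm.ColorSolidGenerators(vecs))
        v2 = cm.zonotope_volume(cm.ColorSolidGenerators(2.5 * vecs))
        assert v2 == pytest.approx(2.5**3 * v1, rel=1e-12)

    @pytest.mark.parametrize("n", range(4, 11))
    def test_agrees_with_minkowski_hull_oracle(self, n):
        rng = np.random.default_rng(n)
        vecs = rng.normal(size=(n, 3))
        ours = cm.zonotope_volume(cm.ColorSolidGenerators(vecs))
        assert ours == pytest.approx(_hull_volume(vecs), rel=1e-9)

    def test_too_few_generators_rejected(self):
        with pytest.raises(DomainError):
            cm.zonotope_volume(cm.ColorSolidGenerators(np.eye(3)[:2]))

    def test_coarsening_stays_close(self, d65_coarse, cmf1964_coarse):
        gens = cm.color_solid_generators(d65_coarse, cmf1964_coarse)
        exact = cm.zonotope_volume(gens)
        coarse = cm.zonotope_volume(gens, coarsen=2)
        assert coarse == pytest.approx(exact, rel=0.02)


class TestVolumeFraction:
    def test_fraction_below_one(self, d65_coarse, cmf1964_coarse):
        frac = cm.volume_fraction(
            d65_coarse, cmf1964_coarse, cm.BandPartition(483.0, 565.0)
        )
        assert 0.0 < frac < 1.0

    def test_boxcar_fills_the_solid(self, boxcar_tables):
        ill, cmf, _ = boxcar_tables
        frac = cm.volume_fraction(ill, cmf, cm.BandPartition(30.0, 60.0))
        assert frac == pytest.approx(1.0, rel=1e-12)

    def test_invariant_under_linear_recoding(self, d65_coarse, cmf1964_coarse):
        partition = cm.BandPartition(483.0, 565.0)
        basis = cm.band_tristimulus(d65_coarse, cmf1964_coarse, partition)
        gens = cm.color_solid_generators(d65_coarse, cmf1964_coarse)
        baseline = abs(basis.det) / cm.zonotope_volume(gens)
        rng = np.random.default_rng(5)
        for _ in range(100):
            m = rng.normal(size=(3, 3))
            while abs(np.linalg.det(m)) < 1e-3:
                m = rng.normal(size=(3, 3))
            mapped_basis = m @ basis.matrix
            mapped_gens = cm.ColorSolidGenerators(gens.vectors @ m.T)
            ratio = abs(np.linalg.det(mapped_basis)) / cm.zonotope_volume(mapped_gens)
            assert ratio == pytest.approx(baseline, rel=1e-9)


class TestRGBMatchingFunctions:
    def test_identity_basis_is_noop(self, cmf1964):
        basis = cm.RGBBasis(np.eye(3))
        new = cm.rgb_matching_functions(cmf1964, basis)
        np.testing.assert_allclose(new.values, cmf1964.values)

    def test_band_integrals_reproduce_identity(self, d65, cmf1964):
        partition, _ = cm.optimize_cuts(d65, cmf1964)
        basis = cm.band_tristimulus(d65, cmf1964, partition)
        new = cm.rgb_matching_functions(cmf1964, basis)
        reproduced = cm.band_tristimulus(d65, new, partition)
        np.testing.assert_allclose(reproduced.matrix, np.eye(3), atol=1e-9)

    def test_predominantly_nonnegative(self, d65, cmf1964):
        """Regression fixture: pooled negative-lobe area fraction 0.1134."""
        partition, _ = cm.optimize_cuts(d65, cmf1964)
        basis = cm.band_tristimulus(d65, cmf1964, partition)
        new = cm.rgb_matching_functions(cmf1964, basis)
        neg = np.trapezoid(
            np.clip(-new.values, 0.0, None), new.wavelengths, axis=0
        ).sum()
        total = np.trapezoid(np.abs(new.values), new.wavelengths, axis=0).sum()
        fraction = neg / total
        assert fraction == pytest.approx(0.1134, abs=0.005)
        assert fraction < 0.15

    def test_singular_basis_rejected(self, cmf1964):
        with pytest.raises(DomainError):
            cm.rgb_matching_functions(cmf1964, cm.RGBBasis(np.zeros((3, 3))))
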