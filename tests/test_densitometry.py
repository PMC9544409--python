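"""Baseline estimation, band integration and intensity ratios."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wwfrac import (
    GaussianBand,
    LaneProfile,
    SyntheticLaneSpec,
    UndefinedEfficiencyError,
    ValidationError,
    als_baseline,
    band_area,
    cleavage_ratio,
    measured_efficiency,
    quantify_band,
    read_lanes,
    read_profile,
    relative_intensity,
    suggest_band_regions,
    synth_lane,
)


def dense_als_step(y, w, smoothness):
    """Direct dense solve of the fixed-weight penalised normal equations.

    Independent oracle for one ALS iteration: (W + λ DᵀD) z = W y with D
    the (n−2)×n second-difference matrix, solved with numpy only.
    """
    n = y.size
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i], D[i, i + 1], D[i, i + 2] = 1.0, -2.0, 1.0
    A = np.diag(w) + smoothness * D.T @ D
    return np.linalg.solve(A, w * y)


class TestAlsBaseline:
    def test_constant_profile_is_its_own_baseline(self):
        prof = LaneProfile(np.arange(50.0), np.full(50, 7.0))
        assert als_baseline(prof) == pytest.approx(7.0, abs=1e-8)

    def test_affine_profile_reproduced_exactly(self):
        """Straight lines are in the null space of the curvature penalty."""
        x = np.arange(50.0)
        y = 3.0 + 0.5 * x
        z = als_baseline(LaneProfile(x, y))
        assert np.max(np.abs(z - y) / y) < 1e-6

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_matches_dense_direct_solve_each_iteration(self, n):
        """Sparse-solver path equals the dense normal-equation solve at every iteration."""
        rng = np.random.default_rng(7)
        y = 10.0 + np.sin(np.linspace(0, 3, n)) + rng.normal(0, 0.3, n)
        prof = LaneProfile(np.arange(float(n)), y)
        iterates = []
        als_baseline(prof, smoothness=50.0, asymmetry=0.05, iterations=6,
                     record_iterates=iterates)
        assert iterates
        for w, z in iterates:
            z_ref = dense_als_step(y, w, 50.0)
            assert np.max(np.abs(z - z_ref)) <= 1e-8 * max(1.0, np.max(np.abs(z_ref)))

    def test_baseline_tracks_drift_under_a_band(self):
        """Noiseless Gaussian band on a linear drift: off-peak baseline within 1 %,
        band area recovered within 5 %."""
        spec = SyntheticLaneSpec(
            bands=(GaussianBand(center=250.0, sd=5.0, area=100.0),),
            baseline_coeffs=(10.0, 0.05), noise_sd=0.0,
        )
        prof, truth = synth_lane(spec)
        z = als_baseline(prof)
        off = (prof.positions < 200) | (prof.positions > 300)
        assert np.max(np.abs((z[off] - truth.baseline[off]) / truth.baseline[off])) < 0.01
        area = band_area(prof, truth.band_regions[0], z)
        assert area == pytest.approx(100.0, rel=0.05)

    def test_parameter_validation(self):
        prof = LaneProfile(np.arange(10.0), np.ones(10))
        with pytest.raises(ValidationError):
            als_baseline(prof, smoothness=0.0)
        with pytest.raises(ValidationError):
            als_baseline(prof, asymmetry=1.5)
        with pytest.raises(ValidationError):
            als_baseline(prof, iterations=0)
        with pytest.raises(ValidationError):
            LaneProfile(np.arange(2.0), np.ones(2))


class TestLaneProfile:
    def test_descending_orientation_accepted(self):
        prof = LaneProfile(np.array([5.0, 3.0, 1.0]), np.array([10.0, 20.0, 30.0]))
        assert list(prof.positions) == [1.0, 3.0, 5.0]
        assert list(prof.intensities) == [30.0, 20.0, 10.0]

    def test_non_monotone_positions_rejected(self):
        with pytest.raises(ValidationError):
            LaneProfile(np.array([1.0, 3.0, 2.0]), np.zeros(3))


class TestBandArea:
    def test_exact_on_rectangle(self):
        """Trapezoid is exact on constants: height × width."""
        x = np.linspace(0, 10, 11)
        prof = LaneProfile(x, np.full(11, 4.0))
        assert band_area(prof, (0, 10), np.zeros(11)) == pytest.approx(40.0)

    def test_exact_on_triangle_at_vertices(self):
        prof = LaneProfile(np.array([0.0, 1.0, 2.0]), np.array([0.0, 3.0, 0.0]))
        assert band_area(prof, (0, 2), np.zeros(3)) == pytest.approx(3.0)  # ½·2·3

    def test_negative_residuals_clipped(self):
        prof = LaneProfile(np.arange(5.0), np.array([0.0, -2.0, 0.0, 2.0, 0.0]))
        area = band_area(prof, (0, 4), np.zeros(5))
        assert area == pytest.approx(2.0)  # only the positive lobe contributes

    @given(c=st.floats(min_value=0.01, max_value=100.0))
    def test_linear_in_intensity_scale(self, c):
        x = np.linspace(0, 20, 41)
        y = np.exp(-0.5 * ((x - 10) / 2) ** 2)
        base = band_area(LaneProfile(x, y), (0, 20), np.zeros_like(x))
        scaled = band_area(LaneProfile(x, c * y), (0, 20), np.zeros_like(x))
        assert scaled == pytest.approx(c * base, rel=1e-9)

    def test_region_outside_profile_rejected(self):
        prof = LaneProfile(np.arange(10.0), np.ones(10))
        with pytest.raises(ValidationError):
            band_area(prof, (20, 30), np.zeros(10))
        with pytest.raises(ValidationError):
            band_area(prof, (0, 9), np.zeros(5))


class TestRatios:
    @pytest.mark.parametrize(
        "sample, ref, expected", [(50, 100, 50.0), (105, 100, 105.0), (87.3, 100, 87.3)]
    )
    def test_relative_intensity(self, sample, ref, expected):
        assert relative_intensity(sample, ref) == pytest.approx(expected)

    def test_relative_intensity_validation(self):
        with pytest.raises(ValidationError):
            relative_intensity(10.0, 0.0)
        with pytest.raises(ValidationError):
            relative_intensity(-1.0, 10.0)

    @pytest.mark.parametrize(
        "frag, sub, expected", [(1, 1, 50.0), (0, 5, 0.0), (5, 0, 100.0), (3, 7, 30.0)]
    )
    def test_cleavage_ratio(self, frag, sub, expected):
        assert cleavage_ratio(frag, sub) == pytest.approx(expected)

    def test_cleavage_ratio_both_zero(self):
        with pytest.raises(ValidationError):
            cleavage_ratio(0.0, 0.0)

    @pytest.mark.parametrize(
        "t, c, expected", [(100.0, 0.0, 100.0), (50.0, 50.0, 0.0)]
    )
    def test_measured_efficiency(self, t, c, expected):
        assert measured_efficiency(t, c) == pytest.approx(expected)

    def test_measured_efficiency_matches_printed_pair(self):
        """Relative intensities 87.3 % vs 6.27 % give E ≈ 86.6 %."""
        assert measured_efficiency(87.3, 6.2691) == pytest.approx(86.6, abs=0.05)

    def test_measured_efficiency_undefined(self):
        with pytest.raises(UndefinedEfficiencyError):
            measured_efficiency(0.0, 0.0)


class TestCleavageLane:
    def test_two_band_page_lane_recovers_split(self):
        """Fragment/substrate lane with a 30/70 split reads back within 3 points."""
        spec = SyntheticLaneSpec(
            bands=(
                GaussianBand(center=150.0, sd=5.0, area=30.0),   # fragment
                GaussianBand(center=330.0, sd=5.0, area=70.0),   # substrate
            ),
            baseline_coeffs=(5.0, 0.02), noise_sd=0.01, seed=11,
        )
        prof, truth = synth_lane(spec)
        z = als_baseline(prof)
        frag = band_area(prof, (135.0, 165.0), z)
        sub = band_area(prof, (315.0, 345.0), z)
        assert cleavage_ratio(frag, sub) == pytest.approx(30.0, abs=3.0)


class TestIO:
    def test_read_two_column_csv_with_and_without_header(self, tmp_path):
        p1 = tmp_path / "lane.csv"
        p1.write_text("position,intensity\n0,1.0\n1,2.0\n2,1.5\n")
        prof = read_profile(p1)
        assert list(prof.positions) == [0.0, 1.0, 2.0]
        p2 = tmp_path / "bare.csv"
        p2.write_text("0,1.0\n1,2.0\n2,1.5\n")
        assert list(read_profile(p2).intensities) == [1.0, 2.0, 1.5]

    def test_read_wide_multilane_tsv(self, tmp_path):
        p = tmp_path / "gel.tsv"
        p.write_text("pos\tL1\tL2\n0\t1\t2\n1\t2\t4\n2\t1\t2\n")
        lanes = read_lanes(p)
        assert set(lanes) == {"L1", "L2"}
        assert list(lanes["L2"].intensities) == [2.0, 4.0, 2.0]

    def test_quantify_band_bundles_baseline_and_area(self):
        spec = SyntheticLaneSpec(
            bands=(GaussianBand(250.0, 5.0, 100.0),), baseline_coeffs=(10.0,),
        )
        prof, truth = synth_lane(spec)
        q = quantify_band(prof, truth.band_regions[0])
        assert q.area == pytest.approx(100.0, rel=0.05)
        assert q.baseline.shape == prof.positions.shape

    def test_suggest_band_regions_finds_the_bands(self):
        spec = SyntheticLaneSpec(
            bands=(GaussianBand(150.0, 5.0, 100.0), GaussianBand(350.0, 6.0, 80.0)),
            baseline_coeffs=(10.0, 0.02), noise_sd=0.01, seed=3,
        )
        prof, _ = synth_lane(spec)
        regions = suggest_band_regions(prof, n_bands=2)
        centers = sorted((lo + hi) / 2 for lo, hi in regions)
        assert centers[0] == pytest.approx(150.0, abs=10.0)
        assert centers[1] == pytest.approx(350.0, abs=10.0)
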