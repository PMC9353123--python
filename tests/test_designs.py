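import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from nutriscape import (
    CertaintyKernel,
    NutrientSpace,
    certainty_density,
    design_diagnostics,
    make_gf_design,
    make_hex_design,
    make_random_design,
    make_square_design,
)
from nutriscape.designs import AnchorPoint, Design

RATIOS = [1 / 16, 1 / 8, 1 / 4, 1 / 2, 1.0, 2.0]


def nn_distances(design):
    coords = design.coords_array()
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


class TestGFDesign:
    def test_six_by_four_gives_24_points_on_their_rails(self, square_space):
        concs = [20.0, 40.0, 60.0, 80.0]
        design = make_gf_design(square_space, RATIOS, concs)
        assert len(design) == 24
        # brute-force ratio check on all 24
        for pt in design.points:
            assert pt.c > 0
            assert abs(pt.p / pt.c - pt.rail_ratio) < 1e-9

    def test_single_unit_ratio(self, square_space):
        design = make_gf_design(square_space, [1.0], [50.0])
        (pt,) = design.points
        assert pt.p == pytest.approx(25.0)
        assert pt.c == pytest.approx(25.0)

    def test_multi_rail_hull_smaller_than_space(self, square_space):
        design = make_gf_design(square_space, RATIOS, [20.0, 40.0, 60.0, 80.0])
        diag = design_diagnostics(design, square_space)
        assert diag.coverage_fraction < 1.0

    def test_out_of_space_pair_named_in_error(self, square_space):
        with pytest.raises(ValueError, match="ratio 2.*concentration 200"):
            make_gf_design(square_space, [2.0], [200.0])

    def test_zero_ratio_is_pure_carbohydrate_rail(self, square_space):
        design = make_gf_design(square_space, [0.0], [60.0])
        (pt,) = design.points
        assert pt.p == 0.0
        assert pt.c == pytest.approx(60.0)

    def test_infinite_ratio_is_pure_protein_rail(self, square_space):
        design = make_gf_design(square_space, [math.inf], [60.0])
        (pt,) = design.points
        assert pt.p == pytest.approx(60.0)
        assert pt.c == 0.0

    def test_concentration_tags_sum(self, square_space):
        design = make_gf_design(square_space, RATIOS, [40.0])
        for pt in design.points:
            assert pt.p + pt.c == pytest.approx(pt.concentration)


class TestHexDesign:
    def test_resolution_one_is_centroid(self, space):
        design = make_hex_design(space, 1)
        (pt,) = design.points
        assert (pt.p, pt.c) == space.centroid

    def test_single_nearest_neighbor_distance(self, square_space):
        design = make_hex_design(square_space, 30)
        nn = nn_distances(design)
        assert np.all(np.abs(nn - 2 * design.cell_apothem) < 1e-6)

    @pytest.mark.parametrize("resolution", [30, 50, 250])
    def test_exact_counts(self, space, resolution):
        assert len(make_hex_design(space, resolution)) == resolution

    def test_all_points_in_space(self, space):
        design = make_hex_design(space, 50)
        for pt in design.points:
            assert space.contains(pt.p, pt.c)

    def test_invalid_resolution(self, space):
        with pytest.raises(ValueError):
            make_hex_design(space, 0)


class TestSquareDesign:
    def test_resolution_one_is_centroid(self, space):
        design = make_square_design(space, 1)
        (pt,) = design.points
        assert (pt.p, pt.c) == space.centroid

    def test_interior_neighbor_distances(self, space):
        design = make_square_design(space, 50)
        r = design.cell_apothem
        coords = design.coords_array()
        # most-interior point
        cen = np.array(space.centroid)
        i = np.argmin(np.linalg.norm(coords - cen, axis=1))
        d = np.linalg.norm(coords - coords[i], axis=1)
        d = np.sort(d[d > 1e-12])
        assert d[0] == pytest.approx(2 * r, abs=1e-6)
        diag = d[np.abs(d - 2 * math.sqrt(2) * r) < 1e-6]
        assert len(diag) >= 1  # next-nearest on the diagonal

    def test_space_covered_within_sqrt2_r(self, space):
        # resolution 50 tiles the default 60x120 space exactly (5 x 10)
        design = make_square_design(space, 50)
        r = design.cell_apothem
        xs = np.linspace(space.p_min, space.p_max, 41)
        ys = np.linspace(space.c_min, space.c_max, 81)
        gx, gy = np.meshgrid(xs, ys)
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        d = cdist(grid, design.coords_array()).min(axis=1)
        assert d.max() <= math.sqrt(2) * r + 1e-4

    @pytest.mark.parametrize("resolution", [30, 50, 250])
    def test_exact_counts(self, space, resolution):
        assert len(make_square_design(space, resolution)) == resolution


class TestRandomDesign:
    def test_seed_reproducibility(self, space):
        a = make_random_design(space, 40, seed=7)
        b = make_random_design(space, 40, seed=7)
        assert np.array_equal(a.coords_array(), b.coords_array())

    def test_all_in_bounds(self, space):
        design = make_random_design(space, 500, seed=3)
        coords = design.coords_array()
        assert coords[:, 0].min() >= space.p_min
        assert coords[:, 0].max() <= space.p_max
        assert coords[:, 1].min() >= space.c_min
        assert coords[:, 1].max() <= space.c_max

    def test_large_sample_mean_near_centroid(self, space):
        design = make_random_design(space, 10000, seed=11)
        coords = design.coords_array()
        cen = space.centroid
        assert abs(coords[:, 0].mean() - cen[0]) < 0.02 * space.width
        assert abs(coords[:, 1].mean() - cen[1]) < 0.02 * space.height

    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(1, 60))
    @settings(max_examples=25, deadline=None)
    def test_bounds_property(self, seed, n):
        sp = NutrientSpace(0.0, 60.0, 0.0, 120.0)
        coords = make_random_design(sp, n, seed=seed).coords_array()
        assert len(coords) == n
        assert np.all((coords[:, 0] >= 0) & (coords[:, 0] <= 60))
        assert np.all((coords[:, 1] >= 0) & (coords[:, 1] <= 120))


class TestCertaintyDensity:
    KERNEL = CertaintyKernel(amplitude=5.0, x0=30.0, y0=60.0, sigma_x2=16.0, sigma_y2=25.0)

    def test_center_equals_amplitude(self):
        assert certainty_density(self.KERNEL, 30.0, 60.0) == pytest.approx(5.0)

    def test_one_sigma_along_x(self):
        # direct evaluation of the density formula one sd away
        val = certainty_density(self.KERNEL, 30.0 + 4.0, 60.0)
        assert val == pytest.approx(5.0 * math.exp(-0.5))

    @given(d=st.floats(-50, 50, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_symmetry(self, d):
        left = certainty_density(self.KERNEL, 30.0 - d, 60.0)
        right = certainty_density(self.KERNEL, 30.0 + d, 60.0)
        assert left == pytest.approx(right, rel=1e-12)

    def test_invalid_variance(self):
        with pytest.raises(ValueError):
            CertaintyKernel(1.0, 0.0, 0.0, sigma_x2=-1.0, sigma_y2=1.0)


class TestDiagnostics:
    def test_hex_single_valued_nn_distribution(self, square_space):
        design = make_hex_design(square_space, 40)
        diag = design_diagnostics(design, square_space)
        assert np.ptp(diag.nn_distances) < 1e-6

    def test_corner_points_full_coverage(self, square_space):
        pts = [
            AnchorPoint(0.0, 0.0),
            AnchorPoint(100.0, 0.0),
            AnchorPoint(0.0, 100.0),
            AnchorPoint(100.0, 100.0),
        ]
        design = Design(strategy="random", resolution=4, points=pts, seed=0)
        diag = design_diagnostics(design, square_space)
        assert diag.coverage_fraction == pytest.approx(1.0)

    def test_gf_partial_coverage(self, square_space):
        design = make_gf_design(square_space, RATIOS, [20.0, 40.0, 60.0, 80.0])
        diag = design_diagnostics(design, square_space)
        assert diag.coverage_fraction < 1.0

    def test_too_few_points_flagged(self, space):
        design = Design("random", 2, [AnchorPoint(1, 1), AnchorPoint(2, 2)], seed=0)
        diag = design_diagnostics(design, space)
        assert not diag.hull_defined
        assert diag.notes


class TestDesignInvariants:
    def test_duplicates_dropped(self):
        pts = [AnchorPoint(1.0, 2.0), AnchorPoint(1.0, 2.0), AnchorPoint(3.0, 4.0)]
        design = Design("random", 3, pts, seed=0)
        assert len(design) == 2

    def test_anchor_rail_consistency_enforced(self):
        with pytest.raises(ValueError):
            AnchorPoint(10.0, 10.0, rail_ratio=2.0)

    def test_space_validation(self):
        with pytest.raises(ValueError):
            NutrientSpace(10.0, 5.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            NutrientSpace(-1.0, 5.0, 0.0, 1.0)
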