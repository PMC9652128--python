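import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from accessmap.grid import FacilitySet, RasterGrid
from accessmap.surfaces import FrictionSurface, cost_distance_surface, euclidean_surface, kernel_density_surface
from accessmap.survey import (
    loess_curve,
    method_correlation_matrix,
    perceived_access,
    population_by_class,
    spearman,
    stratified_pa_ma,
    subgroup_perceived_access,
    validate_clusters,
)
from conftest import WALK, rank_then_pearson


def make_cluster_frame(**overrides):
    base = dict(
        id=["c1", "c2", "c3", "c4"],
        x=[500.0, 2_500.0, 5_500.0, 8_500.0],
        y=[9_500.0, 7_500.0, 4_500.0, 1_500.0],
        urban=[True, True, False, False],
        region_id=["a", "a", "b", "b"],
        n_respondents=[20, 10, 25, 30],
        n_yes=[5, 0, 25, 12],
        n_yes_motorized=[2, 0, 5, 1],
        n_motorized=[8, 4, 5, 3],
    )
    base.update(overrides)
    return pd.DataFrame(base)


class TestPerceivedAccess:
    def test_basic_proportions(self):
        pa = perceived_access(make_cluster_frame())
        assert list(pa) == [0.25, 0.0, 1.0, 0.4]

    def test_zero_respondents_excluded_with_warning(self):
        frame = make_cluster_frame(n_respondents=[20, 0, 25, 30])
        with pytest.warns(UserWarning, match="zero respondents"):
            pa = perceived_access(frame)
        assert len(pa) == 3

    def test_subgroup_split_is_consistent(self):
        frame = make_cluster_frame()
        pa_m = subgroup_perceived_access(frame, motorized=True)
        pa_n = subgroup_perceived_access(frame, motorized=False)
        # weighted recombination returns the overall PA
        recombined = (
            pa_m * frame["n_motorized"] + pa_n * (frame["n_respondents"] - frame["n_motorized"])
        ) / frame["n_respondents"]
        pd.testing.assert_series_equal(recombined, perceived_access(frame), check_names=False)

    def test_count_invariants_enforced(self):
        with pytest.raises(ValueError, match="invariant"):
            validate_clusters(make_cluster_frame(n_yes=[25, 0, 25, 12]))


class TestSpearman:
    def test_perfect_monotone(self):
        r, p, n = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert r == pytest.approx(1.0)
        r, _, _ = spearman([1, 2, 3, 4], [8, 6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_tied_vectors_match_rank_then_pearson_oracle(self):
        x, y = [1, 2, 2, 4], [3, 1, 4, 4]
        r, _, n = spearman(x, y)
        assert n == 4
        assert r == pytest.approx(rank_then_pearson(x, y), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        xy=st.lists(
            st.tuples(st.integers(-5, 5), st.integers(-5, 5)), min_size=4, max_size=30
        )
    )
    def test_matches_oracle_on_random_tied_data(self, xy):
        x = [a for a, _ in xy]
        y = [b for _, b in xy]
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        r, _, _ = spearman(x, y)
        assert r == pytest.approx(rank_then_pearson(x, y), abs=1e-12)

    @pytest.mark.parametrize("transform", [np.exp, lambda v: v**3])
    def test_invariant_under_strictly_monotone_transform(self, transform):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        r0, _, _ = spearman(x, y)
        r1, _, _ = spearman(transform(x), y)
        r2, _, _ = spearman(x, transform(y))
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert r2 == pytest.approx(r0, abs=1e-12)

    def test_constant_vector_is_undefined(self):
        r, p, n = spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert np.isnan(r) and np.isnan(p)

    def test_pairwise_missing_removal(self):
        r, _, n = spearman([1, 2, np.nan, 4, 5], [2, 4, 6, np.nan, 10])
        assert n == 3
        assert r == pytest.approx(1.0)


def _surfaces_for(grid, facilities):
    walk = FrictionSurface(grid=grid.copy_with(np.full(grid.values.shape, WALK)), mode="walking")
    return [
        euclidean_surface(grid, facilities),
        cost_distance_surface(walk, facilities),
        kernel_density_surface(grid, facilities),
    ]


class TestMethodMatrix:
    def test_symmetric_unit_diagonal_and_duplicate_pair(self):
        grid = RasterGrid(values=np.zeros((30, 30)), x_origin=0, y_origin=30_000, cell_size=1_000)
        rng = np.random.default_rng(4)
        fac = FacilitySet(points=rng.uniform(0, 30_000, size=(5, 2)))
        surfaces = _surfaces_for(grid, fac)
        surfaces.append(surfaces[0])  # duplicated ED surface
        n = 60
        clusters = pd.DataFrame(
            {
                "id": [f"c{i}" for i in range(n)],
                "x": rng.uniform(0, 30_000, n),
                "y": rng.uniform(0, 30_000, n),
                "urban": rng.uniform(size=n) < 0.5,
                "region_id": "a",
                "n_respondents": 10,
                "n_yes": rng.integers(0, 11, n),
                "n_yes_motorized": 0,
                "n_motorized": 0,
            }
        )
        mat, records = method_correlation_matrix(clusters, surfaces)
        assert np.array_equal(mat.values, mat.values.T)
        assert np.all(np.diag(mat.values) == 1.0)
        dup = [r for r in records if set(r.pair) == {"ED"}]
        # note: duplicated method shares its name; the duplicate pair is exact
        assert any(r.r_s_abs == pytest.approx(1.0) for r in dup)
        kd_ed = [r for r in records if set(r.pair) == {"ED", "KD"}]
        assert kd_ed[0].sign == -1  # KD anti-correlated by construction

    def test_uniform_friction_ed_cdw_near_rank_identical(self):
        """On a uniform-friction landscape walking time is a near-monotone
        function of straight-line distance, so |r_s| should be ~1."""
        grid = RasterGrid(values=np.zeros((50, 50)), x_origin=0, y_origin=50_000, cell_size=1_000)
        rng = np.random.default_rng(8)
        fac = FacilitySet(points=rng.uniform(0, 50_000, size=(6, 2)))
        ed = euclidean_surface(grid, fac)
        walk = FrictionSurface(grid=grid.copy_with(np.full((50, 50), WALK)), mode="walking")
        cdw = cost_distance_surface(walk, fac)
        from accessmap.surfaces import extract_at_points

        pts = rng.uniform(0, 50_000, size=(500, 2))
        r, _, n = spearman(extract_at_points(ed, pts), extract_at_points(cdw, pts))
        assert n == 500
        assert abs(r) >= 0.99


class TestStratified:
    def test_all_stratum_equals_unstratified(self):
        grid = RasterGrid(values=np.zeros((10, 10)), x_origin=0, y_origin=10_000, cell_size=1_000)
        fac = FacilitySet(points=[grid.cell_center(0, 0)])
        surfaces = [euclidean_surface(grid, fac)]
        rng = np.random.default_rng(12)
        n = 40
        clusters = pd.DataFrame(
            {
                "id": [f"c{i}" for i in range(n)],
                "x": rng.uniform(0, 10_000, n),
                "y": rng.uniform(0, 10_000, n),
                "urban": rng.uniform(size=n) < 0.4,
                "region_id": "a",
                "n_respondents": 20,
                "n_yes": rng.integers(0, 21, n),
                "n_yes_motorized": 0,
                "n_motorized": 0,
            }
        )
        records = stratified_pa_ma(clusters, surfaces, strata=("all",))
        from accessmap.surfaces import extract_at_points

        expected, _, _ = spearman(
            clusters["n_yes"] / 20, extract_at_points(surfaces[0], clusters[["x", "y"]].to_numpy())
        )
        assert len(records) == 1
        assert records[0].r_s_abs == pytest.approx(abs(expected))

    def test_undersized_stratum_skipped(self, caplog):
        grid = RasterGrid(values=np.zeros((10, 10)), x_origin=0, y_origin=10_000, cell_size=1_000)
        fac = FacilitySet(points=[grid.cell_center(0, 0)])
        surfaces = [euclidean_surface(grid, fac)]
        clusters = make_cluster_frame(region_id=["a", "a", "a", "tiny"])
        import logging

        with caplog.at_level(logging.INFO, logger="accessmap.survey"):
            records = stratified_pa_ma(clusters, surfaces, strata=("region",))
        strata = {r.stratum for r in records}
        assert "region:tiny" not in strata
        assert any("tiny" in m for m in caplog.messages)


class TestLoess:
    def test_constant_y_gives_flat_curve(self):
        x = np.linspace(0, 10, 30)
        _, fitted = loess_curve(x, np.full(30, 2.5))
        np.testing.assert_allclose(fitted, 2.5, atol=1e-9)

    def test_reproduces_exact_line(self):
        x = np.linspace(0, 10, 50)
        grid, fitted = loess_curve(x, 2 * x, span=0.5)
        interior = (grid > 1) & (grid < 9)
        np.testing.assert_allclose(fitted[interior], 2 * grid[interior], atol=1e-6)

    def test_noisy_logistic_is_monotone_after_isotonic_check(self):
        rng = np.random.default_rng(6)
        x = np.sort(rng.uniform(0, 30_000, 400))
        p = 1 / (1 + np.exp(-(-2 + 2.5e-4 * x)))
        y = rng.binomial(25, p) / 25
        grid, fitted = loess_curve(x, y, span=0.75)
        # isotonic check: pool-adjacent-violators leaves the curve unchanged
        diffs = np.diff(fitted)
        assert np.all(diffs > -1e-3)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            loess_curve([1, 2, 3], [1, 2, 3])


class TestPopulationByClass:
    def _surface(self, values, units="meters", method="ED"):
        grid = RasterGrid(values=np.asarray(values, dtype=float), x_origin=0,
                          y_origin=1_000.0 * len(values), cell_size=1_000.0)
        from accessmap.grid import AccessibilitySurface

        return AccessibilitySurface(grid=grid, method=method, units=units)

    def test_all_population_in_first_class(self):
        surf = self._surface([[500.0, 20_000.0], [8_000.0, 3_000.0]])
        pop = RasterGrid(values=np.array([[10.0, 0.0], [0.0, 0.0]]), x_origin=0,
                         y_origin=2_000, cell_size=1_000)
        shares = population_by_class(surf, pop, breaks=[1_000, 5_000, 15_000])
        assert shares.iloc[0] == pytest.approx(1.0)
        assert shares.iloc[1:].sum() == pytest.approx(0.0)

    def test_shares_sum_to_one_and_match_brute_force(self):
        rng = np.random.default_rng(31)
        acc = rng.uniform(0, 30_000, size=(25, 25))
        acc[rng.uniform(size=(25, 25)) < 0.05] = np.nan
        pop = rng.uniform(0, 100, size=(25, 25))
        surf = self._surface(acc)
        popgrid = RasterGrid(values=pop, x_origin=0, y_origin=25_000, cell_size=1_000)
        breaks = [1_000.0, 5_000.0, 10_000.0, 15_000.0]
        shares = population_by_class(surf, popgrid, breaks)
        assert shares.sum() == pytest.approx(1.0, abs=1e-12)
        # brute-force per-cell classification, right-closed intervals
        expected = np.zeros(len(breaks) + 2)
        edges = [-np.inf] + breaks + [np.inf]
        for r in range(25):
            for c in range(25):
                if np.isnan(acc[r, c]):
                    expected[-1] += pop[r, c]
                    continue
                for k in range(len(edges) - 1):
                    if edges[k] < acc[r, c] <= edges[k + 1]:
                        expected[k] += pop[r, c]
        np.testing.assert_allclose(shares.to_numpy(), expected / pop.sum(), atol=1e-12)

    def test_boundary_value_is_right_closed(self):
        surf = self._surface([[5_000.0]])
        pop = RasterGrid(values=np.array([[7.0]]), x_origin=0, y_origin=1_000, cell_size=1_000)
        shares = population_by_class(surf, pop, breaks=[5_000.0, 10_000.0])
        assert shares.iloc[0] == pytest.approx(1.0)  # 5000 belongs to "<= 5000"

    def test_kd_rejected(self):
        surf = self._surface([[0.5]], units="dimensionless", method="KD")
        pop = RasterGrid(values=np.array([[1.0]]), x_origin=0, y_origin=1_000, cell_size=1_000)
        with pytest.raises(ValueError, match="KD"):
            population_by_class(surf, pop)

    def test_empty_population_is_error(self):
        surf = self._surface([[500.0]])
        pop = RasterGrid(values=np.array([[0.0]]), x_origin=0, y_origin=1_000, cell_size=1_000)
        with pytest.raises(ValueError, match="empty"):
            population_by_class(surf, pop)
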