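import numpy as np
import pytest
from scipy import stats

import prevmap as pm
from prevmap.synthetic import make_scenario, generate_admin_polygons


def test_single_cell_field_is_standard_normal():
    g = pm.GridDefinition(1, 1)
    draws = np.array([pm.simulate_matern_field(g, 1.0, 5.0, 1.0, seed=s)[0]
                      for s in range(500)])
    assert stats.kstest(draws, "norm").pvalue > 0.01


def test_field_variance_matches_sigma_squared():
    g = pm.GridDefinition(10, 10)
    f = pm.simulate_matern_field(g, sigma=1.5, range_=5.0, nu=1.0, seed=1, size=2000)
    np.testing.assert_allclose(f.mean(axis=0), 0.0, atol=0.15)
    np.testing.assert_allclose(f.var(axis=0), 1.5**2, rtol=0.12)


def test_field_pairwise_correlation_matches_exponential_kernel():
    # nu = 1/2: corr(d) = exp(-2 d / range)
    g = pm.GridDefinition(10, 10)
    rho = 6.0
    f = pm.simulate_matern_field(g, 1.0, rho, nu=0.5, seed=2, size=2000)
    for i, j in [(0, 1), (0, 5), (0, 33), (12, 87)]:
        d = np.linalg.norm(g.cell_centers()[i] - g.cell_centers()[j])
        emp = np.corrcoef(f[:, i], f[:, j])[0, 1]
        assert emp == pytest.approx(np.exp(-2 * d / rho), abs=0.08)


def test_field_reproducible_and_param_validation():
    g = pm.GridDefinition(5, 5)
    a = pm.simulate_matern_field(g, 1.0, 3.0, 1.0, seed=9)
    b = pm.simulate_matern_field(g, 1.0, 3.0, 1.0, seed=9)
    np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError):
        pm.simulate_matern_field(g, -1.0, 3.0, 1.0, seed=0)


def test_covariate_surfaces_contract(small_grid):
    stack = pm.generate_covariate_surfaces(small_grid, 4, seed=3)
    np.testing.assert_allclose(stack.values.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(stack.values.std(axis=1), 1.0, atol=1e-12)
    corr = np.corrcoef(stack.values)
    off = np.abs(corr - np.diag(np.diag(corr)))
    assert off.max() > 0.8  # engineered collinear pair
    again = pm.generate_covariate_surfaces(small_grid, 4, seed=3)
    np.testing.assert_array_equal(stack.values, again.values)
    other = pm.generate_covariate_surfaces(small_grid, 4, seed=4)
    assert not np.array_equal(stack.values, other.values)
    with pytest.raises(ValueError):
        pm.generate_covariate_surfaces(small_grid, 0, seed=0)


def _flat_truth(grid, p):
    stack = pm.CovariateStack(grid, ["z"], np.zeros((1, grid.n_cells)))
    truth = pm.make_truth(grid, stack, [0.0, 0.0], 1.0, 5.0, seed=0)
    truth.prevalence_surface = np.full(grid.n_cells, p)
    return truth


def test_survey_degenerate_prevalence(small_grid):
    all_zero = pm.simulate_survey(_flat_truth(small_grid, 0.0), 30, 10, seed=1)
    assert (all_zero.n_sam == 0).all()
    all_one = pm.simulate_survey(_flat_truth(small_grid, 1.0), 30, 10, seed=1)
    assert (all_one.n_sam == all_one.n_examined).all()
    with pytest.raises(ValueError):
        pm.simulate_survey(_flat_truth(small_grid, 1.5), 5, 10, seed=1)


def test_survey_pooled_prevalence_binomial(small_grid):
    truth = _flat_truth(small_grid, 0.07)
    pooled = []
    for s in range(40):
        sv = pm.simulate_survey(truth, 123, 12, seed=s)
        pooled.append(sv.n_sam.sum() / sv.n_examined.sum())
    # binomial sampling: mean 0.07, se ~ sqrt(.07*.93/1476)/sqrt(40) ~ 0.001
    assert np.mean(pooled) == pytest.approx(0.07, abs=0.004)


def test_survey_counts_bounds_and_extent(small_grid, toy_data):
    sv = pm.simulate_survey(toy_data["truth"], 80, (12, 15), seed=5, clumped=True)
    assert ((sv.n_sam >= 0) & (sv.n_sam <= sv.n_examined)).all()
    assert (sv.n_examined.between(12, 15)).all()
    small_grid.cell_index(sv.x.to_numpy(), sv.y.to_numpy())  # must not raise


def test_population_raster_conservation(small_grid):
    pop = pm.generate_population_raster(small_grid, 5000.0, seed=1)
    assert pop.total == pytest.approx(5000.0, rel=1e-9)
    assert (pop.under2_count >= 0).all()
    eq = pm.generate_population_raster(small_grid, 5000.0, seed=1, equal=True)
    np.testing.assert_allclose(eq.under2_count, 5000.0 / small_grid.n_cells)
    again = pm.generate_population_raster(small_grid, 5000.0, seed=1)
    np.testing.assert_array_equal(pop.under2_count, again.under2_count)


def test_admin_polygons_partition(small_grid):
    one = generate_admin_polygons(small_grid, 1)
    assert len(one) == 1
    assert one.polygons[0].bounds == small_grid.extent

    g10 = pm.GridDefinition(10, 10)
    quad = generate_admin_polygons(g10, 4)
    from prevmap.aggregate import assign_cells
    assign = assign_cells(g10, quad)
    assert (assign >= 0).all()
    counts = np.bincount(assign, minlength=4)
    np.testing.assert_array_equal(counts, [25, 25, 25, 25])

    for n_units in (3, 5, 8):
        units = generate_admin_polygons(small_grid, n_units)
        assign = assign_cells(small_grid, units)
        assert (assign >= 0).all()
        assert np.bincount(assign, minlength=n_units).sum() == small_grid.n_cells


def test_admin_geojson_roundtrip(tmp_path, small_grid):
    units = generate_admin_polygons(small_grid, 6)
    units.save(tmp_path / "admin.geojson")
    back = pm.AdminUnits.load(tmp_path / "admin.geojson")
    assert back.unit_ids == units.unit_ids
    for a, b in zip(back.polygons, units.polygons):
        assert a.equals(b)


def test_default_scenario_mirrors_study_scale():
    scen = make_scenario(seed=0)
    assert len(scen.survey) == 123
    assert scen.survey.n_examined.between(12, 15).all()
    assert scen.truth.covariates.n_layers == 6
    # overall prevalence of the truth surface sits in the mid-single digits
    assert 0.03 < scen.truth.prevalence_surface.mean() < 0.13
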