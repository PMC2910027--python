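"""Allelic/spatial decomposition, outlier rules, and the end-to-end pipeline."""

import numpy as np
import pytest

import spnorm as sp


def _glog_grid_from_groups(factory, values, group_of):
    layout, index, grid = factory(np.asarray(values, float), np.asarray(group_of))
    g = sp.IntensityGrid(grid.values, sp.Scale.GLOG, grid.missing_mask)
    return layout, index, g


@pytest.mark.parametrize("replicates,expected", [
    ([1.0, 2.0, 100.0], 2.0),      # robust to the outlier
    ([3.0, 5.0, 7.0, 9.0], 6.0),   # mean-of-two-middles convention
])
def test_initialize_allelic_median(group_layout_factory, replicates, expected):
    _, index, g = _glog_grid_from_groups(
        group_layout_factory, replicates + [5.0, 5.0],
        [0] * len(replicates) + [1, 1])
    a = sp.initialize_allelic(g, index)
    assert a.source == "MEDIAN_INIT"
    assert a[("G000000", "A")] == pytest.approx(expected)


@pytest.mark.parametrize("shift,expected", [(0.0, 2.0), (1.0, 1.0)])
def test_update_allelic_mean_of_bias_adjusted(group_layout_factory, shift, expected):
    layout, index, g = _glog_grid_from_groups(
        group_layout_factory, [1.0, 2.0, 3.0, 5.0, 5.0], [0, 0, 0, 1, 1])
    field = sp.SpatialField(np.full(layout.shape, shift),
                            np.ones(layout.shape, bool))
    a = sp.update_allelic(g, field, index)
    assert a.source == "MEAN_UPDATED"
    assert a[("G000000", "A")] == pytest.approx(expected)


def test_estimate_spatial_zero_residual_gives_zero_field(group_layout_factory):
    """If intensities equal the allelic estimates exactly, S_hat == 0."""
    vals = [4.0] * 6
    layout, index, g = _glog_grid_from_groups(group_layout_factory, vals,
                                              [0, 0, 0, 1, 1, 1])
    a = sp.initialize_allelic(g, index)
    s = sp.estimate_spatial(g, a, layout, index)
    assert np.allclose(s.value, 0.0, atol=1e-12)


def _simulate(cfg):
    layout = sp.make_layout(cfg)
    index = sp.build_probeset_index(layout)
    grid, truth = sp.simulate_chip(layout, cfg, index=index)
    return layout, index, grid, truth


def _to_glog(grid, c):
    return sp.IntensityGrid(sp.glog_transform(grid.values, sp.GlogParams(c)),
                            sp.Scale.GLOG, grid.missing_mask)


def test_estimate_spatial_zero_bias_is_small():
    cfg = sp.SimulationConfig(n_rows=64, n_cols=64, n_probesets=220,
                              stripe_width=2, bias=(), noise_sd=0.02, seed=2)
    layout, index, grid, truth = _simulate(cfg)
    g = _to_glog(grid, cfg.c_sim)
    s = sp.estimate_spatial(g, sp.initialize_allelic(g, index), layout, index)
    assert np.max(np.abs(s.value[s.covered_mask])) < 3 * cfg.noise_sd


def test_estimate_spatial_recovers_gradient():
    """A +/-0.05 planar gradient is recovered with Pearson r >= 0.8."""
    cfg = sp.SimulationConfig(n_rows=64, n_cols=64, n_probesets=220,
                              stripe_width=2, bias=(sp.Gradient(0.05),),
                              noise_sd=0.02, seed=10)
    layout, index, grid, truth = _simulate(cfg)
    g = _to_glog(grid, cfg.c_sim)
    s = sp.estimate_spatial(g, sp.initialize_allelic(g, index), layout, index)
    cov = s.covered_mask
    r = np.corrcoef(s.value[cov], truth.s_true[cov])[0, 1]
    assert r >= 0.8


def test_update_beats_median_under_bias():
    """With spatial bias present, the bias-adjusted mean recovers A_true
    better than the raw-replicate median."""
    cfg = sp.SimulationConfig(n_rows=64, n_cols=64, n_probesets=220,
                              stripe_width=2, seed=4)
    layout, index, grid, truth = _simulate(cfg)
    _, res = sp.normalize_chip(grid, layout, sp.NormalizeConfig(glog_c=cfg.c_sim),
                               index=index)
    rmse_med = np.sqrt(np.mean((res.initial_allelic.values - truth.a_true) ** 2))
    rmse_upd = np.sqrt(np.mean((res.allelic.values - truth.a_true) ** 2))
    assert rmse_upd < rmse_med


def test_run_iterations_validates_and_is_deterministic(small_chip):
    layout, index, grid, _ = small_chip
    g = _to_glog(grid, 50.0)
    with pytest.raises(ValueError, match="iterations"):
        sp.run_iterations(g, layout, index, sp.NormalizeConfig(iterations=0))
    r1 = sp.run_iterations(g, layout, index)
    r2 = sp.run_iterations(g, layout, index)
    assert np.array_equal(r1.allelic.values, r2.allelic.values)
    assert np.array_equal(r1.field.value, r2.field.value)


def test_zero_noise_zero_bias_recovers_exactly():
    cfg = sp.SimulationConfig(n_rows=48, n_cols=48, n_probesets=120,
                              stripe_width=2, bias=(), noise_sd=0.0, seed=6)
    layout, index, grid, truth = _simulate(cfg)
    g = _to_glog(grid, cfg.c_sim)
    res = sp.run_iterations(g, layout, index)
    assert np.allclose(res.allelic.values, truth.a_true, atol=1e-9)


def test_iteration_changes_shrink():
    """Successive surface-fit/mean-update passes move A_hat less and less."""
    cfg = sp.SimulationConfig(n_rows=96, n_cols=96, n_probesets=500,
                              stripe_width=2, bias=(sp.Gradient(0.04),), seed=7)
    layout, index, grid, _ = _simulate(cfg)
    _, res = sp.normalize_chip(grid, layout,
                               sp.NormalizeConfig(iterations=3, glog_c=cfg.c_sim),
                               index=index)
    deltas = [d["max_abs_allelic_change"] for d in res.diagnostics]
    assert deltas[1] < deltas[0] and deltas[2] < deltas[1]


# ---------------------------------------------------------------------------
# outlier flagging


def _field(values, covered=None):
    values = np.asarray(values, float)
    if covered is None:
        covered = np.ones_like(values, bool)
    return sp.SpatialField(values, covered)


def test_isolated_spike_is_reinstated():
    """A lone extreme cell is primary-flagged, then un-flagged as isolated."""
    # uniform background: max deviation is 2 MADs, so only the spike flags
    v = np.linspace(-0.01, 0.01, 81).reshape(9, 9).copy()
    v[4, 4] = 100.0
    mask = sp.flag_outliers(_field(v), n_mad=3)
    assert not mask.flags.any()


def test_surrounded_cell_is_flagged():
    """An unflagged cell with >= 50% flagged neighbors joins the outlier set."""
    v = np.linspace(-0.01, 0.01, 121).reshape(11, 11).copy()
    v[3:8, 3:8] = 50.0
    v[5, 5] = 0.0  # interior cell near the field median
    mask = sp.flag_outliers(_field(v), n_mad=3)
    assert mask.flags[5, 5]
    assert mask.flags[3:8, 3:8].all()
    assert mask.n_flagged == 25


def test_degenerate_mad_flags_nothing():
    mask = sp.flag_outliers(_field(np.zeros((5, 5))), n_mad=3)
    assert not mask.flags.any()


def test_flag_outliers_matches_brute_force_oracle():
    """Full rule (primary n-MAD + both refinements) vs. an explicit
    cell-by-cell oracle on Gaussian fields."""
    rng = np.random.default_rng(6)
    v = rng.normal(size=(60, 60))
    covered = rng.random((60, 60)) < 0.8
    field = _field(v, covered)
    got = sp.flag_outliers(field, n_mad=3)

    vals = v[covered]
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    primary = covered & (np.abs(v - med) > 3 * mad)

    def neighbors(y, x, mask):
        return sum(mask[yy, xx]
                   for yy in range(max(y - 1, 0), min(y + 2, 60))
                   for xx in range(max(x - 1, 0), min(x + 2, 60))
                   if (yy, xx) != (y, x))

    stage1 = primary.copy()
    for y, x in zip(*np.nonzero(primary)):
        if neighbors(y, x, primary) == 0:
            stage1[y, x] = False
    stage2 = stage1.copy()
    for y, x in zip(*np.nonzero(covered & ~stage1)):
        n_cov = neighbors(y, x, covered)
        if n_cov and neighbors(y, x, stage1) / n_cov >= 0.5:
            stage2[y, x] = True
    assert np.array_equal(got.flags, stage2)
    # sanity: the primary fraction is near the Gaussian tail beyond
    # 3 * MAD = 3 * 0.6745 sigma
    frac = primary.sum() / covered.sum()
    from scipy.stats import norm
    assert frac == pytest.approx(2 * norm.sf(3 * 0.6745), abs=0.01)


def test_revise_allelic_excluding(group_layout_factory):
    layout, index, g = _glog_grid_from_groups(
        group_layout_factory, [2.0, 2.0, 50.0, 1.0, 3.0], [0, 0, 0, 1, 1])
    field = sp.SpatialField(np.zeros(layout.shape), np.ones(layout.shape, bool))
    flags = np.zeros(layout.shape, bool)
    flags[0, 2] = True  # the 50.0 replicate
    revised, degen = sp.revise_allelic_excluding(
        g, field, index, sp.OutlierMask(flags, 3.0))
    assert revised.source == "OUTLIER_REVISED"
    assert revised[("G000000", "A")] == pytest.approx(2.0)
    assert degen == []
    # no flags -> identical to the plain update
    none, _ = sp.revise_allelic_excluding(
        g, field, index, sp.OutlierMask(np.zeros(layout.shape, bool), 3.0))
    assert np.array_equal(none.values, sp.update_allelic(g, field, index).values)
    # all replicates flagged -> group keeps the unrevised value, reported
    allflag = np.zeros(layout.shape, bool)
    allflag[0, :3] = True
    kept, degen = sp.revise_allelic_excluding(
        g, field, index, sp.OutlierMask(allflag, 3.0))
    assert degen == [("G000000", "A")]
    assert kept[("G000000", "A")] == pytest.approx((2 + 2 + 50) / 3)


def test_scratch_revision_improves_affected_groups():
    """Excluding scratch-flagged probes lowers the error of the affected
    probesets' estimates."""
    cfg = sp.SimulationConfig(n_rows=96, n_cols=96, n_probesets=500,
                              stripe_width=2,
                              bias=(sp.Scratch(depth=-0.5, width=3.0,
                                               start=(0.2, 0.2), end=(0.8, 0.8)),),
                              seed=12)
    layout, index, grid, truth = _simulate(cfg)
    _, res = sp.normalize_chip(grid, layout,
                               sp.NormalizeConfig(glog_c=cfg.c_sim), index=index)
    outliers = sp.flag_outliers(res.field, 3.0)
    g = _to_glog(grid, cfg.c_sim)
    revised, _ = sp.revise_allelic_excluding(g, res.field, index, outliers)
    hit = np.bincount(index.group_of,
                      truth.scratch_mask[index.rows, index.cols],
                      index.n_groups) > 0
    rmse_rev = np.sqrt(np.mean((revised.values[hit] - truth.a_true[hit]) ** 2))
    rmse_unrev = np.sqrt(np.mean((res.allelic.values[hit] - truth.a_true[hit]) ** 2))
    assert rmse_rev < rmse_unrev


# ---------------------------------------------------------------------------
# end-to-end


def test_normalize_chip_output_contract(small_chip):
    layout, index, grid, _ = small_chip
    corrected, res = sp.normalize_chip(grid, layout, index=index)
    assert corrected.scale is sp.Scale.RAW
    assert np.all(corrected.values[~corrected.missing_mask] >= 0)
    # replicates of one group share a corrected value
    flat = corrected.values[index.rows, index.cols]
    for gi in range(min(index.n_groups, 50)):
        vals = flat[index.group_of == gi]
        assert np.allclose(vals, vals[0], atol=1e-9)
    # non-replicated cells pass through unchanged
    other = ~layout.replicated_mask()
    assert np.array_equal(corrected.values[other], grid.values[other])


def test_normalize_chip_zero_bias_matches_group_means():
    cfg = sp.SimulationConfig(n_rows=64, n_cols=64, n_probesets=220,
                              stripe_width=2, bias=(), noise_sd=0.02, seed=8)
    layout, index, grid, _ = _simulate(cfg)
    corrected, _ = sp.normalize_chip(grid, layout,
                                     sp.NormalizeConfig(glog_c=cfg.c_sim),
                                     index=index)
    raw_means = index.group_reduce(index.values_at(grid.values), "mean")
    got = corrected.values[index.rows, index.cols]
    rel = np.abs(got - raw_means[index.group_of]) / raw_means[index.group_of]
    assert np.max(rel) < 0.01


def test_identifiability_shift(small_chip):
    """Adding a constant on the glog scale shifts A_hat by that constant and
    leaves S_hat unchanged; A_hat + S_hat per cell is invariant."""
    layout, index, grid, _ = small_chip
    g = _to_glog(grid, 50.0)
    shifted = sp.IntensityGrid(g.values + 0.37, sp.Scale.GLOG, g.missing_mask)
    r1 = sp.run_iterations(g, layout, index)
    r2 = sp.run_iterations(shifted, layout, index)
    assert np.allclose(r2.allelic.values - r1.allelic.values, 0.37, atol=1e-8)
    assert np.allclose(r2.field.value, r1.field.value, atol=1e-8)
    cell_sum1 = r1.allelic.values[index.group_of] \
        + r1.field.value[index.rows, index.cols]
    cell_sum2 = r2.allelic.values[index.group_of] \
        + r2.field.value[index.rows, index.cols]
    assert np.allclose(cell_sum2 - cell_sum1, 0.37, atol=1e-8)


def test_normalize_chip_rejects_glog_input(small_chip):
    layout, index, grid, _ = small_chip
    g = _to_glog(grid, 50.0)
    with pytest.raises(ValueError, match="RAW"):
        sp.normalize_chip(g, layout, index=index)
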