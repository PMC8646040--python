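"""Tests of thresholds, areas and group comparisons on hand-built curves."""

import numpy as np
import pytest

from fdpsim import (
    ConfigurationError,
    FDPCurve,
    ThresholdUndefinedError,
    analyze_sweep,
    compare_groups,
    compute_areas,
    find_f_plus,
    find_threshold_f0,
)

TOY_F = np.arange(6.0)                                # 0 ... 5 Hz
TOY_W = np.array([1.0, 0.9, 0.8, 0.9, 1.0, 1.2])      # dip then recovery


def _curve(cv, f, w_rows, ca_rows=None):
    w_rows = np.atleast_2d(w_rows)
    ca = np.atleast_2d(ca_rows) if ca_rows is not None else np.ones_like(w_rows)
    keys = [(cv, i, 0) for i in range(w_rows.shape[0])]
    return FDPCurve(cv=cv, frequencies=f, w=w_rows, ca=ca, replicate_keys=keys)


# ---------------------------------------------------------------- f0


def test_threshold_at_exact_recovery_point():
    assert find_threshold_f0((TOY_F, TOY_W)) == 4.0


def test_threshold_interpolates_crossing():
    f = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    w = np.array([1.0, 0.95, 0.9, 0.9, 1.05])
    # crossing between 3 (0.9) and 4 (1.05): 3 + 0.1/0.15
    assert find_threshold_f0((f, w)) == pytest.approx(3.0 + 0.1 / 0.15, rel=1e-12)


def test_threshold_requires_a_dip():
    with pytest.raises(ThresholdUndefinedError, match="never falls below"):
        find_threshold_f0((TOY_F, np.full(6, 1.1)))


def test_threshold_requires_recovery():
    with pytest.raises(ThresholdUndefinedError, match="never returns"):
        find_threshold_f0((TOY_F, np.array([1.0, 0.9, 0.8, 0.7, 0.6, 0.5])))


def test_threshold_tolerates_initial_suprabaseline_segment():
    # curves can start above 1, dip, then recover (high-fluctuation shape)
    f = np.arange(5.0)
    w = np.array([1.3, 0.9, 0.8, 1.0, 1.4])
    assert find_threshold_f0((f, w)) == 3.0


def test_threshold_needs_two_points():
    with pytest.raises(ConfigurationError):
        find_threshold_f0((np.array([1.0]), np.array([0.5])))


# ---------------------------------------------------------------- f_plus


def test_f_plus_defaults_to_cap_for_rising_curve():
    f = np.arange(1.0, 21.0)
    assert find_f_plus((f, f * 0.1), plateau_tol=1e-6) == 20.0


def test_f_plus_detects_plateau_onset():
    f = np.arange(10.0, 21.0)
    w = np.where(f < 15, f * 0.2, 3.0)   # flat from 15 Hz onward
    assert find_f_plus((f, w), plateau_tol=1e-9) == 15.0


def test_f_plus_zero_tolerance_disables_plateau():
    f = np.arange(10.0, 21.0)
    assert find_f_plus((f, np.full_like(f, 2.0)), plateau_tol=0.0) == 20.0


# ---------------------------------------------------------------- areas


def test_trapezoid_areas_match_hand_sums():
    areas = compute_areas((TOY_F, TOY_W), f0=4.0, f_plus=5.0)
    assert areas.ltd_area == pytest.approx(3.6, rel=1e-12)
    assert areas.ltp_area == pytest.approx(1.1, rel=1e-12)


def test_flat_curve_ltd_area_is_rectangle():
    f = np.arange(0.0, 7.0)
    areas = compute_areas((f, np.ones(7)), f0=4.0, f_plus=6.0)
    assert areas.ltd_area == pytest.approx(4.0, rel=1e-12)


def test_interpolated_f0_node_is_included():
    f = np.array([0.0, 2.0, 4.0])
    w = np.array([0.8, 0.9, 1.1])
    f0 = find_threshold_f0((f, w))           # 3.0 by interpolation
    areas = compute_areas((f, w), f0, 4.0)
    # [0,2]: (0.8+0.9)/2*2 = 1.7 ; [2,3]: (0.9+1.0)/2 = 0.95
    assert areas.ltd_area == pytest.approx(1.7 + 0.95, rel=1e-12)
    assert areas.ltp_area == pytest.approx((1.0 + 1.1) / 2, rel=1e-12)


def test_flat_extension_below_first_grid_point():
    f = np.array([1.0, 2.0, 3.0])
    w = np.array([0.5, 1.0, 1.5])
    areas = compute_areas((f, w), f0=2.0, f_plus=3.0)
    # [0,1] extended flat at 0.5, [1,2] trapezoid 0.75
    assert areas.ltd_area == pytest.approx(0.5 + 0.75, rel=1e-12)


def test_areas_additive_when_f0_is_grid_node():
    f = np.arange(0.0, 6.0)
    total = np.trapezoid(TOY_W, TOY_F)
    areas = compute_areas((f, TOY_W), f0=4.0, f_plus=5.0)
    assert areas.ltd_area + areas.ltp_area == pytest.approx(total, rel=1e-12)


def test_trapezoid_matches_riemann_refinement_oracle():
    """Trapezoid areas equal midpoint Riemann sums of the interpolant."""
    f = np.arange(0.0, 6.0)
    for w in (TOY_W, np.array([1.0, 0.7, 0.6, 0.9, 1.3, 2.0])):
        areas = compute_areas((f, w), f0=4.0, f_plus=5.0)
        xs = np.linspace(0.0, 4.0, 2_000_001)
        mid = 0.5 * (xs[1:] + xs[:-1])
        riemann = np.sum(np.interp(mid, f, w)) * (xs[1] - xs[0])
        assert areas.ltd_area == pytest.approx(riemann, abs=1e-9)


def test_deviation_mode_measures_clipped_baseline_area():
    f = np.array([0.0, 1.0, 2.0, 3.0])
    w = np.array([1.2, 0.8, 1.0, 1.5])
    areas = compute_areas((f, w), f0=2.0, f_plus=3.0, area_mode="deviation")
    # LTD: only the below-baseline part counts: nodes (0,0), (1,0.2), (2,0)
    assert areas.ltd_area == pytest.approx(0.2, rel=1e-12)
    # LTP: (0 + 0.5)/2 over [2, 3]
    assert areas.ltp_area == pytest.approx(0.25, rel=1e-12)


def test_area_bounds_validated():
    with pytest.raises(ConfigurationError):
        compute_areas((TOY_F, TOY_W), f0=5.0, f_plus=4.0)
    with pytest.raises(ConfigurationError):
        compute_areas((TOY_F, TOY_W), f0=2.0, f_plus=9.0)  # beyond curve
    with pytest.raises(ConfigurationError):
        compute_areas((TOY_F, TOY_W), f0=2.0, f_plus=5.0, area_mode="bogus")


# ---------------------------------------------------------------- comparisons


def test_identical_groups_are_not_significant():
    same = np.array([1.0, 1.1, 0.9, 1.05, 0.95])
    comp = compare_groups({"a": same, "b": same.copy()})
    row = comp.table.iloc[0]
    assert row["p_adj"] > 0.05 and not row["significant"]


@pytest.mark.parametrize("test", ["welch", "permutation"])
def test_separated_groups_are_significant(test):
    """Groups of n=15 separated by 10 within-group SDs: p below 1e-3."""
    rng = np.random.default_rng(1)
    a = rng.normal(0.0, 1.0, 15)
    b = rng.normal(10.0, 1.0, 15)
    comp = compare_groups({"a": a, "b": b}, test=test, seed=2)
    row = comp.table.iloc[0]
    assert row["significant"] and row["p_adj"] < 1e-3


def test_four_conditions_give_six_pairs_and_holm_ordering():
    rng = np.random.default_rng(3)
    samples = {f"g{i}": rng.normal(i * 0.5, 1.0, 10) for i in range(4)}
    comp = compare_groups(samples)
    assert len(comp.table) == 6
    assert (comp.table["p_adj"] >= comp.table["p"] - 1e-15).all()
    assert comp.table["p"].between(0, 1).all()


def test_single_replicate_rejected():
    with pytest.raises(ConfigurationError, match="need >= 2"):
        compare_groups({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})


# ---------------------------------------------------------------- analyze


def test_analyze_sweep_control_ratios_are_100_percent():
    f = np.arange(0.0, 6.0)
    reps_ctrl = np.vstack([TOY_W + d for d in (-0.01, 0.0, 0.01)])
    # shallower dip with the same shape (recovers above 1 at the last point)
    reps_cv5 = np.vstack([TOY_W * 0.5 + 0.52 + d for d in (-0.01, 0.0, 0.01)])
    curves = {0.0: _curve(0.0, f, reps_ctrl), 5.0: _curve(5.0, f, reps_cv5)}
    res = analyze_sweep(curves, area_mode="deviation")
    ctrl = res["conditions"][0.0]
    assert ctrl.ltd_area_ratio == pytest.approx(100.0)
    assert ctrl.ltp_area_ratio == pytest.approx(100.0)
    assert set(res["comparisons"]) == {"ltd_area_ratio", "ltp_area_ratio",
                                       "f0", "ca_at_f0"}
    assert len(res["per_replicate"]) == 6


def test_analyze_sweep_tolerates_undefined_condition_threshold():
    f = np.arange(0.0, 6.0)
    curves = {
        0.0: _curve(0.0, f, np.vstack([TOY_W, TOY_W])),
        5.0: _curve(5.0, f, np.full((2, 6), 1.5)),   # never dips
    }
    res = analyze_sweep(curves)
    assert res["conditions"][0.0] is not None
    assert res["conditions"][5.0] is None


def test_curve_aggregates_and_validation():
    f = np.arange(1.0, 4.0)
    c = _curve(0.0, f, np.array([[1.0, 2.0, 3.0], [3.0, 4.0, 5.0]]))
    np.testing.assert_allclose(c.mean_w, [2.0, 3.0, 4.0])
    np.testing.assert_allclose(c.sem_w(), c.sd_w() / np.sqrt(2))
    with pytest.raises(ConfigurationError):
        _curve(0.0, np.array([2.0, 1.0]), np.ones((1, 2)))
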