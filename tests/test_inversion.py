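"""LUT construction/inversion, regressor training, and error metrics."""

import numpy as np
import pytest
from scipy.stats import kstest

import joblib

from sfdiml import (
    InversionModel,
    TrainingSet,
    benchmark_methods,
    build_forward_lut,
    generate_training_set,
    lut_invert,
    mean_relative_error,
    predict_properties,
    train_regressor,
)
from sfdiml.diffusion import STATUS_INVALID, STATUS_OK, STATUS_OUT_OF_DOMAIN


def test_degenerate_grid_equals_direct_forward_calls(diffusion_fwd):
    lut = build_forward_lut(2, 2, diffusion_fwd)
    corners_a = np.array([0.0, 0.0, 2.0, 2.0])
    corners_s = np.array([0.01, 15.0, 0.01, 15.0])
    r0, rn = diffusion_fwd.reflectance_pairs(corners_a, corners_s)
    np.testing.assert_array_equal(lut.r0.ravel(), r0)
    np.testing.assert_array_equal(lut.rn.ravel(), rn)
    with pytest.raises(ValueError):
        build_forward_lut(1, 5, diffusion_fwd)


def test_dense_lut_has_monotone_rows(dense_lut):
    """R0 and Rn strictly decrease with mu_a along every grid row.

    Rn strictness is asserted above the noise-limited strip (mu_s' >= 0.1
    mm^-1, where the scaled frequency exceeds 2/l* and exiting photons are
    scarce); below it only near-monotonicity is required.
    """
    assert np.all(np.diff(dense_lut.r0, axis=0) < 0)
    cols_ok = dense_lut.mu_s_axis >= 0.1
    assert np.all(np.diff(dense_lut.rn[:, cols_ok], axis=0) < 0)
    frac_bad = np.mean(np.diff(dense_lut.rn, axis=0) >= 0)
    assert frac_bad < 1e-4


def test_node_queries_recover_node_properties(dense_lut):
    idx = [(1, 1), (250, 500), (500, 10), (998, 998)]
    for i, j in idx:
        maps = lut_invert(
            dense_lut,
            np.array([dense_lut.r0[i, j]]),
            np.array([dense_lut.rn[i, j]]),
        )
        assert maps.status[0] == STATUS_OK
        assert maps.mu_a[0] == pytest.approx(dense_lut.mu_a_axis[i], abs=1e-9)
        assert maps.mu_s_prime[0] == pytest.approx(
            dense_lut.mu_s_axis[j], abs=1e-9
        )


def test_off_grid_recovery_bounded_by_one_cell(diffusion_fwd):
    """Inverse interpolation errs by at most one grid-cell diameter.

    Asserted for interior queries (at least one cell away from the domain
    edges): in the first grid row the forward map's sqrt(mu_a) curvature
    makes adjacent bilinear cell images overlap, so the containing-cell
    answer there is only accurate to a few cells.
    """
    lut = build_forward_lut(60, 60, diffusion_fwd)
    h_a = np.diff(lut.mu_a_axis)[0]
    h_s = np.diff(lut.mu_s_axis)[0]
    cell = np.hypot(h_a, h_s)
    rng = np.random.default_rng(4)
    mu_a = rng.uniform(h_a, 2.0 - h_a, 500)
    mu_sp = rng.uniform(0.01 + h_s, 15.0 - h_s, 500)
    r0, rn = diffusion_fwd.reflectance_pairs(mu_a, mu_sp)
    maps = lut_invert(lut, r0, rn)
    err = np.hypot(maps.mu_a - mu_a, maps.mu_s_prime - mu_sp)
    assert np.all(err <= cell * (1 + 1e-9))


def test_all_zero_reflectance_flagged_out_of_domain(dense_lut):
    maps = lut_invert(dense_lut, np.zeros((3, 4)), np.zeros((3, 4)))
    assert np.all(maps.status == STATUS_OUT_OF_DOMAIN)


def test_nonfinite_reflectance_flagged_invalid(dense_lut):
    maps = lut_invert(dense_lut, np.array([np.nan, 0.4]), np.array([0.1, 0.1]))
    assert maps.status[0] == STATUS_INVALID
    assert maps.status[1] != STATUS_INVALID


def test_training_set_bounds_and_reproducibility(diffusion_fwd):
    a = generate_training_set(10, 77, diffusion_fwd)
    b = generate_training_set(10, 77, diffusion_fwd)
    assert a.n == 10
    assert np.all((a.mu_a >= 0.0) & (a.mu_a <= 2.0))
    assert np.all((a.mu_s_prime >= 0.01) & (a.mu_s_prime <= 15.0))
    np.testing.assert_array_equal(a.mu_a, b.mu_a)
    np.testing.assert_array_equal(a.r0, b.r0)


def test_training_set_marginals_are_uniform(diffusion_fwd):
    """Empirical CDFs of both marginals stay within KS distance 0.01."""
    ts = generate_training_set(100_000, 55, diffusion_fwd)
    ks_a = kstest(ts.mu_a, "uniform", args=(0.0, 2.0)).statistic
    ks_s = kstest(ts.mu_s_prime, "uniform", args=(0.01, 14.99)).statistic
    assert ks_a < 0.01
    assert ks_s < 0.01


def test_training_set_save_load_round_trip(tmp_path, diffusion_fwd):
    ts = generate_training_set(50, 3, diffusion_fwd)
    path = tmp_path / "ts.npz"
    ts.save(path)
    back = TrainingSet.load(path)
    np.testing.assert_array_equal(back.r0, ts.r0)
    assert back.rng_seed == ts.rng_seed
    assert back.provenance == ts.provenance


def test_constant_training_point_yields_constant_model():
    ts = TrainingSet(
        r0=np.full(50, 0.4),
        rn=np.full(50, 0.1),
        mu_a=np.full(50, 0.3),
        mu_s_prime=np.full(50, 2.5),
    )
    model = train_regressor(ts, seed=1)
    maps = predict_properties(model, np.array([0.1, 0.4, 0.9]),
                              np.array([0.05, 0.1, 0.2]))
    np.testing.assert_allclose(maps.mu_a, 0.3)
    np.testing.assert_allclose(maps.mu_s_prime, 2.5)


def test_constant_inputs_with_varying_targets_rejected():
    ts = TrainingSet(
        r0=np.full(50, 0.4),
        rn=np.full(50, 0.1),
        mu_a=np.linspace(0.1, 1.0, 50),
        mu_s_prime=np.full(50, 2.5),
    )
    with pytest.raises(ValueError):
        train_regressor(ts)


def test_training_set_recall(diffusion_fwd):
    """At min-leaf 2 the forest memorises: train error well below held-out.

    Bootstrap resampling keeps ~37% of samples out of each tree, so the
    recall is not exact; the memorisation regime shows as a large gap
    between training-input and held-out errors.
    """
    ts = generate_training_set(3000, 8, diffusion_fwd)
    model = train_regressor(ts, seed=0)
    pred = predict_properties(model, ts.r0, ts.rn)
    m_train = mean_relative_error(pred, (ts.mu_a, ts.mu_s_prime), mu_a_floor=0.05)
    held = generate_training_set(3000, 81, diffusion_fwd)
    pred_h = predict_properties(model, held.r0, held.rn)
    m_held = mean_relative_error(
        pred_h, (held.mu_a, held.mu_s_prime), mu_a_floor=0.05
    )
    assert m_train["mu_a_pct"] < 0.7 * m_held["mu_a_pct"]
    assert m_train["mu_s_prime_pct"] < 0.7 * m_held["mu_s_prime_pct"]


def test_prediction_is_per_pixel(rf_model):
    """Constant megapixel maps give constant outputs (pixel independence)."""
    r0 = np.full((1000, 1000), 0.55)
    rn = np.full((1000, 1000), 0.11)
    maps = predict_properties(rf_model, r0, rn)
    assert maps.mu_a.shape == (1000, 1000)
    assert np.all(maps.mu_a == maps.mu_a[0, 0])
    assert np.all(maps.mu_s_prime == maps.mu_s_prime[0, 0])


def test_inversions_are_permutation_equivariant(dense_lut, rf_model, rng):
    mu_a = rng.uniform(0.1, 1.9, 64)
    r0 = np.interp(mu_a, dense_lut.mu_a_axis, dense_lut.r0[:, 500])
    rn = np.interp(mu_a, dense_lut.mu_a_axis, dense_lut.rn[:, 500])
    perm = rng.permutation(64)
    for invert in (
        lambda a, b: lut_invert(dense_lut, a, b),
        lambda a, b: predict_properties(rf_model, a, b),
    ):
        base = invert(r0, rn)
        shuffled = invert(r0[perm], rn[perm])
        np.testing.assert_array_equal(base.mu_a[perm], shuffled.mu_a)


def test_mean_relative_error_closed_forms():
    truth = (np.array([0.5, 1.0]), np.array([2.0, 4.0]))
    assert mean_relative_error(truth, truth)["mu_a_pct"] == 0.0
    pred = (np.array([0.55]), np.array([4.4]))
    m = mean_relative_error(pred, (np.array([0.5]), np.array([4.0])))
    assert m["mu_a_pct"] == pytest.approx(10.0)
    assert m["mu_s_prime_pct"] == pytest.approx(10.0)
    pred = (np.array([1.01, 1.03]), np.array([1.0, 1.0]))
    m = mean_relative_error(pred, (np.ones(2), np.ones(2)))
    assert m["mu_a_pct"] == pytest.approx(2.0)


def test_error_metric_is_scale_free():
    rng = np.random.default_rng(0)
    truth = (rng.uniform(0.1, 2, 50), rng.uniform(0.1, 15, 50))
    pred = (truth[0] * 1.02, truth[1] * 0.97)
    m1 = mean_relative_error(pred, truth)
    m2 = mean_relative_error((3 * pred[0], 3 * pred[1]),
                             (3 * truth[0], 3 * truth[1]))
    assert m1["mu_a_pct"] == pytest.approx(m2["mu_a_pct"])


def test_near_zero_absorption_excluded_and_reported():
    truth = (np.array([1e-5, 0.5, 1.0]), np.ones(3))
    pred = (np.array([5.0, 0.5, 1.0]), np.ones(3))
    m = mean_relative_error(pred, truth)
    assert m["mu_a_pct"] == 0.0  # the wild near-zero sample is excluded
    assert m["mu_a_excluded_fraction"] == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        mean_relative_error((np.array([1.0]), np.array([1.0])),
                            (np.array([1e-9]), np.array([0.0])))


def test_benchmark_empty_methods_gives_empty_table(diffusion_fwd):
    test = generate_training_set(10, 1, diffusion_fwd)
    assert benchmark_methods(test, {}) == []


def test_dense_lut_beats_low_lut(dense_lut, low_lut, mc_fwd):
    """Grid refinement dominates: dense-LUT mu_a error is >=10x smaller."""
    test = generate_training_set(20_000, 31, mc_fwd)
    rows = benchmark_methods(
        test,
        {
            "dense": lambda r0, rn: lut_invert(dense_lut, r0, rn),
            "low": lambda r0, rn: lut_invert(low_lut, r0, rn),
        },
    )
    by_name = {r["method"]: r for r in rows}
    assert by_name["dense"]["mu_a_pct"] * 10 <= by_name["low"]["mu_a_pct"]
    assert by_name["dense"]["mu_s_prime_pct"] < by_name["low"]["mu_s_prime_pct"]


def test_model_persistence_round_trip(tmp_path, diffusion_fwd):
    ts = generate_training_set(500, 9, diffusion_fwd)
    model = train_regressor(ts, seed=2)
    assert model.n_estimators == 15
    assert model.min_samples_leaf == 2
    path = tmp_path / "model.joblib"
    model.save(path)
    back = InversionModel.load(path)
    assert back.training_provenance == model.training_provenance
    r0 = np.linspace(0.1, 0.6, 20)
    rn = r0 * 0.3
    np.testing.assert_array_equal(
        predict_properties(back, r0, rn).mu_a,
        predict_properties(model, r0, rn).mu_a,
    )
    joblib.dump({"format_version": 999}, path)
    with pytest.raises(ValueError):
        InversionModel.load(path)
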