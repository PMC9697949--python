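"""Spline-compression tests against independent basis and least-squares oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import thermospline as ts
from thermospline.sensor_model import AnalyteMix, SensorSweep
from thermospline.spline_compress import N_FEATURES, FitError

# ---------------------------------------------------------------------------
# independent oracles


def cox_de_boor(x: float, t: np.ndarray, i: int, k: int) -> float:
    """Textbook Cox-de Boor recursion for basis function B_{i,k} on knots t."""
    if k == 0:
        # half-open intervals, closed at the right edge of the domain
        if t[i] <= x < t[i + 1]:
            return 1.0
        if x == t[-1] and t[i] < t[i + 1] == t[-1]:
            return 1.0
        return 0.0
    left = 0.0
    if t[i + k] > t[i]:
        left = (x - t[i]) / (t[i + k] - t[i]) * cox_de_boor(x, t, i, k - 1)
    right = 0.0
    if t[i + k + 1] > t[i + 1]:
        right = (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * cox_de_boor(x, t, i + 1, k - 1)
    return left + right


def oracle_design(x: np.ndarray, knots: ts.KnotVector, degree: int) -> np.ndarray:
    t = knots.full_knots(degree)
    n_coef = len(t) - degree - 1
    return np.array([[cox_de_boor(xi, t, i, degree) for i in range(n_coef)] for xi in x])


def oracle_lsq_sse(x: np.ndarray, y: np.ndarray, knots: ts.KnotVector, degree: int):
    """Normal-equations solution assembled from the recursion oracle."""
    a = oracle_design(x, knots, degree)
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    r = y - a @ coef
    return coef, float(r @ r)


def _sweep(x: np.ndarray, y: np.ndarray) -> SensorSweep:
    return SensorSweep(heater_v=x, out_v=y, mix=AnalyteMix(0.0, 0.0))


# ---------------------------------------------------------------------------
# basis


def test_basis_partition_of_unity():
    kv = ts.KnotVector(np.array([0.0, 0.7, 1.3, 2.9, 4.1, 5.0]))
    v = np.linspace(0.0, 5.0, 211)
    basis = ts.bspline_basis(v, kv, degree=3)
    assert np.all(basis >= 0)
    np.testing.assert_allclose(basis.sum(axis=1), 1.0, atol=1e-12)


def test_basis_degree_zero_is_interval_indicator():
    kv = ts.KnotVector(np.array([0.0, 1.0, 2.0, 3.0]))
    row = ts.bspline_basis(1.5, kv, degree=0)
    np.testing.assert_array_equal(row, [0.0, 1.0, 0.0])


def test_basis_matches_cox_de_boor_recursion():
    """Cubic basis agrees with an independently coded recursion at 100 points."""
    rng = np.random.default_rng(3)
    kv = ts.KnotVector(np.sort(np.concatenate([[0.0, 5.0], rng.uniform(0.3, 4.7, 6)])))
    v = rng.uniform(0.0, 5.0, 100)
    got = ts.bspline_basis(v, kv, degree=3)
    expected = oracle_design(v, kv, 3)
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_basis_rejects_points_outside_span():
    kv = ts.KnotVector(np.array([0.0, 1.0, 2.0]))
    with pytest.raises(ValueError):
        ts.bspline_basis(2.5, kv, degree=3)


@given(st.floats(0.01, 4.99))
def test_basis_partition_of_unity_property(v):
    kv = ts.KnotVector(np.array([0.0, 1.0, 2.5, 3.0, 5.0]))
    assert ts.bspline_basis(v, kv, degree=3).sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# least-squares fitting


@pytest.mark.parametrize("degree,n_interior", [(1, 0), (2, 3), (3, 4), (3, 10)])
def test_coefficient_count_law(degree, n_interior):
    rng = np.random.default_rng(degree + n_interior)
    x = np.linspace(0, 5, 200)
    y = rng.normal(size=x.size)
    interior = np.linspace(0, 5, n_interior + 2)[1:-1]
    kv = ts.KnotVector(np.concatenate([[0.0], interior, [5.0]]))
    fit = ts.fit_lsq_spline(_sweep(x, y), kv, degree=degree)
    assert fit.model.coefficients.size == n_interior + degree + 1


def test_six_knot_cubic_fit_has_eight_coefficients():
    x = np.linspace(0, 5, 501)
    y = np.sin(x)
    kv = ts.KnotVector(np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0]))
    fit = ts.fit_lsq_spline(_sweep(x, y), kv, degree=3)
    assert fit.model.coefficients.size == N_FEATURES


def test_cubic_data_reproduced_exactly():
    """Cubic splines contain cubics: the residual is numerically zero."""
    x = np.linspace(0, 5, 501)
    y = 0.3 * x**3 - 1.1 * x**2 + 0.5 * x + 2.0
    kv = ts.KnotVector(np.array([0.0, 1.3, 2.6, 3.9, 5.0]))
    fit = ts.fit_lsq_spline(_sweep(x, y), kv, degree=3)
    assert fit.sse < 1e-16


def test_fit_matches_normal_equations_oracle():
    rng = np.random.default_rng(11)
    x = np.sort(rng.uniform(0, 5, 20))
    x[0], x[-1] = 0.0, 5.0
    y = rng.normal(size=20)
    kv = ts.KnotVector(np.array([0.0, 2.3, 5.0]))
    fit = ts.fit_lsq_spline(_sweep(x, y), kv, degree=3)
    coef, sse = oracle_lsq_sse(x, y, kv, 3)
    np.testing.assert_allclose(fit.model.coefficients, coef, atol=1e-9)
    assert fit.sse == pytest.approx(sse, abs=1e-9)


def test_rank_deficient_fit_reports_empty_span():
    x = np.concatenate([np.linspace(0, 1, 30), np.linspace(4, 5, 30)])
    y = np.zeros_like(x)
    kv = ts.KnotVector(np.array([0.0, 1.5, 2.0, 2.5, 3.0, 3.5, 5.0]))
    with pytest.raises(FitError, match="span"):
        ts.fit_lsq_spline(_sweep(x, y), kv, degree=3)


# ---------------------------------------------------------------------------
# initial knots


class TestInitialKnotVector:
    def test_default_gives_51_knots(self):
        kv = ts.initial_knot_vector(0.0, 5.0, 0.1)
        assert len(kv) == 51
        np.testing.assert_allclose(kv.interior, np.arange(1, 50) * 0.1)

    def test_quarter_spacing(self):
        kv = ts.initial_knot_vector(0.0, 1.0, 0.25)
        np.testing.assert_allclose(kv.breakpoints, [0.0, 0.25, 0.5, 0.75, 1.0])

    def test_degenerate_spacing_gives_endpoints_only(self):
        kv = ts.initial_knot_vector(0.0, 5.0, 5.0)
        np.testing.assert_allclose(kv.breakpoints, [0.0, 5.0])


# ---------------------------------------------------------------------------
# greedy knot elimination


@pytest.fixture(scope="module")
def wiggly_sweep():
    x = np.linspace(0, 5, 501)
    y = np.tanh(2 * (x - 1.5)) + 0.8 * np.tanh(4 * (x - 3.2)) + 0.1 * np.sin(3 * x)
    return _sweep(x, y)


def test_elimination_noop_returns_direct_fit(wiggly_sweep):
    kv = ts.initial_knot_vector(0, 5, 0.5)
    direct = ts.fit_lsq_spline(wiggly_sweep, kv)
    fit = ts.eliminate_knots(wiggly_sweep, kv, target_total=len(kv))
    np.testing.assert_array_equal(fit.model.knots.breakpoints, kv.breakpoints)
    np.testing.assert_allclose(fit.model.coefficients, direct.model.coefficients, atol=1e-12)


def test_single_step_matches_exhaustive_oracle(wiggly_sweep):
    """One greedy step drops exactly the argmin over all single-knot refits."""
    kv = ts.initial_knot_vector(0, 5, 0.625)  # 9 knots total
    assert len(kv) == 9
    x, y = wiggly_sweep.heater_v, wiggly_sweep.out_v
    sse = [oracle_lsq_sse(x, y, kv.without(i), 3)[1] for i in range(len(kv) - 2)]
    dropped_oracle = kv.interior[int(np.argmin(sse))]
    fit = ts.eliminate_knots(wiggly_sweep, kv, target_total=8)
    remaining = fit.model.knots.breakpoints
    assert dropped_oracle not in remaining
    assert fit.sse == pytest.approx(min(sse), rel=1e-9)


def test_elimination_path_sse_nondecreasing(wiggly_sweep):
    kv = ts.initial_knot_vector(0, 5, 0.25)
    fit, path = ts.eliminate_knots(wiggly_sweep, kv, target_total=6, return_path=True)
    assert len(path) == len(kv) - 6 + 1
    assert np.all(np.diff(path) >= -1e-12)
    assert fit.sse == pytest.approx(path[-1])


def test_full_elimination_51_to_6_yields_8_features(calibrated_params):
    sweep = ts.simulate_sweep(
        ts.AnalyteMix(0.125, 0.25), params=calibrated_params, noise_sd=0.02, seed=5
    )
    start = ts.initial_knot_vector(0, 5, 0.1)
    assert len(start) == 51
    fit = ts.eliminate_knots(sweep, start, target_total=6)
    assert len(fit.model.knots) == 6
    feats = ts.features(fit)
    assert feats.shape == (N_FEATURES,)


def test_elimination_target_below_two_rejected(wiggly_sweep):
    kv = ts.initial_knot_vector(0, 5, 1.0)
    with pytest.raises(ValueError):
        ts.eliminate_knots(wiggly_sweep, kv, target_total=1)


def test_removing_any_interior_knot_never_decreases_sse(wiggly_sweep):
    """Nested-space monotonicity: the reduced spline space is a subspace."""
    kv = ts.initial_knot_vector(0, 5, 0.625)
    base = ts.fit_lsq_spline(wiggly_sweep, kv).sse
    for i in range(len(kv) - 2):
        reduced = ts.fit_lsq_spline(wiggly_sweep, kv.without(i)).sse
        assert reduced >= base - 1e-12


# ---------------------------------------------------------------------------
# features


def test_constant_data_gives_constant_features():
    x = np.linspace(0, 5, 501)
    fit = ts.eliminate_knots(_sweep(x, np.full_like(x, 2.75)), ts.initial_knot_vector(0, 5, 0.5), 6)
    np.testing.assert_allclose(ts.features(fit), 2.75, atol=1e-9)


def test_features_deterministic(wiggly_sweep):
    kv = ts.KnotVector(np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0]))
    f1 = ts.features(ts.fit_lsq_spline(wiggly_sweep, kv))
    f2 = ts.features(ts.fit_lsq_spline(wiggly_sweep, kv))
    np.testing.assert_array_equal(f1, f2)


def test_features_require_eight_coefficients(wiggly_sweep):
    kv = ts.KnotVector(np.array([0.0, 2.5, 5.0]))
    fit = ts.fit_lsq_spline(wiggly_sweep, kv)
    with pytest.raises(ValueError):
        ts.features(fit)


def test_compression_residual_stays_near_noise_floor(calibrated_params):
    """6-knot fits of noisy sweeps keep the rms residual below 5x the noise sd."""
    noise_sd = 0.02
    start = ts.initial_knot_vector(0, 5, 0.1)
    rng = np.random.default_rng(9)
    for k in range(4):
        mix = ts.AnalyteMix(*rng.choice(ts.concentration_levels(), 2))
        sweep = ts.simulate_sweep(
            mix, params=calibrated_params, noise_sd=noise_sd, seed=100 + k
        )
        fit = ts.eliminate_knots(sweep, start, target_total=6)
        rms = np.sqrt(fit.sse / len(sweep))
        assert rms < 5 * noise_sd


def test_consensus_knots_shared_across_sweeps(calibrated_params):
    sweeps = [
        ts.simulate_sweep(ts.AnalyteMix(c, c), params=calibrated_params)
        for c in (0.03125, 0.5)
    ]
    start = ts.initial_knot_vector(0, 5, 0.5)
    kv = ts.consensus_knots(sweeps, start, target_total=6)
    assert len(kv) == 6
    for s in sweeps:
        fit = ts.fit_lsq_spline(s, kv)
        assert ts.features(fit).shape == (N_FEATURES,)
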