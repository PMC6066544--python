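"""Logistic-fitting core: standardization, MLE correctness, prediction,
latent-axis geometry, separation and collinearity diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import phaseaudit as pa
from phaseaudit.lr import _irls

from conftest import make_table


# ---------------------------------------------------------------------------
# standardization


def test_standardize_maps_123_to_unit_scale():
    t = make_table(np.array([[1.0], [2.0], [3.0]]), [0, 1, 1])
    spec = pa.LRModelSpec(predictors=("v0",), event_level="greg")
    out, scaler = pa.standardize_predictors(t, spec)
    np.testing.assert_allclose(out.data["v0"].to_numpy(), [-1.0, 0.0, 1.0])
    assert scaler.means["v0"] == 2.0 and scaler.sds["v0"] == 1.0


def test_standardize_is_idempotent_and_unitizes_extreme_scales(rng):
    # scales spanning 2e-4 to 2e4 must come out with mean 0, sample SD 1
    for scale in (2e-4, 1.0, 2e4):
        x = rng.normal(5.0, 2.0, size=50) * scale
        t = make_table(x[:, None], rng.integers(0, 2, 50))
        spec = pa.LRModelSpec(predictors=("v0",), event_level="greg")
        once, _ = pa.standardize_predictors(t, spec)
        twice, _ = pa.standardize_predictors(once, spec)
        assert np.isclose(once.data["v0"].mean(), 0.0, atol=1e-12)
        assert np.isclose(once.data["v0"].std(ddof=1), 1.0)
        np.testing.assert_allclose(
            once.data["v0"].to_numpy(), twice.data["v0"].to_numpy(), atol=1e-12
        )


def test_standardize_zero_variance_raises_with_column_name():
    t = make_table(np.ones((10, 1)), [0, 1] * 5)
    spec = pa.LRModelSpec(predictors=("v0",), event_level="greg")
    with pytest.raises(pa.ZeroVariancePredictorError, match="v0"):
        pa.standardize_predictors(t, spec)


# ---------------------------------------------------------------------------
# fitting


def test_intercept_only_balanced_outcome_gives_logit_half():
    # IRLS engine directly: a lone intercept on 5 events / 5 non-events
    X = np.ones((10, 1))
    y = np.array([1.0] * 5 + [0.0] * 5)
    beta, mu, converged, _, _ = _irls(X, y)
    assert converged
    assert abs(beta[0]) < 1e-10
    np.testing.assert_allclose(mu, 0.5, atol=1e-10)


def test_saturated_binary_predictor_equals_log_odds_ratio():
    # x=0: 2 events / 8 non-events; x=1: 7 events / 3 non-events
    x = np.array([0.0] * 10 + [1.0] * 10)
    y = np.array([1] * 2 + [0] * 8 + [1] * 7 + [0] * 3)
    t = make_table(x[:, None], y)
    fit = pa.fit_logistic(t, pa.LRModelSpec(predictors=("v0",), event_level="greg"))
    b0_expected = np.log(2 / 8)
    b1_expected = np.log((7 / 3) / (2 / 8))
    np.testing.assert_allclose(fit.coefficients["(Intercept)"], b0_expected, atol=1e-8)
    np.testing.assert_allclose(fit.coefficients["v0"], b1_expected, atol=1e-8)
    # brute-force likelihood grid confirms this is the maximizer
    b0s = b0_expected + np.linspace(-0.5, 0.5, 21)
    b1s = b1_expected + np.linspace(-0.5, 0.5, 21)
    best = -np.inf
    for b0 in b0s:
        for b1 in b1s:
            mu = expit(b0 + b1 * x)
            ll = np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
            best = max(best, ll)
    assert fit.loglik >= best - 1e-9


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_irls_agrees_with_derivative_free_maximization(seed):
    """On non-separated data the IRLS optimum matches a Nelder-Mead
    maximization of the likelihood to <= 1e-4 per coefficient."""
    rng = np.random.default_rng(seed)
    n, p = 150, 3
    X = rng.normal(size=(n, p))
    eta = 0.3 + X @ np.array([0.8, -0.5, 0.2])
    y = (rng.uniform(size=n) < expit(eta)).astype(float)
    t = make_table(X, y)
    fit = pa.fit_logistic(
        t, pa.LRModelSpec(predictors=("v0", "v1", "v2"), event_level="greg")
    )
    assert not fit.separation.flagged

    Xd = np.column_stack([np.ones(n), X])

    def negll(b):
        mu = np.clip(expit(Xd @ b), 1e-12, 1 - 1e-12)
        return -np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))

    res = minimize(negll, np.zeros(p + 1), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000})
    np.testing.assert_allclose(fit.coefficients.to_numpy(), res.x, atol=1e-4)


def test_irls_matches_statsmodels_coefficients_and_ses(rng):
    sm = pytest.importorskip("statsmodels.api")
    n, p = 200, 4
    X = rng.normal(size=(n, p))
    y = (rng.uniform(size=n) < expit(0.2 + X @ np.array([1.0, -0.7, 0.4, 0.0]))).astype(float)
    t = make_table(X, y)
    fit = pa.fit_logistic(
        t, pa.LRModelSpec(predictors=tuple(f"v{i}" for i in range(p)), event_level="greg")
    )
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    np.testing.assert_allclose(fit.coefficients.to_numpy(), ref.params, atol=1e-5)
    np.testing.assert_allclose(fit.standard_errors.to_numpy(), ref.bse, rtol=1e-4)
    np.testing.assert_allclose(fit.loglik, ref.llf, atol=1e-6)


def test_single_class_outcome_raises():
    t = make_table(np.arange(6.0)[:, None], [1] * 6)
    with pytest.raises(pa.PhenotypeError):
        pa.fit_logistic(t, pa.LRModelSpec(predictors=("v0",), event_level="greg"))


def test_rank_deficient_design_names_later_aliased_term(rng):
    x = rng.normal(size=20)
    t = make_table(np.column_stack([x, 2.0 * x]), rng.integers(0, 2, 20))
    with pytest.raises(pa.RankDeficientDesignError) as exc:
        pa.fit_logistic(t, pa.LRModelSpec(predictors=("v0", "v1"), event_level="greg"))
    assert exc.value.aliased == ["v1"]


def test_default_event_level_is_alphabetically_last(rng):
    X = rng.normal(size=(30, 1))
    t = make_table(X, rng.integers(0, 2, 30), event="greg", nonevent="sol")
    fit = pa.fit_logistic(t, pa.LRModelSpec(predictors=("v0",)))
    assert fit.event_level == "sol"  # 'sol' sorts after 'greg'


# ---------------------------------------------------------------------------
# prediction


def test_predict_reproduces_fitted_probabilities_bitwise(rng):
    X = rng.normal(size=(80, 2))
    y = (rng.uniform(size=80) < expit(X[:, 0])).astype(float)
    t = make_table(X, y)
    for standardize in (False, True):
        spec = pa.LRModelSpec(
            predictors=("v0", "v1"), event_level="greg", standardize=standardize
        )
        fit = pa.fit_logistic(t, spec)
        pred = pa.predict_prob(fit, t)
        assert np.array_equal(pred, fit.fitted_probabilities)


def test_zero_coefficients_predict_one_half(rng):
    X = rng.normal(size=(20, 2))
    t = make_table(X, rng.integers(0, 2, 20))
    fit = pa.fit_logistic(t, pa.LRModelSpec(predictors=("v0", "v1"), event_level="greg"))
    fit.coefficients[:] = 0.0
    np.testing.assert_allclose(pa.predict_prob(fit, t), 0.5)


def test_point_on_decision_line_predicts_one_half(rng):
    X = rng.normal(size=(60, 2))
    y = (rng.uniform(size=60) < expit(X[:, 0] - X[:, 1])).astype(float)
    t = make_table(X, y)
    fit = pa.fit_logistic(t, pa.LRModelSpec(predictors=("v0", "v1"), event_level="greg"))
    b0, b1, b2 = fit.coefficients.to_numpy()
    # construct a phenotype with linear predictor exactly 0
    x1 = 0.7
    x2 = -(b0 + b1 * x1) / b2
    probe = make_table(np.array([[x1, x2], [0.0, -b0 / b2]]), [0, 1])
    np.testing.assert_allclose(pa.predict_prob(fit, probe), 0.5, atol=1e-12)


def test_predict_missing_column_raises(rng):
    X = rng.normal(size=(30, 2))
    y = rng.integers(0, 2, 30)
    t = make_table(X, y)
    fit = pa.fit_logistic(t, pa.LRModelSpec(predictors=("v0", "v1"), event_level="greg"))
    other = make_table(X[:, :1], y)
    with pytest.raises(pa.PhenotypeError):
        pa.predict_prob(fit, other)


def test_standardization_rescales_coefficients_but_not_probabilities(rng):
    X = rng.normal(loc=[10.0, -3.0], scale=[4.0, 0.2], size=(120, 2))
    y = (rng.uniform(size=120) < expit((X[:, 0] - 10) / 4)).astype(float)
    t = make_table(X, y)
    raw = pa.fit_logistic(t, pa.LRModelSpec(predictors=("v0", "v1"), event_level="greg"))
    std = pa.fit_logistic(
        t, pa.LRModelSpec(predictors=("v0", "v1"), event_level="greg", standardize=True)
    )
    np.testing.assert_allclose(
        std.fitted_probabilities, raw.fitted_probabilities, atol=1e-7
    )
    back = std.coefficients_raw_scale()
    np.testing.assert_allclose(back.to_numpy(), raw.coefficients.to_numpy(), atol=1e-6)
    for v in ("v0", "v1"):
        np.testing.assert_allclose(
            std.coefficients[v], raw.coefficients[v] * std.scaler.sds[v], atol=1e-6
        )


# ---------------------------------------------------------------------------
# latent-axis geometry


def test_latent_axis_slope_is_coefficient_ratio(rng):
    X = rng.normal(size=(100, 2))
    y = (rng.uniform(size=100) < expit(X[:, 0] + X[:, 1])).astype(float)
    t = make_table(X, y)
    fit = pa.fit_logistic(t, pa.LRModelSpec(predictors=("v0", "v1"), event_level="greg"))
    slope = pa.latent_axis_slope(fit, "v0", "v1")
    assert np.isclose(slope, fit.coefficients["v1"] / fit.coefficients["v0"])
    # unit coefficients give slope 1
    fit.coefficients["v0"] = 1.0
    fit.coefficients["v1"] = 1.0
    assert pa.latent_axis_slope(fit, "v0", "v1") == 1.0
    # iso-probability direction is orthogonal to the latent direction
    dx, dy = pa.iso_probability_direction(fit, "v0", "v1")
    assert abs(dx * fit.coefficients["v0"] + dy * fit.coefficients["v1"]) < 1e-12
    fit.coefficients["v0"] = 0.0
    with pytest.raises(ZeroDivisionError):
        pa.latent_axis_slope(fit, "v0", "v1")


# ---------------------------------------------------------------------------
# separation


def test_threshold_separated_data_flagged_complete():
    x = np.array([-2.0, -1.0, 1.0, 2.0])
    t = make_table(x[:, None], [0, 0, 1, 1])
    fit = pa.fit_logistic(t, pa.LRModelSpec(predictors=("v0",), event_level="greg"))
    assert fit.separation.flagged
    assert fit.separation.kind == "complete"
    rep = pa.detect_separation(fit, t)
    assert rep.kind == "complete"


def test_overlapping_classes_not_flagged(rng):
    x = np.concatenate([rng.normal(0, 1, 100), rng.normal(1, 1, 100)])
    y = np.array([0] * 100 + [1] * 100)
    t = make_table(x[:, None], y)
    fit = pa.fit_logistic(t, pa.LRModelSpec(predictors=("v0",), event_level="greg"))
    assert fit.converged
    assert not fit.separation.flagged
    assert pa.separating_hyperplane_exists(
        np.column_stack([np.ones(200), x]), y.astype(float)
    ) == "none"


def _brute_force_separable_1d(x, y):
    """Independent oracle: in 1D a separating threshold exists iff the two
    classes' supports do not interleave (strictly)."""
    a, b = x[y == 1], x[y == 0]
    return a.min() > b.max() or a.max() < b.min()


def _brute_force_separable_2d(X, y):
    """Independent oracle: test all lines through pairs of points, nudged to
    each side, plus axis-aligned thresholds."""
    n = len(y)
    cands = []
    for i in range(n):
        for j in range(i + 1, n):
            d = X[j] - X[i]
            nrm = np.array([-d[1], d[0]])
            if np.linalg.norm(nrm) == 0:
                continue
            for eps in (-1e-7, 1e-7):
                w = nrm
                c = -w @ X[i] + eps
                cands.append((w, c))
    for k in range(2):
        for thr in np.unique(X[:, k]):
            w = np.zeros(2)
            w[k] = 1.0
            for eps in (-1e-7, 1e-7):
                cands.append((w, -thr + eps))
    for w, c in cands:
        s = X @ w + c
        if np.all(s[y == 1] > 0) and np.all(s[y == 0] < 0):
            return True
        if np.all(s[y == 1] < 0) and np.all(s[y == 0] > 0):
            return True
    return False


@pytest.mark.parametrize("p", [1, 2])
def test_separation_detector_matches_brute_force_oracle(p):
    """detect_separation agrees with an exhaustive geometric separability
    check on random small instances (both separable and not)."""
    rng = np.random.default_rng(99)
    n_checked = 0
    for trial in range(60):
        n = int(rng.integers(8, 16))
        gap = rng.choice([0.0, 2.5])  # mixes overlapping and separable designs
        X = rng.normal(size=(n, p))
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            continue
        X[y == 1] += gap
        oracle = (
            _brute_force_separable_1d(X[:, 0], y)
            if p == 1
            else _brute_force_separable_2d(X, y)
        )
        t = make_table(X, y)
        fit = pa.fit_logistic(
            t, pa.LRModelSpec(predictors=tuple(f"v{i}" for i in range(p)), event_level="greg")
        )
        rep = pa.detect_separation(fit, t)
        if oracle:
            assert rep.flagged and rep.kind == "complete"
        elif fit.converged:
            assert not rep.flagged
        n_checked += 1
    assert n_checked >= 40


# ---------------------------------------------------------------------------
# collinearity / redundancy


def test_duplicated_column_flagged_at_r_one(rng):
    x = rng.normal(size=50)
    t = make_table(np.column_stack([x, x.copy(), rng.normal(size=50)]),
                   rng.integers(0, 2, 50))
    rep = pa.collinearity_screen(
        t, pa.LRModelSpec(predictors=("v0", "v1", "v2"), event_level="greg"),
        threshold=0.99,
    )
    assert ("v0", "v1", pytest.approx(1.0)) in [
        (a, b, r) for a, b, r in rep.flagged_pairs
    ]


def test_independent_columns_not_flagged(rng):
    X = rng.normal(size=(1000, 2))
    t = make_table(X, rng.integers(0, 2, 1000))
    rep = pa.collinearity_screen(
        t, pa.LRModelSpec(predictors=("v0", "v1"), event_level="greg"), threshold=0.99
    )
    assert rep.flagged_pairs == []


def test_sign_encoding_redundancy_detected(rng):
    x = rng.normal(size=80)
    x[x == 0] = 0.1
    choice = np.where(x > 0, 1.0, -1.0)
    t = make_table(np.column_stack([x, choice]), rng.integers(0, 2, 80))
    rep = pa.collinearity_screen(
        t, pa.LRModelSpec(predictors=("v0", "v1"), event_level="greg")
    )
    assert ("v1", "v0") in rep.sign_redundant_pairs
    assert "signs" in rep.advice
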