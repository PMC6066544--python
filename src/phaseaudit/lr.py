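"""Binary logistic regression with fit-pathology diagnostics.

Maximum-likelihood fitting is by iteratively reweighted least squares
(IRLS) with an explicit per-iteration trace, because the diagnostics this
package exists for — complete and quasi-separation, divergence, collinearity
blow-ups — live in *how* the fit behaves, not just in the final estimate.
A non-convergent fit is returned (with ``converged=False`` and a populated
:class:`SeparationReport`) rather than raised: a failed fit is a result that
downstream audits must see.

Separation detection combines three signals:

1. the fraction of fitted probabilities numerically at 0 or 1;
2. monotone growth of the coefficient norm over the last IRLS iterations;
3. for small problems, an exact linear-program feasibility test for a
   separating hyperplane (the decisive oracle where it runs).

The central failure mode this guards against is reading a separated fit as
"100% accurate": when a linear combination of predictors perfectly splits
the two phases, the MLE does not exist and the fitted probabilities of 0/1
are a symptom of estimation failure, not of predictive power.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.special import expit

from .phenotypes import PhenotypeError, PhenotypeTable

logger = logging.getLogger(__name__)

INTERCEPT = "(Intercept)"

#: fitted probability within this distance of 0/1 counts as numerically extreme
SEPARATION_EPS = 1e-8
#: exact separating-hyperplane LP is run only below these sizes (cost control)
LP_MAX_N = 500
LP_MAX_P = 15

SIGN_CONSISTENCY_ADVICE = (
    "Examine whether the directions (signs) of the estimated coefficients are "
    "consistent both internally and with prior subject knowledge; where they "
    "are not, the model may be ill-specified."
)


class RankDeficientDesignError(PhenotypeError):
    """Design matrix is rank deficient; carries the aliased term names."""

    def __init__(self, aliased: Sequence[str]):
        self.aliased = list(aliased)
        super().__init__(
            "rank-deficient design; aliased terms (later-listed terms are "
            f"dropped first): {self.aliased}"
        )


class ZeroVariancePredictorError(PhenotypeError):
    """A predictor has zero sample standard deviation."""


class SingleClassOutcomeError(PhenotypeError):
    """The outcome column has a single level after filtering."""


@dataclass(frozen=True)
class LRModelSpec:
    """Predictor selection for a binary logistic model.

    ``event_level`` names which environment level is modeled as the event
    (probability-one end).  If ``None``, the alphabetically last level is
    used and a warning is logged.
    ``interactions`` is a list of (factor_column, trait) pairs; each adds
    dummy-coded factor main effects (once) plus factor x trait products.
    """

    predictors: tuple[str, ...]
    event_level: str | None = None
    interactions: tuple[tuple[str, str], ...] = ()
    standardize: bool = False

    def __post_init__(self) -> None:
        if not self.predictors:
            raise PhenotypeError("model spec needs at least one predictor")
        if len(set(self.predictors)) != len(self.predictors):
            raise PhenotypeError("duplicate predictor names in model spec")


@dataclass(frozen=True)
class Scaler:
    """Means/SDs used to standardize predictors; kept so coefficients can be
    mapped back to the raw scale (beta_raw = beta_std / sd)."""

    means: dict[str, float]
    sds: dict[str, float]

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        out = data.copy()
        for c, m in self.means.items():
            out[c] = (out[c] - m) / self.sds[c]
        return out


@dataclass
class SeparationReport:
    flagged: bool
    kind: str  # none | complete | quasi | nonconvergence
    extreme_fraction: float
    diverging_terms: list[str] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        assert self.flagged == (self.kind != "none")

    def to_dict(self) -> dict:
        return {
            "flagged": self.flagged,
            "kind": self.kind,
            "extreme_fraction": self.extreme_fraction,
            "diverging_terms": list(self.diverging_terms),
            "note": self.note,
        }


@dataclass
class LRFit:
    """A fitted (or failed) binary logistic regression."""

    spec: LRModelSpec
    term_names: list[str]
    coefficients: pd.Series
    standard_errors: pd.Series
    vcov: pd.DataFrame
    loglik: float
    deviance: float
    converged: bool
    n_iterations: int
    fitted_probabilities: np.ndarray
    separation: SeparationReport
    n_event: int
    n_nonevent: int
    event_level: str
    nonevent_level: str
    scaler: Scaler | None
    coef_history: np.ndarray  # iterations x terms
    n_dropped: int = 0

    @property
    def k(self) -> int:
        """Number of non-intercept coefficients."""
        return len(self.term_names) - 1

    @property
    def epv(self) -> float:
        """Events per variable: limiting group size over non-intercept terms."""
        return min(self.n_event, self.n_nonevent) / self.k if self.k else np.inf

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.term_names)

    def coefficients_raw_scale(self) -> pd.Series:
        """Coefficients mapped back to the unstandardized predictor scale."""
        if self.scaler is None:
            return self.coefficients.copy()
        beta = self.coefficients.copy()
        shift = 0.0
        for name in self.term_names:
            if name in self.scaler.sds:
                beta[name] = beta[name] / self.scaler.sds[name]
                shift += beta[name] * self.scaler.means[name]
        beta[INTERCEPT] = beta[INTERCEPT] - shift
        return beta

    def to_dict(self) -> dict:
        return {
            "terms": list(self.term_names),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "standard_errors": {k: float(v) for k, v in self.standard_errors.items()},
            "vcov": [[float(v) for v in row] for row in self.vcov.to_numpy()],
            "loglik": float(self.loglik),
            "deviance": float(self.deviance),
            "aic": float(self.aic),
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "n_event": self.n_event,
            "n_nonevent": self.n_nonevent,
            "event_level": self.event_level,
            "nonevent_level": self.nonevent_level,
            "epv": float(self.epv),
            "n_dropped": self.n_dropped,
            "separation": self.separation.to_dict(),
        }


# ---------------------------------------------------------------------------
# standardization


def standardize_predictors(
    table: PhenotypeTable, spec: LRModelSpec
) -> tuple[PhenotypeTable, Scaler]:
    """Means-center and scale each predictor to sample SD 1 (n-1 denominator).

    Returns the transformed table and the :class:`Scaler` holding the
    constants, so coefficients can be reported on either scale.  Raises
    :class:`ZeroVariancePredictorError` naming any constant column.
    """
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for name in spec.predictors:
        if name not in table.data.columns:
            raise PhenotypeError(f"predictor column {name!r} not in table")
        x = table.data[name].to_numpy(dtype=float)
        sd = float(np.std(x, ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise ZeroVariancePredictorError(
                f"predictor {name!r} has zero sample variance; cannot standardize"
            )
        means[name] = float(np.mean(x))
        sds[name] = sd
    scaler = Scaler(means=means, sds=sds)
    data = scaler.transform(table.data)
    out = PhenotypeTable(
        data=data,
        environment=table.environment,
        trait_meta=dict(table.trait_meta),
        strain=table.strain,
        stadium=table.stadium,
    )
    return out, scaler


# ---------------------------------------------------------------------------
# design matrix


def _encode_outcome(table: PhenotypeTable, spec: LRModelSpec) -> tuple[np.ndarray, str, str]:
    lo, hi = table.require_binary_environment()
    if spec.event_level is None:
        event = hi
        logger.warning(
            "no event level named; using alphabetically last level %r as the event",
            event,
        )
    else:
        if str(spec.event_level) not in (lo, hi):
            raise PhenotypeError(
                f"event level {spec.event_level!r} not among outcome levels {[lo, hi]}"
            )
        event = str(spec.event_level)
    nonevent = lo if event == hi else hi
    y = (table.data[table.environment].astype(str) == event).to_numpy(dtype=float)
    return y, event, nonevent


def build_design(
    table: PhenotypeTable, spec: LRModelSpec, scaler: Scaler | None = None
) -> tuple[np.ndarray, list[str], Scaler | None]:
    """Assemble intercept + predictors (+ dummy-coded interactions).

    If ``spec.standardize`` and no scaler is passed, scaling constants are
    estimated from ``table``; a passed scaler is applied as-is (prediction on
    new data must reuse the fit-time constants).
    """
    data = table.data
    for name in spec.predictors:
        if name not in data.columns:
            raise PhenotypeError(f"predictor column {name!r} not in table")
    if spec.standardize:
        if scaler is None:
            _, scaler = standardize_predictors(table, spec)
        data = scaler.transform(data)

    cols: list[np.ndarray] = [np.ones(len(data))]
    names: list[str] = [INTERCEPT]
    for name in spec.predictors:
        cols.append(data[name].to_numpy(dtype=float))
        names.append(name)

    factors_added: set[str] = set()
    for factor, trait in spec.interactions:
        if factor not in data.columns:
            raise PhenotypeError(f"interaction factor column {factor!r} not in table")
        if trait not in data.columns:
            raise PhenotypeError(f"interaction trait column {trait!r} not in table")
        levels = sorted(pd.unique(data[factor].astype(str)))
        if len(levels) < 2:
            raise PhenotypeError(f"interaction factor {factor!r} has < 2 levels")
        for lev in levels[1:]:  # treatment coding, first level is reference
            dummy = (data[factor].astype(str) == lev).to_numpy(dtype=float)
            if factor not in factors_added:
                cols.append(dummy)
                names.append(f"{factor}[{lev}]")
            cols.append(dummy * data[trait].to_numpy(dtype=float))
            names.append(f"{factor}[{lev}]:{trait}")
        factors_added.add(factor)

    X = np.column_stack(cols)
    return X, names, scaler


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    """Greedy rank check in column order; later-listed aliased terms raise."""
    n, p = X.shape
    kept: list[int] = []
    aliased: list[str] = []
    for j in range(p):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            aliased.append(names[j])
    if aliased:
        raise RankDeficientDesignError(aliased)


# ---------------------------------------------------------------------------
# IRLS


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-300, 1 - 1e-16)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, bool, int, np.ndarray]:
    """IRLS for the binomial-logit GLM.

    Returns (beta, fitted_mu, converged, n_iter, coef_history).
    Convergence: relative deviance change below ``tol``.  On numerical
    breakdown or iteration exhaustion the last iterate is returned with
    ``converged=False`` — callers decide what a failed fit means.
    """
    n, p = X.shape
    beta = np.zeros(p)
    history = [beta.copy()]
    dev_old = _deviance(y, np.full(n, 0.5))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        try:
            beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(beta_new)):
            break
        beta = beta_new
        history.append(beta.copy())
        dev = _deviance(y, expit(X @ beta))
        if abs(dev_old - dev) / (abs(dev) + 0.1) < tol:
            converged = True
            dev_old = dev
            break
        dev_old = dev
    return beta, expit(X @ beta), converged, it, np.asarray(history)


# ---------------------------------------------------------------------------
# separation


def separating_hyperplane_exists(X: np.ndarray, y: np.ndarray) -> str:
    """Exact LP feasibility test for separation on design ``X`` (with
    intercept column) and 0/1 outcome ``y``.

    Returns ``"complete"`` if some direction w satisfies s_i * (w.x_i) >= 1
    for all i (s_i = +/-1 by class), ``"quasi"`` if only the weak version
    with at least one strict inequality is attainable, else ``"none"``.
    """
    s = np.where(y > 0.5, 1.0, -1.0)
    A = -(s[:, None] * X)  # A w <= -1  <=>  s_i w.x_i >= 1
    n, p = X.shape
    res = linprog(
        c=np.zeros(p),
        A_ub=A,
        b_ub=-np.ones(n),
        bounds=[(None, None)] * p,
        method="highs",
    )
    if res.status == 0:
        return "complete"
    # quasi: maximize total margin subject to all margins in [0, 1]
    res2 = linprog(
        c=-(s[:, None] * X).sum(axis=0),
        A_ub=np.vstack([A, -A]),
        b_ub=np.concatenate([np.zeros(n), np.ones(n)]),
        bounds=[(-1e6, 1e6)] * p,
        method="highs",
    )
    if res2.status == 0 and -res2.fun > 1e-7:
        return "quasi"
    return "none"


def _assess_separation(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    mu: np.ndarray,
    converged: bool,
    coef_history: np.ndarray,
    eps: float = SEPARATION_EPS,
    run_exact: bool | None = None,
) -> SeparationReport:
    extreme = (mu <= eps) | (mu >= 1.0 - eps)
    extreme_fraction = float(np.mean(extreme))

    # coefficient-norm divergence over the last iterations of the IRLS trace
    norms = np.linalg.norm(coef_history, axis=1)
    tail = norms[-min(10, len(norms)) :]
    diverging = len(tail) >= 3 and bool(np.all(np.diff(tail) > 0)) and tail[-1] > 10
    diverging_terms: list[str] = []
    if len(coef_history) >= 2 and diverging:
        growth = np.abs(coef_history[-1]) - np.abs(coef_history[max(0, len(coef_history) - 10)])
        diverging_terms = [n for n, g in zip(names, growth) if g > 1.0]

    n, p = X.shape
    if run_exact is None:
        heuristic_hit = extreme_fraction > 0 or not converged
        run_exact = heuristic_hit and n <= LP_MAX_N and p <= LP_MAX_P

    if run_exact:
        verdict = separating_hyperplane_exists(X, y)
        if verdict == "complete":
            return SeparationReport(
                True,
                "complete",
                extreme_fraction,
                diverging_terms,
                note=(
                    "A separating hyperplane exists: the MLE does not exist and "
                    "fitted probabilities of 0/1 reflect estimation failure, not "
                    "perfect predictive accuracy."
                ),
            )
        if verdict == "quasi":
            return SeparationReport(
                True,
                "quasi",
                extreme_fraction,
                diverging_terms,
                note="Quasi-separation: some observations lie exactly on a splitting hyperplane.",
            )
        if not converged:
            return SeparationReport(
                True,
                "nonconvergence",
                extreme_fraction,
                diverging_terms,
                note="IRLS did not converge; no separating hyperplane was found.",
            )
        return SeparationReport(False, "none", extreme_fraction)

    # heuristic-only path (large problems)
    if extreme_fraction >= 1.0 - 1e-12 and (diverging or not converged):
        return SeparationReport(
            True,
            "complete",
            extreme_fraction,
            diverging_terms,
            note="All fitted probabilities numerically 0/1 with diverging coefficients.",
        )
    if extreme_fraction > 0 and (diverging or not converged):
        return SeparationReport(True, "quasi", extreme_fraction, diverging_terms)
    if not converged:
        return SeparationReport(True, "nonconvergence", extreme_fraction, diverging_terms)
    return SeparationReport(False, "none", extreme_fraction)


def detect_separation(fit: LRFit, table: PhenotypeTable) -> SeparationReport:
    """Re-assess separation for ``fit`` on ``table`` (exact check when small)."""
    work, _ = table.complete_cases(
        [table.environment, *fit.spec.predictors, *[f for f, _ in fit.spec.interactions]]
    )
    X, names, _ = build_design(work, fit.spec, scaler=fit.scaler)
    y, _, _ = _encode_outcome(work, fit.spec)
    eta = X @ fit.coefficients.to_numpy()
    run_exact = len(y) <= LP_MAX_N and X.shape[1] <= LP_MAX_P
    return _assess_separation(
        X, y, names, expit(eta), fit.converged, fit.coef_history, run_exact=run_exact
    )


# ---------------------------------------------------------------------------
# fitting / prediction


def fit_logistic(
    table: PhenotypeTable,
    spec: LRModelSpec,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LRFit:
    """Fit a binary logistic regression by IRLS.

    Non-convergence and separation do not raise: the returned :class:`LRFit`
    carries ``converged`` and a :class:`SeparationReport`.  Rank-deficient
    designs and single-class outcomes do raise.
    """
    used = [table.environment, *spec.predictors, *{f for f, _ in spec.interactions}]
    work, n_dropped = table.complete_cases(used)
    if n_dropped:
        logger.info("complete-case filtering dropped %d row(s)", n_dropped)

    y, event, nonevent = _encode_outcome(work, spec)
    n_event = int(y.sum())
    n_nonevent = int(len(y) - n_event)
    if n_event == 0 or n_nonevent == 0:
        raise SingleClassOutcomeError(
            f"outcome has a single class after filtering (events={n_event}, "
            f"non-events={n_nonevent})"
        )

    X, names, scaler = build_design(work, spec)
    if len(y) <= X.shape[1]:
        raise PhenotypeError(
            f"n rows ({len(y)}) must exceed number of coefficients ({X.shape[1]})"
        )
    _check_rank(X, names)

    beta, mu, converged, n_iter, history = _irls(X, y, tol=tol, max_iter=max_iter)

    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = X.T @ (X * w[:, None])
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))

    mu_c = np.clip(mu, 1e-300, 1 - 1e-16)
    loglik = float(np.sum(y * np.log(mu_c) + (1 - y) * np.log(1 - mu_c)))
    separation = _assess_separation(X, y, names, mu, converged, history)

    return LRFit(
        spec=spec,
        term_names=names,
        coefficients=pd.Series(beta, index=names),
        standard_errors=pd.Series(se, index=names),
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        loglik=loglik,
        deviance=_deviance(y, mu),
        converged=converged,
        n_iterations=n_iter,
        fitted_probabilities=mu,
        separation=separation,
        n_event=n_event,
        n_nonevent=n_nonevent,
        event_level=event,
        nonevent_level=nonevent,
        scaler=scaler,
        coef_history=history,
        n_dropped=n_dropped,
    )


def linear_predictor(fit: LRFit, table: PhenotypeTable) -> np.ndarray:
    """Evaluate the fitted linear predictor on ``table`` (fit-time scaling)."""
    X, _, _ = build_design(table, fit.spec, scaler=fit.scaler)
    return X @ fit.coefficients.to_numpy()


def predict_prob(fit: LRFit, table: PhenotypeTable) -> np.ndarray:
    """Predicted event probabilities on ``table``.

    Uses the standardization constants retained from fit time.  If the fit
    was separated, probabilities pinned at 0/1 are reported with a warning —
    they are a symptom of the failed fit, not of accuracy.
    """
    eta = linear_predictor(fit, table)
    p = expit(eta)
    if fit.separation.flagged and np.any((p <= SEPARATION_EPS) | (p >= 1 - SEPARATION_EPS)):
        warnings.warn(
            "predicting from a separated/non-convergent fit: probabilities at "
            "0/1 are clipped outputs of a failed estimation",
            RuntimeWarning,
            stacklevel=2,
        )
    return p


# ---------------------------------------------------------------------------
# latent-axis geometry


def latent_axis_slope(fit: LRFit, i: str, j: str) -> float:
    """Slope over trait ``i`` of the fitted latent axis in the (i, j) plane.

    A two-trait logistic model projects every phenotype onto a single latent
    axis in the direction (beta_i, beta_j); the slope of that axis over
    trait i is beta_j / beta_i.
    """
    for name in (i, j):
        if name not in fit.coefficients.index:
            raise PhenotypeError(f"term {name!r} not in fitted model")
    bi = float(fit.coefficients[i])
    bj = float(fit.coefficients[j])
    if bi == 0.0:
        raise ZeroDivisionError(f"coefficient of {i!r} is zero; latent-axis slope undefined")
    return bj / bi


def iso_probability_direction(fit: LRFit, i: str, j: str) -> tuple[float, float]:
    """Unit direction of constant predicted probability in the (i, j) plane
    (orthogonal to the latent axis)."""
    bi = float(fit.coefficients[i])
    bj = float(fit.coefficients[j])
    v = np.array([-bj, bi])
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ZeroDivisionError("both coefficients are zero; direction undefined")
    v = v / nrm
    return float(v[0]), float(v[1])


# ---------------------------------------------------------------------------
# collinearity / redundancy screen


@dataclass
class CollinearityReport:
    correlations: pd.DataFrame
    threshold: float
    flagged_pairs: list[tuple[str, str, float]]
    sign_redundant_pairs: list[tuple[str, str]]
    advice: str = SIGN_CONSISTENCY_ADVICE

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "flagged_pairs": [
                {"a": a, "b": b, "r": float(r)} for a, b, r in self.flagged_pairs
            ],
            "sign_redundant_pairs": [
                {"encoded": a, "base": b} for a, b in self.sign_redundant_pairs
            ],
            "advice": self.advice,
        }


def _is_sign_encoding(encoded: np.ndarray, base: np.ndarray) -> bool:
    """True if ``encoded`` is a deterministic two-valued function of
    sign(base) (the final-choice / last-coordinate kind of redundancy)."""
    vals = np.unique(encoded)
    if len(vals) != 2:
        return False
    pos = base > 0
    neg = base < 0
    if pos.sum() == 0 or neg.sum() == 0:
        return False
    if np.any(base == 0):
        return False
    pos_vals = np.unique(encoded[pos])
    neg_vals = np.unique(encoded[neg])
    return len(pos_vals) == 1 and len(neg_vals) == 1 and pos_vals[0] != neg_vals[0]


def collinearity_screen(
    table: PhenotypeTable, spec: LRModelSpec, threshold: float = 0.95
) -> CollinearityReport:
    """All pairwise predictor correlations; flags |r| >= threshold and
    sign-encoding redundancies."""
    if len(spec.predictors) < 2:
        raise PhenotypeError("collinearity screen needs at least 2 predictors")
    sub = table.data[list(spec.predictors)].astype(float)
    corr = sub.corr()
    flagged: list[tuple[str, str, float]] = []
    preds = list(spec.predictors)
    for a_i in range(len(preds)):
        for b_i in range(a_i + 1, len(preds)):
            r = float(corr.iloc[a_i, b_i])
            if np.isfinite(r) and abs(r) >= threshold:
                flagged.append((preds[a_i], preds[b_i], r))
    redundant: list[tuple[str, str]] = []
    arrs = {p: sub[p].to_numpy() for p in preds}
    for enc in preds:
        for base in preds:
            if enc == base:
                continue
            if _is_sign_encoding(arrs[enc], arrs[base]):
                redundant.append((enc, base))
    return CollinearityReport(
        correlations=corr,
        threshold=threshold,
        flagged_pairs=flagged,
        sign_redundant_pairs=redundant,
    )
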