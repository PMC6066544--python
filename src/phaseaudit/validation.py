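"""Rank discrimination, calibration, and bootstrap optimism correction.

Apparent (training-sample) performance of a logistic model overstates how
well it will predict new data, severely so at low events-per-variable.  The
standard internal-validation remedy is the optimism bootstrap: refit the
model on resamples, measure how much better each refit looks on its own
resample than on the original data, and subtract that average optimism from
the apparent performance.

Two measures are corrected:

* Somers' Dxy — rank discrimination, (concordant - discordant) over all
  event/non-event pairs; 0 is no predictive power, 1 perfect.  Equals
  2*(c-index - 1/2).
* the calibration line — intercept and slope of a logistic recalibration of
  the outcomes on the model's linear predictor; (0, 1) is ideal on the
  training data by construction, and a corrected slope well below 1 is the
  signature of overfitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .lr import (
    LRFit,
    LRModelSpec,
    PhenotypeError,
    RankDeficientDesignError,
    SingleClassOutcomeError,
    ZeroVariancePredictorError,
    _irls,
    fit_logistic,
    linear_predictor,
)
from .phenotypes import PhenotypeTable


class DegenerateLinearPredictorError(PhenotypeError):
    """Constant linear predictor: calibration slope undefined."""


def somers_dxy(predictions: np.ndarray, outcomes: np.ndarray) -> float:
    """Somers' Dxy of ``predictions`` against binary ``outcomes``.

    Dxy = (C - D) / (C + D + T) over all event/non-event pairs, where tied
    predictions contribute to T.  Computed via midranks (Mann-Whitney U), so
    it is exact and O(n log n); tests check it against brute-force pair
    enumeration.
    """
    pred = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if pred.shape != y.shape:
        raise PhenotypeError("predictions and outcomes must have the same length")
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise SingleClassOutcomeError("both outcome classes required for Somers' Dxy")
    ranks = rankdata(pred)
    u = float(np.sum(ranks[y == 1])) - n1 * (n1 + 1) / 2.0  # C + T/2
    auc = u / (n1 * n0)
    return 2.0 * auc - 1.0


def calibration_line(
    linear_pred: np.ndarray, outcomes: np.ndarray
) -> tuple[float, float]:
    """Intercept and slope of the logistic recalibration of ``outcomes`` on
    ``linear_pred``: logit P(y=1) = a + b * lp.  Ideal (0, 1)."""
    lp = np.asarray(linear_pred, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise PhenotypeError("linear predictor must be finite")
    if np.std(lp) == 0.0:
        raise DegenerateLinearPredictorError(
            "constant linear predictor: calibration slope undefined"
        )
    if len(np.unique(y)) != 2:
        raise SingleClassOutcomeError("both outcome classes required for calibration")
    X = np.column_stack([np.ones_like(lp), lp])
    beta, _, _, _, _ = _irls(X, y)
    return float(beta[0]), float(beta[1])


@dataclass
class ValidationResult:
    """Apparent and bootstrap-bias-corrected discrimination and calibration."""

    dxy_apparent: float
    dxy_corrected: float
    cal_intercept_apparent: float  # exactly 0 by construction
    cal_intercept_corrected: float
    cal_slope_apparent: float  # exactly 1 by construction
    cal_slope_corrected: float
    B_requested: int
    B_failed: int
    failure_reasons: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    optimism_dxy: float = float("nan")

    @property
    def B_successful(self) -> int:
        return self.B_requested - self.B_failed

    @property
    def failure_fraction(self) -> float:
        return self.B_failed / self.B_requested if self.B_requested else 0.0

    def to_dict(self) -> dict:
        return {
            "dxy_apparent": float(self.dxy_apparent),
            "dxy_corrected": float(self.dxy_corrected),
            "cal_intercept_apparent": float(self.cal_intercept_apparent),
            "cal_intercept_corrected": float(self.cal_intercept_corrected),
            "cal_slope_apparent": float(self.cal_slope_apparent),
            "cal_slope_corrected": float(self.cal_slope_corrected),
            "optimism_dxy": float(self.optimism_dxy),
            "B_requested": self.B_requested,
            "B_failed": self.B_failed,
            "failure_fraction": float(self.failure_fraction),
            "failure_reasons": dict(self.failure_reasons),
            "seed": self.seed,
        }


class AllReplicatesFailedError(RuntimeError):
    def __init__(self, reasons: dict[str, int]):
        self.reasons = reasons
        super().__init__(f"every bootstrap replicate failed: {reasons}")


def bootstrap_validate(
    table: PhenotypeTable,
    spec: LRModelSpec,
    B: int = 1000,
    seed: int = 0,
    base_fit: LRFit | None = None,
) -> ValidationResult:
    """Optimism-bootstrap internal validation of a logistic model.

    For each of ``B`` replicates: resample rows with replacement
    (unstratified), refit, and evaluate the replicate model both on its own
    resample (training performance) and on the original table (test
    performance).  Corrected Dxy = apparent - mean(training - test) over
    successful replicates.  Corrected calibration intercept/slope = mean of
    the original-table recalibration coefficients (the apparent values being
    exactly 0 and 1 by construction).

    Replicates whose refit diverges, separates, or hits a singular or
    single-class design are excluded and tallied by reason — the failure
    fraction is itself an informative diagnostic of model instability.

    One integer ``seed`` governs the whole bootstrap; replicate ``b`` uses
    the independent substream ``default_rng([seed, b])``.
    """
    if B < 1:
        raise PhenotypeError("B must be >= 1")
    if B < 50:
        warnings.warn(
            f"B={B} bootstrap replicates is too few for stable corrected indices",
            UserWarning,
            stacklevel=2,
        )
    if base_fit is None:
        base_fit = fit_logistic(table, spec)
    y_orig = (
        table.data[table.environment].astype(str) == base_fit.event_level
    ).to_numpy(dtype=float)
    dxy_apparent = somers_dxy(base_fit.fitted_probabilities, y_orig)

    n = table.n
    optimisms: list[float] = []
    cal_intercepts: list[float] = []
    cal_slopes: list[float] = []
    failures: dict[str, int] = {}

    def _fail(reason: str) -> None:
        failures[reason] = failures.get(reason, 0) + 1

    for b in range(B):
        rng = np.random.default_rng([seed, b])
        idx = rng.integers(0, n, size=n)
        boot = PhenotypeTable(
            data=table.data.iloc[idx].reset_index(drop=True),
            environment=table.environment,
            trait_meta=dict(table.trait_meta),
            strain=table.strain,
            stadium=table.stadium,
        )
        try:
            fit_b = fit_logistic(boot, spec)
        except (RankDeficientDesignError, np.linalg.LinAlgError):
            _fail("singular")
            continue
        except SingleClassOutcomeError:
            _fail("single_class")
            continue
        except ZeroVariancePredictorError:
            _fail("singular")
            continue
        if fit_b.separation.kind in ("complete", "quasi"):
            _fail("separation")
            continue
        if not fit_b.converged:
            _fail("nonconvergence")
            continue
        y_b = (boot.data[boot.environment].astype(str) == fit_b.event_level).to_numpy(
            dtype=float
        )
        dxy_train = somers_dxy(fit_b.fitted_probabilities, y_b)
        lp_orig = linear_predictor(fit_b, table)
        dxy_test = somers_dxy(lp_orig, y_orig)
        try:
            a_b, b_b = calibration_line(lp_orig, y_orig)
        except (DegenerateLinearPredictorError, SingleClassOutcomeError):
            _fail("degenerate_calibration")
            continue
        optimisms.append(dxy_train - dxy_test)
        cal_intercepts.append(a_b)
        cal_slopes.append(b_b)

    n_failed = B - len(optimisms)
    if not optimisms:
        raise AllReplicatesFailedError(failures)

    mean_optimism = float(np.mean(optimisms))
    return ValidationResult(
        dxy_apparent=float(dxy_apparent),
        dxy_corrected=float(dxy_apparent - mean_optimism),
        cal_intercept_apparent=0.0,
        cal_intercept_corrected=float(np.mean(cal_intercepts)),
        cal_slope_apparent=1.0,
        cal_slope_corrected=float(np.mean(cal_slopes)),
        B_requested=B,
        B_failed=n_failed,
        failure_reasons=failures,
        seed=seed,
        optimism_dxy=mean_optimism,
    )
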