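"""Sample-size auditing, strain-generalization comparison, and the
orchestrated model audit.

Events per variable (EPV) — the size of the smaller outcome group divided
by the number of non-intercept coefficients — is the standard heuristic for
how many predictors a binary logistic model can support.  Ten to twenty EPV
is the conventional minimum; below two, fits are unreliable and complete
separation becomes likely.

A fitted model does not transfer across laboratory strains by assumption.
Whether strain can be pooled is itself a modeling question: fit the model
crossed with strain (main effect plus all strain x predictor interactions,
Model 1) against the pooled model (Model 2) and compare by AIC and a
likelihood-ratio test — which in turn requires an adequately powered sample
of both phases in both strains, roughly ``epv_floor * (2k + 2)`` per phase.

:func:`audit_model` runs every check in one pipeline and emits a structured
report with stable warning codes.  Its non-negotiable behavior: a separated
fit is reported as an estimation failure, never as perfect accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy import stats

from .lr import (
    CollinearityReport,
    LRFit,
    LRModelSpec,
    PhenotypeError,
    collinearity_screen,
    fit_logistic,
)
from .phenotypes import PhenotypeTable
from .validation import AllReplicatesFailedError, ValidationResult, bootstrap_validate

logger = logging.getLogger(__name__)

#: stable machine-readable warning codes (catalogue rendered by cli_io)
W_HYBRID_DOMAIN = "W_HYBRID_DOMAIN"
W_DOMAIN_MIX = "W_DOMAIN_MIX"
W_SCOPE_REFUSED = "W_SCOPE_REFUSED"
W_COLLINEARITY = "W_COLLINEARITY"
W_SIGN_REDUNDANT = "W_SIGN_REDUNDANT"
W_EPV_FAIL = "W_EPV_FAIL"
W_EPV_WARN = "W_EPV_WARN"
W_SEPARATION = "W_SEPARATION"
W_NONCONVERGENCE = "W_NONCONVERGENCE"
W_BOOTSTRAP_FAILURES = "W_BOOTSTRAP_FAILURES"
W_VALIDATION_SKIPPED = "W_VALIDATION_SKIPPED"
W_SIGN_OPPOSED = "W_SIGN_OPPOSED"

WARNING_CATALOGUE: dict[str, str] = {
    W_HYBRID_DOMAIN: (
        "Model contains hybrid-domain predictor(s) (behavior divided by a "
        "body-size measure); these carry morphometric information and cannot "
        "be read as purely behavioral."
    ),
    W_DOMAIN_MIX: (
        "Model mixes behavioral (fast-responding) and morphometric "
        "(slow-responding) predictors; for individuals in transition its "
        "prediction conflates two decoupled aspects of phase state."
    ),
    W_SCOPE_REFUSED: (
        "Model was requested as 'non-morphometric' but contains morphometric "
        "or hybrid predictors; the label is refused."
    ),
    W_COLLINEARITY: "Near-collinear predictor pair(s) flagged.",
    W_SIGN_REDUNDANT: (
        "Predictor is a deterministic sign-encoding of another predictor and "
        "is redundant."
    ),
    W_EPV_FAIL: "Events per variable below 2: model fit is unreliable.",
    W_EPV_WARN: "Events per variable below the configured floor: underpowered.",
    W_SEPARATION: (
        "Complete or quasi-separation detected: the maximum-likelihood "
        "estimate does not exist; fitted probabilities of 0/1 indicate a "
        "failed fit, NOT perfect accuracy."
    ),
    W_NONCONVERGENCE: "Model fitting did not converge.",
    W_BOOTSTRAP_FAILURES: "A substantial fraction of bootstrap refits failed.",
    W_VALIDATION_SKIPPED: (
        "Bootstrap validation skipped: the base fit is separated or "
        "non-convergent, so performance indices would be meaningless."
    ),
    W_SIGN_OPPOSED: (
        "Near-collinear predictors carry opposing coefficient signs; the "
        "estimates likely cancel and are not individually interpretable."
    ),
}


@dataclass
class DesignAudit:
    n_event: int
    n_nonevent: int
    k: int
    epv_floor: float = 10.0

    @property
    def limiting_n(self) -> int:
        return min(self.n_event, self.n_nonevent)

    @property
    def epv(self) -> float:
        return self.limiting_n / self.k

    @property
    def verdict(self) -> str:
        if self.epv < 2:
            return "fail"
        if self.epv < self.epv_floor:
            return "warn"
        return "pass"

    def to_dict(self) -> dict:
        return {
            "n_event": self.n_event,
            "n_nonevent": self.n_nonevent,
            "limiting_n": self.limiting_n,
            "k": self.k,
            "epv": float(self.epv),
            "epv_floor": float(self.epv_floor),
            "verdict": self.verdict,
        }


def events_per_variable(
    n_event: int, n_nonevent: int, k: int, epv_floor: float = 10.0
) -> DesignAudit:
    """EPV audit: min(n_event, n_nonevent) / k with a pass/warn/fail verdict.

    Verdict is ``fail`` below 2 EPV, ``warn`` below ``epv_floor`` (default
    10, the low end of the conventional 10–20 minimum), else ``pass``.
    """
    if k <= 0:
        raise PhenotypeError("k (non-intercept coefficients) must be positive")
    if n_event <= 0 or n_nonevent <= 0:
        raise PhenotypeError("both outcome groups must be non-empty")
    return DesignAudit(n_event=n_event, n_nonevent=n_nonevent, k=k, epv_floor=epv_floor)


def min_sample_size(
    k: int, with_strain_interactions: bool = False, epv_floor: float = 15.0
) -> int:
    """Rule-of-thumb minimum individuals of EACH phase for k predictors.

    A single-strain model estimates k+1 coefficients, needing about
    ``epv_floor * (k + 1)`` of each phase; the strain-crossed model (two
    strains) estimates 2k+2, needing ``epv_floor * (2k + 2)`` of each phase,
    balanced across strains.
    """
    if k < 1:
        raise PhenotypeError("k must be >= 1")
    coeffs = 2 * k + 2 if with_strain_interactions else k + 1
    return int(round(epv_floor * coeffs))


@dataclass
class ModelComparison:
    loglik_1: float
    loglik_2: float
    aic_1: float
    aic_2: float
    lrt_statistic: float
    lrt_df: int
    lrt_p: float
    recommendation: str  # pooled-model | strain-specific | underpowered
    design_audit_full: DesignAudit | None = None

    def to_dict(self) -> dict:
        d = {
            "loglik_1": float(self.loglik_1),
            "loglik_2": float(self.loglik_2),
            "aic_1": float(self.aic_1),
            "aic_2": float(self.aic_2),
            "lrt_statistic": float(self.lrt_statistic),
            "lrt_df": self.lrt_df,
            "lrt_p": float(self.lrt_p),
            "recommendation": self.recommendation,
        }
        if self.design_audit_full is not None:
            d["design_audit_full"] = self.design_audit_full.to_dict()
        return d


class SeparatedModelError(PhenotypeError):
    """A model required to be separation-free is separated."""

    def __init__(self, which: str, fit: LRFit):
        self.which = which
        self.fit = fit
        super().__init__(
            f"{which} is separated ({fit.separation.kind}); comparison invalid"
        )


def strain_generalization_compare(
    table: PhenotypeTable,
    spec: LRModelSpec,
    factor: str,
    epv_floor: float = 10.0,
    pooling_p: float = 0.15,
) -> ModelComparison:
    """Compare the strain-crossed model against the pooled model.

    Model 1: predictors crossed with ``factor`` (factor main effect plus all
    factor x predictor interactions).  Model 2: predictors only.  Returns
    AIC for both, the likelihood-ratio test of the nested pair, and an
    advisory recommendation: pooling is endorsed only if AIC favors Model 2
    or the LRT is decisively non-significant (p > ``pooling_p``), and
    "underpowered" overrides both whenever the EPV audit of Model 1 fails.
    """
    if factor not in table.data.columns:
        raise PhenotypeError(f"factor column {factor!r} not in table")
    levels = sorted(table.data[factor].astype(str).unique())
    if len(levels) < 2:
        raise PhenotypeError(f"factor {factor!r} needs >= 2 levels")
    env = table.data[table.environment].astype(str)
    for lev in levels:
        sub = env[table.data[factor].astype(str) == lev]
        if sub.nunique() < 2:
            raise PhenotypeError(
                f"factor level {lev!r} lacks one of the phases; crossed model "
                "cannot be estimated"
            )

    spec2 = spec
    spec1 = LRModelSpec(
        predictors=spec.predictors,
        event_level=spec.event_level,
        interactions=tuple((factor, p) for p in spec.predictors),
        standardize=spec.standardize,
    )
    fit2 = fit_logistic(table, spec2)
    fit1 = fit_logistic(table, spec1)
    for which, f in (("Model 1 (strain-crossed)", fit1), ("Model 2 (pooled)", fit2)):
        if f.separation.kind in ("complete", "quasi"):
            raise SeparatedModelError(which, f)

    lrt_df = len(fit1.term_names) - len(fit2.term_names)
    lrt_stat = max(0.0, 2.0 * (fit1.loglik - fit2.loglik))
    lrt_p = float(stats.chi2.sf(lrt_stat, lrt_df))

    audit_full = events_per_variable(
        fit1.n_event, fit1.n_nonevent, fit1.k, epv_floor=epv_floor
    )
    if audit_full.verdict == "fail":
        rec = "underpowered"
    elif fit2.aic <= fit1.aic or lrt_p > pooling_p:
        rec = "pooled-model"
    else:
        rec = "strain-specific"
    return ModelComparison(
        loglik_1=fit1.loglik,
        loglik_2=fit2.loglik,
        aic_1=fit1.aic,
        aic_2=fit2.aic,
        lrt_statistic=lrt_stat,
        lrt_df=lrt_df,
        lrt_p=lrt_p,
        recommendation=rec,
        design_audit_full=audit_full,
    )


# ---------------------------------------------------------------------------
# orchestrated audit


@dataclass
class AuditConfig:
    collinearity_threshold: float = 0.95
    epv_floor: float = 10.0
    bootstrap_B: int = 200
    seed: int = 0
    run_bootstrap: bool = True
    claimed_scope: str | None = None  # e.g. "non-morphometric"
    bootstrap_failure_warn: float = 0.10

    def to_dict(self) -> dict:
        return {
            "collinearity_threshold": self.collinearity_threshold,
            "epv_floor": self.epv_floor,
            "bootstrap_B": self.bootstrap_B,
            "seed": self.seed,
            "run_bootstrap": self.run_bootstrap,
            "claimed_scope": self.claimed_scope,
            "bootstrap_failure_warn": self.bootstrap_failure_warn,
        }


@dataclass
class AuditWarning:
    code: str
    detail: str = ""

    @property
    def message(self) -> str:
        return WARNING_CATALOGUE.get(self.code, "")

    def to_dict(self) -> dict:
        return {"code": self.code, "message": self.message, "detail": self.detail}


@dataclass
class AuditReport:
    config: AuditConfig
    completed_stages: list[str] = field(default_factory=list)
    warnings: list[AuditWarning] = field(default_factory=list)
    domain_census: dict[str, list[str]] = field(default_factory=dict)
    collinearity: CollinearityReport | None = None
    design_audit: DesignAudit | None = None
    fit: LRFit | None = None
    validation: ValidationResult | None = None
    sign_report: dict[str, float] = field(default_factory=dict)
    fatal_error: str | None = None

    @property
    def warning_codes(self) -> list[str]:
        return [w.code for w in self.warnings]

    def warn(self, code: str, detail: str = "") -> None:
        self.warnings.append(AuditWarning(code=code, detail=detail))

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "completed_stages": list(self.completed_stages),
            "warnings": [w.to_dict() for w in self.warnings],
            "domain_census": {k: list(v) for k, v in self.domain_census.items()},
            "collinearity": self.collinearity.to_dict() if self.collinearity else None,
            "design_audit": self.design_audit.to_dict() if self.design_audit else None,
            "fit": self.fit.to_dict() if self.fit else None,
            "validation": self.validation.to_dict() if self.validation else None,
            "sign_report": {k: float(v) for k, v in self.sign_report.items()},
            "fatal_error": self.fatal_error,
        }


def audit_model(
    table: PhenotypeTable, spec: LRModelSpec, config: AuditConfig | None = None
) -> AuditReport:
    """Run the full audit pipeline for one model on one dataset.

    Stages, in order: trait-domain census, collinearity/redundancy screen,
    design (EPV) audit, model fit, separation check, coefficient-sign
    report, bootstrap validation.  Fatal errors from a stage are recorded
    and later stages skipped; the report always carries a manifest of the
    stages that completed.
    """
    config = config or AuditConfig()
    report = AuditReport(config=config)

    # 1. trait-domain census
    census: dict[str, list[str]] = {"behavioral": [], "morphometric": [], "hybrid": []}
    for p in spec.predictors:
        domain = (
            table.trait_meta[p].domain if p in table.trait_meta else "behavioral"
        )
        census.setdefault(domain, []).append(p)
    report.domain_census = census
    if census["hybrid"]:
        report.warn(W_HYBRID_DOMAIN, detail=", ".join(census["hybrid"]))
    if census["behavioral"] and (census["morphometric"] or census["hybrid"]):
        report.warn(
            W_DOMAIN_MIX,
            detail=(
                f"behavioral: {census['behavioral']}; "
                f"morphometric: {census['morphometric']}; hybrid: {census['hybrid']}"
            ),
        )
    if config.claimed_scope == "non-morphometric" and (
        census["morphometric"] or census["hybrid"]
    ):
        report.warn(
            W_SCOPE_REFUSED,
            detail=", ".join(census["morphometric"] + census["hybrid"]),
        )
    report.completed_stages.append("domain_census")

    # 2. collinearity / redundancy screen (raw scale; correlation is
    #    invariant to the later standardization)
    try:
        if len(spec.predictors) >= 2:
            screen = collinearity_screen(
                table, spec, threshold=config.collinearity_threshold
            )
            report.collinearity = screen
            for a, b, r in screen.flagged_pairs:
                report.warn(W_COLLINEARITY, detail=f"{a} ~ {b}: r = {r:.4f}")
            for enc, base in screen.sign_redundant_pairs:
                report.warn(W_SIGN_REDUNDANT, detail=f"{enc} encodes sign({base})")
        report.completed_stages.append("collinearity_screen")
    except PhenotypeError as exc:
        report.fatal_error = f"collinearity_screen: {exc}"
        return report

    # 3. fit (standardization happens inside per spec.standardize)
    try:
        fit = fit_logistic(table, spec)
        report.fit = fit
        report.completed_stages.append("fit")
    except PhenotypeError as exc:
        report.fatal_error = f"fit: {exc}"
        return report

    # 4. design audit (uses realized event counts from the fit)
    audit = events_per_variable(
        fit.n_event, fit.n_nonevent, fit.k, epv_floor=config.epv_floor
    )
    report.design_audit = audit
    if audit.verdict == "fail":
        report.warn(W_EPV_FAIL, detail=f"EPV = {audit.epv:.2f}")
    elif audit.verdict == "warn":
        report.warn(W_EPV_WARN, detail=f"EPV = {audit.epv:.2f}")
    report.completed_stages.append("design_audit")

    # 5. separation check
    if fit.separation.kind in ("complete", "quasi"):
        report.warn(
            W_SEPARATION,
            detail=(
                f"kind = {fit.separation.kind}; extreme fraction = "
                f"{fit.separation.extreme_fraction:.3f}"
            ),
        )
    elif not fit.converged:
        report.warn(W_NONCONVERGENCE, detail=f"{fit.n_iterations} iterations")
    report.completed_stages.append("separation_check")

    # 6. coefficient sign report (flag opposing signs on near-collinear pairs)
    report.sign_report = {
        name: float(fit.coefficients[name]) for name in fit.term_names
    }
    if report.collinearity is not None:
        for a, b, r in report.collinearity.flagged_pairs:
            if a in fit.coefficients.index and b in fit.coefficients.index:
                if r > 0 and fit.coefficients[a] * fit.coefficients[b] < 0:
                    report.warn(W_SIGN_OPPOSED, detail=f"{a} vs {b}")
    report.completed_stages.append("sign_report")

    # 7. bootstrap validation — refused on a failed base fit
    if config.run_bootstrap:
        if fit.separation.flagged or not fit.converged:
            report.warn(W_VALIDATION_SKIPPED, detail=fit.separation.kind)
        else:
            try:
                val = bootstrap_validate(
                    table,
                    spec,
                    B=config.bootstrap_B,
                    seed=config.seed,
                    base_fit=fit,
                )
                report.validation = val
                if val.failure_fraction > config.bootstrap_failure_warn:
                    report.warn(
                        W_BOOTSTRAP_FAILURES,
                        detail=f"{val.failure_fraction:.0%} of {val.B_requested}",
                    )
            except AllReplicatesFailedError as exc:
                report.warn(W_BOOTSTRAP_FAILURES, detail=str(exc))
        report.completed_stages.append("validation")

    return report
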