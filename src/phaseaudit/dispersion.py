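"""Relative-dispersion inference and morphometric-normalization analysis.

Variance depends on measurement scale, so Bartlett's homogeneity test is
meaningless when applied to the same data before and after division by a
body-size measure — dividing any sample by a constant s > 1 mechanically
shrinks its variance.  The coefficient of variation (CV = s / x-bar) is the
scale- and dimension-free dispersion measure appropriate for that
comparison, and the Feltz–Miller asymptotic chi-square test compares CVs
across samples.  Both are provided here, alongside Bartlett's K^2 (kept
deliberately, to demonstrate its scale dependence), ratio "normalization"
of a behavioral trait by a morphometric one, and within- vs across-phase
correlation analysis.

Normalized traits are tagged domain="hybrid": dividing behavior by a
body-size measure that itself differs between phases re-introduces
morphometric information, so the result can no longer be treated as a
purely behavioral predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .phenotypes import PhenotypeError, PhenotypeTable, TraitMeta


def coefficient_of_variation(x: np.ndarray) -> float:
    """Sample CV: s / x-bar with the n-1 sample SD.  Requires x-bar > 0."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise PhenotypeError("CV requires n >= 2")
    m = float(np.mean(x))
    if m <= 0:
        raise PhenotypeError(f"CV undefined for non-positive sample mean ({m:.6g})")
    return float(np.std(x, ddof=1) / m)


@dataclass
class CVTestResult:
    """Per-sample CV estimates plus the Feltz–Miller test."""

    cv_estimates: list[float]
    ns: list[int]
    statistic: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "cv_estimates": [float(c) for c in self.cv_estimates],
            "ns": list(self.ns),
            "statistic": float(self.statistic),
            "df": self.df,
            "p_value": float(self.p_value),
        }


def feltz_miller_test(samples: Sequence[np.ndarray]) -> CVTestResult:
    """Asymptotic chi-square test of equal CVs across k samples.

    With m_i = n_i - 1 and CV estimates c_i, the pooled CV is
    D = sum(m_i c_i) / sum(m_i) and the statistic

        chi2 = sum_i m_i (c_i - D)^2 / (D^2 (0.5 + D^2))

    is asymptotically chi-square with k - 1 degrees of freedom under
    equality of the population CVs.
    """
    if len(samples) < 2:
        raise PhenotypeError("Feltz-Miller test needs >= 2 samples")
    cvs = [coefficient_of_variation(s) for s in samples]
    ns = [len(s) for s in samples]
    m = np.array(ns, dtype=float) - 1.0
    c = np.array(cvs, dtype=float)
    d = float(np.sum(m * c) / np.sum(m))
    if d == 0.0:
        stat = 0.0
    else:
        stat = float(np.sum(m * (c - d) ** 2) / (d * d * (0.5 + d * d)))
    df = len(samples) - 1
    p = float(stats.chi2.sf(stat, df))
    return CVTestResult(cv_estimates=cvs, ns=ns, statistic=stat, df=df, p_value=p)


def bartlett_k2(groups: Sequence[np.ndarray]) -> tuple[float, int, float]:
    """Bartlett's homogeneity-of-variance K^2, df, and p-value.

    Only meaningful for groups measured on the same scale: applied to a
    sample and a rescaled copy of itself it will trivially reject, which is
    exactly the pitfall the CV machinery above exists to avoid.
    """
    if len(groups) < 2:
        raise PhenotypeError("Bartlett test needs >= 2 groups")
    for g in groups:
        if len(g) < 2:
            raise PhenotypeError("each group needs n >= 2")
        if np.std(np.asarray(g, dtype=float), ddof=1) == 0.0:
            raise PhenotypeError("zero-variance group: Bartlett statistic undefined")
    stat, p = stats.bartlett(*[np.asarray(g, dtype=float) for g in groups])
    return float(stat), len(groups) - 1, float(p)


def normalize_by_morphometric(
    table: PhenotypeTable, trait: str, size_trait: str
) -> tuple[PhenotypeTable, str]:
    """Add ``trait / size_trait`` as a new column tagged domain="hybrid".

    The hybrid tag is deliberate: the ratio mixes a behavioral signal with a
    morphometric one and must not be treated as purely behavioral
    downstream.  Returns (new table, new column name).
    """
    for c in (trait, size_trait):
        if c not in table.data.columns:
            raise PhenotypeError(f"column {c!r} not in table")
    size = table.data[size_trait].to_numpy(dtype=float)
    if np.any(size <= 0):
        raise PhenotypeError(
            f"size trait {size_trait!r} has non-positive values; ratio undefined"
        )
    name = f"{trait}_per_{size_trait}"
    values = table.data[trait].to_numpy(dtype=float) / size
    ts = table.trait_meta[trait].timescale if trait in table.trait_meta else "fast"
    new = table.with_columns(
        new=table.data.assign(**{name: values})[[name]],
        meta={name: TraitMeta(domain="hybrid", timescale=ts)},
    )
    return new, name


@dataclass
class CorrelationResult:
    coefficient: float
    n: int
    statistic: float
    p_value: float
    method: str
    scope: str
    s_statistic: float | None = None  # Spearman's S, for cross-study comparability

    def to_dict(self) -> dict:
        d = {
            "coefficient": float(self.coefficient),
            "n": self.n,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "method": self.method,
            "scope": self.scope,
        }
        if self.s_statistic is not None:
            d["s_statistic"] = float(self.s_statistic)
        return d


def correlate(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "pearson",
    scope: str = "across-groups",
) -> CorrelationResult:
    """Pearson or Spearman correlation with its test.

    ``scope`` is a mandatory label ("within-group" or "across-groups") so
    that reports always state which question a correlation answers: a
    correlation across the two phases reflects the phase difference itself
    and says nothing about a within-phase association.
    """
    if scope not in ("within-group", "across-groups"):
        raise PhenotypeError("scope must be 'within-group' or 'across-groups'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise PhenotypeError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise PhenotypeError("correlation needs n >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise PhenotypeError("constant input: correlation coefficient undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        t = float(r) * np.sqrt((n - 2) / max(1.0 - r * r, 1e-300))
        return CorrelationResult(float(r), n, float(t), float(p), method, scope)
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
        s = (1.0 - float(rho)) * n * (n * n - 1) / 6.0
        return CorrelationResult(
            float(rho), n, float(rho), float(p), method, scope, s_statistic=float(s)
        )
    raise PhenotypeError(f"unknown correlation method {method!r}")
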