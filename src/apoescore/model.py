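"""Multivariable logistic modelling of case-control status.

Unconditional logistic regression (maximum likelihood via Newton /
iteratively reweighted least squares, through statsmodels) over
configurable predictor sets, an exhaustive best-subsets search ranked
by a penalized-likelihood criterion (AIC by default), and refits in
epsilon-defined subgroups (E2 carriers excluded, E4 carriers excluded,
E3/E3 only, E4 carriers only).

Predictors are built from the cohort: epsilon carriership indicators,
the preventive score (numeric 0-4), serum ApoE level, male sex,
education as an ordinal 1-4 (1 primary ... 4 university), a large-city
residence indicator and age.  Complete-case analysis per model; the
rows actually used are reported.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genotypes import (
    GROUP_CASE,
    Cohort,
    UndefinedStatisticError,
    ValidationError,
)
from .score import DEFAULT_SCORE_TABLE, ScoreTable, score_cohort

log = logging.getLogger(__name__)

CODINGS = ("binary", "ordinal", "numeric", "categorical")

#: |coefficient| beyond which a fit is flagged as (quasi-)separated
SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class Predictor:
    name: str
    coding: str = "numeric"
    reference: Optional[str] = None  # for categorical coding

    def __post_init__(self) -> None:
        if self.coding not in CODINGS:
            raise ValidationError(f"unknown coding {self.coding!r}")


@dataclass
class DesignSpec:
    outcome: str = "group"
    predictors: list[Predictor] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.predictors]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate predictor names")


@dataclass
class LogisticFit:
    terms: list[str]
    coefficients: dict[str, float]
    or_per_term: dict[str, float]
    ci_per_term: dict[str, tuple[float, float]]
    p_per_term: dict[str, float]
    loglik: float
    loglik_null: float
    criterion: float
    criterion_name: str
    n_used: int
    converged: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def separation_flagged(self) -> bool:
        return any("separation" in w for w in self.warnings)


DEFAULT_CANDIDATES: list[Predictor] = [
    Predictor("e4_carrier", "binary"),
    Predictor("score", "numeric"),
    Predictor("apoe_level", "numeric"),
    Predictor("male", "binary"),
    Predictor("education", "ordinal"),
    Predictor("large_city", "binary"),
]

#: the wider screen: individual promoter/intron dosages and E2 in place of
#: the composite score
FULL_CANDIDATES: list[Predictor] = [
    Predictor("rs449647_dosage", "numeric"),
    Predictor("rs405509_dosage", "numeric"),
    Predictor("rs440446_dosage", "numeric"),
    Predictor("e4_carrier", "binary"),
    Predictor("e2_carrier", "binary"),
    Predictor("apoe_level", "numeric"),
    Predictor("male", "binary"),
    Predictor("education", "ordinal"),
    Predictor("large_city", "binary"),
]


def build_features(cohort: Cohort,
                   score_table: ScoreTable = DEFAULT_SCORE_TABLE) -> pd.DataFrame:
    """Per-subject model features derived from a cohort."""
    df = pd.DataFrame(index=cohort.data.index)
    df["case"] = (cohort.data["group"] == GROUP_CASE).astype(float)
    df["e4_carrier"] = cohort.epsilon_carrier("E4").astype(float)
    df["e2_carrier"] = cohort.epsilon_carrier("E2").astype(float)
    df["score"] = score_cohort(cohort, score_table)["score"].to_numpy()
    if "apoe_level" in cohort.data:
        df["apoe_level"] = pd.to_numeric(cohort.data["apoe_level"],
                                         errors="coerce")
    if "sex" in cohort.data:
        df["male"] = (cohort.data["sex"] == "M").astype(float)
    if "education" in cohort.data:
        df["education"] = pd.to_numeric(cohort.data["education"],
                                        errors="coerce").astype(float)
    if "residence" in cohort.data:
        df["large_city"] = (cohort.data["residence"] == "large_city").astype(float)
    if "age" in cohort.data:
        df["age"] = pd.to_numeric(cohort.data["age"], errors="coerce")
    for rsid in ("rs449647", "rs405509", "rs440446"):
        if rsid in cohort.data:
            df[f"{rsid}_dosage"] = cohort.minor_dosage(rsid)
    return df


def _expand_columns(features: pd.DataFrame, predictor: Predictor) -> pd.DataFrame:
    if predictor.name not in features.columns:
        raise ValidationError(f"feature {predictor.name!r} not available")
    col = features[predictor.name]
    if predictor.coding == "categorical":
        dummies = pd.get_dummies(col, prefix=predictor.name, dtype=float)
        ref = (f"{predictor.name}_{predictor.reference}"
               if predictor.reference is not None else dummies.columns[0])
        return dummies.drop(columns=[ref])
    return col.to_frame(predictor.name).astype(float)


def logistic_fit(features: pd.DataFrame, outcome: str = "case",
                 predictors: Sequence[Predictor] = (),
                 criterion: str = "aic") -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald intervals.

    Complete cases only; convergence by Newton iterations on the
    log-likelihood.  Complete or quasi-complete separation is flagged
    (coefficients reported with a warning) rather than silently
    diverging; singular designs raise naming the collinear terms.
    """
    blocks = [_expand_columns(features, p) for p in predictors]
    X = pd.concat([pd.Series(1.0, index=features.index, name="intercept")]
                  + blocks, axis=1)
    y = features[outcome]
    mask = X.notna().all(axis=1) & y.notna()
    X, y = X.loc[mask], y.loc[mask]
    n_used = int(mask.sum())
    if n_used < X.shape[1] + 1:
        raise UndefinedStatisticError(
            f"{n_used} complete cases for {X.shape[1]} terms")
    if y.nunique() < 2:
        raise UndefinedStatisticError("outcome constant in complete cases")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValidationError(
            f"singular design matrix; collinear terms among {list(X.columns)}")

    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    warnings: list[str] = []
    model = sm.Logit(y.to_numpy(), X.to_numpy())
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        try:
            with np.errstate(all="ignore"):
                res = model.fit(disp=0, method="newton", maxiter=100,
                                tol=1e-10)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception as exc:  # perfect separation can raise in statsmodels
            with np.errstate(all="ignore"):
                res = model.fit(disp=0, method="bfgs", maxiter=500)
            converged = False
            warnings.append(f"separation suspected ({type(exc).__name__})")
    if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
        warnings.append("separation suspected (perfect prediction)")

    params = np.asarray(res.params, dtype=float)
    if np.abs(params[1:]).max(initial=0.0) > SEPARATION_BOUND:
        warnings.append("separation suspected (|coefficient| > 15)")
    try:
        cov = np.asarray(res.cov_params())
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except Exception:
        se = np.full_like(params, np.nan)
        warnings.append("information matrix near-singular")
    if not np.isfinite(se).all():
        warnings.append("information matrix near-singular")
    for w in warnings:
        log.info("logistic fit [%s]: %s", ", ".join(X.columns[1:]) or "null", w)

    z = 1.959963984540054
    names = list(X.columns)
    coeffs = dict(zip(names, params))
    with np.errstate(over="ignore"):
        ors = {k: float(np.exp(v)) for k, v in coeffs.items()}
        cis = {k: (float(np.exp(v - z * s)), float(np.exp(v + z * s)))
               for (k, v), s in zip(coeffs.items(), se)}
    with np.errstate(all="ignore"):
        pvals = dict(zip(names, np.asarray(res.pvalues, dtype=float)))
    llf = float(res.llf)
    ll_null = float(sm.Logit(y.to_numpy(),
                             np.ones((n_used, 1))).fit(disp=0).llf)
    k = X.shape[1]
    crit = {"aic": 2 * k - 2 * llf,
            "bic": k * math.log(n_used) - 2 * llf,
            "loglik": -llf}
    if criterion not in crit:
        raise ValidationError(f"unknown criterion {criterion!r}")
    return LogisticFit(
        terms=names, coefficients=coeffs, or_per_term=ors, ci_per_term=cis,
        p_per_term=pvals, loglik=llf, loglik_null=ll_null,
        criterion=float(crit[criterion]), criterion_name=criterion,
        n_used=n_used, converged=converged, warnings=warnings)


def cohort_logistic_fit(cohort: Cohort, design: DesignSpec,
                        criterion: str = "aic",
                        score_table: ScoreTable = DEFAULT_SCORE_TABLE
                        ) -> LogisticFit:
    features = build_features(cohort, score_table)
    return logistic_fit(features, "case", design.predictors, criterion)


@dataclass
class SubsetSearchResult:
    ranking: list[tuple[tuple[str, ...], LogisticFit]]  # best first

    @property
    def best(self) -> LogisticFit:
        return self.ranking[0][1]

    @property
    def best_terms(self) -> tuple[str, ...]:
        return self.ranking[0][0]


def best_subsets(features: pd.DataFrame,
                 candidates: Sequence[Predictor] = tuple(DEFAULT_CANDIDATES),
                 outcome: str = "case", criterion: str = "aic",
                 max_terms: int = 20) -> SubsetSearchResult:
    """Fit every predictor subset and rank by the model-selection criterion.

    All 2^k subsets (including the intercept-only null model) are
    fitted on the complete cases of the *full* candidate set, so that
    criteria are comparable across subsets; k is capped at ``max_terms``.
    """
    candidates = list(candidates)
    if len(candidates) > max_terms:
        raise ValidationError(
            f"{len(candidates)} candidates exceed the exhaustive budget "
            f"({max_terms}); prune the candidate set")
    cols = [outcome] + [c.name for c in candidates]
    complete = features.loc[features[cols].notna().all(axis=1)]
    results = []
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            try:
                fit = logistic_fit(complete, outcome, subset, criterion)
            except (UndefinedStatisticError, ValidationError) as exc:
                log.info("subset %s unfittable, skipped: %s",
                         [p.name for p in subset], exc)
                continue
            results.append((tuple(p.name for p in subset), fit))
    if not results:
        raise UndefinedStatisticError("no candidate subset could be fitted")
    results.sort(key=lambda t: (t[1].criterion, len(t[0])))
    return SubsetSearchResult(results)


EPSILON_STRATA = {
    "excluding_E2_carriers": lambda c: ~c.epsilon_carrier("E2"),
    "excluding_E4_carriers": lambda c: ~c.epsilon_carrier("E4"),
    "E3_E3_only": lambda c: c.epsilon_genotypes().map(
        lambda e: e is not None and str(e) == "E3/E3").astype(bool),
    "E4_carriers_only": lambda c: c.epsilon_carrier("E4"),
}

#: below this per-stratum size a warning is attached to the fit
SMALL_STRATUM = 50


def stratified_fits(cohort: Cohort, design: DesignSpec,
                    strata: Optional[dict] = None, criterion: str = "aic",
                    score_table: ScoreTable = DEFAULT_SCORE_TABLE
                    ) -> dict[str, Optional[LogisticFit]]:
    """Refit a design within epsilon-defined subgroups.

    Strata with an empty outcome class (or too few complete cases) are
    skipped with the reason logged; small strata get a warning attached.
    """
    strata = EPSILON_STRATA if strata is None else strata
    out: dict[str, Optional[LogisticFit]] = {}
    for name, rule in strata.items():
        mask = rule(cohort)
        sub = cohort.subset(mask)
        if sub.n_case == 0 or sub.n_control == 0:
            log.info("stratum %s skipped: empty outcome class "
                     "(%d cases / %d controls)", name, sub.n_case, sub.n_control)
            out[name] = None
            continue
        try:
            fit = cohort_logistic_fit(sub, design, criterion, score_table)
        except (UndefinedStatisticError, ValidationError) as exc:
            log.info("stratum %s skipped: %s", name, exc)
            out[name] = None
            continue
        if fit.n_used < SMALL_STRATUM:
            fit.warnings.append(f"small stratum (n={fit.n_used})")
        out[name] = fit
    return out
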