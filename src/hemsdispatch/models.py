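"""Per-category multivariate logistic models with backward elimination.

For each of the most frequently dispatched AMPDS categories two models
are fitted: patient contact (all coded dispatches in the category) and
HLIDD (contact taskings only).  Covariates are all categorical: shift
(night vs day), platform (RRV vs helicopter), dispatch-desk composition
(CCP present vs not), and - for the HLIDD outcome, where a patient
exists - sex (male vs female) and age bin (<16 and >55 vs 16-55).
Reference levels are day, helicopter, no-CCP desk, female, age 16-55.

Model building: an optional univariate pre-screen keeps terms
significant on their own; the full main-effects model is then reduced
by removing the single least-significant term (p >= 0.05) and
refitting, until every retained term is significant.  Multi-level terms
(age bin) are judged by a 2-df likelihood-ratio test, single-column
terms by their Wald p.  Configured pairwise interactions among retained
terms are then tested by likelihood-ratio tests.  Taskings treating
more than one patient are excluded from the age/sex analysis; remaining
missing values are handled as missing-at-random by listwise deletion.

Diagnostics on the final model: Cook's distance (> 4/n flags
influence), variance inflation factors (> 5 flags collinearity), and a
logit-linearity check that reports "not applicable" while all
covariates are categorical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .contingency import odds_ratio_2x2
from .records import DispatchRecord

__all__ = [
    "ModelDataset",
    "TermEstimate",
    "InteractionTest",
    "DiagnosticsReport",
    "CovariateModelResult",
    "ModelFitError",
    "prepare_category_dataset",
    "fit_reduced_model",
    "odds_ratio_2x2",
    "assign_age_bin",
    "DEFAULT_INTERACTIONS",
]

ALPHA = 0.05
DEFAULT_MIN_ROWS = 50
DEFAULT_INTERACTIONS: tuple[tuple[str, str], ...] = (("night", "rrv"),)

# term -> design columns it contributes
_TERM_COLUMNS = {
    "night": ("night",),
    "rrv": ("rrv",),
    "desk_ccp": ("desk_ccp",),
    "male": ("male",),
    "age_bin": ("age_lt16", "age_gt55"),
}
_CONTACT_TERMS = ("night", "rrv", "desk_ccp")
_HLIDD_TERMS = ("night", "rrv", "desk_ccp", "male", "age_bin")


class ModelFitError(RuntimeError):
    """Raised when a model cannot be fitted (non-convergence/separation)."""

    def __init__(self, message: str, terms: tuple[str, ...] = ()):
        self.terms = terms
        super().__init__(message)


def assign_age_bin(age_years: float) -> str:
    """Clinically pragmatic bins: [0,16) -> lt16, [16,55] -> 16to55, (55,) -> gt55."""
    if age_years < 16:
        return "lt16"
    if age_years <= 55:
        return "16to55"
    return "gt55"


@dataclass
class ModelDataset:
    """A category's design frame for one outcome, plus its attrition."""

    category: str
    outcome: str
    frame: pd.DataFrame  # columns: y + design columns for `terms`
    terms: tuple[str, ...]
    exclusions_log: dict[str, int] = field(default_factory=dict)
    error: str | None = None

    @property
    def n_rows(self) -> int:
        return len(self.frame)


def prepare_category_dataset(
    records: list[DispatchRecord],
    category: str,
    outcome: str,
    *,
    min_rows: int = DEFAULT_MIN_ROWS,
) -> ModelDataset:
    """Build the complete-case design frame for one category and outcome."""
    if not (len(category) == 2 and category.isdigit()):
        raise ValueError(f"category must be a 2-digit string, got {category!r}")
    if outcome not in ("contact", "hlidd"):
        raise ValueError(f"unknown outcome {outcome!r}")

    subset = [r for r in records if r.code is not None and r.code.category == category]
    log: dict[str, int] = {}
    rows = []
    if outcome == "contact":
        terms = _CONTACT_TERMS
        for r in subset:
            rows.append(
                {
                    "y": int(r.contact),
                    "night": int(r.shift == "night"),
                    "rrv": int(r.platform == "rrv"),
                    "desk_ccp": int(r.desk_ccp),
                }
            )
    else:
        terms = _HLIDD_TERMS
        contacts = [r for r in subset if r.contact]
        for r in contacts:
            male: float = np.nan
            lt16: float = np.nan
            gt55: float = np.nan
            if r.n_patients > 1:
                # multi-patient taskings are excluded from the age/sex analysis
                log["multi_patient_age_sex"] = log.get("multi_patient_age_sex", 0) + 1
            elif r.patients:
                p = r.patients[0]
                if p.sex == "male":
                    male = 1.0
                elif p.sex == "female":
                    male = 0.0
                else:
                    # transgender kept in descriptive tables, missing in models
                    log["sex_missing"] = log.get("sex_missing", 0) + 1
                if p.age_years is not None:
                    b = assign_age_bin(p.age_years)
                    lt16, gt55 = float(b == "lt16"), float(b == "gt55")
                else:
                    log["age_missing"] = log.get("age_missing", 0) + 1
            rows.append(
                {
                    "y": int(r.hlidd),
                    "night": int(r.shift == "night"),
                    "rrv": int(r.platform == "rrv"),
                    "desk_ccp": int(r.desk_ccp),
                    "male": male,
                    "age_lt16": lt16,
                    "age_gt55": gt55,
                }
            )

    frame = pd.DataFrame(rows)
    if len(frame):
        before = len(frame)
        frame = frame.dropna().reset_index(drop=True)
        log["listwise_deleted"] = before - len(frame)

    error = None
    if len(frame) < min_rows:
        error = f"only {len(frame)} complete rows (< {min_rows}); refusing to fit"
    return ModelDataset(
        category=category, outcome=outcome, frame=frame, terms=terms,
        exclusions_log=log, error=error,
    )


@dataclass(frozen=True, slots=True)
class TermEstimate:
    term: str
    level: str  # design column, e.g. "age_lt16"
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float


@dataclass(frozen=True, slots=True)
class InteractionTest:
    terms: tuple[str, str]
    lr_statistic: float
    p_value: float
    retained: bool


@dataclass
class DiagnosticsReport:
    influence_flags: list[int]  # row indices with Cook's distance > 4/n
    cooks_cutoff: float
    vif_by_term: dict[str, float]
    logit_linearity: str  # "not_applicable" while all covariates categorical


@dataclass
class CovariateModelResult:
    category: str
    outcome: str
    n_rows: int
    retained_terms: list[TermEstimate]
    eliminated_terms: list[tuple[str, str, float]]  # (term, stage, p at removal)
    interaction_tests: list[InteractionTest]
    diagnostics: DiagnosticsReport | None

    @property
    def retained_term_names(self) -> set[str]:
        return {t.term for t in self.retained_terms}

    def estimate(self, level: str) -> TermEstimate | None:
        for t in self.retained_terms:
            if t.level == level:
                return t
        return None


def _design(frame: pd.DataFrame, columns: list[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(frame))] + [frame[c].to_numpy(float) for c in columns])
    return X


def _fit(frame: pd.DataFrame, columns: list[str]):
    y = frame["y"].to_numpy(float)
    X = _design(frame, columns)
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    except Exception as exc:  # pragma: no cover - statsmodels internal failures
        raise ModelFitError(f"model failed to fit: {exc}", tuple(columns)) from exc
    if not np.all(np.isfinite(res.bse)):
        raise ModelFitError("non-finite standard errors (separation?)", tuple(columns))
    return res


def _term_pvalue(frame: pd.DataFrame, columns: list[str], res, term: str) -> float:
    """Whole-term p: Wald for single columns, LR test for multi-level terms."""
    cols = _TERM_COLUMNS[term]
    if len(cols) == 1:
        return float(res.pvalues[columns.index(cols[0]) + 1])
    reduced_cols = [c for c in columns if c not in cols]
    res0 = _fit(frame, reduced_cols)
    lr = 2.0 * (res.llf - res0.llf)
    return float(stats.chi2.sf(max(lr, 0.0), df=len(cols)))


def fit_reduced_model(
    dataset: ModelDataset,
    *,
    interactions: tuple[tuple[str, str], ...] = DEFAULT_INTERACTIONS,
    univariate_prescreen: bool = True,
    alpha: float = ALPHA,
    run_diagnostics: bool = True,
) -> CovariateModelResult:
    """Univariate pre-screen, backward elimination, interaction tests,
    and diagnostics, returning the final reduced model."""
    if dataset.error is not None:
        raise ModelFitError(dataset.error, dataset.terms)
    frame = dataset.frame
    if frame["y"].nunique() < 2:
        raise ModelFitError("outcome has no variation", dataset.terms)

    eliminated: list[tuple[str, str, float]] = []
    terms = list(dataset.terms)

    if univariate_prescreen:
        surviving = []
        for term in terms:
            cols = list(_TERM_COLUMNS[term])
            res = _fit(frame, cols)
            p = _term_pvalue(frame, cols, res, term)
            if p < alpha:
                surviving.append(term)
            else:
                eliminated.append((term, "univariate", p))
        terms = surviving

    # backward elimination on the multivariate model
    while terms:
        columns = [c for t in terms for c in _TERM_COLUMNS[t]]
        res = _fit(frame, columns)
        pvals = {t: _term_pvalue(frame, columns, res, t) for t in terms}
        worst = max(terms, key=lambda t: pvals[t])
        if pvals[worst] < alpha:
            break
        eliminated.append((worst, "backward", pvals[worst]))
        terms.remove(worst)

    columns = [c for t in terms for c in _TERM_COLUMNS[t]]
    res = _fit(frame, columns) if terms else _fit(frame, [])

    # likelihood-ratio tests for configured interactions among retained terms
    interaction_tests: list[InteractionTest] = []
    inter_columns: list[str] = []
    work = frame
    for t1, t2 in interactions:
        if t1 not in terms or t2 not in terms:
            continue
        c1, c2 = _TERM_COLUMNS[t1][0], _TERM_COLUMNS[t2][0]
        name = f"{c1}_x_{c2}"
        work = work.assign(**{name: work[c1] * work[c2]})
        res_full = _fit(work, columns + inter_columns + [name])
        res_base = _fit(work, columns + inter_columns)
        lr = 2.0 * (res_full.llf - res_base.llf)
        p = float(stats.chi2.sf(max(lr, 0.0), df=1))
        keep = p < alpha
        interaction_tests.append(InteractionTest((t1, t2), float(lr), p, keep))
        if keep:
            inter_columns.append(name)
    if inter_columns:
        res = _fit(work, columns + inter_columns)
        columns = columns + inter_columns

    z = stats.norm.ppf(0.975)
    retained: list[TermEstimate] = []
    for j, col in enumerate(columns):
        b, se, p = res.params[j + 1], res.bse[j + 1], float(res.pvalues[j + 1])
        term = next(
            (t for t, cols in _TERM_COLUMNS.items() if col in cols), col
        )
        retained.append(
            TermEstimate(
                term=term,
                level=col,
                odds_ratio=float(np.exp(b)),
                ci95=(float(np.exp(b - z * se)), float(np.exp(b + z * se))),
                p_value=p,
            )
        )

    diagnostics = None
    if run_diagnostics:
        diagnostics = _diagnostics(work if inter_columns else frame, columns, res)

    return CovariateModelResult(
        category=dataset.category,
        outcome=dataset.outcome,
        n_rows=len(frame),
        retained_terms=retained,
        eliminated_terms=eliminated,
        interaction_tests=interaction_tests,
        diagnostics=diagnostics,
    )


def _diagnostics(frame: pd.DataFrame, columns: list[str], res) -> DiagnosticsReport:
    n = len(frame)
    cutoff = 4.0 / n if n else np.inf
    try:
        cooks = res.get_influence(observed=False).cooks_distance[0]
        flags = [int(i) for i in np.flatnonzero(cooks > cutoff)]
    except Exception:  # influence can fail on saturated/degenerate fits
        flags = []
    vif: dict[str, float] = {}
    if len(columns) >= 2:
        X = _design(frame, columns)
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        for j, col in enumerate(columns):
            vif[col] = float(variance_inflation_factor(X, j + 1))
    elif columns:
        vif[columns[0]] = 1.0
    return DiagnosticsReport(
        influence_flags=flags,
        cooks_cutoff=cutoff,
        vif_by_term=vif,
        logit_linearity="not_applicable",
    )


def models_to_frame(results: list[CovariateModelResult]) -> pd.DataFrame:
    """Flat export shaped like an adjusted-OR summary table."""
    rows = []
    for r in results:
        for t in r.retained_terms:
            rows.append(
                {
                    "category": r.category,
                    "outcome": r.outcome,
                    "n": r.n_rows,
                    "term": t.level,
                    "odds_ratio": t.odds_ratio,
                    "ci_low": t.ci95[0],
                    "ci_high": t.ci95[1],
                    "p_value": t.p_value,
                    "significant": "yes",
                }
            )
        for term, stage, p in r.eliminated_terms:
            rows.append(
                {
                    "category": r.category,
                    "outcome": r.outcome,
                    "n": r.n_rows,
                    "term": term,
                    "odds_ratio": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_value": p,
                    "significant": "ns",
                }
            )
    return pd.DataFrame(rows)
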