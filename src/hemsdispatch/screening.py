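"""Per-code tallies and the dual logistic screens.

Codes with at least 50 HEMS dispatches over the study window are
*eligible*; all rarer codes are collapsed into a single pooled reference
level.  Two unadjusted logistic regressions - one per outcome - model
the binary outcome on the code as a categorical predictor:

* ``contact``: patient seen (1) vs stand-down (0), over all coded
  dispatches;
* ``hlidd``: tasking produced an HLIDD for at least one patient (1) vs
  not (0), restricted to taskings with patient contact.

Each eligible code's Wald odds ratio, 95% CI and p-value are reported
against the pooled baseline; because the model is saturated these equal
the 2x2 cross-product ratios against the pool, which the test suite
pins down against the closed form.  A code is flagged *significantly
high* when p < 0.05 and OR > 1.  No multiplicity correction is applied
across codes (reported as-is in exports).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .contingency import odds_ratio_2x2
from .records import AmpdsCode, DispatchRecord

__all__ = [
    "CodeTally",
    "ScreeningResult",
    "tally_codes",
    "split_eligible",
    "screen_outcome",
    "screening_to_frame",
]

DEFAULT_MIN_DISPATCHES = 50
ALPHA = 0.05


@dataclass(frozen=True, slots=True)
class CodeTally:
    """Per-code counts: dispatches, contacts, HLIDD-positive contacts."""

    code: AmpdsCode
    n_dispatch: int
    n_contact: int
    n_hlidd: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_hlidd <= self.n_contact <= self.n_dispatch:
            raise ValueError("need 0 <= n_hlidd <= n_contact <= n_dispatch")

    @property
    def contact_rate(self) -> float:
        return self.n_contact / self.n_dispatch if self.n_dispatch else float("nan")

    @property
    def hlidd_rate(self) -> float | None:
        """HLIDD rate among contacts; None when the code has no contacts."""
        return self.n_hlidd / self.n_contact if self.n_contact else None


@dataclass(frozen=True, slots=True)
class ScreeningResult:
    """One eligible code's screen estimate for one outcome."""

    code: AmpdsCode
    outcome: str  # "contact" | "hlidd"
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    significantly_high: bool
    n: int  # analysis-set size for this code (denominator of its rate)

    def __post_init__(self) -> None:
        if not self.ci95[0] <= self.odds_ratio <= self.ci95[1]:
            raise ValueError("CI must bracket the odds ratio")


def tally_codes(records: list[DispatchRecord]) -> list[CodeTally]:
    """One tally per distinct code; records without a code are excluded
    (they are removed from all analysis upstream, see the attrition log)."""
    coded = [r for r in records if r.code is not None]
    if not coded:
        return []
    frame = pd.DataFrame(
        {
            "code": [r.code.canonical_text for r in coded],
            "contact": [r.contact for r in coded],
            "hlidd": [r.hlidd for r in coded],
        }
    )
    by_code = {r.code.canonical_text: r.code for r in coded}
    grouped = frame.groupby("code", sort=True).agg(
        n_dispatch=("contact", "size"),
        n_contact=("contact", "sum"),
        n_hlidd=("hlidd", "sum"),
    )
    return [
        CodeTally(
            code=by_code[text],
            n_dispatch=int(row.n_dispatch),
            n_contact=int(row.n_contact),
            n_hlidd=int(row.n_hlidd),
        )
        for text, row in grouped.iterrows()
    ]


def split_eligible(
    tallies: list[CodeTally], min_dispatches: int = DEFAULT_MIN_DISPATCHES
) -> tuple[list[CodeTally], list[CodeTally]]:
    """Partition into (eligible, reference_pool) at >= ``min_dispatches``."""
    if min_dispatches < 1:
        raise ValueError("min_dispatches must be >= 1")
    eligible = [t for t in tallies if t.n_dispatch >= min_dispatches]
    pool = [t for t in tallies if t.n_dispatch < min_dispatches]
    return eligible, pool


def _outcome_counts(t: CodeTally, outcome: str) -> tuple[int, int]:
    """(successes, trials) for this outcome; hlidd restricts to contacts."""
    if outcome == "contact":
        return t.n_contact, t.n_dispatch
    if outcome == "hlidd":
        return t.n_hlidd, t.n_contact
    raise ValueError(f"unknown outcome {outcome!r}")


def screen_outcome(
    records: list[DispatchRecord],
    eligible: list[CodeTally],
    outcome: str,
    *,
    alpha: float = ALPHA,
) -> list[ScreeningResult]:
    """Fit the one-model-per-outcome logistic screen.

    The model has an intercept (the pooled sub-threshold baseline) plus
    one indicator per eligible code, fitted on binomially aggregated
    data.  Codes with a zero cell (perfect separation) are reported via
    the Haldane-corrected 2x2 closed form, with the significance flag
    decided by a one-sided Fisher exact test.
    """
    if not eligible:
        return []
    tallies = tally_codes(records)
    eligible_texts = {t.code.canonical_text for t in eligible}
    pool_succ = pool_trials = 0
    for t in tallies:
        if t.code.canonical_text not in eligible_texts:
            s, n = _outcome_counts(t, outcome)
            pool_succ += s
            pool_trials += n

    # align eligible tallies with the freshly computed ones (they may
    # have been produced from the same records; recompute to be safe)
    tally_map = {t.code.canonical_text: t for t in tallies}
    ordered = [tally_map.get(t.code.canonical_text, t) for t in eligible]

    counts = [_outcome_counts(t, outcome) for t in ordered]
    regular: list[int] = []
    fallback: list[int] = []
    for i, (s, n) in enumerate(counts):
        if n > 0 and 0 < s < n and pool_succ > 0 and pool_succ < pool_trials:
            regular.append(i)
        else:
            fallback.append(i)

    results: dict[int, ScreeningResult] = {}
    if regular:
        k = len(regular)
        endog = np.zeros((k + 1, 2))
        exog = np.zeros((k + 1, k + 1))
        exog[:, 0] = 1.0
        for row, i in enumerate(regular):
            s, n = counts[i]
            endog[row] = (s, n - s)
            exog[row, row + 1] = 1.0
        endog[k] = (pool_succ, pool_trials - pool_succ)
        with warnings.catch_warnings():
            # the design is saturated (one parameter per code level), so
            # statsmodels flags exact prediction and a zero-df scale;
            # both are expected and harmless here
            warnings.simplefilter("ignore", RuntimeWarning)
            try:
                from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
                warnings.simplefilter("ignore", PerfectSeparationWarning)
            except ImportError:  # older statsmodels
                pass
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(
                tol=1e-12, maxiter=500
            )
        for row, i in enumerate(regular):
            b = fit.params[row + 1]
            se = fit.bse[row + 1]
            z = stats.norm.ppf(0.975)
            p = float(fit.pvalues[row + 1])
            orr = float(np.exp(b))
            results[i] = ScreeningResult(
                code=ordered[i].code,
                outcome=outcome,
                odds_ratio=orr,
                ci95=(float(np.exp(b - z * se)), float(np.exp(b + z * se))),
                p_value=p,
                significantly_high=bool(p < alpha and orr > 1.0),
                n=counts[i][1],
            )

    for i in fallback:
        s, n = counts[i]
        if n == 0:
            # no analysis set for this code (e.g. zero contacts in the
            # HLIDD screen): report a null, never-significant result
            results[i] = ScreeningResult(
                code=ordered[i].code, outcome=outcome, odds_ratio=1.0,
                ci95=(1.0, 1.0), p_value=1.0, significantly_high=False, n=0,
            )
            continue
        orr, ci = odds_ratio_2x2(s, n - s, pool_succ, pool_trials - pool_succ)
        table = np.array([[s, n - s], [pool_succ, pool_trials - pool_succ]])
        p_one_sided = float(stats.fisher_exact(table, alternative="greater")[1])
        results[i] = ScreeningResult(
            code=ordered[i].code,
            outcome=outcome,
            odds_ratio=orr,
            ci95=ci,
            p_value=p_one_sided,
            significantly_high=bool(p_one_sided < alpha and orr > 1.0),
            n=n,
        )
    return [results[i] for i in range(len(ordered))]


def screening_to_frame(
    results: list[ScreeningResult], tallies: list[CodeTally] | None = None
) -> pd.DataFrame:
    """Flat export (code, outcome, n, rate, OR, CI, p, flag)."""
    rate_map = {}
    if tallies:
        for t in tallies:
            rate_map[("contact", t.code.canonical_text)] = t.contact_rate
            rate_map[("hlidd", t.code.canonical_text)] = t.hlidd_rate
    return pd.DataFrame(
        {
            "code": [r.code.canonical_text for r in results],
            "outcome": [r.outcome for r in results],
            "n": [r.n for r in results],
            "rate": [
                rate_map.get((r.outcome, r.code.canonical_text), np.nan)
                for r in results
            ],
            "odds_ratio": [r.odds_ratio for r in results],
            "ci_low": [r.ci95[0] for r in results],
            "ci_high": [r.ci95[1] for r in results],
            "p_value": [r.p_value for r in results],
            "significantly_high": [r.significantly_high for r in results],
        }
    )
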