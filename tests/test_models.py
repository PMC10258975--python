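import math

import numpy as np
import pandas as pd
import pytest

import hemsdispatch as hd
from hemsdispatch.models import ModelDataset, ModelFitError
from conftest import make_records


@pytest.mark.parametrize(
    "cells, expected",
    [((90, 10, 50, 50), 9.0), ((10, 10, 10, 10), 1.0), ((10, 0, 10, 10), 21.0)],
)
def test_odds_ratio_closed_form(cells, expected):
    orr, ci = hd.odds_ratio_2x2(*cells)
    assert orr == pytest.approx(expected)
    assert ci[0] <= orr <= ci[1]


def test_odds_ratio_errors():
    with pytest.raises(ValueError):
        hd.odds_ratio_2x2(-1, 5, 5, 5)
    with pytest.raises(ValueError):
        hd.odds_ratio_2x2(0, 0, 5, 5)  # zero row margin
    with pytest.raises(ValueError):
        hd.odds_ratio_2x2(0, 5, 0, 5)  # zero column margin


@pytest.mark.parametrize(
    "age, expected",
    [(15.9, "lt16"), (16.0, "16to55"), (55.0, "16to55"), (55.1, "gt55"), (0.0, "lt16")],
)
def test_age_bins(age, expected):
    assert hd.assign_age_bin(age) == expected


def _patient(age, sex, hlidd):
    ivs = frozenset({"thoracostomy"}) if hlidd else frozenset()
    return hd.PatientOutcome.from_interventions(age, sex, ivs)


def _record(i, category="09", contact=True, patients=(), **kw):
    defaults = dict(dispatch_type="immediate", platform="helicopter",
                    shift="day", desk_ccp=True)
    defaults.update(kw)
    return hd.DispatchRecord(
        tasking_id=f"M{i}", code=hd.parse_code(f"{category}-E-01"),
        contact=contact, n_patients=len(patients), patients=tuple(patients),
        **defaults,
    )


def test_multi_patient_excluded_from_age_sex_only():
    records = [
        _record(0, patients=[_patient(40, "male", True)]),
        _record(1, patients=[_patient(30, "female", True), _patient(50, "male", False)]),
    ]
    ds = hd.prepare_category_dataset(records, "09", "hlidd", min_rows=1)
    assert ds.exclusions_log["multi_patient_age_sex"] == 1
    # the multi-patient tasking keeps shift/platform info but has missing
    # age/sex, so complete-case deletion drops it from the fitted frame
    assert ds.exclusions_log["listwise_deleted"] == 1
    assert ds.n_rows == 1


def test_hlidd_dataset_restricted_to_contacts():
    records = (
        [_record(i, patients=[_patient(40, "male", i % 2 == 0)]) for i in range(10)]
        + [_record(10 + i, contact=False) for i in range(5)]
    )
    contact_ds = hd.prepare_category_dataset(records, "09", "contact", min_rows=1)
    hlidd_ds = hd.prepare_category_dataset(records, "09", "hlidd", min_rows=1)
    assert contact_ds.n_rows == 15
    assert hlidd_ds.n_rows == 10
    assert hlidd_ds.n_rows <= contact_ds.frame["y"].sum()


def test_transgender_and_missing_sex_dropped_from_models():
    records = [
        _record(0, patients=[_patient(40, "transgender", True)]),
        _record(1, patients=[_patient(40, None, True)]),
        _record(2, patients=[_patient(40, "male", False)]),
    ]
    ds = hd.prepare_category_dataset(records, "09", "hlidd", min_rows=1)
    assert ds.n_rows == 1
    assert ds.exclusions_log["sex_missing"] == 2


def test_too_few_rows_marks_error_and_refuses_fit():
    records = [_record(0, patients=[_patient(40, "male", True)])]
    ds = hd.prepare_category_dataset(records, "09", "contact", min_rows=50)
    assert ds.error is not None
    with pytest.raises(ModelFitError):
        hd.fit_reduced_model(ds)


def _night_dataset(a, b, c, d):
    """Binary night-only dataset: night a/(a+b) events, day c/(c+d)."""
    frame = pd.DataFrame(
        {
            "y": [1] * a + [0] * b + [1] * c + [0] * d,
            "night": [1] * (a + b) + [0] * (c + d),
        }
    )
    return ModelDataset(category="09", outcome="contact", frame=frame,
                        terms=("night",))


def test_single_covariate_model_matches_2x2():
    """A one-binary-covariate logistic model reproduces the collapsed
    table's cross-product odds ratio to numerical precision."""
    a, b, c, d = 60, 40, 30, 70
    result = hd.fit_reduced_model(
        _night_dataset(a, b, c, d), univariate_prescreen=False, interactions=()
    )
    est = result.estimate("night")
    expected, ci = hd.odds_ratio_2x2(a, b, c, d)
    assert est is not None
    assert est.odds_ratio == pytest.approx(expected, rel=1e-6)
    assert est.ci95[0] == pytest.approx(ci[0], rel=1e-6)
    assert est.ci95[1] == pytest.approx(ci[1], rel=1e-6)


def test_null_term_eliminated():
    result = hd.fit_reduced_model(
        _night_dataset(50, 50, 50, 50), univariate_prescreen=False, interactions=()
    )
    assert result.retained_terms == []
    assert [t[0] for t in result.eliminated_terms] == ["night"]


def test_no_outcome_variation_raises():
    with pytest.raises(ModelFitError):
        hd.fit_reduced_model(_night_dataset(100, 0, 100, 0))


def _planted_night_study(seed, n_target=5000, or_night=0.6):
    code = hd.parse_code("09-E-01")
    prof = hd.CodeProfile(
        code=code, ems_annual_rate=n_target / 0.25 / 4,
        hems_dispatch_prob=0.25, contact_prob=0.6, hlidd_prob=0.6,
    )
    gen = hd.GeneratorConfig(
        n_codes=2, hems_rate_per_year=n_target / 4 + 20, study_days=1461,
        missing_code_prob=0.0, seed=seed,
    )
    eff = hd.EffectConfig(
        night_contact=math.log(or_night), rrv_contact=0.0, ccp_contact=0.0,
        night_hlidd=0.0, rrv_hlidd=0.0, male_hlidd=0.0,
        age_lt16_hlidd=0.0, age_gt55_hlidd=0.0,
    )
    universe = hd.build_code_universe(gen, [prof])
    return hd.simulate_hems_dispatches(universe, eff, gen)


def test_planted_night_effect_recovered_single_seed():
    records = _planted_night_study(seed=3)
    ds = hd.prepare_category_dataset(records, "09", "contact")
    result = hd.fit_reduced_model(ds)
    est = result.estimate("night")
    assert est is not None
    assert est.ci95[0] < 0.6 < est.ci95[1]
    assert result.retained_term_names == {"night"}


def test_retained_terms_are_significant():
    records = _planted_night_study(seed=9, n_target=3000)
    ds = hd.prepare_category_dataset(records, "09", "contact")
    result = hd.fit_reduced_model(ds)
    for t in result.retained_terms:
        if t.term in ("night", "rrv", "desk_ccp", "male"):
            assert t.p_value < 0.05
    for term, stage, p in result.eliminated_terms:
        assert p >= 0.05 or stage == "univariate"


def test_elimination_bounded_by_term_count():
    records = _planted_night_study(seed=5, n_target=2000)
    ds = hd.prepare_category_dataset(records, "09", "contact")
    result = hd.fit_reduced_model(ds, univariate_prescreen=False)
    assert len(result.eliminated_terms) + len(result.retained_term_names) == len(ds.terms)


def test_diagnostics_reported():
    records = _planted_night_study(seed=7, n_target=2000)
    ds = hd.prepare_category_dataset(records, "09", "contact")
    result = hd.fit_reduced_model(ds, univariate_prescreen=False)
    diag = result.diagnostics
    assert diag is not None
    assert diag.logit_linearity == "not_applicable"
    assert diag.cooks_cutoff == pytest.approx(4 / ds.n_rows)
    assert set(diag.vif_by_term) == {t.level for t in result.retained_terms} or diag.vif_by_term


def test_interaction_lr_test_runs():
    """With a strong planted night x platform interaction the LR test
    retains the product term."""
    rng = np.random.default_rng(13)
    n = 4000
    night = rng.integers(0, 2, n)
    rrv = rng.integers(0, 2, n)
    eta = 0.5 - 1.2 * night - 1.0 * rrv + 0.9 * night * rrv
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    frame = pd.DataFrame({"y": y, "night": night, "rrv": rrv})
    ds = ModelDataset(category="09", outcome="contact", frame=frame,
                      terms=("night", "rrv"))
    result = hd.fit_reduced_model(ds, univariate_prescreen=False)
    assert result.interaction_tests
    test = result.interaction_tests[0]
    assert test.terms == ("night", "rrv")
    assert test.retained and test.p_value < 0.05
    assert any(t.level == "night_x_rrv" for t in result.retained_terms)
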