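import math

import numpy as np
import pytest

import hemsdispatch as hd
from hemsdispatch.synthetic import default_planted_golden


def small_config(**overrides):
    base = dict(n_codes=30, hems_rate_per_year=600.0, study_days=365,
                reference_days=120, seed=17)
    base.update(overrides)
    return hd.GeneratorConfig(**base)


def test_same_seed_identical_universe_and_streams():
    cfg = small_config()
    u1 = hd.build_code_universe(cfg)
    u2 = hd.build_code_universe(cfg)
    assert u1 == u2
    assert hd.simulate_ems_reference_year(u1, cfg) == hd.simulate_ems_reference_year(u2, cfg)
    eff = hd.EffectConfig()
    assert hd.simulate_hems_dispatches(u1, eff, cfg) == hd.simulate_hems_dispatches(u2, eff, cfg)


def test_different_seed_differs():
    u1 = hd.build_code_universe(small_config(seed=1))
    u2 = hd.build_code_universe(small_config(seed=2))
    assert u1 != u2


def test_planted_profile_passes_through_unchanged():
    planted = hd.CodeProfile(
        code=hd.parse_code("09-E-01"), ems_annual_rate=100.0,
        hems_dispatch_prob=0.2, contact_prob=0.9, hlidd_prob=0.8,
        is_planted_golden=True,
    )
    universe = hd.build_code_universe(small_config(), [planted])
    match = [p for p in universe if p.code == planted.code]
    assert match == [planted]
    assert len(universe) == 30


def test_duplicate_planted_codes_rejected():
    p = default_planted_golden()
    with pytest.raises(ValueError, match="duplicate"):
        hd.build_code_universe(small_config(), [p[0], p[0]])


def test_heavy_tail_concentration_at_study_scale():
    """With the default dispersion the top 84 of 678 codes carry
    roughly four-fifths of the HEMS dispatch volume."""
    cfg = hd.GeneratorConfig(seed=23)
    universe = hd.build_code_universe(cfg)
    rates = np.sort([p.hems_annual_rate for p in universe])[::-1]
    share = rates[:84].sum() / rates.sum()
    assert 0.68 <= share <= 0.90


def test_poisson_count_scale():
    planted = hd.CodeProfile(
        code=hd.parse_code("09-E-01"), ems_annual_rate=365.0,
        hems_dispatch_prob=0.5, contact_prob=0.6, hlidd_prob=0.6,
    )
    cfg = small_config(n_codes=2, reference_days=365)
    universe = hd.build_code_universe(cfg, [planted])
    ems = hd.simulate_ems_reference_year(universe, cfg)
    count = sum(1 for r in ems if r.code == planted.code)
    assert abs(count - 365) <= 3 * math.sqrt(365)


def test_zero_dispatch_probability_never_dispatches():
    planted = hd.CodeProfile(
        code=hd.parse_code("09-E-01"), ems_annual_rate=500.0,
        hems_dispatch_prob=0.0, contact_prob=0.6, hlidd_prob=0.6,
    )
    cfg = small_config(n_codes=2)
    universe = hd.build_code_universe(cfg, [planted])
    ems = hd.simulate_ems_reference_year(universe, cfg)
    assert not any(r.hems_dispatched for r in ems if r.code == planted.code)


def test_dispatch_fraction_recovers_planted_probability():
    planted = hd.CodeProfile(
        code=hd.parse_code("09-E-01"), ems_annual_rate=2000.0,
        hems_dispatch_prob=0.25, contact_prob=0.6, hlidd_prob=0.6,
    )
    cfg = small_config(n_codes=2, reference_days=365)
    universe = hd.build_code_universe(cfg, [planted])
    ems = [r for r in hd.simulate_ems_reference_year(universe, cfg)
           if r.code == planted.code]
    frac = sum(r.hems_dispatched for r in ems) / len(ems)
    se = math.sqrt(0.25 * 0.75 / len(ems))
    assert abs(frac - 0.25) <= 3 * se


def test_contact_and_hlidd_rates_recover_planted_values():
    """Per-code empirical rates converge on the planted probabilities
    when covariate effects are switched off."""
    planted = hd.CodeProfile(
        code=hd.parse_code("29-D-06"), ems_annual_rate=4000.0,
        hems_dispatch_prob=0.5, contact_prob=0.7, hlidd_prob=0.4,
    )
    cfg = small_config(n_codes=2, study_days=730, missing_code_prob=0.0,
                       hems_rate_per_year=2200.0)
    universe = hd.build_code_universe(cfg, [planted])
    records = [
        r for r in hd.simulate_hems_dispatches(universe, hd.EffectConfig.null(), cfg)
        if r.code == planted.code
    ]
    (tally,) = [t for t in hd.tally_codes(records) if t.code == planted.code]
    se_c = math.sqrt(0.7 * 0.3 / tally.n_dispatch)
    assert abs(tally.contact_rate - 0.7) <= 3 * se_c
    se_h = math.sqrt(0.4 * 0.6 / tally.n_contact)
    assert abs(tally.hlidd_rate - 0.4) <= 3 * se_h


def test_degenerate_contact_probability_one():
    planted = hd.CodeProfile(
        code=hd.parse_code("09-E-01"), ems_annual_rate=500.0,
        hems_dispatch_prob=0.8, contact_prob=1.0, hlidd_prob=0.5,
    )
    cfg = small_config(n_codes=2)
    universe = hd.build_code_universe(cfg, [planted])
    records = [
        r for r in hd.simulate_hems_dispatches(universe, hd.EffectConfig(), cfg)
        if r.code == planted.code or r.code is None
    ]
    coded = [r for r in records if r.code is not None]
    assert coded and all(r.contact for r in coded)


def test_patient_conservation():
    """Every generated patient belongs to exactly one contact tasking."""
    cfg = small_config(hems_rate_per_year=2000.0)
    universe = hd.build_code_universe(cfg)
    records = hd.simulate_hems_dispatches(universe, hd.EffectConfig(), cfg)
    for r in records:
        assert len(r.patients) == r.n_patients
        if not r.contact:
            assert r.n_patients == 0
        else:
            assert r.n_patients in (1, 2)
    assert any(r.n_patients == 2 for r in records)


def test_default_marginals_near_study_shares():
    cfg = hd.GeneratorConfig(n_codes=100, hems_rate_per_year=4000.0,
                             study_days=365, seed=29)
    universe = hd.build_code_universe(cfg)
    records = hd.simulate_hems_dispatches(universe, hd.EffectConfig(), cfg)
    n = len(records)
    day = sum(r.shift == "day" for r in records) / n
    heli = sum(r.platform == "helicopter" for r in records) / n
    patients = [p for r in records for p in r.patients]
    male = sum(p.sex == "male" for p in patients) / len(patients)
    assert abs(day - 0.717) < 0.03
    assert abs(heli - 0.641) < 0.03
    assert abs(male - 0.661) < 0.03  # about two-thirds male


def test_intervention_sets_consistent_with_hlidd_flag():
    cfg = small_config(hems_rate_per_year=1500.0)
    universe = hd.build_code_universe(cfg)
    records = hd.simulate_hems_dispatches(universe, hd.EffectConfig(), cfg)
    for r in records:
        for p in r.patients:
            assert p.hlidd == hd.classify_hlidd(p.interventions)
            if r.platform == "rrv":
                assert "helicopter_conveyance" not in p.interventions


def test_planted_golden_defaults_satisfy_criteria_with_margin():
    for p in default_planted_golden():
        assert p.contact_prob >= 0.8 and p.hlidd_prob >= 0.8
        assert p.hems_dispatch_prob > 0.2
    load = sum(p.ems_annual_rate for p in default_planted_golden()) / 365
    assert 10 < load < 20
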