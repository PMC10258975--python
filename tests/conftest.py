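import pytest

import hemsdispatch as hd


def make_records(code_text, n_dispatch, n_contact, n_hlidd, start_id=0,
                 **overrides):
    """Build dispatch records with given per-code outcome counts.

    The first ``n_hlidd`` contact taskings carry an HLIDD patient
    (endotracheal tube), the next ``n_contact - n_hlidd`` a non-HLIDD
    patient, the rest are stand-downs.
    """
    code = hd.parse_code(code_text) if code_text else None
    defaults = dict(dispatch_type="immediate", platform="helicopter",
                    shift="day", desk_ccp=True)
    defaults.update(overrides)
    records = []
    for i in range(n_dispatch):
        contact = i < n_contact
        patients = ()
        if contact:
            ivs = frozenset({"endotracheal_tube"}) if i < n_hlidd else frozenset()
            patients = (
                hd.PatientOutcome.from_interventions(40.0, "male", ivs),
            )
        records.append(
            hd.DispatchRecord(
                tasking_id=f"R{start_id + i:06d}",
                code=code,
                contact=contact,
                n_patients=1 if contact else 0,
                patients=patients,
                **defaults,
            )
        )
    return records


def make_reference(code_text, n_ems, n_dispatched):
    code = hd.parse_code(code_text)
    return [
        hd.EmsReferenceRecord(code, i < n_dispatched) for i in range(n_ems)
    ]


@pytest.fixture(scope="session")
def planted_study():
    """A mid-sized synthetic study with the nine planted golden codes."""
    gen = hd.GeneratorConfig(n_codes=200, hems_rate_per_year=6000.0, seed=11)
    planted = hd.default_planted_golden()
    universe = hd.build_code_universe(gen, planted)
    records = hd.simulate_hems_dispatches(universe, hd.EffectConfig(), gen)
    ems = hd.simulate_ems_reference_year(universe, gen)
    tallies = hd.tally_codes(records)
    eligible, pool = hd.split_eligible(tallies)
    screening = hd.screen_outcome(records, eligible, "contact") + hd.screen_outcome(
        records, eligible, "hlidd"
    )
    utility = hd.system_utility(ems)
    cells = hd.evaluate_grid(tallies, screening, utility, ems)
    return {
        "config": gen,
        "universe": universe,
        "planted": planted,
        "records": records,
        "ems": ems,
        "tallies": tallies,
        "eligible": eligible,
        "pool": pool,
        "screening": screening,
        "utility": utility,
        "cells": cells,
    }
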