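import numpy as np
import pytest

import hemsdispatch as hd
from conftest import make_records, make_reference
from hemsdispatch.selection import grid_to_frame


def utility_result(text, ems, dispatched, threshold=0.10):
    (res,) = hd.system_utility(make_reference(text, ems, dispatched), threshold)
    return res


def screen_result(text, flagged=True, outcome="contact"):
    return hd.ScreeningResult(
        code=hd.parse_code(text), outcome=outcome,
        odds_ratio=3.0 if flagged else 1.0, ci95=(2.0, 4.5) if flagged else (0.8, 1.2),
        p_value=0.001 if flagged else 0.8, significantly_high=flagged, n=100,
    )


@pytest.mark.parametrize(
    "ems, dispatched, fraction, passes",
    [(100, 11, 0.11, True), (100, 10, 0.10, False), (100, 0, 0.0, False)],
)
def test_system_utility_strict_threshold(ems, dispatched, fraction, passes):
    res = utility_result("09-E-01", ems, dispatched)
    assert res.hems_dispatch_fraction == pytest.approx(fraction)
    assert res.passes is passes


def test_system_utility_reports_workload_share():
    refs = make_reference("09-E-01", 100, 40) + make_reference("17-D-06", 100, 60)
    results = {r.code.canonical_text: r for r in hd.system_utility(refs)}
    assert results["09-E-01"].hems_workload_share == pytest.approx(0.4)


def make_tally(text, n_dispatch, n_contact, n_hlidd):
    return hd.CodeTally(hd.parse_code(text), n_dispatch, n_contact, n_hlidd)


def test_selection_rule_branches():
    # (0.75, 0.40): selected via the contact branch
    # (0.65, 0.72): selected via the HLIDD branch
    # (0.90, 0.90) but utility 0.05: vetoed
    tallies = [
        make_tally("09-E-01", 100, 75, 30),
        make_tally("17-D-06", 100, 65, 47),  # hlidd rate 47/65 ~ 0.723
        make_tally("29-D-06", 100, 90, 81),
    ]
    screening = [screen_result(t) for t in ("09-E-01", "17-D-06", "29-D-06")]
    utility = [
        utility_result("09-E-01", 100, 20),
        utility_result("17-D-06", 100, 20),
        utility_result("29-D-06", 100, 5),
    ]
    selected = hd.select_codes(tallies, screening, utility, 0.7, 0.7)
    assert {c.canonical_text for c in selected} == {"09-E-01", "17-D-06"}


def test_unflagged_code_never_selected():
    tallies = [make_tally("09-E-01", 100, 90, 80)]
    utility = [utility_result("09-E-01", 100, 50)]
    selected = hd.select_codes(
        tallies, [screen_result("09-E-01", flagged=False)], utility, 0.6, 0.6
    )
    assert selected == frozenset()


def test_code_absent_from_reference_fails_utility(caplog):
    tallies = [make_tally("09-E-01", 100, 90, 80)]
    selected = hd.select_codes(
        tallies, [screen_result("09-E-01")], [], 0.6, 0.6
    )
    assert selected == frozenset()


def test_zero_contact_code_fails_hlidd_threshold():
    tallies = [make_tally("09-E-01", 100, 0, 0)]
    utility = [utility_result("09-E-01", 100, 50)]
    selected = hd.select_codes(
        tallies, [screen_result("09-E-01")], utility, 1.01, 0.6
    )
    assert selected == frozenset()


def test_projection_arithmetic():
    refs = make_reference("09-E-01", 6205, 100) + make_reference("17-D-06", 1000, 10)
    codes = frozenset({hd.parse_code("09-E-01")})
    assert hd.project_taskings_per_day(codes, "ems_reference", refs, 365) == pytest.approx(17.0)
    assert hd.project_taskings_per_day(frozenset(), "ems_reference", refs, 365) == 0.0


def test_projection_hems_historical_basis():
    tallies = [make_tally("09-E-01", 730, 400, 100)]
    codes = frozenset({hd.parse_code("09-E-01")})
    assert hd.project_taskings_per_day(codes, "hems_historical", tallies, 365) == 2.0


def test_vacuous_thresholds_select_nothing(planted_study):
    cells = hd.evaluate_grid(
        planted_study["tallies"], planted_study["screening"],
        planted_study["utility"], planted_study["ems"],
        grid=((1.0, 1.0),), period_days=planted_study["config"].reference_days,
    )
    (cell,) = cells
    # no code achieves a 100% rate at study scale
    assert cell.selected_codes == frozenset()
    assert cell.projected_taskings_per_day == 0.0
    assert not cell.within_target


def test_grid_monotonicity(planted_study):
    """Raising either threshold never adds codes nor load."""
    cells = planted_study["cells"]
    for a in cells:
        for b in cells:
            if b.theta_contact >= a.theta_contact and b.theta_hlidd >= a.theta_hlidd:
                assert b.selected_codes <= a.selected_codes
                assert (
                    b.projected_taskings_per_day <= a.projected_taskings_per_day + 1e-12
                )


def test_selection_soundness(planted_study):
    """Every selected code is flagged, utility-passing and satisfies the
    rate rule - re-checked here code by code against the raw inputs."""
    flagged = {
        r.code.canonical_text
        for r in planted_study["screening"]
        if r.significantly_high
    }
    util = {u.code.canonical_text: u.passes for u in planted_study["utility"]}
    tallies = {t.code.canonical_text: t for t in planted_study["tallies"]}
    for cell in planted_study["cells"]:
        for code in cell.selected_codes:
            text = code.canonical_text
            t = tallies[text]
            assert text in flagged
            assert util[text]
            hlidd_ok = t.hlidd_rate is not None and t.hlidd_rate >= cell.theta_hlidd
            assert t.contact_rate >= cell.theta_contact or hlidd_ok


def test_derive_single_within_target_cell():
    codes = frozenset({hd.parse_code("09-E-01")})
    cells = [
        hd.GridCell(0.6, 0.6, codes, 25.0, False),
        hd.GridCell(0.7, 0.7, codes, 15.0, True),
    ]
    golden = hd.derive_golden_codes(cells)
    assert golden.codes == codes
    assert (golden.theta_contact, golden.theta_hlidd) == (0.7, 0.7)


def test_derive_prefers_highest_thresholds():
    codes = frozenset({hd.parse_code("09-E-01")})
    cells = [
        hd.GridCell(0.6, 0.6, codes, 15.0, True),
        hd.GridCell(0.8, 0.7, codes, 14.0, True),
        hd.GridCell(0.7, 0.8, codes, 14.0, True),
    ]
    golden = hd.derive_golden_codes(cells)
    assert (golden.theta_contact, golden.theta_hlidd) == (0.8, 0.7)


def test_derive_errors_when_no_cell_in_target():
    cells = [hd.GridCell(0.6, 0.6, frozenset(), 0.0, False)]
    with pytest.raises(hd.NoCellWithinTargetError):
        hd.derive_golden_codes(cells)


def test_derive_explicit_policy():
    codes = frozenset({hd.parse_code("09-E-01")})
    cells = [hd.GridCell(0.6, 0.6, codes, 25.0, False)]
    golden = hd.derive_golden_codes(cells, policy=(0.6, 0.6))
    assert golden.codes == codes
    assert golden.provenance["policy"] == "explicit"


def test_grid_export_shape(planted_study):
    frame = grid_to_frame(planted_study["cells"])
    assert len(frame) == 16
    assert list(frame.columns) == [
        "theta_contact", "theta_hlidd", "n_codes",
        "projected_taskings_per_day", "within_target",
    ]
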