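"""System-utility filter, threshold grid, and golden-code derivation.

A code has *high system utility* when strictly more than 10% of the
whole-system EMS taskings carrying that code led to a HEMS dispatch in
the reference year.  The derivation then sweeps paired patient-contact
and HLIDD rate thresholds (default grid {0.6, 0.7, 0.8, 0.9} squared):
a code is selected at (theta_c, theta_h) when it

* was flagged significantly high on either screen, and
* passes the system-utility filter, and
* has contact rate >= theta_c OR HLIDD rate >= theta_h (inclusive).

Each grid cell projects the daily tasking load its selection implies.
The default basis counts the selected codes' taskings in the EMS
reference stream - the load if every such call triggered an immediate
HEMS dispatch; the alternative ``hems_historical`` basis divides the
historical HEMS dispatch count by the study period.  The *golden* set
is the selection of the highest-threshold cell whose projected load
falls inside the 10-20 dispatches/24 h operating target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .records import AmpdsCode, DispatchRecord, EmsReferenceRecord
from .screening import CodeTally, ScreeningResult

__all__ = [
    "SystemUtilityResult",
    "GridCell",
    "GoldenCodeSet",
    "NoCellWithinTargetError",
    "system_utility",
    "select_codes",
    "project_taskings_per_day",
    "evaluate_grid",
    "derive_golden_codes",
    "DEFAULT_GRID",
    "DEFAULT_TARGET",
]

logger = logging.getLogger(__name__)

DEFAULT_UTILITY_THRESHOLD = 0.10
DEFAULT_GRID: tuple[tuple[float, float], ...] = tuple(
    (tc / 10, th / 10) for tc in (6, 7, 8, 9) for th in (6, 7, 8, 9)
)
DEFAULT_TARGET = (10.0, 20.0)


class NoCellWithinTargetError(RuntimeError):
    """No grid cell projects inside the tasking target; expand the grid
    or revisit the target range rather than silently taking the nearest."""


@dataclass(frozen=True, slots=True)
class SystemUtilityResult:
    """Per-code HEMS-dispatch fraction of the EMS reference stream.

    ``hems_workload_share`` is the code's share of all HEMS dispatches
    in the reference stream - a different utility notion sometimes used
    descriptively; it plays no part in the filter.
    """

    code: AmpdsCode
    ems_count: int
    hems_dispatched_count: int
    hems_dispatch_fraction: float
    passes: bool
    hems_workload_share: float = float("nan")


@dataclass(frozen=True, slots=True)
class GridCell:
    theta_contact: float
    theta_hlidd: float
    selected_codes: frozenset[AmpdsCode]
    projected_taskings_per_day: float
    within_target: bool


@dataclass(frozen=True, slots=True)
class GoldenCodeSet:
    codes: frozenset[AmpdsCode]
    theta_contact: float
    theta_hlidd: float
    projected_taskings_per_day: float
    provenance: dict = field(default_factory=dict)


def system_utility(
    ems_reference: list[EmsReferenceRecord],
    threshold: float = DEFAULT_UTILITY_THRESHOLD,
) -> list[SystemUtilityResult]:
    """Per-code dispatch fraction with a strict ``> threshold`` pass rule."""
    if not ems_reference:
        raise ValueError("EMS reference stream must be non-empty")
    frame = pd.DataFrame(
        {
            "code": [r.code.canonical_text for r in ems_reference],
            "hems": [r.hems_dispatched for r in ems_reference],
        }
    )
    by_code = {r.code.canonical_text: r.code for r in ems_reference}
    grouped = frame.groupby("code", sort=True)["hems"].agg(["size", "sum"])
    total_hems = int(grouped["sum"].sum())
    out = []
    for text, row in grouped.iterrows():
        n, s = int(row["size"]), int(row["sum"])
        frac = s / n
        out.append(
            SystemUtilityResult(
                code=by_code[text],
                ems_count=n,
                hems_dispatched_count=s,
                hems_dispatch_fraction=frac,
                passes=frac > threshold,
                hems_workload_share=(s / total_hems) if total_hems else float("nan"),
            )
        )
    return out


def select_codes(
    tallies: list[CodeTally],
    screening: list[ScreeningResult],
    utility: list[SystemUtilityResult],
    theta_contact: float,
    theta_hlidd: float,
) -> frozenset[AmpdsCode]:
    """Apply the three-part selection rule at one threshold pair.

    Codes absent from the EMS reference stream cannot demonstrate
    system utility: they fail the filter and a warning is logged.
    """
    flagged = {
        r.code.canonical_text for r in screening if r.significantly_high
    }
    util_pass = {u.code.canonical_text: u.passes for u in utility}
    selected = set()
    for t in tallies:
        text = t.code.canonical_text
        if text not in flagged:
            continue
        if text not in util_pass:
            logger.warning(
                "code %s absent from EMS reference; utility undefined, treated as failing",
                text,
            )
            continue
        if not util_pass[text]:
            continue
        contact_ok = t.contact_rate >= theta_contact
        hr = t.hlidd_rate
        hlidd_ok = (theta_hlidd == 0.0) if hr is None else hr >= theta_hlidd
        if contact_ok or hlidd_ok:
            selected.add(t.code)
    return frozenset(selected)


def project_taskings_per_day(
    codes: frozenset[AmpdsCode] | set[AmpdsCode],
    basis: str,
    data,
    period_days: int,
) -> float:
    """Daily tasking load projected for a code set.

    ``ems_reference`` basis: ``data`` is the EMS reference stream; every
    reference tasking with a selected code counts (projected immediate
    dispatch).  ``hems_historical`` basis: ``data`` is either dispatch
    records or tallies; historical HEMS dispatches to the codes count.
    """
    if period_days < 1:
        raise ValueError("period_days must be >= 1")
    if not codes:
        return 0.0
    texts = {c.canonical_text for c in codes}
    if basis == "ems_reference":
        n = sum(1 for r in data if r.code.canonical_text in texts)
    elif basis == "hems_historical":
        if data and isinstance(data[0], CodeTally):
            n = sum(t.n_dispatch for t in data if t.code.canonical_text in texts)
        else:
            n = sum(
                1 for r in data
                if r.code is not None and r.code.canonical_text in texts
            )
    else:
        raise ValueError(f"unknown projection basis {basis!r}")
    return n / period_days


def evaluate_grid(
    tallies: list[CodeTally],
    screening: list[ScreeningResult],
    utility: list[SystemUtilityResult],
    data,
    *,
    grid: tuple[tuple[float, float], ...] = DEFAULT_GRID,
    target: tuple[float, float] = DEFAULT_TARGET,
    basis: str = "ems_reference",
    period_days: int = 365,
) -> list[GridCell]:
    """One :class:`GridCell` per threshold pair."""
    if not grid:
        raise ValueError("grid must be non-empty")
    cells = []
    for tc, th in grid:
        codes = select_codes(tallies, screening, utility, tc, th)
        projected = project_taskings_per_day(codes, basis, data, period_days)
        cells.append(
            GridCell(
                theta_contact=tc,
                theta_hlidd=th,
                selected_codes=codes,
                projected_taskings_per_day=projected,
                within_target=target[0] <= projected <= target[1],
            )
        )
    return cells


def derive_golden_codes(
    grid_cells: list[GridCell],
    policy: str | tuple[float, float] = "smallest_within_target",
) -> GoldenCodeSet:
    """Package the golden set from an evaluated grid.

    Default policy: among within-target cells take the one with the
    highest thresholds (largest theta sum, ties broken toward higher
    theta_contact) - the smallest, most specific selection that still
    meets the operating target.  An explicit ``(theta_c, theta_h)`` pair
    may be passed instead.
    """
    if isinstance(policy, tuple):
        for cell in grid_cells:
            if (cell.theta_contact, cell.theta_hlidd) == policy:
                return _package(cell, policy="explicit")
        raise ValueError(f"threshold pair {policy} not in the evaluated grid")
    if policy != "smallest_within_target":
        raise ValueError(f"unknown policy {policy!r}")
    within = [c for c in grid_cells if c.within_target]
    if not within:
        raise NoCellWithinTargetError(
            "no threshold pair projects inside the tasking target; "
            "expand the grid or reconsider the target range"
        )
    best = max(
        within,
        key=lambda c: (c.theta_contact + c.theta_hlidd, c.theta_contact),
    )
    return _package(best, policy="smallest_within_target")


def _package(cell: GridCell, policy: str) -> GoldenCodeSet:
    return GoldenCodeSet(
        codes=cell.selected_codes,
        theta_contact=cell.theta_contact,
        theta_hlidd=cell.theta_hlidd,
        projected_taskings_per_day=cell.projected_taskings_per_day,
        provenance={
            "policy": policy,
            "within_target": cell.within_target,
        },
    )


def grid_to_frame(cells: list[GridCell]) -> pd.DataFrame:
    """Sensitivity-grid export (theta_c, theta_h, n_codes, projected, flag)."""
    return pd.DataFrame(
        {
            "theta_contact": [c.theta_contact for c in cells],
            "theta_hlidd": [c.theta_hlidd for c in cells],
            "n_codes": [len(c.selected_codes) for c in cells],
            "projected_taskings_per_day": [
                c.projected_taskings_per_day for c in cells
            ],
            "within_target": [c.within_target for c in cells],
        }
    )
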