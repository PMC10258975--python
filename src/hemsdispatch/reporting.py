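"""Descriptive summaries, pipeline orchestration, and report writing.

``run_pipeline`` executes the whole derivation: load or simulate the
two streams, tally codes, run both logistic screens, apply the
system-utility filter, sweep the threshold grid, derive the golden
code set, and fit the per-category covariate models.  Every stage's
attrition and decisions are carried in the returned bundle, and a run
manifest (config hash, seed, package version) makes runs auditable.
Percentages in summary tables are rounded half-up to one decimal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import ReadResult, read_dispatch_records, read_ems_reference
from .models import (
    DEFAULT_INTERACTIONS,
    CovariateModelResult,
    ModelFitError,
    fit_reduced_model,
    models_to_frame,
    prepare_category_dataset,
)
from .records import DEFAULT_REGISTRY, DispatchRecord, HliddRegistry
from .screening import (
    DEFAULT_MIN_DISPATCHES,
    CodeTally,
    ScreeningResult,
    screen_outcome,
    screening_to_frame,
    split_eligible,
    tally_codes,
)
from .selection import (
    DEFAULT_GRID,
    DEFAULT_TARGET,
    DEFAULT_UTILITY_THRESHOLD,
    GoldenCodeSet,
    GridCell,
    SystemUtilityResult,
    derive_golden_codes,
    evaluate_grid,
    grid_to_frame,
    system_utility,
)
from .synthetic import (
    CodeProfile,
    EffectConfig,
    GeneratorConfig,
    build_code_universe,
    simulate_ems_reference_year,
    simulate_hems_dispatches,
)

__all__ = [
    "RunConfig",
    "SummaryTable",
    "ReportBundle",
    "PipelineError",
    "percent",
    "summarize_dispatches",
    "run_pipeline",
    "write_bundle",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def percent(numerator: float, denominator: float) -> float:
    """Percentage rounded half-up to one decimal (table style)."""
    if denominator == 0:
        return float("nan")
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class SummaryTable:
    """Descriptive analogue of the dispatch and HLIDD frequency tables."""

    n_dispatches: int
    dispatch_type: dict[str, tuple[int, float]]  # name -> (count, pct)
    characteristics: dict[str, tuple[int, float]]
    categories: list[tuple[str, int, float]]  # sorted by frequency
    n_contacts: int
    median_age: float
    age_iqr: tuple[float, float]
    sex_counts: dict[str, tuple[int, float]]
    n_hlidd_patients: int
    hlidd_table: list[tuple[str, int, float]]  # (identifier, count, pct of HLIDD patients)


def summarize_dispatches(
    records: list[DispatchRecord],
    *,
    hlidd_min_patients: int = 400,
) -> SummaryTable:
    """Descriptive counts over coded dispatches, attended patients and
    HLIDD frequency (identifiers received by more than
    ``hlidd_min_patients`` patients; lower it for small datasets)."""
    coded = [r for r in records if r.code is not None]
    n = len(coded)

    def pair(count: int, denom: int) -> tuple[int, float]:
        return count, percent(count, denom)

    dispatch_type = {
        k: pair(sum(1 for r in coded if r.dispatch_type == k), n)
        for k in ("immediate", "interrogate", "crew_request")
    }
    characteristics = {
        "ccp_in_dispatch_team": pair(sum(1 for r in coded if r.desk_ccp), n),
        "day_shift": pair(sum(1 for r in coded if r.shift == "day"), n),
        "helicopter": pair(sum(1 for r in coded if r.platform == "helicopter"), n),
        "rrv": pair(sum(1 for r in coded if r.platform == "rrv"), n),
    }
    cat_counts: dict[str, int] = {}
    for r in coded:
        cat_counts[r.code.category] = cat_counts.get(r.code.category, 0) + 1
    categories = sorted(
        ((c, k, percent(k, n)) for c, k in cat_counts.items()),
        key=lambda row: (-row[1], row[0]),
    )

    patients = [p for r in coded if r.contact for p in r.patients]
    n_contacts = sum(1 for r in coded if r.contact)
    ages = np.array([p.age_years for p in patients if p.age_years is not None])
    median_age = float(np.median(ages)) if ages.size else float("nan")
    iqr = (
        (float(np.percentile(ages, 25)), float(np.percentile(ages, 75)))
        if ages.size
        else (float("nan"), float("nan"))
    )
    n_pat = len(patients)
    sex_counts = {
        k: pair(sum(1 for p in patients if p.sex == k), n_pat)
        for k in ("male", "female", "transgender")
    }
    sex_counts["missing"] = pair(sum(1 for p in patients if p.sex is None), n_pat)

    hlidd_patients = [p for p in patients if p.hlidd]
    n_hlidd = len(hlidd_patients)
    iv_counts: dict[str, int] = {}
    for p in hlidd_patients:
        for iv in p.interventions:
            iv_counts[iv] = iv_counts.get(iv, 0) + 1
    hlidd_table = sorted(
        (
            (iv, k, percent(k, n_hlidd))
            for iv, k in iv_counts.items()
            if k > hlidd_min_patients
        ),
        key=lambda row: (-row[1], row[0]),
    )
    return SummaryTable(
        n_dispatches=n,
        dispatch_type=dispatch_type,
        characteristics=characteristics,
        categories=categories,
        n_contacts=n_contacts,
        median_age=median_age,
        age_iqr=iqr,
        sex_counts=sex_counts,
        n_hlidd_patients=n_hlidd,
        hlidd_table=hlidd_table,
    )


@dataclass
class RunConfig:
    """Pipeline configuration: either file inputs or generator settings."""

    dispatch_path: str | None = None
    ems_reference_path: str | None = None
    generator: GeneratorConfig | None = None
    effects: EffectConfig = field(default_factory=EffectConfig)
    planted: tuple[CodeProfile, ...] = ()
    registry: HliddRegistry = DEFAULT_REGISTRY
    min_dispatches: int = DEFAULT_MIN_DISPATCHES
    utility_threshold: float = DEFAULT_UTILITY_THRESHOLD
    grid: tuple[tuple[float, float], ...] = DEFAULT_GRID
    target: tuple[float, float] = DEFAULT_TARGET
    projection_basis: str = "ems_reference"
    reference_days: int = 365
    categories: tuple[str, ...] | int = 10  # explicit list or top-N by frequency
    interactions: tuple[tuple[str, str], ...] = DEFAULT_INTERACTIONS
    fit_covariate_models: bool = True
    hlidd_min_patients: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.dispatch_path is not None and self.ems_reference_path is not None
        if not has_files and self.generator is None:
            raise ValueError("need input paths or generator settings")
        if not self.grid:
            raise ValueError("grid must be non-empty")
        if not 0 <= self.utility_threshold < 1:
            raise ValueError("utility_threshold must be in [0,1)")
        if self.target[0] > self.target[1]:
            raise ValueError("target range inverted")

    def manifest(self) -> dict:
        payload = json.dumps(
            dataclasses.asdict(
                dataclasses.replace(self, registry=None)  # type: ignore[arg-type]
            ),
            default=str,
            sort_keys=True,
        )
        return {
            "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
            "seed": self.seed,
            "package_version": __version__,
        }


@dataclass
class ReportBundle:
    summary: SummaryTable
    tallies: list[CodeTally]
    screening_contact: list[ScreeningResult]
    screening_hlidd: list[ScreeningResult]
    utility: list[SystemUtilityResult]
    grid_cells: list[GridCell]
    golden: GoldenCodeSet
    covariate_models: list[CovariateModelResult]
    attrition: dict[str, int]
    manifest: dict


def _top_categories(tallies: list[CodeTally], n: int) -> tuple[str, ...]:
    counts: dict[str, int] = {}
    for t in tallies:
        counts[t.code.category] = counts.get(t.code.category, 0) + t.n_dispatch
    ranked = sorted(counts, key=lambda c: (-counts[c], c))
    return tuple(ranked[:n])


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full derivation; stage errors carry the stage name."""
    attrition: dict[str, int] = {}
    try:
        if config.generator is not None:
            gen = dataclasses.replace(config.generator, seed=config.seed)
            universe = build_code_universe(gen, list(config.planted))
            ems_reference = simulate_ems_reference_year(universe, gen)
            records = simulate_hems_dispatches(
                universe, config.effects, gen, registry=config.registry
            )
            reference_days = gen.reference_days
            study_days = gen.study_days
            attrition["uncoded_dispatches"] = sum(1 for r in records if r.code is None)
        else:
            result = read_dispatch_records(
                config.dispatch_path, registry=config.registry
            )
            records = result.records
            attrition.update(result.attrition)
            ems_reference = read_ems_reference(config.ems_reference_path)
            reference_days = config.reference_days
            study_days = None
    except (OSError, ValueError) as exc:
        raise PipelineError("load", str(exc)) from exc

    try:
        summary = summarize_dispatches(
            records, hlidd_min_patients=config.hlidd_min_patients
        )
        tallies = tally_codes(records)
        eligible, pool = split_eligible(tallies, config.min_dispatches)
        attrition["codes_pooled_below_threshold"] = len(pool)
    except ValueError as exc:
        raise PipelineError("tally", str(exc)) from exc

    try:
        scr_contact = screen_outcome(records, eligible, "contact")
        scr_hlidd = screen_outcome(records, eligible, "hlidd")
    except Exception as exc:
        raise PipelineError("screen", str(exc)) from exc

    try:
        util = system_utility(ems_reference, config.utility_threshold)
        cells = evaluate_grid(
            tallies,
            scr_contact + scr_hlidd,
            util,
            ems_reference if config.projection_basis == "ems_reference" else records,
            grid=config.grid,
            target=config.target,
            basis=config.projection_basis,
            period_days=(
                reference_days
                if config.projection_basis == "ems_reference"
                else (study_days or config.reference_days)
            ),
        )
        golden = derive_golden_codes(cells)
    except Exception as exc:
        raise PipelineError("select", str(exc)) from exc

    models: list[CovariateModelResult] = []
    if config.fit_covariate_models:
        cats = (
            _top_categories(tallies, config.categories)
            if isinstance(config.categories, int)
            else config.categories
        )
        for cat in cats:
            for outcome in ("contact", "hlidd"):
                ds = prepare_category_dataset(records, cat, outcome)
                if ds.error is not None:
                    attrition[f"model_skipped_{cat}_{outcome}"] = 1
                    continue
                try:
                    models.append(
                        fit_reduced_model(ds, interactions=config.interactions)
                    )
                except ModelFitError as exc:
                    logger.warning("model %s/%s not fitted: %s", cat, outcome, exc)
                    attrition[f"model_failed_{cat}_{outcome}"] = 1

    return ReportBundle(
        summary=summary,
        tallies=tallies,
        screening_contact=scr_contact,
        screening_hlidd=scr_hlidd,
        utility=util,
        grid_cells=cells,
        golden=golden,
        covariate_models=models,
        attrition=attrition,
        manifest=config.manifest(),
    )


def write_bundle(bundle: ReportBundle, outdir: str | Path) -> None:
    """Write CSV tables, the golden-set JSON and a plain-text run log."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tallies = bundle.tallies
    pd.DataFrame(
        {
            "code": [t.code.canonical_text for t in tallies],
            "n_dispatch": [t.n_dispatch for t in tallies],
            "n_contact": [t.n_contact for t in tallies],
            "n_hlidd": [t.n_hlidd for t in tallies],
            "contact_rate": [t.contact_rate for t in tallies],
            "hlidd_rate": [t.hlidd_rate for t in tallies],
        }
    ).to_csv(out / "code_tallies.csv", index=False)
    screening_to_frame(
        bundle.screening_contact + bundle.screening_hlidd, tallies
    ).to_csv(out / "screening.csv", index=False)
    pd.DataFrame(
        {
            "code": [u.code.canonical_text for u in bundle.utility],
            "ems_count": [u.ems_count for u in bundle.utility],
            "hems_dispatched_count": [u.hems_dispatched_count for u in bundle.utility],
            "hems_dispatch_fraction": [u.hems_dispatch_fraction for u in bundle.utility],
            "hems_workload_share": [u.hems_workload_share for u in bundle.utility],
            "passes": [u.passes for u in bundle.utility],
        }
    ).to_csv(out / "system_utility.csv", index=False)
    grid_to_frame(bundle.grid_cells).to_csv(out / "threshold_grid.csv", index=False)
    golden = {
        "codes": sorted(c.canonical_text for c in bundle.golden.codes),
        "theta_contact": bundle.golden.theta_contact,
        "theta_hlidd": bundle.golden.theta_hlidd,
        "projected_taskings_per_day": bundle.golden.projected_taskings_per_day,
        "provenance": {**bundle.golden.provenance, "manifest": bundle.manifest},
    }
    (out / "golden_codes.json").write_text(json.dumps(golden, indent=2))
    if bundle.covariate_models:
        models_to_frame(bundle.covariate_models).to_csv(
            out / "covariate_models.csv", index=False
        )
    log_lines = [f"{k}: {v}" for k, v in sorted(bundle.attrition.items())]
    log_lines.append(f"manifest: {json.dumps(bundle.manifest, sort_keys=True)}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
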