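"""National and global extrapolation of institute-level emissions.

Pathology case counts are not registered nationally or globally, so the
model anchors on one institute's census — its yearly cancer case count and
total (cancer + non-cancer) case count — and scales a region's cancer-case
count (e.g. from the Global Burden of Disease study) by the institute's
total-to-cancer ratio, a simple cross-multiplication of proportions:

    total_cases(region) = cancer_cases(region) x total_inst / cancer_inst

Each region's emission is then its extrapolated case count times the
institute's mean per-case emission, converted at the region's own grid
intensity. Extrapolations use the tissue input mode by default: whole-WSI
input is wasteful and ROI-only input discards diagnostic context.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .emission_model import (
    DEFAULT_CONSTANTS,
    EmissionResult,
    GridIntensity,
    ModelConstants,
    Scenario,
    _offsets,
)
from .errors import CalibrationError, PathocarbonError

#: Aachen institute census, 2019: 4 804 cancer cases among 40 356 total.
DEFAULT_INSTITUTE_CANCER_CASES = 4_804
DEFAULT_INSTITUTE_TOTAL_CASES = 4_804 + 35_552


@dataclass(frozen=True)
class InstituteAnchor:
    """The institute census and per-case workload the extrapolation scales from.

    ``mean_tiles_per_case`` maps input mode -> mean tiles per case, as
    measured on the institute cohort.
    """

    cancer_cases: int = DEFAULT_INSTITUTE_CANCER_CASES
    total_cases: int = DEFAULT_INSTITUTE_TOTAL_CASES
    mean_tiles_per_case: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.cancer_cases < 1:
            raise ValueError("anchor cancer_cases must be >= 1")
        if self.total_cases < self.cancer_cases:
            raise ValueError("anchor total_cases must be >= cancer_cases")

    @property
    def cases_per_cancer_case(self) -> float:
        return self.total_cases / self.cancer_cases


@dataclass(frozen=True)
class RegionStats:
    """One region's cancer burden, grid and forest area."""

    region: str
    cancer_cases_per_year: int
    grid: GridIntensity
    forest_area_km2: float | None = None

    def __post_init__(self):
        if self.cancer_cases_per_year < 1:
            raise ValueError(f"region {self.region}: cancer cases must be >= 1")
        if self.forest_area_km2 is not None and self.forest_area_km2 <= 0:
            raise ValueError(f"region {self.region}: forest area must be > 0")


def extrapolate_case_count(region_cancer_cases: int, anchor: InstituteAnchor) -> int:
    """Total pathology cases implied by a region's cancer-case count."""
    if region_cancer_cases < 1:
        raise ValueError("region cancer cases must be >= 1")
    return int(round(region_cancer_cases * anchor.cases_per_cancer_case))


def underestimation_factor(survey_cases: int, modelled_cases: int) -> float:
    """Ratio of a survey-based national case count to the modelled count.

    A value above 1 means the cancer-anchored extrapolation undershoots the
    survey; emissions scale by the same factor.
    """
    if modelled_cases < 1 or survey_cases < 1:
        raise ValueError("case counts must be >= 1")
    return survey_cases / modelled_cases


def region_emission(
    region: RegionStats,
    anchor: InstituteAnchor,
    scenario: Scenario,
    energies: Mapping[tuple[str, str | None], float],
    constants: ModelConstants = DEFAULT_CONSTANTS,
    *,
    energy_draws: Mapping[str, np.ndarray] | None = None,
    noise_sd: float = 0.02,
    n_boot: int = 2000,
    seed: int = 0,
) -> EmissionResult:
    """Yearly scenario emission of one region.

    Per-case tiles come from the anchor at the scenario's input mode; the
    region's case count is extrapolated from its cancer cases; conversion
    uses the region's own grid intensity. CI as in
    :func:`pathocarbon.emission_model.scenario_emission`.
    """
    mode = scenario.input_mode
    if mode not in anchor.mean_tiles_per_case:
        raise PathocarbonError(
            f"anchor has no mean tiles per case for input mode {mode!r}"
        )
    mean_tiles = anchor.mean_tiles_per_case[mode]
    n_cases = extrapolate_case_count(region.cancer_cases_per_year, anchor)
    intensity = region.grid.resolve(constants)

    task_energy: dict[str, float] = {}
    for task in scenario.tasks:
        key = (task.task_type, task.size_class)
        if key not in energies:
            raise CalibrationError(
                f"no calibrated energy for ({task.task_type}, {task.size_class})"
            )
        task_energy[task.name] = energies[key]

    tiles_total = mean_tiles * n_cases
    kg_per_task = {
        name: tiles_total * e / constants.reference_tiles * intensity
        for name, e in task_energy.items()
    }
    total_kg = float(sum(kg_per_task.values()))
    energy_kwh = tiles_total * sum(task_energy.values()) / constants.reference_tiles

    if total_kg == 0.0 or n_boot <= 0:
        ci = (total_kg, total_kg)
    else:
        rng = np.random.default_rng(seed)
        n_tasks = len(scenario.tasks)
        energies_b = np.empty((n_boot, n_tasks))
        for j, task in enumerate(scenario.tasks):
            if energy_draws is not None and task.name in energy_draws:
                draws = np.asarray(energy_draws[task.name], dtype=float)
                energies_b[:, j] = rng.choice(draws, size=n_boot, replace=True)
            else:
                energies_b[:, j] = task_energy[task.name]
        jitter = rng.lognormal(0.0, max(noise_sd, 0.0), size=(n_boot, n_tasks))
        totals = (energies_b * jitter).sum(axis=1) * (
            tiles_total / constants.reference_tiles * intensity
        )
        lo, hi = np.percentile(totals, [2.5, 97.5])
        ci = (float(lo), float(hi))

    forests = {region.region: region.forest_area_km2} if region.forest_area_km2 else None
    return EmissionResult(
        energy_kwh=energy_kwh,
        co2eq_kg=total_kg,
        ci95_kg=ci,
        per_task_kg=kg_per_task,
        offsets=_offsets(total_kg, constants, forests),
    )


def world_table(
    regions: Sequence[RegionStats],
    anchor: InstituteAnchor,
    scenario: Scenario,
    energies: Mapping[tuple[str, str | None], float],
    constants: ModelConstants = DEFAULT_CONSTANTS,
    *,
    energy_draws: Mapping[str, np.ndarray] | None = None,
    noise_sd: float = 0.02,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, EmissionResult]:
    """Per-region emission table (sorted by emission, descending) + world total.

    The world total is the exact sum of the regional totals; its offsets are
    computed against the world forest.
    """
    if len(regions) == 0:
        raise PathocarbonError("need at least one region")
    names = [r.region for r in regions]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise PathocarbonError(f"duplicate region names: {dupes}")

    seeds = np.random.SeedSequence(seed).spawn(len(regions))
    rows = []
    results = []
    for region, child in zip(regions, seeds):
        res = region_emission(
            region, anchor, scenario, energies, constants,
            energy_draws=energy_draws, noise_sd=noise_sd, n_boot=n_boot,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        results.append(res)
        rows.append(
            {
                "region": region.region,
                "cases": extrapolate_case_count(region.cancer_cases_per_year, anchor),
                "co2eq_t": res.co2eq_t,
                "ci_low_t": res.ci95_kg[0] / 1000.0,
                "ci_high_t": res.ci95_kg[1] / 1000.0,
                "forest_km2": res.offsets.forest_km2,
                "world_forest_fraction": res.offsets.forest_fraction["world"],
            }
        )
    table = pd.DataFrame(rows).sort_values("co2eq_t", ascending=False).reset_index(drop=True)

    total_kg = float(sum(r.co2eq_kg for r in results))
    total = EmissionResult(
        energy_kwh=float(sum(r.energy_kwh for r in results)),
        co2eq_kg=total_kg,
        ci95_kg=(
            float(sum(r.ci95_kg[0] for r in results)),
            float(sum(r.ci95_kg[1] for r in results)),
        ),
        per_task_kg={},
        offsets=_offsets(total_kg, constants, None),
    )
    return table, total


def read_region_csv(path) -> list[RegionStats]:
    """Load the region table.

    Columns: region, cancer_cases, renewable_share (optional),
    intensity_kg_per_kwh (optional; overrides the share), forest_area_km2
    (optional).
    """
    df = pd.read_csv(path)
    if "region" not in df.columns or "cancer_cases" not in df.columns:
        raise PathocarbonError("region table needs 'region' and 'cancer_cases' columns")
    regions = []
    for r in df.itertuples():
        share = getattr(r, "renewable_share", None)
        share = None if share is None or pd.isna(share) else float(share)
        direct = getattr(r, "intensity_kg_per_kwh", None)
        direct = None if direct is None or pd.isna(direct) else float(direct)
        forest = getattr(r, "forest_area_km2", None)
        forest = None if forest is None or pd.isna(forest) else float(forest)
        regions.append(
            RegionStats(
                region=str(r.region),
                cancer_cases_per_year=int(r.cancer_cases),
                grid=GridIntensity(str(r.region), share, direct),
                forest_area_km2=forest,
            )
        )
    return regions


def packaged_region_path() -> Path:
    """Path of the packaged synthetic region table."""
    return Path(__file__).parent / "data" / "regions_synthetic.csv"
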