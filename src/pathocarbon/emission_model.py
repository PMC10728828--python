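"""Emission accounting: workloads x calibrated energies -> CO2-equivalents.

The accounting chain is linear end to end: a deployment scenario applies one
or more models to every tile of the chosen data-input mode, so

    kg CO2eq = tiles x (kWh per 10^7 tiles) / 10^7 x grid intensity (kg/kWh)

summed over the scenario's tasks. Grid intensity comes either from a direct
regional value (kg CO2eq per kWh) or from a linear renewable/fossil mix.
Emissions are also expressed as sequestration equivalents: mature trees
(21.8 kg CO2eq per tree per year) and forest area, via the world forest's
annual capacity of 7.6 Gt spread over 40.6 million km^2 (~187.2 t per km^2
per year).

Confidence intervals are percentile bootstrap over per-run energy noise
(multiplicative log-normal, sigma defaulting to 0.02 in line with the tight
repeatability of hardware energy measurement); for the regression-estimated
multitask model the bootstrap can instead consume the regression's own
prediction draws, which dominate its uncertainty. Resampling cases is
available as an option but off by default — the yearly case census is a
fixed quantity, not a sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import CalibrationError, PathocarbonError
from .power_accounting import REFERENCE_TILES, ModelProfile
from .synthetic_cohort import Workload

__all__ = [
    "ModelConstants",
    "GridIntensity",
    "Task",
    "Scenario",
    "make_scenario",
    "OffsetEquivalents",
    "EmissionResult",
    "intensity_from_mix",
    "energy_to_co2",
    "trees_required",
    "forest_area_required",
    "scanner_emission",
    "scenario_emission",
    "reduction_factor",
    "pathomics_emission",
    "build_energy_table",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = ("one_task", "two_task", "seven_task", "multitask")


@dataclass(frozen=True)
class ModelConstants:
    """Physical and conversion constants of the emission model.

    Tree uptake and world-forest figures follow standard sequestration
    references (Arbor Day Foundation; global forest assessments). The
    fossil/renewable endpoint intensities define the linear grid mix used
    when a region reports only its renewable share.
    """

    tree_uptake_kg_per_year: float = 21.8
    world_forest_capacity_t: float = 7.6e9
    world_forest_area_km2: float = 40.6e6
    reference_tiles: int = REFERENCE_TILES
    intensity_fossil_kg_per_kwh: float = 0.70
    intensity_renewable_kg_per_kwh: float = 0.03

    def __post_init__(self):
        vals = (
            self.tree_uptake_kg_per_year,
            self.world_forest_capacity_t,
            self.world_forest_area_km2,
            self.reference_tiles,
            self.intensity_fossil_kg_per_kwh,
            self.intensity_renewable_kg_per_kwh,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all model constants must be strictly positive")
        if self.intensity_renewable_kg_per_kwh >= self.intensity_fossil_kg_per_kwh:
            raise ValueError("renewable intensity must be below fossil intensity")

    @property
    def sequestration_t_per_km2(self) -> float:
        """Annual world-forest sequestration rate, tonnes CO2eq per km^2."""
        return self.world_forest_capacity_t / self.world_forest_area_km2


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class GridIntensity:
    """Carbon intensity of one region's electricity.

    A direct ``intensity_kg_per_kwh`` (e.g. an Electricity Maps yearly
    value) overrides the share-derived linear mix.
    """

    region: str
    renewable_share: float | None = None
    intensity_kg_per_kwh: float | None = None

    def __post_init__(self):
        if self.renewable_share is None and self.intensity_kg_per_kwh is None:
            raise ValueError(f"region {self.region}: need a share or a direct intensity")
        if self.renewable_share is not None and not 0.0 <= self.renewable_share <= 1.0:
            raise ValueError(f"region {self.region}: renewable share outside [0, 1]")
        if self.intensity_kg_per_kwh is not None and self.intensity_kg_per_kwh <= 0:
            raise ValueError(f"region {self.region}: intensity must be > 0")

    def resolve(self, constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
        if self.intensity_kg_per_kwh is not None:
            return self.intensity_kg_per_kwh
        return intensity_from_mix(self.renewable_share, constants)


def intensity_from_mix(
    renewable_share: float, constants: ModelConstants = DEFAULT_CONSTANTS
) -> float:
    """Linear renewable/fossil blend of grid intensity, kg CO2eq per kWh."""
    if not 0.0 <= renewable_share <= 1.0:
        raise ValueError("renewable share must lie in [0, 1]")
    return (
        renewable_share * constants.intensity_renewable_kg_per_kwh
        + (1.0 - renewable_share) * constants.intensity_fossil_kg_per_kwh
    )


def energy_to_co2(energy_kwh: float, intensity_kg_per_kwh: float) -> float:
    """kWh -> kg CO2eq at the given grid intensity."""
    if energy_kwh < 0 or intensity_kg_per_kwh < 0:
        raise ValueError("energy and intensity must be non-negative")
    return energy_kwh * intensity_kg_per_kwh


def trees_required(co2eq_kg: float, constants: ModelConstants = DEFAULT_CONSTANTS) -> int:
    """Mature trees needed to absorb the emission in one year (rounded up)."""
    if co2eq_kg < 0:
        raise ValueError("emission mass must be non-negative")
    return math.ceil(co2eq_kg / constants.tree_uptake_kg_per_year)


def forest_area_required(
    co2eq_t: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    region_forest_area_km2: float | None = None,
) -> tuple[float, float | None]:
    """Forest area (km^2) to sequester the emission, and the regional fraction.

    Area = tonnes / (world capacity / world area). The fraction uses the
    given region's forest area as denominator and is None when no region
    area is supplied.
    """
    if co2eq_t < 0:
        raise ValueError("emission mass must be non-negative")
    km2 = co2eq_t / constants.sequestration_t_per_km2
    if region_forest_area_km2 is None:
        return km2, None
    if region_forest_area_km2 <= 0:
        raise ValueError("region forest area must be > 0")
    return km2, km2 / region_forest_area_km2


def scanner_emission(
    n_slides: int,
    power_w: float = 580.0,
    minutes_per_slide: float = 1.0,
    intensity_kg_per_kwh: float = 0.40,
) -> float:
    """CO2eq (kg) of digitising ``n_slides`` on a slide scanner.

    Defaults describe an Aperio AT2-class scanner (580 W) at one minute per
    slide on a 0.40 kg/kWh grid.
    """
    if min(n_slides, power_w, minutes_per_slide, intensity_kg_per_kwh) <= 0:
        raise ValueError("all scanner parameters must be positive")
    kwh = n_slides * (minutes_per_slide / 60.0) * (power_w / 1000.0)
    return energy_to_co2(kwh, intensity_kg_per_kwh)


@dataclass(frozen=True)
class Task:
    """One model inference applied per case within a scenario."""

    name: str
    task_type: str  # classification | segmentation | multitask
    size_class: str | None  # None for the multitask model


@dataclass(frozen=True)
class Scenario:
    """A named deployment pattern binding tasks to a data-input mode."""

    name: str
    tasks: tuple[Task, ...]
    input_mode: str = "wsi"

    def __post_init__(self):
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"scenario name must be one of {SCENARIO_NAMES}")
        expected = {"one_task": 1, "two_task": 2, "seven_task": 7, "multitask": 1}
        if len(self.tasks) != expected[self.name]:
            raise ValueError(
                f"scenario {self.name} needs {expected[self.name]} task(s), "
                f"got {len(self.tasks)}"
            )
        if self.name == "multitask" and self.tasks[0].task_type != "multitask":
            raise ValueError("multitask scenario needs a multitask task")
        if self.name == "two_task":
            types = sorted(t.task_type for t in self.tasks)
            if types != ["classification", "segmentation"]:
                raise ValueError(
                    "two_task scenario pairs one classification with one segmentation"
                )


def make_scenario(name: str, size_class: str = "large", input_mode: str = "wsi") -> Scenario:
    """Build a standard deployment scenario at one model size and input mode.

    The seven-task composition maps the automated-workflow task list to
    three segmentation tasks (tissue, ROI and instance annotation) and four
    classification tasks (grading — which also serves case prioritisation —
    molecular-alteration detection, treatment-response prediction, survival
    analysis).
    """
    if name == "one_task":
        tasks = (Task("diagnosis", "classification", size_class),)
    elif name == "two_task":
        tasks = (
            Task("diagnosis", "classification", size_class),
            Task("segmentation", "segmentation", size_class),
        )
    elif name == "seven_task":
        tasks = (
            Task("tissue_annotation", "segmentation", size_class),
            Task("roi_annotation", "segmentation", size_class),
            Task("instance_annotation", "segmentation", size_class),
            Task("grading", "classification", size_class),
            Task("molecular_alteration", "classification", size_class),
            Task("treatment_response", "classification", size_class),
            Task("survival", "classification", size_class),
        )
    elif name == "multitask":
        tasks = (Task("multitask", "multitask", None),)
    else:
        raise ValueError(f"unknown scenario {name!r}")
    return Scenario(name, tasks, input_mode)


@dataclass(frozen=True)
class OffsetEquivalents:
    """Sequestration equivalents of an emission mass."""

    trees: int
    forest_km2: float
    forest_fraction: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class EmissionResult:
    """Energy, CO2eq mass with 95% CI, per-task split and offsets."""

    energy_kwh: float
    co2eq_kg: float
    ci95_kg: tuple[float, float]
    per_task_kg: Mapping[str, float]
    offsets: OffsetEquivalents

    def __post_init__(self):
        lo, hi = self.ci95_kg
        if not lo <= hi:
            raise ValueError("CI bounds out of order")
        if self.per_task_kg:
            s = sum(self.per_task_kg.values())
            if not math.isclose(s, self.co2eq_kg, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError("per-task emissions do not sum to the total")

    @property
    def co2eq_t(self) -> float:
        return self.co2eq_kg / 1000.0


def build_energy_table(
    size_classes: Mapping[str, Mapping[str, ModelProfile]],
    device_name: str,
    multitask_kwh_per_ref: float | None = None,
) -> dict[tuple[str, str | None], float]:
    """Flatten size-classed profiles into a (task_type, size_class) -> kWh map."""
    table: dict[tuple[str, str | None], float] = {}
    for task_type, classes in size_classes.items():
        for size, profile in classes.items():
            table[(task_type, size)] = profile.energy_on(device_name)
    if multitask_kwh_per_ref is not None:
        table[("multitask", None)] = multitask_kwh_per_ref
    return table


def _offsets(
    co2eq_kg: float,
    constants: ModelConstants,
    region_forest_km2: Mapping[str, float] | None,
) -> OffsetEquivalents:
    km2, _ = forest_area_required(co2eq_kg / 1000.0, constants)
    fractions = {}
    if region_forest_km2:
        for region, area in region_forest_km2.items():
            fractions[region] = forest_area_required(co2eq_kg / 1000.0, constants, area)[1]
    fractions["world"] = km2 / constants.world_forest_area_km2
    return OffsetEquivalents(
        trees=trees_required(co2eq_kg, constants),
        forest_km2=km2,
        forest_fraction=fractions,
    )


def scenario_emission(
    workload: Workload,
    scenario: Scenario,
    energies: Mapping[tuple[str, str | None], float],
    intensity_kg_per_kwh: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    *,
    energy_draws: Mapping[str, np.ndarray] | None = None,
    noise_sd: float = 0.02,
    n_boot: int = 2000,
    seed: int = 0,
    resample_cases: bool = False,
    region_forest_km2: Mapping[str, float] | None = None,
) -> EmissionResult:
    """Emission of running a scenario over a cohort workload for one year.

    The point estimate is the noise-free linear accounting; the 95% CI is a
    seeded percentile bootstrap in which each task's per-tile energy is
    jittered log-normally (sd ``noise_sd`` on the log scale) and, where
    ``energy_draws`` provides regression prediction draws for a task (the
    multitask model), those draws replace the fixed energy. Optionally the
    per-case tile counts are also resampled with replacement.
    """
    if workload.tiling.mode != scenario.input_mode:
        raise PathocarbonError(
            f"workload mode {workload.tiling.mode!r} does not match scenario "
            f"input mode {scenario.input_mode!r}"
        )
    task_energy: dict[str, float] = {}
    for task in scenario.tasks:
        key = (task.task_type, task.size_class)
        if key not in energies:
            raise CalibrationError(
                f"no calibrated energy for task {task.name!r} "
                f"({task.task_type}, {task.size_class})"
            )
        task_energy[task.name] = energies[key]

    tiles_total = float(workload.total_tiles)
    kg_per_task = {
        name: tiles_total * e / constants.reference_tiles * intensity_kg_per_kwh
        for name, e in task_energy.items()
    }
    total_kg = float(sum(kg_per_task.values()))

    if total_kg == 0.0 or n_boot <= 0:
        ci = (total_kg, total_kg)
    else:
        rng = np.random.default_rng(seed)
        n_tasks = len(scenario.tasks)
        if resample_cases:
            case_tiles = workload.per_case["tiles"].to_numpy(dtype=float)
            idx = rng.integers(0, len(case_tiles), size=(n_boot, len(case_tiles)))
            tiles_b = case_tiles[idx].sum(axis=1)
        else:
            tiles_b = np.full(n_boot, tiles_total)
        energies_b = np.empty((n_boot, n_tasks))
        for j, task in enumerate(scenario.tasks):
            if energy_draws is not None and task.name in energy_draws:
                draws = np.asarray(energy_draws[task.name], dtype=float)
                energies_b[:, j] = rng.choice(draws, size=n_boot, replace=True)
            else:
                energies_b[:, j] = task_energy[task.name]
        jitter = rng.lognormal(0.0, max(noise_sd, 0.0), size=(n_boot, n_tasks))
        totals = (
            tiles_b[:, None] * energies_b * jitter
        ).sum(axis=1) / constants.reference_tiles * intensity_kg_per_kwh
        lo, hi = np.percentile(totals, [2.5, 97.5])
        ci = (float(lo), float(hi))

    energy_kwh = tiles_total * sum(task_energy.values()) / constants.reference_tiles
    return EmissionResult(
        energy_kwh=energy_kwh,
        co2eq_kg=total_kg,
        ci95_kg=ci,
        per_task_kg=kg_per_task,
        offsets=_offsets(total_kg, constants, region_forest_km2),
    )


def reduction_factor(baseline: EmissionResult, alternative: EmissionResult) -> float:
    """How many times lower the alternative's emission is than the baseline's."""
    if alternative.co2eq_kg <= 0:
        raise PathocarbonError("alternative emission must be > 0 for a ratio")
    return baseline.co2eq_kg / alternative.co2eq_kg


def pathomics_emission(
    workload_tissue: Workload,
    segmentation_profile: ModelProfile,
    device_name: str,
    intensity_kg_per_kwh: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    *,
    detection_profile: ModelProfile | None = None,
    overhead_fraction: float = 0.0,
    noise_sd: float = 0.02,
    n_boot: int = 2000,
    seed: int = 0,
    region_forest_km2: Mapping[str, float] | None = None,
) -> EmissionResult:
    """Emission of a pathomics workflow on the tissue workload.

    Pathomics replaces end-to-end deep learning with a tissue-detection
    pass, a segmentation pass (UNet-2D-class) over tissue tiles, and
    handcrafted feature extraction whose cost enters as a relative
    ``overhead_fraction`` on the deep-learning energy (default 0: feature
    extraction is negligible next to network inference). With no detection
    profile configured, the single segmentation pass is priced exactly like
    a one-segmentation-task scenario.
    """
    if workload_tissue.tiling.mode != "tissue":
        raise PathocarbonError("pathomics runs on the tissue-mode workload")
    if segmentation_profile.task_type != "segmentation":
        raise CalibrationError("pathomics needs a segmentation-type profile")
    if overhead_fraction < 0:
        raise ValueError("overhead_fraction must be >= 0")

    tiles = float(workload_tissue.total_tiles)
    passes = {"segmentation": segmentation_profile.energy_on(device_name)}
    if detection_profile is not None:
        passes = {"tissue_detection": detection_profile.energy_on(device_name), **passes}

    scale = (1.0 + overhead_fraction) * intensity_kg_per_kwh / constants.reference_tiles
    kg_per_task = {name: tiles * e * scale for name, e in passes.items()}
    total_kg = float(sum(kg_per_task.values()))
    energy_kwh = tiles * sum(passes.values()) * (1.0 + overhead_fraction) / constants.reference_tiles

    if total_kg == 0.0 or n_boot <= 0:
        ci = (total_kg, total_kg)
    else:
        rng = np.random.default_rng(seed)
        jitter = rng.lognormal(0.0, max(noise_sd, 0.0), size=(n_boot, len(passes)))
        base = np.array(list(kg_per_task.values()))
        totals = (base[None, :] * jitter).sum(axis=1)
        lo, hi = np.percentile(totals, [2.5, 97.5])
        ci = (float(lo), float(hi))

    return EmissionResult(
        energy_kwh=energy_kwh,
        co2eq_kg=total_kg,
        ci95_kg=ci,
        per_task_kg=kg_per_task,
        offsets=_offsets(total_kg, constants, region_forest_km2),
    )
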