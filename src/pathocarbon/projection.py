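"""Emission projections 2023-2052 under four multiplicative drivers.

The drivers are the renewable share of the grid (lowering intensity), deep-
learning model complexity (raising per-tile energy), hardware efficiency
(lowering it), and pathology case counts (raising workload). Emission
accounting is linear in each factor, so the only combination rule
consistent with it is multiplicative and separable:

    E(y) = E0 * complexity(y)/complexity(y0)
              * cases(y)/cases(y0)
              * intensity(renew(y))/intensity(renew(y0))
              / efficiency(y)/efficiency(y0)

Each driver is an anchored trajectory: a monotone interpolation through
anchor means (geometric/log-linear for positive growth quantities, linear
and clamped to [0, 1] for the renewable share), with seeded bootstrap bands
obtained by perturbing anchors (log-normally, or logit-normally for the
share) and re-interpolating. The best/mean/worst emission paths are the
2.5th percentile, the plain mean-anchor path, and the 97.5th percentile of
the drawn paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.special import expit, logit

from .emission_model import DEFAULT_CONSTANTS, ModelConstants
from .errors import DriverSpecError, GridMismatchError

DRIVERS = ("renewables", "model_complexity", "hardware_efficiency", "cases")
YEAR_START, YEAR_END = 2023, 2052


@dataclass(frozen=True)
class DriverSpec:
    """Anchors (or a growth rate) plus uncertainty for one projection driver.

    ``anchors`` are (year, value) means; ``rel_sd`` is the relative standard
    deviation applied to every anchor (or one value per anchor). Instead of
    anchors, ``growth_rate`` (per-year fractional growth from ``base_value``
    at ``base_year``) may be given; it is converted to two end anchors and
    interpolated geometrically, which reproduces compound growth exactly.
    """

    driver: str
    anchors: tuple[tuple[int, float], ...] = ()
    rel_sd: float | tuple[float, ...] = 0.0
    growth_rate: float | None = None
    base_value: float = 1.0
    base_year: int = YEAR_START
    scenario_label: str | None = None  # renewables only: planned | below_2C | mean

    def __post_init__(self):
        if self.driver not in DRIVERS:
            raise DriverSpecError(f"unknown driver {self.driver!r}")
        if self.growth_rate is None and len(self.anchors) < 2:
            raise DriverSpecError(
                f"driver {self.driver}: need >= 2 anchors or a growth_rate"
            )
        if self.growth_rate is not None and self.growth_rate <= -1.0:
            raise DriverSpecError(f"driver {self.driver}: growth_rate must be > -1")
        for year, value in self.anchors:
            if self.driver == "renewables":
                if not 0.0 <= value <= 1.0:
                    raise DriverSpecError(
                        f"driver renewables: share {value} outside [0, 1] at {year}"
                    )
            elif value <= 0:
                raise DriverSpecError(
                    f"driver {self.driver}: value must be > 0 at {year}"
                )

    def resolved_anchors(self) -> tuple[np.ndarray, np.ndarray]:
        if self.growth_rate is not None:
            y0, yn = self.base_year, YEAR_END
            v0 = self.base_value
            vn = v0 * (1.0 + self.growth_rate) ** (yn - y0)
            return np.array([y0, yn], dtype=float), np.array([v0, vn])
        yrs = np.array([y for y, _ in self.anchors], dtype=float)
        vals = np.array([v for _, v in self.anchors], dtype=float)
        order = np.argsort(yrs)
        return yrs[order], vals[order]

    def anchor_sds(self, n_anchors: int) -> np.ndarray:
        if np.isscalar(self.rel_sd):
            return np.full(n_anchors, float(self.rel_sd))
        sds = np.asarray(self.rel_sd, dtype=float)
        if len(sds) != n_anchors:
            raise DriverSpecError(
                f"driver {self.driver}: rel_sd length {len(sds)} != {n_anchors} anchors"
            )
        return sds


@dataclass(frozen=True)
class Trajectory:
    """Yearly mean path with a 95% bootstrap band and the raw path draws."""

    driver: str
    years: np.ndarray
    mean: np.ndarray
    band95: tuple[np.ndarray, np.ndarray]
    draws: np.ndarray  # (n_boot, n_years)
    n_boot: int
    seed: int

    def value_at(self, year: int) -> float:
        i = int(np.searchsorted(self.years, year))
        if i >= len(self.years) or self.years[i] != year:
            raise GridMismatchError(f"year {year} not on the trajectory grid")
        return float(self.mean[i])


def _interp(years: np.ndarray, ax: np.ndarray, av: np.ndarray, share: bool) -> np.ndarray:
    """Monotone interpolation through anchors, flat-slope extrapolation of the
    edge segments; log-space for positive drivers, direct for shares."""
    v = av if share else np.log(av)
    if len(ax) == 2:
        out = v[0] + (years - ax[0]) * (v[1] - v[0]) / (ax[1] - ax[0])
    else:
        spline = PchipInterpolator(ax, v, extrapolate=False)
        out = spline(years)
        left = years < ax[0]
        right = years > ax[-1]
        s0 = (v[1] - v[0]) / (ax[1] - ax[0])
        sn = (v[-1] - v[-2]) / (ax[-1] - ax[-2])
        out[left] = v[0] + (years[left] - ax[0]) * s0
        out[right] = v[-1] + (years[right] - ax[-1]) * sn
    if share:
        return np.clip(out, 0.0, 1.0)
    return np.exp(out)


def fit_driver(
    spec: DriverSpec,
    n_boot: int = 2000,
    seed: int = 0,
    years: tuple[int, int] = (YEAR_START, YEAR_END),
) -> Trajectory:
    """Fit a driver trajectory with seeded bootstrap bands.

    Anchor means are interpolated deterministically; each bootstrap draw
    perturbs every anchor independently (log-normal for positive values,
    logit-normal for the renewable share, sd scaled by the anchor's
    relative sd) and re-interpolates the whole path. Zero uncertainty
    therefore yields a zero-width band.
    """
    grid = np.arange(years[0], years[1] + 1, dtype=float)
    share = spec.driver == "renewables"
    ax, av = spec.resolved_anchors()
    mean = _interp(grid, ax, av, share)

    rng = np.random.default_rng(seed)
    sds = spec.anchor_sds(len(ax))
    draws = np.empty((max(n_boot, 0), len(grid)))
    if n_boot > 0:
        noise = rng.normal(0.0, 1.0, size=(n_boot, len(ax))) * sds[None, :]
        if share:
            eps = 1e-9
            base = logit(np.clip(av, eps, 1.0 - eps))
            pav = expit(base[None, :] + noise)
        else:
            pav = av[None, :] * np.exp(noise)
        for b in range(n_boot):
            draws[b] = _interp(grid, ax, pav[b], share)
    if n_boot > 0 and np.any(sds > 0):
        lo = np.percentile(draws, 2.5, axis=0)
        hi = np.percentile(draws, 97.5, axis=0)
        lo, hi = np.minimum(lo, mean), np.maximum(hi, mean)
    else:
        lo, hi = mean.copy(), mean.copy()
        if n_boot > 0:
            draws[:] = mean[None, :]
    return Trajectory(spec.driver, grid, mean, (lo, hi), draws, n_boot, seed)


@dataclass(frozen=True)
class ProjectionResult:
    """Best/mean/worst emission paths (kg CO2eq) and forest fractions per year."""

    years: np.ndarray
    emissions_kg: Mapping[str, np.ndarray]  # keys: best, mean, worst
    forest_fraction: Mapping[str, np.ndarray]
    year0: int
    e0_kg: float
    n_boot: int

    def path(self, name: str) -> np.ndarray:
        if name not in self.emissions_kg:
            raise KeyError(f"path must be one of {sorted(self.emissions_kg)}")
        return self.emissions_kg[name]


def _scale_paths(
    drivers: Mapping[str, Trajectory],
    idx0: int,
    use_draws: bool,
    constants: ModelConstants,
) -> np.ndarray:
    """Per-year emission multiplier relative to year0, for means or all draws."""

    def series(name):
        t = drivers[name]
        return t.draws if use_draws else t.mean[None, :]

    ren = series("renewables")
    intensity = (
        ren * constants.intensity_renewable_kg_per_kwh
        + (1.0 - ren) * constants.intensity_fossil_kg_per_kwh
    )
    cmplx = series("model_complexity")
    eff = series("hardware_efficiency")
    cases = series("cases")
    return (
        (cmplx / cmplx[:, idx0:idx0 + 1])
        * (cases / cases[:, idx0:idx0 + 1])
        * (intensity / intensity[:, idx0:idx0 + 1])
        / (eff / eff[:, idx0:idx0 + 1])
    )


def combine_projection(
    e0_kg: float,
    year0: int,
    drivers: Mapping[str, Trajectory],
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> ProjectionResult:
    """Combine the four driver trajectories into emission paths.

    ``e0_kg`` is the anchor emission in ``year0``. Draw b of each driver is
    paired across drivers (draws are independent by construction), each
    drawn path is scaled multiplicatively, and the best/worst paths are the
    2.5/97.5 per-year percentiles; the mean path uses the driver means.
    """
    if e0_kg <= 0:
        raise ValueError("anchor emission must be > 0")
    missing = [d for d in DRIVERS if d not in drivers]
    if missing:
        raise GridMismatchError(f"missing drivers: {missing}")
    years = drivers[DRIVERS[0]].years
    for d in DRIVERS[1:]:
        if not np.array_equal(drivers[d].years, years):
            raise GridMismatchError(f"driver {d} is on a different year grid")
    n_boots = {drivers[d].n_boot for d in DRIVERS}
    if len(n_boots) != 1:
        raise GridMismatchError(f"drivers disagree on bootstrap size: {n_boots}")
    i0 = int(np.searchsorted(years, year0))
    if i0 >= len(years) or years[i0] != year0:
        raise GridMismatchError(f"year0 {year0} not on the common grid")

    mean_path = e0_kg * _scale_paths(drivers, i0, use_draws=False, constants=constants)[0]
    n_boot = n_boots.pop()
    if n_boot > 0:
        drawn = e0_kg * _scale_paths(drivers, i0, use_draws=True, constants=constants)
        best = np.percentile(drawn, 2.5, axis=0)
        worst = np.percentile(drawn, 97.5, axis=0)
        best, worst = np.minimum(best, mean_path), np.maximum(worst, mean_path)
    else:
        best = mean_path.copy()
        worst = mean_path.copy()

    emissions = {"best": best, "mean": mean_path, "worst": worst}
    rate = constants.sequestration_t_per_km2
    fractions = {
        k: (v / 1000.0) / rate / constants.world_forest_area_km2
        for k, v in emissions.items()
    }
    return ProjectionResult(
        years=years,
        emissions_kg=emissions,
        forest_fraction=fractions,
        year0=year0,
        e0_kg=e0_kg,
        n_boot=n_boot,
    )


def forest_exceedance_year(result: ProjectionResult, path: str = "worst") -> int | None:
    """First year the chosen path needs >= 100% of the world's forest, if any."""
    frac = result.forest_fraction[path] if path in result.forest_fraction else None
    if frac is None:
        raise KeyError(f"path must be one of {sorted(result.forest_fraction)}")
    hits = np.nonzero(frac >= 1.0)[0]
    return int(result.years[hits[0]]) if hits.size else None


def read_driver_csv(path) -> dict[str, DriverSpec]:
    """Load driver anchors (driver, scenario_label, year, value, rel_sd).

    For the renewables driver the rows are grouped by scenario label and the
    ``mean`` scenario — the per-year average of the planned and below-2C
    paths — is synthesised when both are present; the returned renewables
    spec is the mean scenario (others accessible by re-reading with a
    filter). Other drivers use all their rows as anchors.
    """
    df = pd.read_csv(path)
    specs: dict[str, DriverSpec] = {}
    for driver, g in df.groupby("driver"):
        if driver == "renewables":
            by_label = {
                str(label): lg.sort_values("year")
                for label, lg in g.groupby("scenario_label")
            }
            if {"planned", "below_2C"} <= set(by_label):
                a, b = by_label["planned"], by_label["below_2C"]
                merged = a.merge(b, on="year", suffixes=("_p", "_b"))
                anchors = tuple(
                    (int(r.year), float((r.value_p + r.value_b) / 2.0))
                    for r in merged.itertuples()
                )
                sds = tuple(
                    float((r.rel_sd_p + r.rel_sd_b) / 2.0) for r in merged.itertuples()
                )
                specs[driver] = DriverSpec(
                    "renewables", anchors, sds, scenario_label="mean"
                )
            else:
                label, lg = next(iter(by_label.items()))
                specs[driver] = DriverSpec(
                    "renewables",
                    tuple((int(r.year), float(r.value)) for r in lg.itertuples()),
                    tuple(float(r.rel_sd) for r in lg.itertuples()),
                    scenario_label=label,
                )
        else:
            lg = g.sort_values("year")
            specs[str(driver)] = DriverSpec(
                str(driver),
                tuple((int(r.year), float(r.value)) for r in lg.itertuples()),
                tuple(float(r.rel_sd) for r in lg.itertuples()),
            )
    return specs


def renewables_scenario_specs(path) -> dict[str, DriverSpec]:
    """All renewable-share scenarios in a driver CSV, keyed by label,
    plus the synthesised per-year 'mean' of planned and below-2C."""
    df = pd.read_csv(path)
    g = df[df["driver"] == "renewables"]
    out: dict[str, DriverSpec] = {}
    for label, lg in g.groupby("scenario_label"):
        lg = lg.sort_values("year")
        out[str(label)] = DriverSpec(
            "renewables",
            tuple((int(r.year), float(r.value)) for r in lg.itertuples()),
            tuple(float(r.rel_sd) for r in lg.itertuples()),
            scenario_label=str(label),
        )
    if {"planned", "below_2C"} <= set(out):
        a = dict(out["planned"].anchors)
        b = dict(out["below_2C"].anchors)
        common = sorted(set(a) & set(b))
        sds_a = dict(zip([y for y, _ in out["planned"].anchors], out["planned"].anchor_sds(len(out["planned"].anchors))))
        sds_b = dict(zip([y for y, _ in out["below_2C"].anchors], out["below_2C"].anchor_sds(len(out["below_2C"].anchors))))
        out["mean"] = DriverSpec(
            "renewables",
            tuple((y, (a[y] + b[y]) / 2.0) for y in common),
            tuple((sds_a[y] + sds_b[y]) / 2.0 for y in common),
            scenario_label="mean",
        )
    return out


def packaged_driver_path() -> Path:
    """Path of the packaged driver-anchor table (partly synthetic)."""
    return Path(__file__).parent / "data" / "driver_anchors_synthetic.csv"
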