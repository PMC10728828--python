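"""Synthetic slide-cohort generation and tile-workload accounting.

A pathology *case* (one patient's specimen set) yields a variable number of
glass slides; each digitised slide is a whole-slide image (WSI) of up to
several gigapixels, of which only a fraction is occupied by tissue and a
smaller fraction by the region of interest (ROI, e.g. tumour). Deep-learning
inference consumes the WSI as fixed-size square *tiles*, so the unit of
computational workload is the tile count, under one of three data-input
modes: every tile (``wsi``), tiles containing tissue (``tissue``), or tiles
inside the ROI (``roi``).

Because real WSI cohorts are rarely shareable, this module generates
synthetic cohorts with the statistical structure the emission model
assumes — right-skewed pixel counts, bounded tissue/ROI fractions with
roi <= tissue, and a concave pixels-to-bytes compression curve tuned to a
target Pearson correlation between file size and pixel count (the study
cohort shows a moderate r of about 0.58).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .distributions import DistSpec
from .errors import ConfigurationError, EmptyCohortError

Organ = Literal["prostate", "breast", "other"]
InputMode = Literal["wsi", "tissue", "roi"]

ORGANS: tuple[str, ...] = ("prostate", "breast", "other")
INPUT_MODES: tuple[str, ...] = ("wsi", "tissue", "roi")

#: Column order of the cohort CSV interchange format.
COHORT_COLUMNS = [
    "slide_id",
    "case_id",
    "organ",
    "specimen_type",
    "n_pixels",
    "file_size_bytes",
    "tissue_fraction",
    "roi_fraction",
]


@dataclass(frozen=True)
class SlideMeta:
    """One whole-slide image's workload-relevant metadata.

    ``tissue_fraction`` and ``roi_fraction`` both use the full WSI area as
    denominator, so ``roi_fraction <= tissue_fraction <= 1`` always.
    """

    slide_id: str
    case_id: str
    organ: str
    n_pixels: int
    file_size_bytes: int
    tissue_fraction: float
    roi_fraction: float

    def __post_init__(self):
        if self.n_pixels < 1:
            raise ValueError(f"slide {self.slide_id}: n_pixels must be >= 1")
        if self.file_size_bytes < 1:
            raise ValueError(f"slide {self.slide_id}: file_size_bytes must be >= 1")
        if not 0.0 <= self.roi_fraction <= self.tissue_fraction <= 1.0:
            raise ValueError(
                f"slide {self.slide_id}: need 0 <= roi_fraction <= tissue_fraction <= 1"
            )


@dataclass(frozen=True)
class CaseMeta:
    """One pathology case (patient specimen set)."""

    case_id: str
    organ: str
    specimen_type: str
    n_slides: int

    def __post_init__(self):
        if self.n_slides < 1:
            raise ValueError(f"case {self.case_id}: n_slides must be >= 1")


@dataclass(frozen=True)
class TilingSpec:
    """Square non-overlapping tiling of a WSI.

    The default edge of 512 px is a common computational-pathology patch
    size; counts are ceilings of area ratios (partial edge tiles are still
    processed).
    """

    tile_edge_px: int = 512
    mode: str = "wsi"

    def __post_init__(self):
        if self.tile_edge_px < 1:
            raise ValueError("tile_edge_px must be >= 1")
        if self.mode not in INPUT_MODES:
            raise ValueError(f"mode must be one of {INPUT_MODES}, got {self.mode!r}")


def _default_slides_per_case() -> dict:
    # Medians chosen to emulate the digitised study cohort: 140 slides over
    # eight breast cases (~17.5 each) and 223 over five prostate cases (~44.6).
    return {
        "prostate": DistSpec("lognormal", {"median": 40.0, "sigma": 0.5}),
        "breast": DistSpec("lognormal", {"median": 16.0, "sigma": 0.5}),
        "other": DistSpec("lognormal", {"median": 8.0, "sigma": 0.6}),
    }


@dataclass
class CohortConfig:
    """Generator configuration for a synthetic slide cohort.

    Parameters
    ----------
    n_cases
        Cases per organ, e.g. ``{"prostate": 5, "breast": 8}``.
    slides_per_case
        Distribution spec per organ (a single spec is broadcast to all
        organs). Draws are rounded and clamped to >= 1.
    pixels_per_slide
        Distribution of total pixels per WSI. Default is log-normal with a
        median of 4x10^9 px (a 40x gigapixel scan) and wide spread.
    tissue_fraction
        Distribution on [0, 1] of the tissue share of the slide area.
    roi_given_tissue
        Distribution on [0, 1]; the ROI fraction is this draw times the
        slide's tissue fraction, which enforces roi <= tissue by
        construction.
    filesize_coeff, filesize_exponent
        Concave compression curve ``bytes = a * pixels**b`` (b < 1 reflects
        scanner compression being relatively more effective on large scans).
    target_size_pixel_corr
        Target Pearson correlation, on the raw scale, between file size and
        pixel count. The multiplicative log-normal noise sigma of the size
        model is solved to hit this target (study cohort: about 0.58).
    seed
        Root seed; child streams are spawned per purpose so adding a field
        does not reshuffle unrelated draws.
    """

    n_cases: Mapping[str, int] = field(
        default_factory=lambda: {"prostate": 5, "breast": 8}
    )
    slides_per_case: Mapping[str, DistSpec] | DistSpec = field(
        default_factory=_default_slides_per_case
    )
    pixels_per_slide: DistSpec = field(
        default_factory=lambda: DistSpec("lognormal", {"median": 4.0e9, "sigma": 1.0})
    )
    tissue_fraction: DistSpec = field(
        default_factory=lambda: DistSpec("beta", {"a": 2.5, "b": 4.5})
    )
    roi_given_tissue: DistSpec = field(
        default_factory=lambda: DistSpec("beta", {"a": 2.0, "b": 2.0})
    )
    filesize_coeff: float = 25.0
    filesize_exponent: float = 0.8
    target_size_pixel_corr: float = 0.58
    seed: int = 0

    def __post_init__(self):
        for organ, n in self.n_cases.items():
            if organ not in ORGANS:
                raise ConfigurationError("n_cases", f"unknown organ {organ!r}")
            if int(n) < 1:
                raise ConfigurationError("n_cases", f"{organ}: need >= 1 case")
        if isinstance(self.slides_per_case, DistSpec) or (
            isinstance(self.slides_per_case, Mapping)
            and "name" in self.slides_per_case
        ):
            spec = DistSpec.from_config(self.slides_per_case, "slides_per_case")
            self.slides_per_case = {organ: spec for organ in ORGANS}
        else:
            self.slides_per_case = {
                organ: DistSpec.from_config(spec, f"slides_per_case.{organ}")
                for organ, spec in self.slides_per_case.items()
            }
            for organ in self.n_cases:
                if organ not in self.slides_per_case:
                    raise ConfigurationError(
                        "slides_per_case", f"no spec for organ {organ!r}"
                    )
        self.pixels_per_slide = DistSpec.from_config(
            self.pixels_per_slide, "pixels_per_slide"
        )
        self.tissue_fraction = DistSpec.from_config(
            self.tissue_fraction, "tissue_fraction"
        )
        self.roi_given_tissue = DistSpec.from_config(
            self.roi_given_tissue, "roi_given_tissue"
        )
        if not 0.0 < self.filesize_exponent <= 1.0:
            raise ConfigurationError(
                "filesize_exponent", "must be in (0, 1] (concave compression)"
            )
        if self.filesize_coeff <= 0:
            raise ConfigurationError("filesize_coeff", "must be > 0")
        if not 0.0 < self.target_size_pixel_corr < 1.0:
            raise ConfigurationError("target_size_pixel_corr", "must be in (0, 1)")


def _lognormal_pair_corr(s_u: float, b: float, sigma: float) -> float:
    """Raw-scale Pearson correlation of (X, a*X**b * e^eps) for log-normal X.

    With U = log X ~ N(mu, s_u^2) and V = log a + b U + eps, eps ~ N(0, sigma^2),
    (U, V) is bivariate normal, and for X = e^U, Y = e^V:

        corr(X, Y) = (exp(b s_u^2) - 1)
                     / sqrt((exp(s_u^2) - 1) (exp(b^2 s_u^2 + sigma^2) - 1))
    """
    num = math.expm1(b * s_u**2)
    den = math.sqrt(math.expm1(s_u**2) * math.expm1(b**2 * s_u**2 + sigma**2))
    return num / den


def solve_filesize_noise_sigma(
    log_pixel_sd: float, exponent: float, target_corr: float
) -> float:
    """Noise sigma of the size model that yields ``target_corr`` on raw scale.

    Raises :class:`ConfigurationError` when the target exceeds the noise-free
    ceiling (the correlation achievable at sigma = 0).
    """
    ceiling = _lognormal_pair_corr(log_pixel_sd, exponent, 0.0)
    if target_corr >= ceiling:
        raise ConfigurationError(
            "target_size_pixel_corr",
            f"target {target_corr:.3f} unattainable; noise-free ceiling is "
            f"{ceiling:.3f} for these pixel/compression settings",
        )
    f = lambda s: _lognormal_pair_corr(log_pixel_sd, exponent, s) - target_corr
    # at sigma = 10 the raw-scale correlation is numerically zero already
    return brentq(f, 0.0, 10.0)


def generate_cohort(config: CohortConfig) -> tuple[list[CaseMeta], list[SlideMeta]]:
    """Draw a synthetic cohort; deterministic for a fixed config seed."""
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("slides", "pixels", "tissue", "roi", "filesize"), root.spawn(5)
        )
    }

    cases: list[CaseMeta] = []
    slide_organ: list[str] = []
    slide_case: list[str] = []
    for organ in sorted(config.n_cases):
        n = int(config.n_cases[organ])
        counts = config.slides_per_case[organ].sample(streams["slides"], n)
        counts = np.maximum(1, np.rint(counts)).astype(int)
        for i, k in enumerate(counts, start=1):
            case_id = f"{organ}-{i:03d}"
            cases.append(CaseMeta(case_id, organ, f"{organ} specimen", int(k)))
            slide_case.extend([case_id] * int(k))
            slide_organ.extend([organ] * int(k))

    m = len(slide_case)
    pixels = np.maximum(
        1, np.rint(config.pixels_per_slide.sample(streams["pixels"], m))
    ).astype(np.int64)
    tissue = np.clip(config.tissue_fraction.sample(streams["tissue"], m), 0.0, 1.0)
    roi = tissue * np.clip(config.roi_given_tissue.sample(streams["roi"], m), 0.0, 1.0)

    log_pixel_sd = float(np.std(np.log(pixels.astype(float)), ddof=1)) if m > 1 else 0.0
    sigma = (
        solve_filesize_noise_sigma(
            log_pixel_sd, config.filesize_exponent, config.target_size_pixel_corr
        )
        if log_pixel_sd > 0
        else 0.0
    )
    noise = streams["filesize"].lognormal(0.0, sigma, m)
    size = np.maximum(
        1,
        np.rint(
            config.filesize_coeff
            * pixels.astype(float) ** config.filesize_exponent
            * noise
        ),
    ).astype(np.int64)

    slides = [
        SlideMeta(
            slide_id=f"{slide_case[j]}-s{j:05d}",
            case_id=slide_case[j],
            organ=slide_organ[j],
            n_pixels=int(pixels[j]),
            file_size_bytes=int(size[j]),
            tissue_fraction=float(tissue[j]),
            roi_fraction=float(roi[j]),
        )
        for j in range(m)
    ]
    return cases, slides


def tiles_per_slide(slide: SlideMeta, tiling: TilingSpec) -> int:
    """Tile count of one slide under the tiling's data-input mode.

    ``wsi`` counts every tile (ceiling of the pixel ratio); ``tissue`` and
    ``roi`` scale that count by the respective area fraction, again rounded
    up. Ceiling monotonicity guarantees roi <= tissue <= wsi.
    """
    wsi_tiles = math.ceil(slide.n_pixels / tiling.tile_edge_px**2)
    if tiling.mode == "wsi":
        return wsi_tiles
    if tiling.mode == "tissue":
        return math.ceil(wsi_tiles * slide.tissue_fraction)
    return math.ceil(wsi_tiles * slide.roi_fraction)


@dataclass(frozen=True)
class Workload:
    """Tile workload of a cohort under one tiling: exact partition by case/organ."""

    tiling: TilingSpec
    per_slide: pd.DataFrame  # slide_id, case_id, organ, tiles
    per_case: pd.DataFrame  # case_id, organ, n_slides, tiles
    per_organ: pd.DataFrame  # organ, n_cases, n_slides, tiles
    total_tiles: int

    @property
    def n_cases(self) -> int:
        return len(self.per_case)

    @property
    def mean_tiles_per_case(self) -> float:
        return self.total_tiles / self.n_cases


def cohort_workload(slides: Sequence[SlideMeta], tiling: TilingSpec) -> Workload:
    """Aggregate per-slide tile counts into case, organ and total workloads."""
    if len(slides) == 0:
        raise EmptyCohortError("cannot compute a workload for an empty cohort")
    per_slide = pd.DataFrame(
        {
            "slide_id": [s.slide_id for s in slides],
            "case_id": [s.case_id for s in slides],
            "organ": [s.organ for s in slides],
            "tiles": [tiles_per_slide(s, tiling) for s in slides],
        }
    )
    per_case = (
        per_slide.groupby("case_id", sort=True)
        .agg(organ=("organ", "first"), n_slides=("slide_id", "size"), tiles=("tiles", "sum"))
        .reset_index()
    )
    per_organ = (
        per_case.groupby("organ", sort=True)
        .agg(n_cases=("case_id", "size"), n_slides=("n_slides", "sum"), tiles=("tiles", "sum"))
        .reset_index()
    )
    return Workload(
        tiling=tiling,
        per_slide=per_slide,
        per_case=per_case,
        per_organ=per_organ,
        total_tiles=int(per_slide["tiles"].sum()),
    )


def validate_cohort(
    slides: Iterable[SlideMeta], cases: Iterable[CaseMeta] | None = None
) -> list[str]:
    """Report every invariant violation; an empty list means the cohort is valid.

    Checks fraction ordering, positivity, duplicate slide ids, and — when
    cases are given — orphan slides and per-case slide-count consistency.
    Report-only: never raises.
    """
    report: list[str] = []
    seen: set[str] = set()
    case_counts: dict[str, int] = {}
    for s in slides:
        if s.slide_id in seen:
            report.append(f"slide {s.slide_id}: duplicate slide_id")
        seen.add(s.slide_id)
        if s.n_pixels < 1:
            report.append(f"slide {s.slide_id}: n_pixels < 1")
        if s.file_size_bytes < 1:
            report.append(f"slide {s.slide_id}: file_size_bytes < 1")
        if not 0.0 <= s.tissue_fraction <= 1.0:
            report.append(f"slide {s.slide_id}: tissue_fraction outside [0, 1]")
        if s.roi_fraction > s.tissue_fraction:
            report.append(
                f"slide {s.slide_id}: roi_fraction {s.roi_fraction:.4f} exceeds "
                f"tissue_fraction {s.tissue_fraction:.4f}"
            )
        if s.roi_fraction < 0:
            report.append(f"slide {s.slide_id}: roi_fraction < 0")
        case_counts[s.case_id] = case_counts.get(s.case_id, 0) + 1
    if cases is not None:
        known = {c.case_id: c for c in cases}
        for case_id, n in sorted(case_counts.items()):
            if case_id not in known:
                report.append(f"slide case {case_id}: orphan (no matching case)")
            elif known[case_id].n_slides != n:
                report.append(
                    f"case {case_id}: n_slides={known[case_id].n_slides} but "
                    f"{n} slides reference it"
                )
        for case_id, c in sorted(known.items()):
            if case_id not in case_counts:
                report.append(f"case {case_id}: has no slides")
    return report


def slides_to_frame(slides: Sequence[SlideMeta], cases: Sequence[CaseMeta] | None = None) -> pd.DataFrame:
    """Cohort as a DataFrame in the CSV interchange column order."""
    spec_types = {c.case_id: c.specimen_type for c in cases} if cases else {}
    return pd.DataFrame(
        [
            {
                "slide_id": s.slide_id,
                "case_id": s.case_id,
                "organ": s.organ,
                "specimen_type": spec_types.get(s.case_id, ""),
                "n_pixels": s.n_pixels,
                "file_size_bytes": s.file_size_bytes,
                "tissue_fraction": s.tissue_fraction,
                "roi_fraction": s.roi_fraction,
            }
            for s in slides
        ],
        columns=COHORT_COLUMNS,
    )


def read_cohort_csv(path) -> tuple[list[CaseMeta], list[SlideMeta]]:
    """Load a cohort CSV (one row per slide) and rebuild case records."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns and c != "specimen_type"]
    if missing:
        raise ConfigurationError("cohort_csv", f"missing columns: {missing}")
    slides = [
        SlideMeta(
            slide_id=str(r.slide_id),
            case_id=str(r.case_id),
            organ=str(r.organ),
            n_pixels=int(r.n_pixels),
            file_size_bytes=int(r.file_size_bytes),
            tissue_fraction=float(r.tissue_fraction),
            roi_fraction=float(r.roi_fraction),
        )
        for r in df.itertuples()
    ]
    spec_types = (
        df.groupby("case_id")["specimen_type"].first().to_dict()
        if "specimen_type" in df.columns
        else {}
    )
    grouped = df.groupby("case_id", sort=True)
    cases = [
        CaseMeta(
            case_id=str(case_id),
            organ=str(g["organ"].iloc[0]),
            specimen_type=str(spec_types.get(case_id, "")),
            n_slides=len(g),
        )
        for case_id, g in grouped
    ]
    return cases, slides
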