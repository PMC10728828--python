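import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathocarbon.emission_model import (
    DEFAULT_CONSTANTS,
    GridIntensity,
    ModelConstants,
    Scenario,
    Task,
    energy_to_co2,
    forest_area_required,
    intensity_from_mix,
    make_scenario,
    pathomics_emission,
    reduction_factor,
    scanner_emission,
    scenario_emission,
    trees_required,
)
from pathocarbon.errors import CalibrationError, PathocarbonError
from pathocarbon.synthetic_cohort import TilingSpec, cohort_workload, tiles_per_slide

DEVICE = "quadro_6000"


class TestGridIntensity:
    def test_pure_renewable_floor(self):
        assert intensity_from_mix(1.0) == pytest.approx(0.03)

    def test_pure_fossil_ceiling(self):
        assert intensity_from_mix(0.0) == pytest.approx(0.70)

    def test_german_mix(self):
        # 46.2% renewable share on the linear blend
        assert intensity_from_mix(0.462) == pytest.approx(0.462 * 0.03 + 0.538 * 0.70)
        assert intensity_from_mix(0.462) == pytest.approx(0.39, abs=5e-3)

    def test_strictly_decreasing_in_share(self):
        shares = np.linspace(0, 1, 11)
        vals = [intensity_from_mix(s) for s in shares]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_share_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            intensity_from_mix(1.2)

    def test_direct_intensity_overrides_share(self):
        g = GridIntensity("Germany", renewable_share=0.462, intensity_kg_per_kwh=0.40)
        assert g.resolve() == 0.40

    def test_region_needs_share_or_intensity(self):
        with pytest.raises(ValueError):
            GridIntensity("nowhere")


class TestConversions:
    def test_energy_to_co2_product(self):
        assert energy_to_co2(0.0, 0.4) == 0.0
        assert energy_to_co2(1.0, 0.4) == pytest.approx(0.4)
        assert energy_to_co2(2292.73, 0.4) == pytest.approx(917.0, rel=1e-3)

    @pytest.mark.parametrize("kg,expected", [(0.0, 0), (21.8, 1), (21.81, 2), (7650.0, 351)])
    def test_trees_required(self, kg, expected):
        assert trees_required(kg) == expected

    def test_forest_area_unit_rate(self):
        # world capacity / world area = 7.6e9 / 40.6e6 ~ 187.19 t per km^2
        rate = DEFAULT_CONSTANTS.sequestration_t_per_km2
        km2, frac = forest_area_required(rate, region_forest_area_km2=2.0)
        assert km2 == pytest.approx(1.0)
        assert frac == pytest.approx(0.5)

    def test_forest_area_16_megatons(self):
        km2, _ = forest_area_required(16e6)
        assert km2 == pytest.approx(16e6 / (7.6e9 / 40.6e6), rel=1e-12)
        assert km2 == pytest.approx(85_474, rel=1e-4)

    def test_zero_emission_zero_area(self):
        assert forest_area_required(0.0) == (0.0, None)

    def test_bad_region_area_rejected(self):
        with pytest.raises(ValueError):
            forest_area_required(1.0, region_forest_area_km2=0.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(k=st.floats(0.01, 1e4), x=st.floats(0.0, 1e7))
    def test_conversion_homogeneity(self, k, x):
        """trees(kx) = ceil(kx/21.8); forest area is exactly degree-1."""
        assert trees_required(k * x) == math.ceil(k * x / 21.8)
        a1, _ = forest_area_required(x)
        ak, _ = forest_area_required(k * x)
        assert ak == pytest.approx(k * a1, rel=1e-12, abs=1e-12)


class TestScanner:
    def test_unit_case(self):
        assert scanner_emission(60, 1000.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_yearly_institute_scan_load(self):
        assert scanner_emission(237_179, 580.0, 1.0, 0.40) == pytest.approx(917.0, rel=1e-3)

    def test_linear_in_scan_time(self):
        one = scanner_emission(1000, 580.0, 1.0, 0.4)
        two = scanner_emission(1000, 580.0, 2.0, 0.4)
        assert two == pytest.approx(2 * one)


class TestScenarioConstruction:
    def test_compositions(self):
        assert len(make_scenario("seven_task").tasks) == 7
        types = [t.task_type for t in make_scenario("seven_task").tasks]
        assert types.count("segmentation") == 3 and types.count("classification") == 4
        assert make_scenario("multitask").tasks[0].size_class is None

    def test_two_task_mix_enforced(self):
        with pytest.raises(ValueError):
            Scenario(
                "two_task",
                (Task("a", "classification", "large"), Task("b", "classification", "large")),
            )


class TestScenarioEmission:
    def test_brute_force_per_slide_oracle(self, study_cohort, workloads, energies):
        _, slides = study_cohort
        scen = make_scenario("one_task", "large", "wsi")
        res = scenario_emission(workloads["wsi"], scen, energies, 0.40, n_boot=0)
        e = energies[("classification", "large")]
        oracle = sum(
            tiles_per_slide(s, TilingSpec(512, "wsi")) * e / 1e7 * 0.40 for s in slides
        )
        assert res.co2eq_kg == pytest.approx(oracle, rel=1e-9)

    def test_seven_tasks_with_identical_energies_is_sevenfold(self, workloads):
        energies = {("classification", "large"): 5.0, ("segmentation", "large"): 5.0}
        one = scenario_emission(
            workloads["wsi"], make_scenario("one_task", "large", "wsi"), energies, 0.4, n_boot=0
        )
        seven = scenario_emission(
            workloads["wsi"], make_scenario("seven_task", "large", "wsi"), energies, 0.4, n_boot=0
        )
        assert seven.co2eq_kg == pytest.approx(7 * one.co2eq_kg, rel=1e-12)

    def test_scenario_monotonicity(self, workloads, energies):
        vals = [
            scenario_emission(
                workloads["wsi"], make_scenario(n, "large", "wsi"), energies, 0.4, n_boot=0
            ).co2eq_kg
            for n in ("one_task", "two_task", "seven_task")
        ]
        assert vals[0] <= vals[1] <= vals[2]

    def test_input_mode_monotonicity(self, workloads, energies):
        vals = [
            scenario_emission(
                workloads[m], make_scenario("one_task", "large", m), energies, 0.4, n_boot=0
            ).co2eq_kg
            for m in ("roi", "tissue", "wsi")
        ]
        assert vals[0] <= vals[1] <= vals[2]

    def test_bilinear_in_intensity_and_energy(self, workloads):
        base = {("classification", "large"): 3.0}
        scen = make_scenario("one_task", "large", "wsi")
        a = scenario_emission(workloads["wsi"], scen, base, 0.4, n_boot=0).co2eq_kg
        b = scenario_emission(workloads["wsi"], scen, base, 0.8, n_boot=0).co2eq_kg
        c = scenario_emission(
            workloads["wsi"], scen, {("classification", "large"): 6.0}, 0.4, n_boot=0
        ).co2eq_kg
        assert b == pytest.approx(2 * a, rel=1e-12)
        assert c == pytest.approx(2 * a, rel=1e-12)

    def test_ci_contains_point_and_shrinks_with_noise(self, workloads, energies):
        scen = make_scenario("two_task", "medium", "tissue")
        widths = []
        for sd in (0.05, 0.02, 0.005, 1e-6):
            res = scenario_emission(
                workloads["tissue"], scen, energies, 0.4, noise_sd=sd, n_boot=1000, seed=9
            )
            lo, hi = res.ci95_kg
            assert lo <= res.co2eq_kg <= hi
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)
        assert widths[-1] < 1e-4 * res.co2eq_kg

    def test_per_task_breakdown_sums_to_total(self, workloads, energies):
        res = scenario_emission(
            workloads["wsi"], make_scenario("seven_task", "small", "wsi"), energies, 0.4, n_boot=50
        )
        assert sum(res.per_task_kg.values()) == pytest.approx(res.co2eq_kg, rel=1e-9)

    def test_offsets_attached(self, workloads, energies):
        res = scenario_emission(
            workloads["wsi"], make_scenario("one_task", "large", "wsi"), energies, 0.4,
            n_boot=0, region_forest_km2={"Germany": 114_000.0},
        )
        assert res.offsets.trees == math.ceil(res.co2eq_kg / 21.8)
        assert res.offsets.forest_fraction["Germany"] == pytest.approx(
            res.offsets.forest_km2 / 114_000.0
        )

    def test_missing_profile_rejected(self, workloads):
        with pytest.raises(CalibrationError):
            scenario_emission(
                workloads["wsi"], make_scenario("multitask", input_mode="wsi"), {}, 0.4
            )

    def test_mode_mismatch_rejected(self, workloads, energies):
        with pytest.raises(PathocarbonError, match="mode"):
            scenario_emission(
                workloads["roi"], make_scenario("one_task", "large", "wsi"), energies, 0.4
            )

    def test_zero_tiles_zero_emission(self, study_cohort, energies):
        _, slides = study_cohort
        # construct an all-zero ROI workload by zeroing fractions
        from pathocarbon.synthetic_cohort import SlideMeta

        flat = [
            SlideMeta(s.slide_id, s.case_id, s.organ, s.n_pixels, s.file_size_bytes, 0.0, 0.0)
            for s in slides[:10]
        ]
        w = cohort_workload(flat, TilingSpec(512, "roi"))
        res = scenario_emission(w, make_scenario("one_task", "large", "roi"), energies, 0.4)
        assert res.co2eq_kg == 0.0 and res.offsets.trees == 0


class TestReductionComparators:
    def test_reduction_factor(self, workloads, energies):
        big = scenario_emission(
            workloads["wsi"], make_scenario("one_task", "large", "wsi"), energies, 0.4, n_boot=0
        )
        small = scenario_emission(
            workloads["roi"], make_scenario("one_task", "small", "roi"), energies, 0.4, n_boot=0
        )
        assert reduction_factor(big, big) == pytest.approx(1.0)
        assert reduction_factor(big, small) == pytest.approx(big.co2eq_kg / small.co2eq_kg)

    def test_pathomics_single_pass_reduces_to_scenario(self, workloads, size_classes, energies):
        seg = size_classes["segmentation"]["small"]
        res = pathomics_emission(workloads["tissue"], seg, DEVICE, 0.4, n_boot=0)
        ref_energies = {("segmentation", "small"): seg.energy_on(DEVICE)}
        scen = Scenario("one_task", (Task("segmentation", "segmentation", "small"),), "tissue")
        ref = scenario_emission(workloads["tissue"], scen, ref_energies, 0.4, n_boot=0)
        assert res.co2eq_kg == pytest.approx(ref.co2eq_kg, rel=1e-12)

    def test_pathomics_overhead_scales(self, workloads, size_classes):
        seg = size_classes["segmentation"]["small"]
        base = pathomics_emission(workloads["tissue"], seg, DEVICE, 0.4, n_boot=0)
        plus = pathomics_emission(
            workloads["tissue"], seg, DEVICE, 0.4, overhead_fraction=0.10, n_boot=0
        )
        assert plus.co2eq_kg == pytest.approx(1.10 * base.co2eq_kg, rel=1e-12)

    def test_pathomics_vs_multitask_ratio_matches_hand_division(
        self, workloads, size_classes, energies
    ):
        seg = size_classes["segmentation"]["small"]
        pathomics = pathomics_emission(
            workloads["tissue"], seg, DEVICE, 0.4,
            detection_profile=size_classes["segmentation"]["small"], n_boot=0,
        )
        multi = scenario_emission(
            workloads["tissue"], make_scenario("multitask", input_mode="tissue"),
            energies, 0.4, n_boot=0,
        )
        assert reduction_factor(multi, pathomics) == pytest.approx(
            multi.co2eq_kg / pathomics.co2eq_kg, rel=1e-12
        )
        assert reduction_factor(multi, pathomics) > 1.0

    def test_pathomics_requires_tissue_mode(self, workloads, size_classes):
        with pytest.raises(PathocarbonError):
            pathomics_emission(workloads["wsi"], size_classes["segmentation"]["small"], DEVICE, 0.4)


class TestConstants:
    def test_renewable_below_fossil_enforced(self):
        with pytest.raises(ValueError):
            ModelConstants(intensity_fossil_kg_per_kwh=0.02)
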