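import pytest

from pathocarbon.emission_model import build_energy_table
from pathocarbon.power_accounting import (
    estimate_multitask_energy,
    fit_param_energy,
    packaged_calibration_path,
    read_calibration_csv,
    select_size_classes,
)
from pathocarbon.synthetic_cohort import (
    CohortConfig,
    TilingSpec,
    cohort_workload,
    generate_cohort,
)

DEVICE = "quadro_6000"


@pytest.fixture(scope="session")
def profiles():
    return read_calibration_csv(packaged_calibration_path())


@pytest.fixture(scope="session")
def size_classes(profiles):
    return select_size_classes(profiles, DEVICE)


@pytest.fixture(scope="session")
def regression_fit(profiles):
    return fit_param_energy(profiles, DEVICE, n_boot=2000, seed=11)


@pytest.fixture(scope="session")
def multitask_estimate(regression_fit):
    return estimate_multitask_energy(regression_fit)


@pytest.fixture(scope="session")
def energies(size_classes, multitask_estimate):
    point, _, _ = multitask_estimate
    return build_energy_table(size_classes, DEVICE, multitask_kwh_per_ref=point)


@pytest.fixture(scope="session")
def study_cohort():
    """The study-shaped cohort: 5 prostate + 8 breast cases."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def workloads(study_cohort):
    _, slides = study_cohort
    return {
        mode: cohort_workload(slides, TilingSpec(512, mode))
        for mode in ("wsi", "tissue", "roi")
    }
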