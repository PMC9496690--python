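import numpy as np
import pytest

from sersdx.spectra_io import MappingGroup, Spectrum, canonical_grid
from sersdx.synthetic import (
    ClassTemplate,
    CohortDesign,
    PeakModel,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def grid():
    return canonical_grid()


@pytest.fixture()
def single_peak():
    """One unit-height Lorentzian band at the phenylalanine position."""
    return PeakModel(center=1000.0, width=5.0, base_amplitude=1.0)


@pytest.fixture()
def toy_group(grid):
    """Three deterministic spectra on the canonical grid in one mapping."""
    rng = np.random.default_rng(7)
    spectra = [
        Spectrum(grid, rng.uniform(0.1, 1.0, size=grid.size), {"sample_id": "toy"})
        for _ in range(3)
    ]
    return MappingGroup("toy", spectra)


def small_cohort_design(seed=0, noise=0.05, cv=0.02, spectra_per_mapping=8):
    """A fast 2-class cohort for classifier/evaluation tests."""
    classes = (
        ClassTemplate("normal", (1.0,) * 6),
        ClassTemplate("dementia", (1.5, 0.65, 1.6, 0.6, 1.45, 0.65)),
    )
    return CohortDesign(
        classes=classes,
        samples_per_class=3,
        replicates_per_sample=1,
        spectra_per_mapping=spectra_per_mapping,
        sample_cv=cv,
        spectrum_noise_sd=noise,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    groups, records, severities = simulate_cohort(small_cohort_design())
    labels = {r.sample_id: r.label for r in records}
    return groups, labels
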