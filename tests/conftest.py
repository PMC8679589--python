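import numpy as np
import pytest

import tmtvkit as tk


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def uniform_volume():
    """Factory for a constant-SUV volume."""

    def make(value=1.0, shape=(20, 20, 20), spacing=2.0):
        return tk.SUVVolume(np.full(shape, float(value)), spacing)

    return make


@pytest.fixture
def sharp_lesion_phantom():
    """Factory: noiseless body with hard-edged spherical lesions of known volume.

    Background SUV 1, lesion SUV constant inside the sphere; the reference
    admission stats are fixed at mean 1.6 / SD 0.5 (threshold 4.2).
    """

    def make(lesion_specs, shape=(64, 64, 64), spacing=2.0, background=1.0):
        spec = tk.PhantomSpec(
            shape=shape,
            spacing=(spacing,) * 3,
            background_suv=background,
            lesions=tuple(
                tk.BlobSpec.sphere(center, radius, suv, blur_sigma_mm=0.0)
                for center, radius, suv in lesion_specs
            ),
            noise_sigma=0.0,
            aorta_center_mm=(spacing * shape[0] / 2, spacing * shape[1] / 2, spacing * 4),
            seed=0,
        )
        vol, truth = tk.generate_phantom(spec)
        return vol, truth, tk.ReferenceStats(mean_suv=1.6, sd_suv=0.5)

    return make


@pytest.fixture(scope="session")
def small_cohort():
    """10-subject default-condition cohort processed with the oracle classifier."""
    cohort = tk.generate_cohort(tk.CohortSpec(n_subjects=10, seed=11))
    clf = tk.OracleClassifier()
    results = [
        tk.process_subject(f"S{i:03d}", vol, tk.PRESETS["percist42"], clf,
                           truth=truth, settings_name="percist42")
        for i, (vol, truth) in enumerate(cohort)
    ]
    return cohort, results
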