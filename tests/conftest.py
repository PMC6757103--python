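import numpy as np
import pytest

from specklestrain import (
    CohortSpec,
    PhantomSpec,
    generate_cohort,
    generate_speckle_sequence,
    generate_strain_profile,
)


@pytest.fixture(scope="session")
def small_phantom_spec():
    """A reduced phantom (quarter-size, 3 s) that tracks in ~a second."""
    return PhantomSpec(
        height_px=160,
        width_px=220,
        mm_per_px=38.0 / 418.0,
        fps=50.0,
        duration_s=3.0,
        band_rows=(40, 120),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec):
    """(frames, truth, spec) for a noise-free +8% ramp-hold-release phantom."""
    profile = generate_strain_profile(
        small_phantom_spec, target_strain_pct=8.0, ramp_s=1.2, hold_s=0.8
    )
    frames, truth = generate_speckle_sequence(small_phantom_spec, profile)
    return frames, truth, small_phantom_spec


@pytest.fixture(scope="session")
def noise_free_linear_cohort():
    spec = CohortSpec(
        n_subjects=6,
        relationship="linear",
        subject_scale_sd=0.3,
        coactivation_sd=0.0,
        trial_noise_sd=0.0,
        elapsed_sd_s=0.0,
        seed=11,
    )
    return generate_cohort(spec), spec


@pytest.fixture(scope="session")
def default_cohort():
    spec = CohortSpec(seed=5)
    return generate_cohort(spec), spec
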