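import numpy as np
import pytest
from hypothesis import settings

import opendce as od

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def small_spec():
    """Three attributes (3, 2, 3 levels), 8 tasks, pairwise choices."""
    return od.StudySpec(
        attributes=(
            od.AttributeSpec("color", ("red", "green", "blue")),
            od.AttributeSpec("size", ("small", "large")),
            od.AttributeSpec("shape", ("round", "square", "hex")),
        ),
        n_tasks=8,
        n_alternatives=2,
    )


@pytest.fixture(scope="session")
def map_spec():
    """The six-attribute contraceptive-patch study spec with the
    duration-by-menstruation interaction."""
    spec, _, _ = od.study_preset("india")
    return spec


@pytest.fixture(scope="session")
def small_design(small_spec):
    return od.generate_design(small_spec, n_versions=2, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_spec, small_design):
    """Simulated choices from a known moderate-signal population."""
    rng = np.random.default_rng(0)
    cm = od.CodedMatrix.from_spec(small_spec)
    beta_mean = np.linspace(-0.8, 0.8, cm.n_params)
    beta = beta_mean + 0.3 * rng.standard_normal((40, cm.n_params))
    return od.simulate_choices(beta, small_design, seed=1)
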