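"""Shared fixtures: templates, modes and cohorts are expensive, so they are
built once per session and treated as read-only by the tests."""

import numpy as np
import pytest

from footshape import alignment, shape_model
from footshape.synthetic_cohort import (
    GeneratorConfig,
    build_template_foot,
    define_modes,
    sample_cohort,
)

COHORT_SEED = 7


@pytest.fixture(scope="session")
def template():
    return build_template_foot(2500)


@pytest.fixture(scope="session")
def small_template():
    return build_template_foot(1000)


@pytest.fixture(scope="session")
def modes(template):
    return define_modes(template, 6)


@pytest.fixture(scope="session")
def cohort(template, modes):
    """Default study conditions: 62 subjects x 4 scans, template topology."""
    cfg = GeneratorConfig(n_subjects=62, seed=COHORT_SEED)
    subjects, scans = sample_cohort(cfg, template=template, modes=modes)
    return cfg, subjects, scans


@pytest.fixture(scope="session")
def aligned_cohort(cohort):
    _, _, scans = cohort
    coords = np.stack(
        [np.asarray(s.mesh.vertices, float).reshape(-1) for s in scans]
    )
    return alignment.gpa(coords, reference_update_iters=3)


@pytest.fixture(scope="session")
def cohort_model(aligned_cohort):
    return shape_model.fit_pca(aligned_cohort, "full")
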