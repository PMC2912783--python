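import pytest

from subtypepredict import (
    SimulationSpec,
    build_reference,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_spec():
    """The default study conditions: six-leaf glioma hierarchy, 20 samples per
    leaf, 30 classifier genes per node, per-gene shift 4 sigma_e."""
    return SimulationSpec(seed=11)


@pytest.fixture(scope="session")
def cohort(default_spec):
    return simulate_cohort(default_spec)


@pytest.fixture(scope="session")
def models(default_spec, cohort):
    reference, classifier_sets = cohort
    return build_reference(reference, default_spec.hierarchy, classifier_sets)
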