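"""Shared fixtures: a modest synthetic cohort scored end-to-end.

Session-scoped so the generation/scoring cost is paid once.
"""

import pytest

from socmob.pipeline import compute_scores
from socmob.synthetic import SyntheticConfig, generate_cohort, generate_reference_panel


@pytest.fixture(scope="session")
def config():
    return SyntheticConfig(n_subjects=3000, seed=11)


@pytest.fixture(scope="session")
def cohort(config):
    return generate_cohort(config)


@pytest.fixture(scope="session")
def reference(config):
    return generate_reference_panel(config, n=6000)


@pytest.fixture(scope="session")
def analysis(cohort, reference):
    """Full analysis table: advancement outcomes + SES scores + mobility."""
    return compute_scores(cohort.subjects, cohort.wealth, reference)
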