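"""Shared fixtures: small synthetic surveys and reference tables."""

from __future__ import annotations

import pytest

from hcesfort import generate_fixtures, generate_survey
from hcesfort.synthetic import SurveyDesignConfig, default_model


def small_design(clusters=(2, 2, 4, 2)) -> SurveyDesignConfig:
    labels = ["Dar es Salaam", "Mainland other urban", "Mainland rural", "Zanzibar"]
    return SurveyDesignConfig(
        clusters_per_stratum=dict(zip(labels, clusters)))


@pytest.fixture(scope="session")
def fixtures_tables():
    return generate_fixtures(seed=0)


@pytest.fixture(scope="session")
def small_survey():
    """An 80-household survey across all four strata with ground truth."""
    design = small_design()
    return generate_survey(design=design, model=default_model(design), seed=7)
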