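"""Shared fixtures: the packaged reference design, its fitted surface, and
small synthetic campaigns reused across test modules."""

import json

import numpy as np
import pytest
from hypothesis import settings

from rsmtune import SimConfig, generate, make_split
from rsmtune.rsm import TransformSpec, anova, fit_quadratic
from rsmtune.workflow import (
    _data_path,
    load_reference_design,
    run_conventional_campaign,
    run_rsm_campaign,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

CAMPAIGN_SEED = 5
CAMPAIGN_N = 900
CAMPAIGN_EPOCH_SCALE = 0.05


@pytest.fixture(scope="session")
def reference_design():
    return load_reference_design()


@pytest.fixture(scope="session")
def reference_surface(reference_design):
    return fit_quadratic(reference_design, TransformSpec(0.0))


@pytest.fixture(scope="session")
def reference_anova(reference_surface, reference_design):
    return anova(reference_surface, reference_design)


@pytest.fixture(scope="session")
def published():
    return json.loads(_data_path("reference_values.json").read_text())


@pytest.fixture(scope="session")
def small_dataset():
    return generate(SimConfig(n_samples=CAMPAIGN_N, seed=CAMPAIGN_SEED))


@pytest.fixture(scope="session")
def small_plan(small_dataset):
    return make_split(len(small_dataset), 0.6, 3, seed=CAMPAIGN_SEED)


@pytest.fixture(scope="session")
def rsm_report(small_dataset, small_plan):
    return run_rsm_campaign(
        small_dataset, seed=CAMPAIGN_SEED, plan=small_plan,
        epoch_scale=CAMPAIGN_EPOCH_SCALE,
    )


@pytest.fixture(scope="session")
def conventional_reports(small_dataset, small_plan):
    return {
        alg: run_conventional_campaign(
            small_dataset, alg, seed=CAMPAIGN_SEED, plan=small_plan,
            epoch_scale=CAMPAIGN_EPOCH_SCALE,
        )
        for alg in ("lm", "gdm")
    }
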