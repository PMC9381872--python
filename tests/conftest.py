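"""Shared fixtures: one default synthetic campaign and one pipeline run."""

from __future__ import annotations

import pytest

from crustfix import CampaignConfig, default_params, generate_campaign, noiseless
from crustfix.pipeline import run_pipeline
from crustfix.synthetic import Normal


@pytest.fixture(scope="session")
def default_campaign_dir(tmp_path_factory):
    """A default-design campaign (seed 1) written to disk."""
    path = tmp_path_factory.mktemp("campaign")
    generate_campaign(CampaignConfig(seed=1)).to_dir(path)
    return path


@pytest.fixture(scope="session")
def pipeline_out(default_campaign_dir, tmp_path_factory):
    """Full pipeline outputs for the default campaign."""
    out = tmp_path_factory.mktemp("pipeline")
    manifest = run_pipeline(default_campaign_dir, out)
    return out, manifest


@pytest.fixture(scope="session")
def noiseless_campaign_dir(tmp_path_factory):
    """A campaign with every SD, CV and censoring probability zeroed."""
    path = tmp_path_factory.mktemp("noiseless")
    config = CampaignConfig(
        seed=3,
        gc_noise_cv=0.0,
        dry_mass_g=Normal(mean=4.9, sd=0.0),
        blank_nmol=Normal(mean=0.4, sd=0.0),
    )
    generate_campaign(config, noiseless(default_params())).to_dir(path)
    return path


@pytest.fixture(scope="session")
def noiseless_out(noiseless_campaign_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("noiseless_out")
    manifest = run_pipeline(noiseless_campaign_dir, out)
    return out, manifest
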