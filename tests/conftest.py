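"""Shared fixtures: a generated synthetic quarter and its parsed stages."""

from __future__ import annotations

import dataclasses

import pytest

from faers_signalminer.case_dedup import deduplicate
from faers_signalminer.cohort import SynonymList
from faers_signalminer.faers_io import join_cases, read_quarter
from faers_signalminer.synthetic_faers import (
    SyntheticConfig,
    generate,
    pt_soc_map_from_config,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A quarter small enough for fast end-to-end runs, with heavy duplication."""
    return SyntheticConfig(seed=11, n_cases=600, target_share=0.08, duplication_rate=0.3)


@pytest.fixture(scope="session")
def quarter(tmp_path_factory, small_config):
    """(directory, ground truth) of a generated quarter."""
    out = tmp_path_factory.mktemp("quarter")
    truth = generate(small_config, out)
    return out, truth


@pytest.fixture(scope="session")
def synonyms() -> SynonymList:
    return SynonymList.default()


@pytest.fixture(scope="session")
def pt_soc_map(small_config):
    return pt_soc_map_from_config(small_config)


@pytest.fixture(scope="session")
def joined(quarter):
    directory, _ = quarter
    tables = read_quarter(directory)
    return join_cases(tables["DEMO"], tables["DRUG"], tables["REAC"], tables["THER"])


@pytest.fixture(scope="session")
def kept_cases(joined):
    return deduplicate(joined.cases).kept
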