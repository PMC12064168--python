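from __future__ import annotations

import dataclasses

import pytest

from trhkit.chain_lift import ChainSet
from trhkit.synthetic_fixtures import (
    PRESETS,
    FixtureSpec,
    make_cohort_vcf,
    make_genome_pair,
)


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    return dataclasses.replace(PRESETS["small"], seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return make_genome_pair(small_spec)


@pytest.fixture(scope="session")
def medium_spec() -> FixtureSpec:
    return dataclasses.replace(PRESETS["medium"], seed=7)


@pytest.fixture(scope="session")
def medium_bundle(medium_spec):
    return make_genome_pair(medium_spec)


@pytest.fixture(scope="session")
def small_cohort(small_spec, small_bundle):
    return make_cohort_vcf(small_spec, small_bundle.catalog_a)


@pytest.fixture(scope="session")
def small_chains(small_bundle):
    return ChainSet(small_bundle.chains_ab), ChainSet(small_bundle.chains_ba)


@pytest.fixture()
def vcf_file(tmp_path):
    """Write VCF text to a temp file and return its path."""

    def write(text: str):
        path = tmp_path / "cohort.vcf"
        path.write_text(text)
        return path

    return write
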