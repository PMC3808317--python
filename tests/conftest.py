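"""Shared fixtures: a small synthetic study generated once per session.

The small study uses reduced depths so unit tests stay fast; the
acceptance suite builds the full-scale study itself.
"""

from __future__ import annotations

import dataclasses

import pytest

from mirstress.annotate import annotate_tags
from mirstress.preprocess import clean_reads, collapse_to_tags, merge_tag_sets
from mirstress.simulate import SimConfig, simulate_study

SMALL = dict(library_depth=20_000, degradome_depth=5_000)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=11, **SMALL)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_tags(small_bundle, small_config):
    ck = clean_reads(small_bundle.reads_ck, small_config.adapter3, small_config.adapter5)
    cd = clean_reads(small_bundle.reads_cd, small_config.adapter3, small_config.adapter5)
    return merge_tag_sets(
        collapse_to_tags(ck.sequences, "CK"), collapse_to_tags(cd.sequences, "Cd200")
    )


@pytest.fixture(scope="session")
def small_annotation(small_bundle, small_tags):
    return annotate_tags(small_tags, small_bundle.reference, small_bundle.ncrna)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory, small_config):
    """The small study written to disk (for pipeline/CLI tests)."""
    outdir = tmp_path_factory.mktemp("study")
    simulate_study(dataclasses.replace(small_config), outdir)
    return outdir
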