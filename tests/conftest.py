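"""Shared fixtures: all test data is generated programmatically."""

import pytest

from csabref.families import GENERATOR_TEMPLATES, TEMPLATES
from csabref.mapping import map_to_reference
from csabref.records import PeptideRecord
from csabref.simulate import generate


@pytest.fixture(scope="session")
def insect_record() -> PeptideRecord:
    """One canonical six-cysteine insect-type fixture."""
    return generate("insect_type", 1, seed=101)[0]


@pytest.fixture(scope="session")
def family_records() -> dict[str, PeptideRecord]:
    """One fixture per generator family template."""
    return {name: generate(name, 1, seed=202)[0] for name in GENERATOR_TEMPLATES}


@pytest.fixture(scope="session")
def family_mappings(family_records):
    return {name: map_to_reference(rec) for name, rec in family_records.items()}


@pytest.fixture
def templates():
    return TEMPLATES
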