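"""Shared fixtures: small synthetic records with known ground truth."""

import pytest

from orgmap import default_config, read_genbank_string
from orgmap.fixtures import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def plastome():
    """30 kb plastome-like record with a planted 3 kb IR pair and introns."""
    text, truth = make_fixture(
        FixtureSpec(
            kind="plastome_like",
            length_bp=30_000,
            ir_len=3_000,
            n_genes=25,
            plant_introns=True,
            seed=11,
            enzymes=("EcoRI", "HindIII"),
        )
    )
    record = read_genbank_string(text)[0]
    return record, truth, text


@pytest.fixture(scope="session")
def mitogenome():
    """16 kb mitogenome-like record with an origin-wrapping D-loop."""
    text, truth = make_fixture(
        FixtureSpec(
            kind="mitogenome_like",
            length_bp=16_000,
            n_genes=20,
            wrap_origin_feature=True,
            seed=12,
        )
    )
    record = read_genbank_string(text)[0]
    return record, truth, text


@pytest.fixture()
def plastid_config():
    return default_config("plastid")
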