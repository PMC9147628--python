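import json
from pathlib import Path

import pytest

from igsflow import SampleManifest, SpeciesRole
from igsflow.seqio import Sample

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def filter_fixture_path() -> Path:
    return DATA / "filter_fixture.tsv"


@pytest.fixture(scope="session")
def filter_fixture_expected() -> dict:
    with open(DATA / "filter_fixture_expected.json") as fh:
        return json.load(fh)


@pytest.fixture()
def toy_manifest() -> SampleManifest:
    """Two focal species with two samples each, one outgroup with one."""
    samples = [
        Sample("T1", "V_tricolor", "complex_member", 1),
        Sample("T2", "V_tricolor", "complex_member", 1),
        Sample("A1", "V_arvensis", "complex_member", 1),
        Sample("A2", "V_arvensis", "complex_member", 2),
        Sample("K1", "V_kitaibeliana", "complex_member", 1),
        Sample("K2", "V_kitaibeliana", "complex_member", 1),
        Sample("H1", "V_hymettia", "complex_member", 1),
        Sample("O1", "V_eugeniae", "outgroup", 1),
    ]
    roles = {
        "V_tricolor": SpeciesRole("complex_member", is_tricolor=True),
        "V_arvensis": SpeciesRole("complex_member", is_arvensis=True),
        "V_kitaibeliana": SpeciesRole("complex_member", is_kit_or_hym=True),
        "V_hymettia": SpeciesRole("complex_member", is_kit_or_hym=True),
        "V_eugeniae": SpeciesRole("outgroup"),
    }
    return SampleManifest(samples=samples, roles=roles)
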