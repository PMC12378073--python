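import pytest

from bmrisk.data import DEFAULT_SPECS, ConcentrationRecord
from bmrisk.synthetic import paper_fixture


@pytest.fixture(scope="session")
def fixture_bundle():
    """The pinned survey-emulation fixture, built once per session."""
    return paper_fixture()


@pytest.fixture(scope="session")
def specs():
    return DEFAULT_SPECS


def make_records(values, analyte="MEL", lod=90.0):
    """Build records from a list where None marks a non-detect."""
    out = []
    for i, v in enumerate(values):
        if v is None:
            out.append(ConcentrationRecord(f"S{i + 1:03d}", analyte, None, True))
        else:
            out.append(
                ConcentrationRecord(f"S{i + 1:03d}", analyte, float(v), v < lod)
            )
    return out
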