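import itertools

import pytest
from hypothesis import HealthCheck, settings

from sulfsite.windowing import PeptideWindow

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

_counter = itertools.count(1)


def _make_window(residues: str) -> PeptideWindow:
    """A 21-mer window with unique synthetic provenance."""
    assert len(residues) == 21 and residues[10] == "C"
    i = next(_counter)
    return PeptideWindow(
        residues=residues,
        center_index=10,
        source_protein=f"TEST{i:05d}",
        site_position=11,
    )


def window_from_flanks(flanks: str) -> PeptideWindow:
    """Build a window from its 20 flanking residues (center C inserted)."""
    assert len(flanks) == 20
    return _make_window(flanks[:10] + "C" + flanks[10:])


@pytest.fixture
def make_window():
    return _make_window


@pytest.fixture
def make_window_from_flanks():
    return window_from_flanks
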