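import numpy as np
import pytest

from indelpop import polish_panel_counts, polish_panel_frame
from indelpop.types import Locus, LocusCounts


@pytest.fixture(scope="session")
def panel_frame():
    """Published per-locus summary for the 30-locus Polish DIP panel."""
    return polish_panel_frame()


@pytest.fixture(scope="session")
def panel_counts():
    """Genotype counts reconstructed from the published summaries (n = 631)."""
    return polish_panel_counts()


@pytest.fixture
def make_counts():
    def _make(n_dd, n_di, n_ii, locus_id="LOC"):
        return LocusCounts(Locus(locus_id), n_dd, n_di, n_ii)

    return _make
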