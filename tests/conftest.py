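import numpy as np
import pytest

from phycolight import default_grid, default_palmaria_profile, make_palmaria_spectra


@pytest.fixture
def grid():
    return default_grid(400.0, 800.0, 1.0)


@pytest.fixture
def palmaria():
    """Default red-algal fixture: PS II red weight 0.40, dilution 0.5."""
    return make_palmaria_spectra(default_palmaria_profile(0.40), dilution=0.5)
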