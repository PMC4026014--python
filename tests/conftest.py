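import logging

import numpy as np
import pytest

from fticrmet.simulate import StudyDesign, generate_panel

logging.getLogger("fticrmet").setLevel(logging.ERROR)


@pytest.fixture
def design():
    return StudyDesign()


@pytest.fixture
def small_panel():
    """A mixed panel: 40 trended (10 per cluster) + 60 null metabolites."""
    return generate_panel(
        n_metabolites=100,
        cluster_fractions=(0.1, 0.1, 0.1, 0.1),
        effect_size=1.5,
        seed=42,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
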