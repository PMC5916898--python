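import numpy as np
import pandas as pd
import pytest

from kdapp import ReporterMatrix, build_channel_map


@pytest.fixture(scope="session")
def tmt10_map():
    """The standard ten-point, 3-fold titration from 3 uM."""
    return build_channel_map(3000.0, 3.0, 10)


@pytest.fixture
def toy_matrix(tmt10_map):
    """Three proteins with clean intensities, no missing cells."""
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.uniform(10, 100, size=(3, 10)),
        index=["P1", "P2", "P3"],
        columns=list(tmt10_map.channel_labels),
    )
    return ReporterMatrix("exp", "bait", "rep1", df)
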