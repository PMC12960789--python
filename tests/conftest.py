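import warnings

import numpy as np
import pytest

from alcolag import AnnualSeries, SimulationConfig, generate_study

# statsmodels emits user-facing warnings (e.g. about date-less indexes in
# helper fits) that are irrelevant to the assertions here
warnings.filterwarnings("ignore", category=UserWarning, module="statsmodels")


@pytest.fixture
def linear_series() -> AnnualSeries:
    return AnnualSeries(label="lin", start_year=1950,
                        values=10.0 + 0.5 * np.arange(40), unit="u")


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study dataset plus its ground truth (seed 7)."""
    return generate_study(SimulationConfig(seed=7))
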