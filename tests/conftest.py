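import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from ecgbp import Coupling, GridConfig, SimConfig, SplitSpec, generate_cohort
from ecgbp.pipeline import build_feature_table

#: fully coupled configuration: all label variance is driven by the
#: ECG-visible latents (amplitude and rate), so labels are a deterministic
#: function of the ECG by construction
FULL_COUPLING = Coupling(
    amp_to_sbp=float(np.sqrt(0.91)), rate_to_sbp=0.3,
    amp_to_dbp=float(np.sqrt(0.91)), rate_to_dbp=0.3,
)


@pytest.fixture(scope="session")
def coupled_cohort():
    """Two coupled low-noise subjects, 5 minutes each."""
    cfg = SimConfig(
        duration_s=300.0, coupling=FULL_COUPLING,
        hr_jitter_frac=0.05, noise_sd=0.005, seed=3,
    )
    return generate_cohort(2, cfg)


@pytest.fixture(scope="session")
def coupled_table(coupled_cohort):
    """Pooled feature table of the coupled cohort at 4-second epochs."""
    return build_feature_table(coupled_cohort, 4.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
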