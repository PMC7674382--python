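import numpy as np
import pytest

from nmmt.physics import TwoPoolParams
from nmmt.presets import LC_SUBJECT1, LC_MEAN, PONS_MEAN, SN_MEAN


@pytest.fixture(scope="session")
def lc1_params() -> TwoPoolParams:
    """Single-subject LC two-pool set (R1f from the observed-T1 constraint)."""
    return LC_SUBJECT1.params()


@pytest.fixture(scope="session")
def roi_presets():
    return {"LC": LC_MEAN, "SN": SN_MEAN, "Pons": PONS_MEAN}


@pytest.fixture(scope="session")
def random_valid_params():
    """20 random valid two-pool parameter sets (fixed seed)."""
    rng = np.random.default_rng(42)
    out = []
    for _ in range(20):
        out.append(
            TwoPoolParams(
                R1f=rng.uniform(0.25, 2.0),
                R1r=rng.uniform(0.5, 4.0),
                T2f=rng.uniform(0.05, 0.3),
                T2r=rng.uniform(5e-6, 40e-6),
                krf=rng.uniform(1.0, 60.0),
                f=rng.uniform(0.01, 0.25),
            )
        )
    return out
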