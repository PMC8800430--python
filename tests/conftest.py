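import numpy as np
import pytest

from cellugel import SynthConfig, UnifiedModelParams, generate_saxs_curve
from cellugel.tables import unified_params_published


@pytest.fixture
def space_upper_params() -> UnifiedModelParams:
    return unified_params_published("space", "upper")


@pytest.fixture
def ground_middle_params() -> UnifiedModelParams:
    return unified_params_published("ground", "middle")


@pytest.fixture
def noiseless_space_upper_curve(space_upper_params):
    cfg = SynthConfig(kind="saxs", seed=0, noise=0.0, grid={"n": 300},
                      truth=space_upper_params.to_dict())
    return generate_saxs_curve(cfg)


def perturbed_init(params: UnifiedModelParams, seed: int, frac: float = 0.2):
    """Deterministically jittered starting point for fit tests."""
    rng = np.random.default_rng(seed)
    d = {k: v * rng.uniform(1 - frac, 1 + frac) for k, v in params.to_dict().items()}
    d["p1"] = float(np.clip(d["p1"], 0.2, 8.0))
    d["p2"] = float(np.clip(d["p2"], 0.2, 8.0))
    d["rg1"] = max(d["rg1"], d["rg2"] * 1.2)
    return UnifiedModelParams(**d)
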