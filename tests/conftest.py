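import numpy as np
import pytest

from plasdyn import ModelParams, ModelVariant, lhs_sample, run_experiment_II


@pytest.fixture
def defaults() -> ModelParams:
    return ModelParams()


def random_params(n: int, seed: int, **forced) -> list[ModelParams]:
    """Random parameter sets from the scan's sampling ranges."""
    design = lhs_sample(n, seed=seed)
    out = []
    for _, row in design.iterrows():
        kwargs = {c: float(row[c]) for c in ("k", "psi", "alpha", "beta", "omega",
                                             "upsilon", "tau", "gamma", "chi")}
        kwargs.update(forced)
        out.append(ModelParams(**kwargs))
    return out


@pytest.fixture(scope="session")
def scan_small():
    """Shared 1,000-set global scan (both regimes, all variants)."""
    return run_experiment_II(1000, seed=2)


@pytest.fixture(scope="session")
def scan_large():
    """Shared 5,000-set global scan used for the amelioration-equivalence read-out."""
    return run_experiment_II(5000, seed=1)
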