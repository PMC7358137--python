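import numpy as np
import pytest

from simap import pipeline, synthetic
from simap.synthetic import SentinelProfile, SimulationConfig, VariantTruth


NOISELESS = SimulationConfig(seed=0, sigma_spot=0.0, sigma_plate=0.0,
                             sigma_a600=0.0, label_noise=0.0)


@pytest.fixture(scope="session")
def noiseless_cfg() -> SimulationConfig:
    return NOISELESS


@pytest.fixture(scope="session")
def f_grid_panel() -> list[VariantTruth]:
    """20 variants spanning the full functional range, plus wt/vector."""
    levels = [0.0, 0.25, 0.5, 0.75, 1.0, 1.2]
    panel = [VariantTruth(f"v{i:04d}", levels[i % len(levels)],
                          levels[i % len(levels)] <= 0.5, levels[i % len(levels)] <= 0.5)
             for i in range(20)]
    panel.append(VariantTruth("wt", 1.0, False, False))
    panel.append(VariantTruth("vector", 0.0, True, True))
    return panel


@pytest.fixture(scope="session")
def default_study() -> dict:
    """One full synthetic study at default noise (100 variants, 8 sentinels).

    Session-scoped: several tests measure different properties of the same
    simulated dataset, exactly as one analysis run would.
    """
    study = pipeline.simulate_study(SimulationConfig(seed=1))
    study["miniarray_scores"] = pipeline.run_miniarray(
        study["miniarray_spots"], study["layouts"])
    return study


@pytest.fixture()
def toy_sentinels() -> dict[str, SentinelProfile]:
    return {f"s{i}": SentinelProfile(f"s{i}", base_area=200.0, d=d)
            for i, d in enumerate((0.6, 0.3, 0.1))}
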