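import numpy as np
import pytest

from fhrkit.evaluation import match_peaks
from fhrkit.signal_io import PipelineConfig, run_pipeline
from fhrkit.synthetic_ecg import SimulationConfig, simulate_recording


@pytest.fixture(scope="session")
def sim_recording():
    """One seeded 60 s default simulated recording."""
    return simulate_recording(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(sim_recording):
    """The full pipeline run once on the seeded default recording."""
    return run_pipeline(sim_recording, PipelineConfig())


def score(result, recording, tolerance=50, burn_in=12000):
    return match_peaks(
        result.peaks,
        recording.foetal_peaks,
        recording.maternal_peaks,
        tolerance=tolerance,
        burn_in=burn_in,
        n_samples=recording.n,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
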