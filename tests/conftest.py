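import warnings

import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

import bioassayfit as bf


@pytest.fixture(scope="session")
def lab_dataset():
    """A resistant-strain style synthetic dataset with known truth."""
    spec = bf.preset_scenarios()["lab_resistant"]
    return spec, bf.simulate_bioassay(spec, seed=2024)


@pytest.fixture(scope="session")
def lab_fit(lab_dataset):
    """Base-model fit of the resistant-strain dataset (shared across tests)."""
    _, ds = lab_dataset
    return bf.DoseResponseModel(ds, "base").fit(n_iterations=8000, seed=17)


@pytest.fixture
def degenerate_samples_factory():
    """Build a PosteriorSamples whose draws are all one parameter point."""

    def make(A, B, C, E, n_records=1, n_chains=2, n_kept=50):
        draws = {
            name: np.full((n_chains, n_kept), val)
            for name, val in zip("ABCE", (A, B, C, E))
        }
        ll = np.zeros((n_chains, n_kept, n_records))
        cfg = bf.SamplerConfig(n_chains=n_chains, n_iterations=2 * n_kept, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return bf.PosteriorSamples(draws, ll, cfg, "base")

    return make
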