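import numpy as np
import pytest

from fmridx.preprocess import MaskedScan, Scan4D, preprocess_scan
from fmridx.synthetic import default_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Ten-subject noisy desk-scale cohort, preprocessed to the averaged
    normalized grid (shared across tests; treat as read-only)."""
    spec = default_cohort_spec(
        n_control=4, n_combined=3, n_inattentive=3, noise_sd=0.5, seed=7
    )
    scans, phenotypes, truth = generate_cohort(spec)
    processed = [preprocess_scan(s) for s in scans]
    return processed, phenotypes, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_masked(waveforms: np.ndarray) -> MaskedScan:
    """Wrap a V x T array as a MaskedScan with a raster index map."""
    V = waveforms.shape[0]
    index_map = np.column_stack([np.arange(V), np.zeros(V, int), np.zeros(V, int)])
    return MaskedScan(waveforms=waveforms, index_map=index_map, sampling_period=0.5)


def constant_scan(value: float, dims=(2, 2, 2), T=4, period=2.0) -> Scan4D:
    return Scan4D(values=np.full(dims + (T,), float(value)), sampling_period=period)
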