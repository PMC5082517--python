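import numpy as np
import pytest

from ictomark import SourceSpec, generate_segment
from ictomark.preprocess import band_filter, broadband_filter


def coupled_spec(n=6, pairs=((0, 1, 0.6), (2, 3, -0.8)), strength=30.0,
                 alpha_peak=7.5, seed=0, **kwargs):
    """SourceSpec with a handful of known lag-coupled channel pairs."""
    C = np.zeros((n, n))
    L = np.zeros((n, n))
    for i, j, lag in pairs:
        C[i, j] = C[j, i] = strength
        L[i, j] = lag
        L[j, i] = -lag
    return SourceSpec(
        n_channels=n, alpha_peak=alpha_peak,
        coupling_matrix=C, phase_lag_matrix=L, seed=seed, **kwargs,
    )


def tone_segment(freq, fs=256.0, duration=20.0, n_channels=2, amp=50.0):
    """Multichannel pure sinusoid (microvolts)."""
    t = np.arange(int(duration * fs)) / fs
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (n_channels, 1))
    from ictomark import EEGSegment

    return EEGSegment(data=data, sample_rate=fs,
                      channel_labels=tuple(f"CH{i}" for i in range(n_channels)))


@pytest.fixture(scope="session")
def lowalpha_coupled_segment():
    """Low-alpha-filtered segment with two known coupled pairs."""
    seg = generate_segment(coupled_spec(seed=11))
    return band_filter(broadband_filter(seg), "low_alpha")


@pytest.fixture(scope="session")
def inferred_network(lowalpha_coupled_segment):
    from ictomark import NetworkConfig, build_network

    return build_network(lowalpha_coupled_segment, NetworkConfig(seed=7))
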