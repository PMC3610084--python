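import numpy as np
import pytest

from artfeat.audio import AudioSample
from artfeat.features import FeatureConfig
from artfeat.modspec import ModulationSpectrum, SpectrogramConfig


@pytest.fixture
def am_tone():
    """Factory for amplitude-modulated tones (carrier 1 kHz by default)."""

    def _make(fm=5.0, depth=0.8, fc=1000.0, dur=4.0, fs=22050):
        t = np.arange(int(fs * dur)) / fs
        x = (1 + depth * np.cos(2 * np.pi * fm * t)) * np.sin(2 * np.pi * fc * t)
        return AudioSample(0.9 * x / np.abs(x).max(), fs)

    return _make


@pytest.fixture
def sim_config():
    """Reduced-resolution analysis config used for simulation studies."""
    return FeatureConfig(
        spectrogram=SpectrogramConfig(hop_ms=5.0, nfft=1024, max_frequency=6000.0)
    )


def make_random_modspec(seed, n_wf=41, n_wt=61, wt_max=150.0, wf_max=50.0):
    """Random normalized modulation spectrum on a symmetric grid."""
    rng = np.random.default_rng(seed)
    power = rng.random((n_wf, n_wt)) ** 3  # skewed, with near-ties
    power /= power.sum()
    wf = np.linspace(-wf_max, wf_max, n_wf)
    wt = np.linspace(-wt_max, wt_max, n_wt)
    return ModulationSpectrum(power=power, wf=wf, wt=wt, total_power=1.0)


def contour_oracle(ms, energy_fraction, wt_max=100.0, wf_max=40.0):
    """Brute-force greedy reference for the minimal 99.9%-energy bin set."""
    cells = []
    for i, wf in enumerate(ms.wf):
        for j, wt in enumerate(ms.wt):
            if wt < 0 or wt > wt_max or abs(wf) > wf_max:
                continue
            if abs(wt) < 1e-12 and abs(wf) < 1e-12:
                continue
            cells.append((-ms.power[i, j], abs(wt), abs(wf), i, j))
    cells.sort()
    total = sum(-c[0] for c in cells)
    chosen, acc = set(), 0.0
    for c in cells:
        chosen.add((c[3], c[4]))
        acc += -c[0]
        if acc >= energy_fraction * total:
            break
    return chosen
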