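import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

from aminospec.spectra import Spectrum

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable


def make_spectrum(peaks: dict, compound_id: str = "X") -> Spectrum:
    return Spectrum(peaks=dict(peaks), compound_id=compound_id)


def random_peak_dict(rng: np.random.Generator, n_peaks: int = 20, max_mz: int = 400) -> dict:
    """A base-peak-100 normalized random integer-m/z stick spectrum."""
    n = int(rng.integers(3, n_peaks + 1))
    mz = rng.choice(np.arange(50, max_mz), size=n, replace=False)
    inten = rng.lognormal(2.0, 1.5, size=n)
    inten *= 100.0 / inten.max()
    return {int(m): float(v) for m, v in zip(mz, inten)}


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_pairs(rng):
    """100 random normalized peak-dict pairs sharing part of their support."""
    pairs = []
    for _ in range(100):
        a = random_peak_dict(rng)
        b = random_peak_dict(rng)
        # overlap part of the support so the pair is neither identical nor disjoint
        shared = dict(list(a.items())[: len(a) // 2])
        b.update(shared)
        b = {k: v * 100.0 / max(b.values()) for k, v in b.items()}
        pairs.append((a, b))
    return pairs
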