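import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from peakscape.intervals import GenomicInterval, PeakSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_peak_set(rng, label, n, chroms=("chr1", "chr2"), span=5_000,
                    max_len=400):
    ivs = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, start + length,
                                   score=float(rng.uniform(0, 100))))
    return PeakSet(label=label, intervals=ivs)


@pytest.fixture
def make_peak_set():
    return random_peak_set
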