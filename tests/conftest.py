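import numpy as np
import pytest

from tescope.io import SequenceRecord
from tescope.simulate import random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20230224)


@pytest.fixture
def te_transcripts(rng):
    """Twenty synthetic TE transcripts, ~1.5 kb each."""
    return [SequenceRecord(f"te{i:02d}", random_sequence(rng, 1500)) for i in range(20)]


def brute_force_placements(query: str, target: str, k: int) -> list[tuple[int, int]]:
    """Sliding-window Hamming oracle: (offset, mismatches) pairs with <= k.

    Non-ACGT symbols never match anything, matching the mapper's contract.
    """
    out = []
    L = len(query)
    for off in range(len(target) - L + 1):
        window = target[off : off + L]
        mism = sum(
            1
            for a, b in zip(query, window)
            if a != b or a not in "ACGT" or b not in "ACGT"
        )
        if mism <= k:
            out.append((off, mism))
    return out
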