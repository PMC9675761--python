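import numpy as np
import pandas as pd
import pytest

from temrkit.consensus import synthetic_alu_consensus, synthetic_line1_consensus
from temrkit.synth import TEPlacement, build_reference, simulate_study


@pytest.fixture(scope="session")
def alu():
    return synthetic_alu_consensus()


@pytest.fixture(scope="session")
def line1():
    return synthetic_line1_consensus()


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by integration tests."""
    return simulate_study(seed=23, genome_length=1_200_000, n_temr=24,
                          n_background_svs=6)


def _mismatch(base: str) -> str:
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[base]


def paired_reference(cons, window_start: int, mh: int, divergence: float = 0.08,
                     strands=("+", "+"), gap: int = 900, seed: int = 5):
    """Two TE copies sharing an identical substitution-free window of exactly
    ``mh`` bases at consensus offset ``window_start`` (boundaries mismatched),
    embedded in random background.  Returns the SyntheticReference."""
    w, m = window_start, mh
    L = len(cons.sequence)
    seq = cons.sequence
    forced3 = {w - 1: _mismatch(seq[w - 1]), w + m: _mismatch(seq[w + m])}
    placements = [
        TEPlacement(2000, cons, divergence, strands[0], 0,
                    protected=((w - 1, w + m + 1),), copy_id="teA"),
        TEPlacement(2000 + L + gap, cons, divergence, strands[1], 0,
                    protected=((w, w + m),), forced=forced3, copy_id="teB"),
    ]
    return build_reference(2000 + L + gap + L + 2000, placements, seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
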