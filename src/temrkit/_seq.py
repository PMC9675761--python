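"""Small DNA-string helpers shared across modules.

Sequences are plain upper-case strings over {A,C,G,T}; coordinates are
0-based half-open everywhere inside the package.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.41) -> str:
    """Random DNA with the given expected GC fraction."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc fraction must be in [0,1], got {gc}")
    p_at = (1.0 - gc) / 2.0
    p_gc = gc / 2.0
    idx = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return np.frombuffer(b"ACGT", dtype="S1")[idx].tobytes().decode()


def other_base(rng: np.random.Generator, base: str) -> str:
    """A base drawn uniformly from the three alternatives to ``base``."""
    choices = [b for b in BASES if b != base]
    return choices[int(rng.integers(3))]


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def as_rng(seed) -> np.random.Generator:
    """Accept a seed or an existing Generator and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_rng(seed, *stream: int) -> np.random.Generator:
    """Derive a generator from a base seed plus an integer stream key.

    Deterministic: the same (seed, stream) always yields the same stream,
    independent of call order.
    """
    if isinstance(seed, np.random.Generator):
        return seed.spawn(1)[0]
    return np.random.default_rng([int(seed), *stream])
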