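"""Small shared nucleotide-sequence helpers."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(n: int, rng: np.random.Generator) -> str:
    """Uniform i.i.d. DNA sequence of length ``n``."""
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def mutate_base(base: str, rng: np.random.Generator) -> str:
    """A uniformly chosen base different from ``base``."""
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]
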