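"""Small DNA helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a kmer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA string of the given length."""
    return "".join(rng.choice(list(BASES), size=length))
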