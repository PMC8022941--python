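"""Small sequence helpers shared across modules."""
from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement (case preserved, N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(rng: np.random.Generator, n: int) -> str:
    """Uniform random ACGT string of length ``n``."""
    if n <= 0:
        return ""
    idx = rng.integers(0, 4, size=n)
    return _BASES[idx].tobytes().decode("ascii")


def seq_to_array(seq: str) -> np.ndarray:
    """Encode as uint8 byte array for vectorised comparisons."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def roman(i: int) -> str:
    """1-based integer to Roman numeral (chromosome naming)."""
    vals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
            (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
            (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for v, s in vals:
        while i >= v:
            out.append(s)
            i -= v
    return "".join(out)
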