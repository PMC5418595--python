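"""Small DNA helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode DNA as uint8 codes (A=0,C=1,G=2,T=3, anything else 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    return bytes(_DECODE[np.asarray(codes, dtype=np.intp)]).decode("ascii")


def random_dna(length: int, rng: np.random.Generator) -> str:
    if length < 0:
        raise ValueError("length must be non-negative")
    return decode(rng.integers(0, 4, size=length))
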