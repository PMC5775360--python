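"""Low-level DNA string/array helpers shared across modules.

Sequences travel as plain upper-case ``str`` at module boundaries; the
numeric kernels re-encode them as ``uint8`` arrays via :func:`encode`.
"""

from __future__ import annotations

import numpy as np

GENOME_ALPHABET = frozenset("ACGTN")
ALIGN_ALPHABET = frozenset("ACGTN-")

_COMP_TABLE = str.maketrans("ACGTN", "TGCAN")

# uint8 complement lookup (identity outside ACGT except N->N)
_COMP_LUT = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_LUT[_a] = _b


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N self-complementary)."""
    return seq.translate(_COMP_TABLE)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMP_TABLE)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def comp_arr(arr: np.ndarray) -> np.ndarray:
    """Complement an encoded array."""
    return _COMP_LUT[arr]


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMP_LUT[arr][::-1]
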