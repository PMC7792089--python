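"""One-hot encoding of binding-site fragments.

A fragment over the alphabet {A, C, G, T/U, N} is stored as an ``L x 4``
binary matrix whose columns follow the fixed base order **A, T, C, G**
(note: not alphabetical).  ``U`` is normalised to ``T`` on input, and the
padding character ``N`` encodes as an all-zero row, so N-padding is inert
under convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Column order of the one-hot matrix.
BASE_ORDER = "ATCG"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}


@dataclass(frozen=True)
class OneHotMatrix:
    """An encoded fragment: the normalised sequence and its L x 4 matrix."""

    sequence: str
    matrix: np.ndarray

    @property
    def length(self) -> int:
        return len(self.sequence)


def normalize_sequence(s: str) -> str:
    """Uppercase, map U->T, and validate the alphabet.

    Raises ``ValueError`` naming the first offending position.
    """
    if not s:
        raise ValueError("empty sequence")
    s = s.upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in "ATCGN":
            raise ValueError(f"unknown character {ch!r} at position {i + 1}")
    return s


def encode_sequence(s: str) -> OneHotMatrix:
    """Encode a nucleotide string as an L x 4 one-hot matrix (columns A,T,C,G)."""
    s = normalize_sequence(s)
    m = np.zeros((len(s), 4), dtype=np.float64)
    for i, ch in enumerate(s):
        j = _BASE_INDEX.get(ch)
        if j is not None:
            m[i, j] = 1.0
    return OneHotMatrix(sequence=s, matrix=m)


def decode_matrix(matrix: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`; all-zero rows decode to ``N``."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != 4:
        raise ValueError(f"expected an L x 4 matrix, got shape {matrix.shape}")
    out = []
    for row in matrix:
        hot = np.nonzero(row)[0]
        if hot.size == 0:
            out.append("N")
        elif hot.size == 1:
            out.append(BASE_ORDER[hot[0]])
        else:
            raise ValueError("row with more than one non-zero entry")
    return "".join(out)


def encode_batch(sequences: list[str]) -> np.ndarray:
    """Stack equal-length fragments into an (N, L, 4) array."""
    if not sequences:
        raise ValueError("no sequences to encode")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequences have mixed lengths {sorted(lengths)}")
    return np.stack([encode_sequence(s).matrix for s in sequences])
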