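"""One-hot encoding of nucleotide strings.

A sequence of length N becomes an N x 4 binary matrix with fixed column
order (A, C, G, T): A -> [1,0,0,0], C -> [0,1,0,0], G -> [0,0,1,0],
T -> [0,0,0,1]. Each row is a unit vector. Ambiguity codes are rejected by
default; with ``ambiguous="uniform"`` any IUPAC ambiguity code (N, R, Y, ...)
is encoded as the uniform row [0.25, 0.25, 0.25, 0.25].
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np

ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_AMBIGUOUS = set("NRYSWKMBDHV")


def encode_one_hot(seq: str, ambiguous: str = "reject") -> np.ndarray:
    """Encode a nucleotide string as an N x 4 one-hot matrix.

    Parameters
    ----------
    seq : str
        Non-empty nucleotide string; case-insensitive.
    ambiguous : {"reject", "uniform"}
        How to handle IUPAC ambiguity codes: raise (default), or emit the
        uniform row (0.25 per base).

    Returns
    -------
    numpy.ndarray of shape (len(seq), 4), dtype float64.
    """
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    if ambiguous not in ("reject", "uniform"):
        raise ValueError(f"unknown ambiguity mode {ambiguous!r}")
    seq = seq.upper()
    out = np.zeros((len(seq), 4))
    for i, base in enumerate(seq):
        j = _INDEX.get(base)
        if j is not None:
            out[i, j] = 1.0
        elif ambiguous == "uniform" and base in _AMBIGUOUS:
            out[i, :] = 0.25
        else:
            raise ValueError(
                f"non-ACGT character {base!r} at position {i + 1}"
            )
    return out


def decode_one_hot(matrix: np.ndarray) -> str:
    """Invert :func:`encode_one_hot`: an N x 4 one-hot matrix back to a string.

    Rows must be exact unit vectors; the first offending row index (1-based)
    is reported otherwise.
    """
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[1] != 4:
        raise ValueError(f"expected an N x 4 matrix, got shape {m.shape}")
    is_unit = (np.sum(m == 1.0, axis=1) == 1) & (np.sum(m == 0.0, axis=1) == 3)
    if not np.all(is_unit):
        row = int(np.argmin(is_unit))
        raise ValueError(f"row {row + 1} is not a one-hot unit vector: {m[row]}")
    return "".join(ALPHABET[j] for j in np.argmax(m, axis=1))


def encode_batch(seqs: Iterable[str] | Sequence, ambiguous: str = "reject") -> np.ndarray:
    """Stack one-hot encodings of equal-length sequences into (B, N, 4).

    Accepts plain strings or objects with a ``seq`` attribute.
    """
    strings = [getattr(s, "seq", s) for s in seqs]
    if not strings:
        raise ValueError("cannot encode an empty batch")
    lengths = {len(s) for s in strings}
    if len(lengths) != 1:
        raise ValueError(f"sequences have mixed lengths: {sorted(lengths)}")
    return np.stack([encode_one_hot(s, ambiguous=ambiguous) for s in strings])
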