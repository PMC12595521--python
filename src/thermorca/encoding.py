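"""Numeric encoding of aligned sequences and sequence-distance utilities.

Sequences live on a 21-letter alphabet: the 20 standard amino acids in
alphabetical one-letter order, plus ``-`` for an alignment gap. The gap is a
first-class symbol — it is one-hot encoded like any residue and it counts as
a mismatch in Hamming distance — so that distances over gapped alignments
are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: 20 amino acids (alphabetical) + gap, in fixed order. Ties in
#: :func:`decode_argmax` resolve to the earliest symbol in this string.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY-"

ALPHABET_SIZE: int = len(ALPHABET)

_SYM_TO_IDX = {s: i for i, s in enumerate(ALPHABET)}


class AlphabetError(ValueError):
    """A sequence contains a symbol outside the 21-letter alphabet."""


class DegenerateDistributionError(ValueError):
    """A position's probability vector is all zeros and cannot be decoded."""


@dataclass
class OneHotMSA:
    """One-hot tensor view of an alignment.

    Attributes
    ----------
    tensor : ndarray of shape (n_seqs, n_columns, 21)
        Indicator array; each (sequence, column) slice sums to exactly 1.
    ids : list of str
        Row labels, parallel to the first tensor axis.
    alphabet : str
        The symbol order of the last axis (always :data:`ALPHABET`).
    """

    tensor: np.ndarray
    ids: list[str]
    alphabet: str = field(default=ALPHABET)

    @property
    def n_seqs(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_columns(self) -> int:
        return self.tensor.shape[1]

    def flat(self) -> np.ndarray:
        """Rows flattened to (n_seqs, n_columns * 21), as consumed by the VAE."""
        return self.tensor.reshape(self.n_seqs, -1)


def encode_sequences(rows: list[str], ids: list[str] | None = None) -> OneHotMSA:
    """One-hot encode equal-length gapped sequences.

    Raises
    ------
    AlphabetError
        If any symbol is outside the alphabet; the message names the
        offending row and column.
    ValueError
        If rows are ragged.
    """
    if not rows:
        raise ValueError("cannot encode an empty set of sequences")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("rows have unequal lengths; encode requires a fixed-width alignment")
    if ids is None:
        ids = [f"seq{i}" for i in range(len(rows))]
    idx = np.empty((len(rows), width), dtype=np.int64)
    for i, row in enumerate(rows):
        for j, sym in enumerate(row):
            k = _SYM_TO_IDX.get(sym)
            if k is None:
                raise AlphabetError(
                    f"alphabet violation: symbol {sym!r} at row {ids[i]!r} column {j + 1}"
                )
            idx[i, j] = k
    tensor = np.zeros((len(rows), width, ALPHABET_SIZE), dtype=np.float32)
    n, c = np.meshgrid(np.arange(len(rows)), np.arange(width), indexing="ij")
    tensor[n, c, idx] = 1.0
    return OneHotMSA(tensor=tensor, ids=list(ids))


def encode(msa) -> OneHotMSA:
    """One-hot encode an :class:`~thermorca.curation.AlignedSet`."""
    return encode_sequences(list(msa.rows), list(msa.ids))


def decode(onehot: OneHotMSA) -> list[str]:
    """Exact inverse of :func:`encode` on valid one-hot input."""
    return decode_argmax(onehot.tensor)


def decode_argmax(probabilities: np.ndarray):
    """Decode per-position symbol distributions to gapped sequences.

    Each position emits the maximal-probability symbol; ties break to the
    earliest symbol in :data:`ALPHABET` (numpy argmax takes the first
    maximum). Accepts a single (columns, 21) matrix — returning one string —
    or a stacked (n, columns, 21) tensor, returning a list of strings.

    Raises
    ------
    DegenerateDistributionError
        If some position's vector is all zeros.
    ValueError
        If the last axis has negative entries or wrong size.
    """
    p = np.asarray(probabilities)
    squeeze = p.ndim == 2
    if squeeze:
        p = p[None]
    if p.ndim != 3 or p.shape[-1] != ALPHABET_SIZE:
        raise ValueError(f"expected trailing axis of size {ALPHABET_SIZE}, got shape {p.shape}")
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    sums = p.sum(axis=-1)
    if np.any(sums == 0):
        n, c = np.argwhere(sums == 0)[0]
        raise DegenerateDistributionError(
            f"degenerate distribution: all-zero vector at sequence {n} column {c + 1}"
        )
    idx = p.argmax(axis=-1)
    lut = np.array(list(ALPHABET))
    seqs = ["".join(row) for row in lut[idx]]
    return seqs[0] if squeeze else seqs


def hamming(a: str, b: str) -> int:
    """Number of columns at which two equal-width gapped sequences differ.

    Gap is an ordinary symbol: aligning a residue against ``-`` counts as a
    difference. Symmetric and satisfies the triangle inequality.
    """
    if len(a) != len(b):
        raise ValueError(f"width mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def hamming_matrix(rows: list[str], reference: str) -> np.ndarray:
    """Hamming distance of every row to a reference, vectorized."""
    ref = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    arr = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8).reshape(len(rows), -1)
    if arr.shape[1] != ref.shape[0]:
        raise ValueError("width mismatch between rows and reference")
    return (arr != ref).sum(axis=1)
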