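"""One-hot DNA encoding for the sequence network.

Channel order is (A, C, G, T); ambiguous bases (N) encode as an all-zero
row so that every row is binary and max pooling stays monotone.  No
reverse-complement augmentation is performed: strand symmetry is left to
the bidirectional recurrent layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import LabeledSequenceSet

__all__ = ["EncodedBatch", "one_hot", "decode", "encode_batch"]

_BASES = "ACGT"
_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i
_LUT[ord("N")] = 4
_LUT[ord("n")] = 4


@dataclass
class EncodedBatch:
    """N x L x 4 one-hot sequences with aligned labels and ids."""

    sequences: np.ndarray
    labels: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        if not (self.sequences.shape[0] == self.labels.shape[0] == len(self.ids)):
            raise ValueError("sequences, labels and ids must agree in first dimension")

    def __len__(self) -> int:
        return self.sequences.shape[0]

    @property
    def length(self) -> int:
        return self.sequences.shape[1]

    def subset(self, idx) -> "EncodedBatch":
        idx = np.asarray(idx)
        return EncodedBatch(
            self.sequences[idx], self.labels[idx], [self.ids[i] for i in idx]
        )

    def save(self, path) -> None:
        """Cache the encoded batch in an npz container."""
        np.savez_compressed(path, sequences=self.sequences, labels=self.labels,
                            ids=np.array(self.ids, dtype=object))

    @classmethod
    def load(cls, path) -> "EncodedBatch":
        with np.load(path, allow_pickle=True) as npz:
            return cls(npz["sequences"], npz["labels"],
                       [str(i) for i in npz["ids"]])


def one_hot(seq: str) -> np.ndarray:
    """Encode a DNA string as an L x 4 binary matrix (A, C, G, T).

    N rows are all-zero; any character outside {A,C,G,T,N} raises
    ``ValueError`` naming its position.
    """
    codes = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    bad = np.flatnonzero(codes < 0)
    if bad.size:
        pos = int(bad[0])
        raise ValueError(f"invalid base {seq[pos]!r} at position {pos}")
    mat = np.zeros((len(seq), 4), dtype=np.float64)
    known = codes < 4
    mat[np.flatnonzero(known), codes[known]] = 1.0
    return mat


def decode(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot`; all-zero rows decode to N."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[1] != 4:
        raise ValueError("expected an L x 4 matrix")
    out = []
    for row in mat:
        nz = np.flatnonzero(row)
        out.append("N" if nz.size == 0 else _BASES[int(nz[0])])
    return "".join(out)


def encode_batch(data: LabeledSequenceSet) -> EncodedBatch:
    """Encode a labeled set, preserving record order, labels and ids."""
    if len(data) == 0:
        raise ValueError("cannot encode an empty sequence set")
    n, L = len(data), data.fixed_length
    joined = "".join(r.sequence for r in data.records)
    codes = _LUT[np.frombuffer(joined.encode(), dtype=np.uint8)].reshape(n, L)
    bad = np.argwhere(codes < 0)
    if bad.size:
        i, j = bad[0]
        rec = data.records[i]
        raise ValueError(
            f"record {rec.id}: invalid base {rec.sequence[j]!r} at position {j}"
        )
    out = np.zeros((n, L, 4), dtype=np.float64)
    ii, jj = np.nonzero(codes < 4)
    out[ii, jj, codes[ii, jj]] = 1.0
    return EncodedBatch(sequences=out, labels=data.labels.astype(np.float64), ids=data.ids)
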