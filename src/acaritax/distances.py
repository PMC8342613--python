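"""Uncorrected p-distances under pairwise deletion, and similarity scores.

For each pair of aligned sequences, alignment columns where either member
carries a gap or an ambiguous base are deleted; the p-distance is the
fraction of mismatches among the remaining (compared) sites.  No
multiple-hit correction is applied, matching the distance used by
nearest-neighbour barcode identification engines.  Pairs with zero
compared sites have an undefined distance, stored as NaN and never
silently treated as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import ReferenceLibrary

# byte -> nucleotide code; A,C,G,T (either case) -> 0..3, everything else
# (gaps, N, IUPAC ambiguity codes) -> 255 and is deleted pairwise
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_sequences(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Encode equal-length sequences to an (n, width) uint8 code matrix and
    a boolean validity mask (True where the base is a plain A/C/G/T)."""
    if not seqs:
        return np.zeros((0, 0), np.uint8), np.zeros((0, 0), bool)
    width = len(seqs[0])
    raw = np.frombuffer("".join(seqs).encode("ascii"), np.uint8)
    codes = _CODE[raw].reshape(len(seqs), width)
    return codes, codes < 4


def pairwise_p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """p-distance and compared-site count for one aligned pair.

    Returns ``(nan, 0)`` when the sequences share no comparable site.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    codes, valid = encode_sequences([seq_a, seq_b])
    both = valid[0] & valid[1]
    overlap = int(both.sum())
    if overlap == 0:
        return math.nan, 0
    mism = int((codes[0, both] != codes[1, both]).sum())
    return mism / overlap, overlap


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with per-pair compared-site counts.

    ``d[i, j]`` is NaN where ``overlap[i, j] == 0`` (undefined distance);
    the diagonal is zero by convention.
    """

    ids: list[str]
    d: np.ndarray
    overlap: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.overlap.shape != (n, n):
            raise ValueError("matrix shapes do not match id count")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, rid: str) -> int:
        return self.ids.index(rid)

    @property
    def has_undefined(self) -> bool:
        off = ~np.eye(len(self.ids), dtype=bool)
        return bool(np.isnan(self.d[off]).any())

    def to_tsv(self, path) -> None:
        """Square TSV with ids as header row and first column."""
        import pandas as pd

        pd.DataFrame(self.d, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", float_format="%.6f"
        )

    def to_phylip(self, path) -> None:
        """PHYLIP square (relaxed names) export."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for rid, row in zip(self.ids, self.d):
                vals = " ".join(f"{v:.6f}" for v in row)
                fh.write(f"{rid}  {vals}\n")


def distance_matrix(lib: ReferenceLibrary) -> DistanceMatrix:
    """All-pairs p-distances for a library.

    Uses per-base indicator matmuls, so the cost is a handful of
    (n x width) x (width x n) products rather than an n^2 Python loop.
    """
    if len(lib) == 0:
        raise ValueError("empty library")
    codes, valid = encode_sequences([r.seq for r in lib.records])
    v = valid.astype(np.float64)
    overlap = v @ v.T
    matches = np.zeros_like(overlap)
    for b in range(4):
        m = ((codes == b) & valid).astype(np.float64)
        matches += m @ m.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (overlap - matches) / overlap
    d[overlap == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    overlap_int = overlap.astype(np.int64)
    np.fill_diagonal(overlap_int, valid.sum(axis=1))
    return DistanceMatrix(list(lib.ids), d, overlap_int)


def similarity(p: float) -> float:
    """Percent similarity ``100 * (1 - p)`` for a p-distance in [0, 1]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-distance {p} outside [0, 1]")
    return 100.0 * (1.0 - p)
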