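"""Grantham amino-acid distance: matrix construction and sequence distances.

The Grantham distance combines three physicochemical properties of the
standard amino acids -- composition (atomic-weight ratio of hetero elements
in side chains), polarity, and molecular volume -- into a single
dissimilarity,

    D(i, j) = rho * [ alpha*(c_i - c_j)^2
                    + beta *(p_i - p_j)^2
                    + gamma*(v_i - v_j)^2 ] ** 0.5

with alpha = 1.833, beta = 0.1018, gamma = 0.000399 and the overall scale
rho chosen so that the mean of the 190 distinct pairwise distances equals
100.  Rounded to integers this reproduces the familiar published table
(L-I = 5, C-W = 215, the largest entry).

Whole-sequence distances are position-wise sums of residue distances over
equal-length (gap-free, pre-aligned) sequences, which keeps the per-position
heatmap decomposition additive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "GRANTHAM_PROPERTIES",
    "GranthamMatrix",
    "grantham_distance",
    "sequence_distance",
    "distance_profile",
    "pairwise_distance_matrix",
    "sequence_identity",
    "sequence_similarity",
]

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: (composition, polarity, volume) per residue, Grantham's 1974 property set.
GRANTHAM_PROPERTIES: Mapping[str, tuple[float, float, float]] = {
    "A": (0.00, 8.1, 31.0),
    "C": (2.75, 5.5, 55.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "F": (0.00, 5.2, 132.0),
    "G": (0.74, 9.0, 3.0),
    "H": (0.58, 10.4, 96.0),
    "I": (0.00, 5.2, 111.0),
    "K": (0.33, 11.3, 119.0),
    "L": (0.00, 4.9, 111.0),
    "M": (0.00, 5.7, 105.0),
    "N": (1.33, 11.6, 56.0),
    "P": (0.39, 8.0, 32.5),
    "Q": (0.89, 10.5, 85.0),
    "R": (0.65, 10.5, 124.0),
    "S": (1.42, 9.2, 32.0),
    "T": (0.71, 8.6, 61.0),
    "V": (0.00, 5.9, 84.0),
    "W": (0.13, 5.4, 170.0),
    "Y": (0.20, 6.2, 136.0),
}

ALPHA = 1.833
BETA = 0.1018
GAMMA = 0.000399

_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class UnknownResidueError(ValueError):
    """Raised for residues outside the 20 standard amino acids (incl. X)."""


def _raw_matrix() -> np.ndarray:
    props = np.array([GRANTHAM_PROPERTIES[aa] for aa in AMINO_ACIDS])
    dc = props[:, 0][:, None] - props[:, 0][None, :]
    dp = props[:, 1][:, None] - props[:, 1][None, :]
    dv = props[:, 2][:, None] - props[:, 2][None, :]
    return np.sqrt(ALPHA * dc**2 + BETA * dp**2 + GAMMA * dv**2)


@dataclass(frozen=True)
class GranthamMatrix:
    """Symmetric 20x20 amino-acid distance table.

    By default the table is computed from the property formula, scaled so
    that the 190 distinct off-diagonal entries average exactly 100, and
    rounded to integers (matching the published table).  ``rounded=False``
    keeps the real-valued scaled distances.
    """

    distance: np.ndarray
    provenance: str = "computed"
    alpha: float = ALPHA
    beta: float = BETA
    gamma: float = GAMMA
    properties: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(GRANTHAM_PROPERTIES)
    )

    @classmethod
    def compute(cls, rounded: bool = True) -> "GranthamMatrix":
        raw = _raw_matrix()
        iu = np.triu_indices(20, 1)
        scaled = raw * (100.0 / raw[iu].mean())
        if rounded:
            scaled = np.round(scaled)
        scaled.setflags(write=False)
        return cls(distance=scaled)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return grantham_distance(a, b, self)

    def off_diagonal_mean(self) -> float:
        iu = np.triu_indices(20, 1)
        return float(self.distance[iu].mean())


_DEFAULT: GranthamMatrix | None = None


def default_matrix() -> GranthamMatrix:
    """The shared integer-rounded matrix instance."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = GranthamMatrix.compute()
    return _DEFAULT


def _index(aa: str) -> int:
    try:
        return _INDEX[aa]
    except KeyError:
        raise UnknownResidueError(f"unknown residue {aa!r}") from None


def grantham_distance(a: str, b: str, matrix: GranthamMatrix | None = None) -> float:
    """Distance between two residues; symmetric with zero diagonal."""
    m = matrix if matrix is not None else default_matrix()
    return float(m.distance[_index(a), _index(b)])


def encode(seq: str) -> np.ndarray:
    """Residue string -> integer codes into :data:`AMINO_ACIDS`."""
    try:
        return np.array([_INDEX[aa] for aa in seq], dtype=np.intp)
    except KeyError as exc:
        raise UnknownResidueError(f"unknown residue {exc.args[0]!r}") from None


def _positions(length: int, positions) -> np.ndarray:
    if positions is None or positions == "all":
        return np.arange(length)
    pos = np.asarray(sorted(positions), dtype=np.intp)
    if len(pos) and (pos[0] < 0 or pos[-1] >= length):
        raise IndexError("positions outside sequence")
    return pos


def sequence_distance(
    s1: str,
    s2: str,
    positions="all",
    matrix: GranthamMatrix | None = None,
) -> float:
    """Summed Grantham distance over compared positions of two sequences."""
    if len(s1) != len(s2):
        raise ValueError(f"length mismatch: {len(s1)} vs {len(s2)}")
    m = matrix if matrix is not None else default_matrix()
    pos = _positions(len(s1), positions)
    c1, c2 = encode(s1)[pos], encode(s2)[pos]
    return float(m.distance[c1, c2].sum())


def distance_profile(
    s: str, consensus: str, matrix: GranthamMatrix | None = None
) -> np.ndarray:
    """Per-position distance of ``s`` to ``consensus`` (one heatmap row)."""
    if len(s) != len(consensus):
        raise ValueError(f"length mismatch: {len(s)} vs {len(consensus)}")
    m = matrix if matrix is not None else default_matrix()
    return m.distance[encode(s), encode(consensus)].astype(float)


def pairwise_distance_matrix(
    sequences: Sequence[str],
    positions="all",
    matrix: GranthamMatrix | None = None,
) -> np.ndarray:
    """Dense symmetric matrix of summed distances between equal-length sequences."""
    seqs = list(sequences)
    if not seqs:
        return np.zeros((0, 0))
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must have identical length")
    m = matrix if matrix is not None else default_matrix()
    pos = _positions(length, positions)
    codes = np.stack([encode(s)[pos] for s in seqs])  # n x |pos|
    n = len(seqs)
    out = np.zeros((n, n))
    # chunk rows to bound the n*n*|pos| intermediate
    step = max(1, int(4e7 / max(1, n * len(pos))))
    for i0 in range(0, n, step):
        block = m.distance[codes[i0 : i0 + step, None, :], codes[None, :, :]]
        out[i0 : i0 + step] = block.sum(axis=2)
    return out


def sequence_identity(s1: str, s2: str) -> float:
    """Fraction of positions with identical residues (equal lengths)."""
    if len(s1) != len(s2):
        raise ValueError("length mismatch")
    if not s1:
        raise ValueError("empty sequences")
    return sum(a == b for a, b in zip(s1, s2)) / len(s1)


def sequence_similarity(s1: str, s2: str, threshold: float = 100.0) -> float:
    """Fraction of positions whose Grantham distance is below ``threshold``.

    A loose notion of conservative substitution: identical residues always
    count; non-identical pairs count when their distance is under the mean
    of the matrix (100 by construction) unless another cutoff is given.
    """
    if len(s1) != len(s2):
        raise ValueError("length mismatch")
    if not s1:
        raise ValueError("empty sequences")
    prof = distance_profile(s1, s2)
    return float((prof < threshold).mean())
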