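"""Numeric (non-string) sequence descriptors.

Implements the closed-form descriptors used both to screen generated
sequences and to build the random-forest feature matrix:

* GC content (percentage of G+C bases);
* the chaos game representation (CGR) of a sequence — the recursive
  midpoint walk in the unit square with corners A=(0,0), T=(1,0),
  C=(0,1), G=(1,1) — and its 20 x 20 occupancy grid ("PSSM grid"),
  where each of the L trajectory points contributes equal weight 1/L;
* overlapping k-mer extraction and per-k k-mer frequency vectors;
* Moran's I spatial autocorrelation of a per-position value series with
  binary lag adjacency weights, and its dinucleotide-frequency variant;
* CKSNAP: 16 normalized dinucleotide-pair frequencies for each gap
  k = 0..K_max-1, concatenated gap-major;
* EIIP features: k-mer frequencies weighted by the summed electron-ion
  interaction potential of their bases.

All per-sequence feature vectors are returned as :class:`pandas.Series`
with stable, globally unique names so they can be concatenated into a
feature matrix without positional bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .sequence_io import BASE_INDEX, BASES

__all__ = [
    "EIIP_TABLE",
    "CGR_CORNERS",
    "MoranResult",
    "gc_content",
    "cgr_trajectory",
    "pssm_from_cgr",
    "extract_kmers",
    "morans_i",
    "dinucleotide_moran",
    "cksnap",
    "eiip_features",
    "kmer_count_features",
]

#: Electron-ion interaction potential of the four bases (standard table).
EIIP_TABLE = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335}

#: Unit-square corners of the chaos game: A, T bottom; C, G top.
CGR_CORNERS = {"A": (0.0, 0.0), "T": (1.0, 0.0), "C": (0.0, 1.0), "G": (1.0, 1.0)}

#: Dinucleotides in fixed lexicographic order AA, AC, ..., TT over (A,C,G,T).
DINUCLEOTIDES = tuple(a + b for a, b in product(BASES, repeat=2))


class ZeroVarianceError(ValueError):
    """Moran's I is undefined for a constant value series."""


def _check_sequence(sequence: str) -> str:
    sequence = sequence.upper()
    for off, ch in enumerate(sequence):
        if ch not in BASE_INDEX:
            raise ValueError(f"invalid base {ch!r} at position {off + 1}")
    return sequence


def gc_content(sequence: str) -> float:
    """GC content as a percentage in [0, 100]."""
    sequence = _check_sequence(sequence)
    if not sequence:
        raise ValueError("GC content of an empty sequence is undefined")
    gc = sum(1 for ch in sequence if ch in "GC")
    return 100.0 * gc / len(sequence)


def cgr_trajectory(
    sequence: str,
    start: tuple[float, float] = (0.5, 0.5),
    corners: dict[str, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Chaos-game trajectory of a sequence: an (L, 2) array in [0,1]^2.

    Point i is the midpoint of point i-1 and the corner of base i; the
    walk begins at ``start`` (default: the conventional center (0.5, 0.5)).
    """
    sequence = _check_sequence(sequence)
    corners = CGR_CORNERS if corners is None else corners
    x, y = start
    if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
        raise ValueError(f"start point {start} outside the unit square")
    points = np.empty((len(sequence), 2), dtype=np.float64)
    for i, ch in enumerate(sequence):
        cx, cy = corners[ch]
        x = (x + cx) / 2.0
        y = (y + cy) / 2.0
        points[i] = (x, y)
    return points


def pssm_from_cgr(trajectory: np.ndarray, grid_size: int = 20) -> np.ndarray:
    """Bin a CGR trajectory into a ``grid_size`` x ``grid_size`` occupancy grid.

    Half-open binning ``floor(coord * grid_size)`` with coordinates equal
    to 1.0 assigned to the last bin; each point carries weight 1/L so the
    grid sums to 1.  Cell (r, c) corresponds to (x-bin r, y-bin c).
    """
    trajectory = np.asarray(trajectory, dtype=np.float64)
    if trajectory.size == 0:
        raise ValueError("cannot bin an empty trajectory")
    if trajectory.ndim != 2 or trajectory.shape[1] != 2:
        raise ValueError(f"expected an (L, 2) trajectory, got shape {trajectory.shape}")
    idx = np.floor(trajectory * grid_size).astype(np.int64)
    idx = np.minimum(idx, grid_size - 1)  # maps coord == 1.0 into the last bin
    if idx.min() < 0:
        raise ValueError("trajectory contains coordinates outside [0, 1]")
    grid = np.zeros((grid_size, grid_size), dtype=np.float64)
    np.add.at(grid, (idx[:, 0], idx[:, 1]), 1.0 / len(trajectory))
    return grid


def extract_kmers(sequence: str, k: int = 3) -> list[str]:
    """All n-k+1 overlapping k-mers of the sequence, in order."""
    sequence = _check_sequence(sequence)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(sequence) < k:
        raise ValueError(f"sequence length {len(sequence)} < k = {k}")
    return [sequence[i : i + k] for i in range(len(sequence) - k + 1)]


@dataclass(frozen=True)
class MoranResult:
    """Moran's I plus the pieces of its definition (n positions, weight sum W)."""

    I: float
    n: int
    W: float


def morans_i(values, weights: np.ndarray | None = None, lag: int = 1) -> MoranResult:
    """Moran's I of a value series under binary adjacency weights.

    I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2,
    with w_ij = 1 iff |i - j| == lag (both directions) unless an explicit
    weight matrix is supplied, and W = sum_ij w_ij.  Ranges over roughly
    [-1, 1]: -1 for a perfectly alternating series, +1 for perfectly
    smooth neighbouring values.  Undefined (raises) for a constant series.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D series of length >= 2")
    n = x.size
    if weights is None:
        i = np.arange(n)
        weights = (np.abs(i[:, None] - i[None, :]) == lag).astype(np.float64)
    else:
        weights = np.asarray(weights, dtype=np.float64)
        if weights.shape != (n, n):
            raise ValueError(f"weight matrix shape {weights.shape} != ({n}, {n})")
    dev = x - x.mean()
    denom = np.sum(dev**2)
    if denom == 0.0:
        raise ZeroVarianceError("Moran's I undefined: zero variance (constant series)")
    W = weights.sum()
    num = dev @ weights @ dev
    return MoranResult(I=float(n / W * num / denom), n=n, W=float(W))


def dinucleotide_moran(sequence: str, lag: int = 1) -> MoranResult:
    """Moran's I of the per-position dinucleotide-frequency series.

    Position i (i = 1..L-1) carries the within-sequence frequency of the
    dinucleotide starting there; lag-1 binary adjacency weights by default.
    Constant series (e.g. a homopolymer) raise :class:`ZeroVarianceError`.
    """
    sequence = _check_sequence(sequence)
    if len(sequence) < 3:
        raise ValueError("need length >= 3 for a dinucleotide series of length >= 2")
    dinucs = [sequence[i : i + 2] for i in range(len(sequence) - 1)]
    total = len(dinucs)
    counts: dict[str, int] = {}
    for d in dinucs:
        counts[d] = counts.get(d, 0) + 1
    series = np.array([counts[d] / total for d in dinucs], dtype=np.float64)
    return morans_i(series, lag=lag)


def cksnap(sequence: str, K_max: int = 5) -> pd.Series:
    """CKSNAP vector: for each gap k in 0..K_max-1 the 16 normalized
    frequencies of pairs (s_i, s_{i+k+1}), concatenated gap-major in the
    fixed dinucleotide order AA..TT.  Each 16-block sums to 1."""
    sequence = _check_sequence(sequence)
    N = len(sequence)
    if N <= K_max:
        raise ValueError(f"sequence length {N} must exceed K_max = {K_max}")
    names: list[str] = []
    values: list[float] = []
    for gap in range(K_max):
        npairs = N - gap - 1
        counts = dict.fromkeys(DINUCLEOTIDES, 0)
        for i in range(npairs):
            counts[sequence[i] + sequence[i + gap + 1]] += 1
        for pair in DINUCLEOTIDES:
            names.append(f"cksnap_g{gap}_{pair}")
            values.append(counts[pair] / npairs)
    return pd.Series(values, index=names, dtype=np.float64)


def eiip_kmer_value(kmer: str, table: dict[str, float] | None = None) -> float:
    """EIIP of a k-mer: the sum of its bases' EIIP values."""
    table = EIIP_TABLE if table is None else table
    return float(sum(table[ch] for ch in kmer))


def eiip_features(
    sequence: str,
    k_values: tuple[int, ...] = (3,),
    table: dict[str, float] | None = None,
) -> pd.Series:
    """EIIP-weighted k-mer frequency vector.

    For every k in ``k_values`` and every possible k-mer, the feature is
    (count / (N - k + 1)) * sum of base EIIP values; k-mers absent from
    the sequence contribute 0.
    """
    sequence = _check_sequence(sequence)
    table = EIIP_TABLE if table is None else table
    names: list[str] = []
    values: list[float] = []
    for k in k_values:
        if k > len(sequence):
            raise ValueError(f"k = {k} exceeds sequence length {len(sequence)}")
        windows = len(sequence) - k + 1
        counts: dict[str, int] = {}
        for i in range(windows):
            km = sequence[i : i + k]
            counts[km] = counts.get(km, 0) + 1
        for km_tuple in product(BASES, repeat=k):
            km = "".join(km_tuple)
            names.append(f"eiip_k{k}_{km}")
            values.append(counts.get(km, 0) / windows * eiip_kmer_value(km, table))
    return pd.Series(values, index=names, dtype=np.float64)


def kmer_count_features(
    sequence: str, k_set: tuple[int, ...] = (2, 3, 4, 5, 6)
) -> pd.Series:
    """Per-k k-mer frequency vectors (counts / (n-k+1)), concatenated.

    Feature names enumerate all 4^k k-mers per k so the name list is
    identical across sequences; each per-k block sums to 1.
    """
    sequence = _check_sequence(sequence)
    names: list[str] = []
    values: list[float] = []
    for k in k_set:
        if k > len(sequence):
            raise ValueError(f"k = {k} exceeds sequence length {len(sequence)}")
        windows = len(sequence) - k + 1
        counts: dict[str, int] = {}
        for i in range(windows):
            km = sequence[i : i + k]
            counts[km] = counts.get(km, 0) + 1
        for km_tuple in product(BASES, repeat=k):
            km = "".join(km_tuple)
            names.append(f"kmer{k}_{km}")
            values.append(counts.get(km, 0) / windows)
    return pd.Series(values, index=names, dtype=np.float64)
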