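"""Contact-map data model, plain-text I/O and patch utilities.

A contact map is a square, symmetric, non-negative matrix whose ``(i, j)``
entry counts chromatin interactions between genomic bins ``i`` and ``j``
at a fixed bin size.  Two plain-text interchange formats are supported:

* sparse triplet text: one ``bin_i<TAB>bin_j<TAB>count`` record per line,
  0-based bins, upper triangle only on write, ``#`` comments ignored;
* dense text: whitespace-separated square matrix, one row per line.

Binary dialects (``.cool``/``.hic``) are deliberately not parsed; both
are convertible to triplet dumps with standard tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ContactMap",
    "Patch",
    "read_triplet",
    "write_triplet",
    "read_dense",
    "write_dense",
    "symmetrize",
    "extract_patches",
    "reassemble",
    "log_view",
]


def symmetrize(matrix: np.ndarray) -> np.ndarray:
    """Return ``(M + M.T) / 2`` for a square matrix ``M``."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {matrix.shape}")
    return (matrix + matrix.T) / 2.0


@dataclass
class ContactMap:
    """Square symmetric non-negative interaction-frequency matrix.

    Parameters
    ----------
    matrix:
        Square array of counts.  Symmetrized and validated on creation.
    resolution_bp:
        Bin size in base pairs.
    chrom:
        Chromosome label (provenance only).
    start_bp:
        Genomic coordinate of bin 0.
    """

    matrix: np.ndarray
    resolution_bp: int = 1
    chrom: str = "chr?"
    start_bp: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"contact map must be square, got shape {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("contact map contains non-finite entries")
        if np.any(m < 0):
            raise ValueError("contact map contains negative entries")
        if self.resolution_bp <= 0:
            raise ValueError("resolution_bp must be positive")
        if self.start_bp < 0:
            raise ValueError("start_bp must be non-negative")
        self.matrix = symmetrize(m)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def with_matrix(self, matrix: np.ndarray) -> "ContactMap":
        """New map with the same metadata and a different matrix."""
        return replace(self, matrix=matrix)

    def total(self) -> float:
        return float(self.matrix.sum())


@dataclass(frozen=True)
class Patch:
    """A square sub-block of a contact map and its offset in the parent."""

    values: np.ndarray
    origin: tuple[int, int]

    @property
    def side(self) -> int:
        return self.values.shape[0]


def read_triplet(
    path: str | Path,
    n_bins: int | None = None,
    resolution_bp: int = 1,
    chrom: str = "chr?",
    start_bp: int = 0,
) -> ContactMap:
    """Read a sparse triplet dump into a dense :class:`ContactMap`.

    Duplicate records for a pair (in either orientation) are summed
    before the matrix is mirrored.  With ``n_bins=None`` the matrix side
    is inferred as ``max bin index + 1``.
    """
    records: dict[tuple[int, int], float] = {}
    max_bin = -1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'bin_i bin_j count', got {line!r}")
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer bin index in {line!r}") from None
            count = float(parts[2])
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative count {count}")
            if i < 0 or j < 0:
                raise ValueError(f"{path}:{lineno}: negative bin index")
            key = (min(i, j), max(i, j))
            records[key] = records.get(key, 0.0) + count
            max_bin = max(max_bin, i, j)

    if n_bins is None:
        if max_bin < 0:
            raise ValueError(f"{path}: empty file and no n_bins given; cannot infer size")
        n_bins = max_bin + 1
    elif max_bin >= n_bins:
        raise ValueError(f"{path}: bin index {max_bin} exceeds n_bins={n_bins}")

    m = np.zeros((n_bins, n_bins))
    for (i, j), count in records.items():
        m[i, j] = count
        m[j, i] = count
    return ContactMap(m, resolution_bp=resolution_bp, chrom=chrom, start_bp=start_bp)


def write_triplet(cm: ContactMap, path: str | Path) -> None:
    """Write the upper triangle (including diagonal) as triplet text.

    Integer-valued counts are written as integers so that a
    read/write round trip is exact.
    """
    with open(path, "w") as fh:
        fh.write(f"# chrom={cm.chrom} resolution_bp={cm.resolution_bp} "
                 f"start_bp={cm.start_bp} n_bins={cm.n_bins}\n")
        iu = np.triu_indices(cm.n_bins)
        for i, j in zip(*iu):
            v = cm.matrix[i, j]
            if v == 0:
                continue
            if float(v).is_integer():
                fh.write(f"{i}\t{j}\t{int(v)}\n")
            else:
                fh.write(f"{i}\t{j}\t{float(v)!r}\n")


def read_dense(path: str | Path, resolution_bp: int = 1, chrom: str = "chr?") -> ContactMap:
    """Read a whitespace-separated dense square matrix."""
    m = np.loadtxt(path, ndmin=2)
    return ContactMap(m, resolution_bp=resolution_bp, chrom=chrom)


def write_dense(cm: ContactMap, path: str | Path) -> None:
    np.savetxt(path, cm.matrix)


def _anchors(n: int, side: int, stride: int) -> list[int]:
    """Raster anchors min(k*stride, n - side); final anchor covers the edge."""
    out: list[int] = []
    k = 0
    while True:
        a = min(k * stride, n - side)
        out.append(a)
        if a == n - side:
            return out
        k += 1


def extract_patches(cm: ContactMap, side: int, stride: int) -> list[Patch]:
    """Deterministic raster-order tiling into ``side``×``side`` patches.

    The last row/column of patches is anchored at ``n_bins - side`` so
    that every bin is covered; it may overlap its predecessor.
    """
    if side > cm.n_bins:
        raise ValueError(f"patch side {side} exceeds n_bins {cm.n_bins}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    anchors = _anchors(cm.n_bins, side, stride)
    patches = []
    for r in anchors:
        for c in anchors:
            patches.append(Patch(cm.matrix[r:r + side, c:c + side].copy(), (r, c)))
    return patches


def reassemble(patches: Sequence[Patch], n_bins: int) -> np.ndarray:
    """Place patches back on an ``n_bins`` square grid, averaging overlaps."""
    acc = np.zeros((n_bins, n_bins))
    cover = np.zeros((n_bins, n_bins))
    for p in patches:
        r, c = p.origin
        s = p.side
        if r + s > n_bins or c + s > n_bins:
            raise ValueError(f"patch at {p.origin} with side {s} exceeds n_bins {n_bins}")
        acc[r:r + s, c:c + s] += p.values
        cover[r:r + s, c:c + s] += 1.0
    if np.any(cover == 0):
        raise ValueError("patches do not cover every bin")
    return acc / cover


def log_view(cm: ContactMap, pseudocount: float = 1.0) -> np.ndarray:
    """``log10(count + pseudocount)`` view for visualization."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return np.log10(cm.matrix + pseudocount)
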