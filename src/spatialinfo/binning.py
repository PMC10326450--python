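"""Exact-k spatial binning via a modified kd-tree.

Sparse genes give the classifier little signal at single-cell resolution, so
training also runs on spatially aggregated copies of the data.  Naive binning
with unequal bin occupancy introduces spurious spatial dependence through the
cell-count channel; to avoid this every bin holds exactly k cells.  A random
n mod k cells are discarded, then the point set is split recursively along
alternating axes, cutting each block at a multiple of k nearest the median,
until blocks of exactly k remain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


@dataclass
class BinLevel:
    """One resolution level: bins of exactly ``bin_size`` cells."""

    bin_size: int
    assignment: np.ndarray  # per-kept-cell bin index, aligned with kept_cells
    kept_cells: np.ndarray  # original cell indices, same order as assignment
    discarded: np.ndarray  # original cell indices dropped (n mod k of them)
    bin_counts: np.ndarray  # bins x genes, summed member counts
    bin_coords: np.ndarray  # bins x 2, member centroid
    n_bins: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_bins = self.bin_counts.shape[0]

    def members(self, b: int) -> np.ndarray:
        return self.kept_cells[self.assignment == b]


def _split_block(order: np.ndarray, coords: np.ndarray, k: int, depth: int, first_axis: int,
                 out: list[np.ndarray]) -> None:
    """Recursively split ``order`` (cell indices) into blocks of exactly k."""
    m = len(order)
    if m == k:
        out.append(order)
        return
    axis = (first_axis + depth) % 2
    # stable sort: ties in coordinate broken by cell index (order is ascending)
    key = coords[order, axis]
    order = order[np.argsort(key, kind="stable")]
    n_bins = m // k
    left_bins = int(round(n_bins / 2.0))
    left_bins = min(max(left_bins, 1), n_bins - 1)
    cut = left_bins * k
    _split_block(order[:cut], coords, k, depth + 1, first_axis, out)
    _split_block(order[cut:], coords, k, depth + 1, first_axis, out)


def bin_cells(
    coords: np.ndarray,
    counts: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> BinLevel:
    """Partition cells into spatially compact bins of exactly k members.

    A random ``n mod k`` cells are discarded first so the partition is exact.
    The first split axis is the axis of larger coordinate range; subsequent
    splits alternate.  Bin counts are member sums; bin coordinates member
    centroids.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k < 2:
        raise ValueError("bin size must be >= 2")
    if k > n:
        raise ValueError(f"bin size {k} exceeds number of cells {n}")
    n_discard = n % k
    perm = rng.permutation(n)
    discarded = np.sort(perm[:n_discard])
    kept = np.sort(perm[n_discard:])

    ranges = np.ptp(coords[kept], axis=0)
    first_axis = int(np.argmax(ranges))
    blocks: list[np.ndarray] = []
    _split_block(kept, coords, k, 0, first_axis, blocks)

    dense = counts.toarray() if sp.issparse(counts) else np.asarray(counts)
    n_bins = len(blocks)
    bin_counts = np.empty((n_bins, dense.shape[1]), dtype=dense.dtype)
    bin_coords = np.empty((n_bins, 2))
    kept_order = np.concatenate(blocks)
    assignment = np.concatenate([np.full(k, b, dtype=np.int64) for b in range(n_bins)])
    for b, block in enumerate(blocks):
        bin_counts[b] = dense[block].sum(axis=0)
        bin_coords[b] = coords[block].mean(axis=0)
    return BinLevel(
        bin_size=k,
        assignment=assignment,
        kept_cells=kept_order,
        discarded=discarded,
        bin_counts=bin_counts,
        bin_coords=bin_coords,
    )


@dataclass
class StackLevel:
    """One training level: expression rows + coordinates + objective weight."""

    weight: float
    counts: np.ndarray
    coords: np.ndarray
    bin_level: BinLevel | None = None  # None for the unbinned level


def build_bin_stack(
    counts: np.ndarray,
    coords: np.ndarray,
    bin_sizes,
    rng: np.random.Generator,
) -> list[StackLevel]:
    """Assemble the multi-resolution training stack.

    Level 0 is the unbinned data with weight 1; each bin size k contributes a
    level with objective weight k (the aggregated rows each summarize k cells,
    so their classification signal is upweighted accordingly).  Sizes larger
    than the number of cells are skipped with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    dense = counts.toarray() if sp.issparse(counts) else np.asarray(counts)
    levels = [StackLevel(weight=1.0, counts=dense, coords=coords)]
    for k in sorted(set(int(k) for k in bin_sizes)):
        if k > coords.shape[0]:
            warnings.warn(f"bin size {k} exceeds n={coords.shape[0]}; skipped")
            continue
        if coords.shape[0] // k < 2:
            warnings.warn(f"bin size {k} would yield fewer than 2 bins; skipped")
            continue
        lvl = bin_cells(coords, dense, k, rng)
        levels.append(
            StackLevel(weight=float(k), counts=lvl.bin_counts, coords=lvl.bin_coords, bin_level=lvl)
        )
    return levels
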