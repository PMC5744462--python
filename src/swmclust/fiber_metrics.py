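"""Fiber and bundle distance measures.

The workhorse metric is the symmetrized maximum Euclidean distance between
corresponding points of two equal-count polylines,

    d_ME(A, B) = min( max_i ||a_i - b_i||, max_i ||a_i - b_(Np-1-i)|| ),

i.e. the larger of the pointwise gaps, taken in whichever of the two fiber
orientations makes it smaller.  It is deliberately restrictive: two fibers
are close only when they run together along their whole extent, which is what
discriminating between neighbouring short association bundles requires.

For atlas-based segmentation the metric is augmented with a dimensionless
length penalty (``dnf``) so that a short subject fiber cannot match a much
longer atlas centroid merely by hugging part of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .tract_io import fiber_length

if TYPE_CHECKING:  # pragma: no cover
    from .atlas_builder import Bundle

__all__ = [
    "SparseDistanceSet",
    "d_me",
    "dnf",
    "d_men",
    "pairwise_d_me",
    "sparse_pairwise",
    "intersection_fractions",
    "bundle_mean_distance",
]


def _stack(fibers: Sequence[np.ndarray]) -> np.ndarray:
    arr = np.asarray(fibers, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("fibers must share a common point count (n, p, 3)")
    return arr


def d_me(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetrized max distance between corresponding points (mm).

    Zero iff ``b`` equals ``a`` or its reversal.  Raises if the point counts
    differ (resample first).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"point counts differ: {a.shape[0]} vs {b.shape[0]}")
    direct = np.linalg.norm(a - b, axis=1).max()
    flipped = np.linalg.norm(a - b[::-1], axis=1).max()
    return float(min(direct, flipped))


def dnf(l_a: float, l_b: float) -> float:
    """Dimensionless penalty for the length difference of two fibers.

    ``(|lA - lB| / max(lA, lB) + 1)^2 - 1``; symmetric, zero iff equal
    lengths, and < 3 since the length ratio term is < 1.
    """
    if l_a <= 0 or l_b <= 0:
        raise ValueError("fiber lengths must be positive")
    r = abs(l_a - l_b) / max(l_a, l_b)
    return (r + 1.0) ** 2 - 1.0


def d_men(
    a: np.ndarray,
    b: np.ndarray,
    l_a: float | None = None,
    l_b: float | None = None,
) -> float:
    """Length-penalized d_ME used for atlas-based segmentation.

    ``d_me + dnf`` when the penalty is positive, plain ``d_me`` otherwise.
    Lengths default to the polyline lengths of the inputs but may be given
    explicitly (e.g. native pre-resampling lengths).
    """
    base = d_me(a, b)
    la = fiber_length(a) if l_a is None else l_a
    lb = fiber_length(b) if l_b is None else l_b
    penalty = dnf(la, lb)
    return base + penalty if penalty > 0 else base


def pairwise_d_me(
    fibers_a: Sequence[np.ndarray],
    fibers_b: Sequence[np.ndarray] | None = None,
    block: int = 128,
) -> np.ndarray:
    """Dense matrix of d_ME between two fiber lists (mm), block-vectorized."""
    A = _stack(fibers_a)
    B = A if fibers_b is None else _stack(fibers_b)
    if A.shape[1] != B.shape[1]:
        raise ValueError("point counts differ between the two sets")
    Brev = B[:, ::-1, :]
    out = np.empty((A.shape[0], B.shape[0]), dtype=np.float64)
    for start in range(0, A.shape[0], block):
        chunk = A[start : start + block]  # (c, p, 3)
        # max of norms == sqrt of max of squared norms: one sqrt per pair
        diff = chunk[:, None, :, :] - B[None, :, :, :]
        direct = (diff**2).sum(-1).max(-1)
        diff = chunk[:, None, :, :] - Brev[None, :, :, :]
        flipped = (diff**2).sum(-1).max(-1)
        out[start : start + block] = np.sqrt(np.minimum(direct, flipped))
    return out


@dataclass
class SparseDistanceSet:
    """Pairs (i < j) whose d_ME is at or below a cutoff.

    Entries are stored as parallel arrays sorted lexicographically by
    (i, j); only about a few percent of all pairs survive a realistic cutoff,
    which is what makes whole-brain clustering tractable.
    """

    i: np.ndarray
    j: np.ndarray
    d: np.ndarray
    d_max: float
    n_elements: int

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=np.int64)
        self.j = np.asarray(self.j, dtype=np.int64)
        self.d = np.asarray(self.d, dtype=np.float64)
        if not (len(self.i) == len(self.j) == len(self.d)):
            raise ValueError("entry arrays disagree in length")
        if np.any(self.i >= self.j):
            raise ValueError("entries must satisfy i < j")
        if len(self.d) and self.d.max() > self.d_max + 1e-12:
            raise ValueError("stored distance exceeds d_max")

    def __len__(self) -> int:
        return len(self.d)

    def to_text(self, path) -> None:
        np.savetxt(
            str(path),
            np.column_stack([self.i, self.j, self.d]),
            fmt=["%d", "%d", "%.8f"],
            header=f"n_elements={self.n_elements} d_max={self.d_max}",
        )

    @classmethod
    def from_text(cls, path) -> "SparseDistanceSet":
        with open(path) as fh:
            header = fh.readline().lstrip("#").split()
        meta = dict(kv.split("=") for kv in header)
        data = np.loadtxt(str(path), ndmin=2)
        if data.size == 0:
            data = np.empty((0, 3))
        return cls(
            i=data[:, 0],
            j=data[:, 1],
            d=data[:, 2],
            d_max=float(meta["d_max"]),
            n_elements=int(meta["n_elements"]),
        )


def sparse_pairwise(
    fibers: Sequence[np.ndarray],
    d_max: float,
    metric: str = "d_me",
    block: int = 128,
) -> SparseDistanceSet:
    """All pairs (i < j) with d_ME <= ``d_max``, in lexicographic order.

    The computation is exact (every pair is evaluated); blocking only bounds
    memory.
    """
    if metric != "d_me":
        raise ValueError(f"unsupported metric {metric!r}")
    A = _stack(fibers) if len(fibers) else np.empty((0, 2, 3))
    n = A.shape[0]
    ii: list[np.ndarray] = []
    jj: list[np.ndarray] = []
    dd: list[np.ndarray] = []
    Brev = A[:, ::-1, :]
    d_max2 = d_max * d_max
    for start in range(0, n, block):
        stop = min(start + block, n)
        chunk = A[start:stop]
        rest = A[start:]  # upper triangle only
        diff = chunk[:, None, :, :] - rest[None, :, :, :]
        direct = (diff**2).sum(-1).max(-1)
        diff = chunk[:, None, :, :] - Brev[start:][None, :, :, :]
        flipped = (diff**2).sum(-1).max(-1)
        dmat2 = np.minimum(direct, flipped)
        rows, cols = np.nonzero(dmat2 <= d_max2)
        keep = rows < cols
        ii.append(rows[keep] + start)
        jj.append(cols[keep] + start)
        dd.append(np.sqrt(dmat2[rows[keep], cols[keep]]))
    i = np.concatenate(ii) if ii else np.empty(0, dtype=np.int64)
    j = np.concatenate(jj) if jj else np.empty(0, dtype=np.int64)
    d = np.concatenate(dd) if dd else np.empty(0)
    order = np.lexsort((j, i))
    return SparseDistanceSet(i=i[order], j=j[order], d=d[order], d_max=d_max, n_elements=n)


def _bundle_fibers(b) -> list[np.ndarray]:
    # Accept a Bundle, a CentroidSet, or a plain fiber sequence.
    if hasattr(b, "fiber_arrays"):
        return list(b.fiber_arrays())
    if hasattr(b, "fibers"):
        return list(b.fibers)
    return list(b)


def intersection_fractions(ba, bb, d_fiber: float = 5.0) -> tuple[float, float]:
    """Fraction of each bundle's fibers with a close fiber in the other.

    A fiber counts as intersecting when its minimum d_ME to the other bundle
    is strictly below ``d_fiber`` (default 5 mm).  Returns
    ``(frac_a, frac_b)``.
    """
    fa, fb = _bundle_fibers(ba), _bundle_fibers(bb)
    if not fa or not fb:
        raise ValueError("intersection_fractions requires nonempty bundles")
    dmat = pairwise_d_me(fa, fb)
    frac_a = float(np.mean(dmat.min(axis=1) < d_fiber))
    frac_b = float(np.mean(dmat.min(axis=0) < d_fiber))
    return frac_a, frac_b


def bundle_mean_distance(ba, bb, mode: str = "all_pairs") -> float:
    """Mean d_ME between two bundles (mm).

    ``all_pairs`` (default) averages d_ME over every cross pair;
    ``centroid`` compares the reversal-aligned pointwise-mean fibers instead.
    """
    fa, fb = _bundle_fibers(ba), _bundle_fibers(bb)
    if not fa or not fb:
        raise ValueError("bundle_mean_distance requires nonempty bundles")
    if mode == "all_pairs":
        return float(pairwise_d_me(fa, fb).mean())
    if mode == "centroid":
        from .atlas_builder import centroid_of_fibers

        return d_me(centroid_of_fibers(fa), centroid_of_fibers(fb))
    raise ValueError(f"unknown mode {mode!r}")
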