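"""Atlas-based segmentation, bundle volume, and lateralization analysis.

A new subject's fibers are labeled by their nearest atlas bundle centroid
under the length-penalized distance ``d_MEn``, accepting only fibers within
a restrictive per-bundle threshold (6-8 mm, scaled with mean bundle length).
Bundle volume is measured on a 2 mm isotropic voxel mask that keeps the
voxels traversed by more than one fiber, and hemispheric asymmetry is
summarized by the lateralization index LI = (R - L)/(R + L) with an unpaired
two-tailed t-test over subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas_builder import Atlas, bundle_centroid
from .fiber_metrics import d_men
from .tract_io import CentroidSet, fiber_length, resample_fiber

__all__ = [
    "SegmentationResult",
    "LateralityReport",
    "bundle_threshold",
    "segment_subject",
    "filter_small",
    "bundle_volume",
    "lateralization_index",
    "volume_ttest",
    "laterality_report",
]


def bundle_threshold(
    mean_length_mm: float,
    min_mm: float = 6.0,
    max_mm: float = 8.0,
    length_lo: float = 35.0,
    length_hi: float = 85.0,
) -> float:
    """Per-bundle acceptance threshold scaled linearly with bundle length.

    Mean bundle lengths in [35, 85] mm map linearly onto [6, 8] mm; lengths
    outside the window clamp to the nearest bound.
    """
    t = (mean_length_mm - length_lo) / (length_hi - length_lo)
    return float(min_mm + (max_mm - min_mm) * min(1.0, max(0.0, t)))


@dataclass
class SegmentationResult:
    """Per-bundle fiber assignments for one segmented subject."""

    subject_id: str
    assignments: dict[str, list[int]]  # bundle id -> subject fiber indices
    distances: dict[str, list[float]]  # matching d_MEn per assigned fiber
    thresholds: dict[str, float]
    present: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.present:
            self.present = {bid: len(ix) > 0 for bid, ix in self.assignments.items()}

    def fiber_count(self, bundle_id: str) -> int:
        return len(self.assignments.get(bundle_id, []))


def segment_subject(
    fibers: CentroidSet,
    atlas: Atlas,
    threshold_mm: Mapping[str, float] | None = None,
    threshold_min: float = 6.0,
    threshold_max: float = 8.0,
) -> SegmentationResult:
    """Assign each subject fiber to its closest atlas bundle under d_MEn.

    Every fiber is compared to every bundle centroid; it joins the arg-min
    bundle iff that minimum is at or below the bundle's threshold, so each
    fiber lands in at most one bundle.  Thresholds default to the linear
    length map of :func:`bundle_threshold` and may be overridden per bundle.
    """
    if fibers.space != atlas.space:
        raise ValueError(
            f"space mismatch: subject in {fibers.space!r}, atlas in {atlas.space!r}"
        )
    n_points = atlas.bundles[0].n_points if atlas.bundles else 51
    subject_fibers = [resample_fiber(f, n_points) for f in fibers.fibers]
    centroids: list[np.ndarray] = []
    thresholds: dict[str, float] = {}
    for b in atlas.bundles:
        c = resample_fiber(bundle_centroid(b), n_points)
        centroids.append(c)
        if threshold_mm is not None and b.id in threshold_mm:
            thresholds[b.id] = float(threshold_mm[b.id])
        else:
            mean_len = float(np.mean([fiber_length(f) for f in b.fiber_arrays()]))
            thresholds[b.id] = bundle_threshold(mean_len, threshold_min, threshold_max)
    assignments: dict[str, list[int]] = {b.id: [] for b in atlas.bundles}
    distances: dict[str, list[float]] = {b.id: [] for b in atlas.bundles}
    if centroids:
        centroid_lengths = [fiber_length(c) for c in centroids]
        for idx, f in enumerate(subject_fibers):
            lf = fiber_length(f)
            dists = np.array(
                [d_men(f, c, lf, lc) for c, lc in zip(centroids, centroid_lengths)]
            )
            best = int(dists.argmin())
            bid = atlas.bundles[best].id
            if dists[best] <= thresholds[bid]:
                assignments[bid].append(idx)
                distances[bid].append(float(dists[best]))
    return SegmentationResult(
        subject_id=fibers.subject_id,
        assignments=assignments,
        distances=distances,
        thresholds=thresholds,
    )


def filter_small(sr: SegmentationResult, min_fibers: int = 10) -> SegmentationResult:
    """Mark bundles with fewer than ``min_fibers`` fibers absent for a subject."""
    present = {
        bid: len(ix) >= min_fibers for bid, ix in sr.assignments.items()
    }
    return SegmentationResult(
        subject_id=sr.subject_id,
        assignments=sr.assignments,
        distances=sr.distances,
        thresholds=sr.thresholds,
        present=present,
    )


def bundle_volume(
    fibers: Sequence[np.ndarray], voxel_mm: float = 2.0, min_fibers_per_voxel: int = 2
) -> int:
    """Voxel count of the bundle mask on a ``voxel_mm`` isotropic grid.

    The grid is anchored at the origin with half-open cells
    ``[k*voxel_mm, (k+1)*voxel_mm)``.  A voxel's count is the number of
    distinct fibers with at least one point inside it; the mask keeps voxels
    with count >= ``min_fibers_per_voxel`` (the default 2 realizes the
    "more than one fiber" binarization).
    """
    if not len(fibers):
        raise ValueError("bundle_volume requires at least one fiber")
    voxel_fibers: dict[tuple[int, int, int], set[int]] = {}
    for fi, f in enumerate(fibers):
        cells = np.floor(np.asarray(f, dtype=np.float64) / voxel_mm).astype(np.int64)
        for cell in {tuple(c) for c in cells}:
            voxel_fibers.setdefault(cell, set()).add(fi)
    return sum(1 for s in voxel_fibers.values() if len(s) >= min_fibers_per_voxel)


def lateralization_index(vol_left: float, vol_right: float) -> float | None:
    """LI = (R - L)/(R + L) in [-1, 1]; negative means left-dominant.

    Undefined (None) when both volumes are zero.
    """
    total = vol_left + vol_right
    if total <= 0:
        return None
    return float((vol_right - vol_left) / total)


def volume_ttest(
    left: Sequence[float],
    right: Sequence[float],
    alpha: float = 0.05,
    welch: bool = False,
) -> tuple[float, float, bool]:
    """Two-tailed unpaired t-test on left vs right volumes.

    Pooled-variance by default (``welch=True`` switches to Welch's form).
    Identical constant samples give (t=0, p=1) rather than an undefined
    statistic.  Returns ``(t, p, significant_at_alpha)``.
    """
    left = np.asarray(left, dtype=np.float64)
    right = np.asarray(right, dtype=np.float64)
    if len(left) < 2 or len(right) < 2:
        raise ValueError("need at least 2 observations per side")
    if left.var(ddof=1) == 0 and right.var(ddof=1) == 0:
        if left.mean() == right.mean():
            return 0.0, 1.0, False
    t, p = stats.ttest_ind(left, right, equal_var=not welch)
    return float(t), float(p), bool(p < alpha)


@dataclass
class LateralityReport:
    """Per-bundle lateralization summary across segmented subjects."""

    table: pd.DataFrame  # bundle, mean_li, t, p, significant, n_left, n_right

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def laterality_report(
    volumes_left: Mapping[str, Sequence[float]],
    volumes_right: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    welch: bool = False,
) -> LateralityReport:
    """Laterality indices and volume t-tests for bundles common to both sides.

    ``volumes_left[bundle]`` / ``volumes_right[bundle]`` are per-subject
    volumes (aligned by subject order for the LI mean; the t-test itself is
    unpaired).  Subjects with both volumes zero are dropped from the LI mean.
    """
    rows = []
    for bid in sorted(set(volumes_left) & set(volumes_right)):
        lv = np.asarray(volumes_left[bid], dtype=np.float64)
        rv = np.asarray(volumes_right[bid], dtype=np.float64)
        lis = [
            li
            for l, r in zip(lv, rv)
            if (li := lateralization_index(l, r)) is not None
        ]
        t, p, sig = volume_ttest(lv, rv, alpha=alpha, welch=welch)
        rows.append(
            {
                "bundle": bid,
                "mean_li": float(np.mean(lis)) if lis else np.nan,
                "t": t,
                "p": p,
                "significant": sig,
                "n_left": len(lv),
                "n_right": len(rv),
            }
        )
    return LateralityReport(table=pd.DataFrame(rows))
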