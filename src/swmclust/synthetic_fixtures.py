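"""Synthetic multi-subject tractograms with known ground truth.

The generator emulates the geometry the pipeline cares about — U-shaped
short association arcs whose endpoints sit in small cortical ROI boxes —
without any claim of biophysical realism.  A population is defined by a set
of template bundles; each subject carries a jittered copy of each template
(with a per-template presence probability) plus subject-unique random
distractor arcs that are guaranteed to stay far from every template.  All
randomness derives from one master seed through per-(subject, template)
substreams, so populations are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .fiber_metrics import d_me
from .tract_io import CentroidSet, ParcellationVolume, fiber_length, resample_fiber

__all__ = [
    "TemplateBundle",
    "PopulationSpec",
    "make_template",
    "make_arc",
    "example_templates",
    "make_population",
    "make_parcellation",
    "parcellation_for_templates",
]

_DENSE = 2001  # samples for numeric arc-length evaluation


def _arc_points(e0, e1, depth, normal, p, n_samples):
    t = np.linspace(0.0, 1.0, n_samples)
    base = e0[None, :] + t[:, None] * (e1 - e0)[None, :]
    bump = depth * np.sin(np.pi * t) ** p
    return base + bump[:, None] * normal[None, :]


def _default_normal(u: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n = np.cross(u, ref)
    return n / np.linalg.norm(n)


def make_arc(
    e0,
    e1,
    depth: float,
    shape_power: float = 1.0,
    normal=None,
    n_points: int = 51,
) -> np.ndarray:
    """Smooth arc between two endpoints with apex ``depth`` along ``normal``.

    The bump profile is ``sin(pi t)^shape_power``; power 1 gives a gentle U,
    larger powers a narrower, longer arch.  Returned resampled to
    ``n_points`` equidistant points.
    """
    e0 = np.asarray(e0, dtype=np.float64)
    e1 = np.asarray(e1, dtype=np.float64)
    u = e1 - e0
    sep = np.linalg.norm(u)
    if sep == 0:
        raise ValueError("endpoints must be distinct")
    if depth == 0:
        return resample_fiber(np.stack([e0, e1]), n_points)
    n = _default_normal(u / sep) if normal is None else np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    dense = _arc_points(e0, e1, depth, n, shape_power, _DENSE)
    return resample_fiber(dense, n_points)


@dataclass
class TemplateBundle:
    """A ground-truth bundle: its centroid arc, length, and ROI endpoint labels."""

    id: str
    centroid: np.ndarray
    target_length: float
    roi_labels: tuple[int, int]

    def __post_init__(self) -> None:
        actual = fiber_length(self.centroid)
        if abs(actual - self.target_length) > 0.02 * self.target_length:
            raise ValueError(
                f"template {self.id!r}: length {actual:.2f} deviates more than "
                f"2% from target {self.target_length:.2f}"
            )


def make_template(
    endpoints,
    depth: float,
    length: float | None = None,
    roi_labels: tuple[int, int] = (0, 0),
    template_id: str = "template",
    n_points: int = 51,
) -> TemplateBundle:
    """Template arc through two endpoints with given apex depth.

    When ``length`` is requested, the bump shape power is tuned numerically
    so the arc length lands within 2% of it; geometrically unreachable
    lengths raise.  With ``length=None`` the gentle (power 1) profile is
    used and its own length recorded as the target.  Deterministic: same
    inputs, same output.
    """
    e0 = np.asarray(endpoints[0], dtype=np.float64)
    e1 = np.asarray(endpoints[1], dtype=np.float64)
    sep = float(np.linalg.norm(e1 - e0))
    if sep == 0:
        raise ValueError("endpoints must be distinct")
    if depth == 0:
        fiber = make_arc(e0, e1, 0.0, n_points=n_points)
        target = sep if length is None else length
        if abs(sep - target) > 0.02 * target:
            raise ValueError("straight segment cannot meet requested length")
        return TemplateBundle(template_id, fiber, target, roi_labels)
    if length is None:
        fiber = make_arc(e0, e1, depth, 1.0, n_points=n_points)
        return TemplateBundle(template_id, fiber, fiber_length(fiber), roi_labels)
    u = (e1 - e0) / sep
    n = _default_normal(u)
    powers = np.geomspace(0.25, 16.0, 160)
    lengths = np.array(
        [fiber_length(_arc_points(e0, e1, depth, n, p, _DENSE)) for p in powers]
    )
    best = int(np.argmin(np.abs(lengths - length)))
    if abs(lengths[best] - length) > 0.02 * length:
        raise ValueError(
            f"length {length:.1f} mm infeasible for separation {sep:.1f} mm "
            f"and depth {depth:.1f} mm (reachable: "
            f"{lengths.min():.1f}-{lengths.max():.1f} mm)"
        )
    fiber = make_arc(e0, e1, depth, float(powers[best]), n_points=n_points)
    return TemplateBundle(template_id, fiber, length, roi_labels)


def example_templates(
    n_templates: int = 10,
    hemisphere: str = "left",
    n_points: int = 51,
) -> list[TemplateBundle]:
    """Deterministic layout of well-separated U-arc templates.

    Templates sit on a coarse (y, z) grid in one hemisphere (x < 0 for left),
    60 mm apart so neighbouring bundles never fall under a 30 mm clustering
    cutoff and their endpoint ROI boxes never touch.  Template k connects
    ROI labels (2k+1, 2k+2).
    """
    sign = -1.0 if hemisphere == "left" else 1.0
    grid = [(y, z) for z in (-120, -60, 0, 60, 120) for y in (-120, -60, 0, 60, 120)]
    if n_templates > len(grid):
        raise ValueError(f"at most {len(grid)} templates supported")
    templates = []
    for k in range(n_templates):
        y, z = grid[k]
        sep = 35.0 + 5.0 * (k % 3)
        depth = 10.0 + 4.0 * (k % 2)
        e0 = np.array([sign * 40.0, y - sep / 2, z])
        e1 = np.array([sign * 40.0, y + sep / 2, z])
        templates.append(
            make_template(
                (e0, e1),
                depth=depth,
                roi_labels=(2 * k + 1, 2 * k + 2),
                template_id=f"T{k:02d}{hemisphere[0]}",
                n_points=n_points,
            )
        )
    return templates


@dataclass
class PopulationSpec:
    """Conditions for a synthetic multi-subject population.

    Defaults mirror the study conditions the pipeline is designed for:
    near-ubiquitous true bundles (presence 0.9), ~1 mm anatomical jitter,
    20 fibers per bundle, and 50 subject-unique distractor arcs kept at
    least ``distractor_min_dist`` (the clustering cutoff) from every
    template.
    """

    templates: list[TemplateBundle]
    n_subjects: int = 8
    presence_prob: float = 0.9
    jitter_sigma: float = 1.0
    fibers_per_bundle: int = 20
    distractors_per_subject: int = 50
    seed: int = 0
    distractor_min_dist: float = 30.0
    hemisphere: str = "left"
    space: str = "template"
    n_points: int = 51


def _jittered_copy(template: np.ndarray, sigma: float, rng) -> np.ndarray:
    """Smooth per-fiber perturbation: rigid offset + low-amplitude point noise."""
    offset = rng.normal(0.0, sigma, size=3)
    noise = rng.normal(0.0, sigma / 4.0, size=template.shape)
    noise = gaussian_filter1d(noise, sigma=3.0, axis=0, mode="nearest")
    return template + offset[None, :] + noise


def _random_distractor(
    rng, templates: Sequence[np.ndarray], min_dist: float, hemisphere: str, n_points: int
) -> np.ndarray:
    sign = -1.0 if hemisphere == "left" else 1.0
    for _ in range(500):
        center = np.array(
            [
                sign * rng.uniform(15.0, 95.0),
                rng.uniform(-110.0, 110.0),
                rng.uniform(-110.0, 110.0),
            ]
        )
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        sep = rng.uniform(30.0, 55.0)
        depth = rng.uniform(6.0, 15.0)
        arc = make_arc(
            center - direction * sep / 2,
            center + direction * sep / 2,
            depth,
            n_points=n_points,
        )
        if all(d_me(arc, t) >= min_dist for t in templates):
            return arc
    raise RuntimeError("could not place a distractor away from all templates")


def make_population(spec: PopulationSpec) -> tuple[list[CentroidSet], pd.DataFrame]:
    """Generate per-subject centroid sets and the fiber-level truth table.

    The truth table has one row per generated fiber with columns
    ``subject_id``, ``fiber_index``, ``source`` (template id or
    "distractor").
    """
    template_fibers = [
        t.centroid
        if t.centroid.shape[0] == spec.n_points
        else resample_fiber(t.centroid, spec.n_points)
        for t in spec.templates
    ]
    subjects: list[CentroidSet] = []
    rows: list[dict] = []
    for s in range(spec.n_subjects):
        subject_id = f"sub{s:03d}"
        fibers: list[np.ndarray] = []
        for k, template in enumerate(spec.templates):
            rng = np.random.default_rng([spec.seed, s, k])
            if rng.random() >= spec.presence_prob:
                continue
            for _ in range(spec.fibers_per_bundle):
                fibers.append(
                    _jittered_copy(template_fibers[k], spec.jitter_sigma, rng)
                )
                rows.append(
                    {
                        "subject_id": subject_id,
                        "fiber_index": len(fibers) - 1,
                        "source": template.id,
                    }
                )
        for d in range(spec.distractors_per_subject):
            rng = np.random.default_rng([spec.seed, s, 10_000 + d])
            fibers.append(
                _random_distractor(
                    rng,
                    template_fibers,
                    spec.distractor_min_dist,
                    spec.hemisphere,
                    spec.n_points,
                )
            )
            rows.append(
                {
                    "subject_id": subject_id,
                    "fiber_index": len(fibers) - 1,
                    "source": "distractor",
                }
            )
        subjects.append(
            CentroidSet(
                subject_id=subject_id,
                fibers=fibers,
                hemisphere=spec.hemisphere,
                space=spec.space,
            )
        )
    return subjects, pd.DataFrame(rows)


def make_parcellation(
    roi_boxes: Mapping[int, tuple[Sequence[float], Sequence[float]]],
    shape: tuple[int, int, int],
    voxel_mm: float = 2.0,
    origin_mm: Sequence[float] = (0.0, 0.0, 0.0),
    label_table: Mapping[int, str] | None = None,
) -> ParcellationVolume:
    """Integer label volume from axis-aligned ROI boxes (mm corners).

    Voxels whose centers fall inside a box get its label; overlapping boxes
    raise.  The affine is ``voxel_mm``-isotropic with the given origin.
    """
    labels = np.zeros(shape, dtype=np.int32)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = origin_mm
    centers = [
        np.arange(shape[k]) * voxel_mm + origin_mm[k] for k in range(3)
    ]
    for label, (lo, hi) in sorted(roi_boxes.items()):
        lo = np.asarray(lo, dtype=np.float64)
        hi = np.asarray(hi, dtype=np.float64)
        if np.any(lo >= hi):
            raise ValueError(f"box for label {label} has non-positive extent")
        masks = [
            (centers[k] >= lo[k]) & (centers[k] <= hi[k]) for k in range(3)
        ]
        region = np.ix_(*[np.nonzero(m)[0] for m in masks])
        if np.any(labels[region] != 0):
            raise ValueError(f"box for label {label} overlaps another box")
        labels[region] = label
    if label_table is None:
        label_table = {int(l): f"R{l}" for l in roi_boxes}
    return ParcellationVolume(labels=labels, voxel_to_mm=affine, label_table=label_table)


def parcellation_for_templates(
    templates: Sequence[TemplateBundle],
    box_half_mm: float = 7.0,
    voxel_mm: float = 2.0,
    pad_mm: float = 20.0,
    label_table: Mapping[int, str] | None = None,
) -> ParcellationVolume:
    """Parcellation whose ROI boxes are centered on the template endpoints."""
    boxes: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    points = []
    for t in templates:
        for end, label in zip((t.centroid[0], t.centroid[-1]), t.roi_labels):
            if label in boxes:
                raise ValueError(f"label {label} used by two endpoints")
            boxes[label] = (end - box_half_mm, end + box_half_mm)
            points.append(end)
    points = np.asarray(points)
    lo = points.min(axis=0) - box_half_mm - pad_mm
    hi = points.max(axis=0) + box_half_mm + pad_mm
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / voxel_mm)) + 1 for k in range(3))
    return make_parcellation(
        boxes, shape, voxel_mm=voxel_mm, origin_mm=lo, label_table=label_table
    )
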