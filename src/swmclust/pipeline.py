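"""Pipeline orchestration: selection → clustering → matching → labeling.

Every tunable that shapes the result lives in :class:`PipelineConfig` with
the method's canonical defaults (length window 35-85 mm, DWM threshold
10 mm, similarity scale sigma2 = 60 mm, cluster cutoff d_clmax = 30 mm, 75%
subject reproducibility, 5 mm / 50% intersection matching, 10 bagging
repetitions with groups of 27 and 8 votes, 6-8 mm segmentation thresholds,
2 mm volume voxels, 10-fiber minimum); nothing is hard-coded downstream.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .anatomical_labeling import main_connection, name_bundles
from .atlas_builder import (
    Atlas,
    Bundle,
    bagging_aggregate,
    fuse_bundles,
    match_groups,
)
from .fiber_metrics import sparse_pairwise
from .hier_clustering import (
    adaptive_partition,
    average_link_dendrogram,
    build_affinity_graph,
    reproducibility_filter,
)
from .swm_selection import DwmReference, dwm_filter, length_filter
from .tract_io import CentroidSet, ParcellationVolume

__all__ = [
    "PipelineConfig",
    "select_centroids",
    "group_atlas",
    "two_group_atlas",
    "run_bagging",
    "label_atlas",
]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All method parameters, at their canonical defaults."""

    min_length_mm: float = 35.0
    max_length_mm: float = 85.0
    dwm_threshold_mm: float = 10.0
    dwm_sample_fraction: float = 0.2
    sigma2: float = 60.0
    d_clmax: float = 30.0
    min_subject_fraction: float = 0.75
    intersection_d_fiber: float = 5.0
    intersection_min_fraction: float = 0.5
    bagging_reps: int = 10
    group_size: int = 27
    min_votes: int = 8
    label_min_fiber_fraction: float = 0.5
    label_oversample_factor: int = 10
    label_probe_depth: int = 3
    segmentation_threshold_min: float = 6.0
    segmentation_threshold_max: float = 8.0
    volume_voxel_mm: float = 2.0
    min_fibers_per_bundle: int = 10
    n_points: int = 51
    seed: int = 0

    def validate(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.d_clmax <= 0:
            raise ValueError("d_clmax must be positive")
        if not 0 < self.min_subject_fraction <= 1:
            raise ValueError("min_subject_fraction must be in (0, 1]")
        if not 0 < self.dwm_sample_fraction <= 1:
            raise ValueError("dwm_sample_fraction must be in (0, 1]")
        if self.min_length_mm < 0 or self.max_length_mm <= self.min_length_mm:
            raise ValueError("length window must satisfy 0 <= min < max")
        if self.min_votes > self.bagging_reps:
            raise ValueError("min_votes cannot exceed bagging_reps")
        if self.segmentation_threshold_max < self.segmentation_threshold_min:
            raise ValueError("segmentation thresholds out of order")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**data)
        config.validate()
        return config


def select_centroids(
    cs: CentroidSet, config: PipelineConfig, dwm_ref: DwmReference | None = None
) -> CentroidSet:
    """Length window plus optional DWM-lookalike removal for one subject."""
    out = length_filter(cs, config.min_length_mm, config.max_length_mm)
    if dwm_ref is not None:
        out = dwm_filter(out, dwm_ref, config.dwm_threshold_mm)
    return out


def group_atlas(
    subjects: Sequence[CentroidSet],
    config: PipelineConfig,
    dwm_ref: DwmReference | None = None,
    group_id: str = "g1",
) -> Atlas:
    """Reproducible-bundle atlas from one group of subjects.

    Selection, pooled sparse distances at the cluster cutoff, average-link
    dendrogram, adaptive partition, and the subject-reproducibility filter;
    each surviving cluster becomes a bundle.
    """
    config.validate()
    selected = [select_centroids(cs, config, dwm_ref) for cs in subjects]
    fibers: list[np.ndarray] = []
    subject_of: list[str] = []
    for cs in selected:
        resampled = cs.resampled(config.n_points)
        fibers.extend(resampled.fibers)
        subject_of.extend([cs.subject_id] * len(cs))
    log.info("%s: %d centroids pooled from %d subjects", group_id, len(fibers), len(subjects))
    if not fibers:
        return Atlas(bundles=[], space=subjects[0].space if subjects else "template")
    sd = sparse_pairwise(fibers, d_max=config.d_clmax)
    graph = build_affinity_graph(sd, sigma2=config.sigma2)
    dendrogram = average_link_dendrogram(graph)
    partition = adaptive_partition(dendrogram, fibers, d_clmax=config.d_clmax)
    kept = reproducibility_filter(
        partition, subject_of, len(subjects), config.min_subject_fraction
    )
    log.info(
        "%s: %d edges, %d clusters, %d reproducible",
        group_id,
        len(sd),
        len(partition),
        len(kept),
    )
    hemisphere = subjects[0].hemisphere if subjects else None
    bundles = []
    for k, cluster in enumerate(sorted(kept.clusters, key=lambda c: (-len(c), int(c[0])))):
        bundles.append(
            Bundle(
                id=f"{group_id}_b{k:03d}",
                fibers=[(subject_of[int(i)], fibers[int(i)]) for i in cluster],
                hemisphere=hemisphere,
                provenance=[group_id],
            )
        )
    return Atlas(
        bundles=bundles,
        space=subjects[0].space if subjects else "template",
        provenance=[group_id],
    )


def two_group_atlas(
    group1: Sequence[CentroidSet],
    group2: Sequence[CentroidSet],
    config: PipelineConfig,
    dwm_ref: DwmReference | None = None,
    atlas_id: str = "atlas",
) -> Atlas:
    """Robust atlas: bundles found independently in two groups, fused."""
    a1 = group_atlas(group1, config, dwm_ref, group_id=f"{atlas_id}_g1")
    a2 = group_atlas(group2, config, dwm_ref, group_id=f"{atlas_id}_g2")
    matches = match_groups(
        a1, a2, d_fiber=config.intersection_d_fiber,
        min_frac=config.intersection_min_fraction,
    )
    log.info("%s: %d/%d + %d bundles matched across groups",
             atlas_id, len(matches), len(a1), len(a2))
    bundles = [
        fuse_bundles(a1.get(id1), a2.get(id2), bundle_id=f"{atlas_id}_b{k:03d}")
        for k, (id1, id2, _, _) in enumerate(matches)
    ]
    return Atlas(bundles=bundles, space=a1.space, provenance=[atlas_id])


def run_bagging(
    subjects: Sequence[CentroidSet],
    config: PipelineConfig,
    dwm_ref: DwmReference | None = None,
) -> Atlas:
    """Bagged atlas: repeat the two-group construction on random subsets.

    Each repetition samples ``2 * group_size`` subjects without replacement
    (per-repetition rng derived from the master seed), splits them into two
    groups, and builds a two-group atlas; the repetitions are aggregated by
    centroid clustering with the >= ``min_votes`` rule.
    """
    config.validate()
    if len(subjects) < 2 * config.group_size:
        raise ValueError(
            f"need at least {2 * config.group_size} subjects, got {len(subjects)}"
        )
    atlases = []
    for rep in range(config.bagging_reps):
        rng = np.random.default_rng([config.seed, rep])
        chosen = rng.choice(len(subjects), size=2 * config.group_size, replace=False)
        g1 = [subjects[i] for i in chosen[: config.group_size]]
        g2 = [subjects[i] for i in chosen[config.group_size :]]
        atlases.append(
            two_group_atlas(g1, g2, config, dwm_ref, atlas_id=f"rep{rep}")
        )
    return bagging_aggregate(
        atlases,
        d_clmax=config.d_clmax,
        min_votes=config.min_votes,
        sigma2=config.sigma2,
    )


def label_atlas(
    atlas: Atlas,
    parcellations: Mapping[str, ParcellationVolume],
    config: PipelineConfig,
    presence: str | Mapping[str, str] = "l",
) -> Atlas:
    """Attach connection names to an atlas; unlabelable bundles are dropped.

    ``presence`` gives the hemisphere suffix (i/l/r), either globally or per
    bundle id.  Bundles whose dominant ROI pair falls below the fiber-
    fraction floor are removed, mirroring the "strong connection" rule.
    """
    label_table = None
    for pv in parcellations.values():
        label_table = dict(pv.label_table)
        break
    kept: list[Bundle] = []
    pairs: list[tuple[tuple[int, int], str, int]] = []
    for b in atlas.bundles:
        pair = main_connection(
            b,
            parcellations,
            min_fiber_frac=config.label_min_fiber_fraction,
            oversample_factor=config.label_oversample_factor,
            probe_depth=config.label_probe_depth,
        )
        if pair is None:
            log.info("bundle %s dropped: no stable connection", b.id)
            continue
        suffix = presence if isinstance(presence, str) else presence.get(b.id, "l")
        kept.append(b)
        pairs.append((pair, suffix, len(b)))
    names = name_bundles(pairs, label_table)
    bundles = [dataclasses.replace(b, label=name) for b, name in zip(kept, names)]
    return Atlas(bundles=bundles, space=atlas.space, provenance=atlas.provenance)
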