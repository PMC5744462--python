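"""Intergroup bundle matching, fusion, bagging aggregation, and symmetry.

An atlas built from one group of subjects is validated against an atlas from
an independent group: bundles whose mutual fiber intersection exceeds 50%
are considered the same bundle and fused.  Robustness is then quantified by
bagging — the two-group construction is repeated on random subject subsets,
the per-repetition bundle centroids are clustered, and only bundles recurring
in at least ``min_votes`` repetitions (8 of 10 by default) enter the final
atlas.  Interhemispheric correspondence mirrors the right-hemisphere bundles
across the midsagittal plane and applies the same intersection criterion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .fiber_metrics import intersection_fractions, pairwise_d_me, sparse_pairwise
from .hier_clustering import adaptive_partition, average_link_dendrogram, build_affinity_graph
from .tract_io import CentroidSet, resample_fiber, write_tractogram, read_tractogram

__all__ = [
    "Bundle",
    "Atlas",
    "centroid_of_fibers",
    "bundle_centroid",
    "match_groups",
    "fuse_bundles",
    "bagging_aggregate",
    "interhemispheric_match",
    "symmetrize_atlas",
    "reflect_bundle",
    "save_atlas",
    "load_atlas",
]


@dataclass
class Bundle:
    """A multi-subject cluster of fiber centroids."""

    id: str
    fibers: list[tuple[str, np.ndarray]]  # (subject_id, fiber)
    hemisphere: str | None = None
    label: str | None = None
    votes: int | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.fibers:
            raise ValueError(f"bundle {self.id!r} is empty")
        counts = {f.shape[0] for _, f in self.fibers}
        if len(counts) != 1:
            raise ValueError(f"bundle {self.id!r} mixes point counts {counts}")

    def __len__(self) -> int:
        return len(self.fibers)

    def fiber_arrays(self) -> list[np.ndarray]:
        return [f for _, f in self.fibers]

    def subjects(self) -> set[str]:
        return {s for s, _ in self.fibers}

    @property
    def n_points(self) -> int:
        return self.fibers[0][1].shape[0]


@dataclass
class Atlas:
    """A set of bundles with space and provenance metadata."""

    bundles: list[Bundle]
    space: str = "template"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [b.id for b in self.bundles]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate bundle ids in atlas")

    def __len__(self) -> int:
        return len(self.bundles)

    def get(self, bundle_id: str) -> Bundle:
        for b in self.bundles:
            if b.id == bundle_id:
                return b
        raise KeyError(bundle_id)


def centroid_of_fibers(fibers: list[np.ndarray]) -> np.ndarray:
    """Reversal-aligned pointwise mean of a fiber list.

    Every fiber is oriented to the first one (direct vs reversed, whichever
    gives the smaller max pointwise gap) before pointwise averaging.  A
    single-fiber bundle is its own centroid.
    """
    if not fibers:
        raise ValueError("cannot average zero fibers")
    ref = fibers[0]
    oriented = [ref]
    for f in fibers[1:]:
        direct = np.linalg.norm(f - ref, axis=1).max()
        flipped = np.linalg.norm(f[::-1] - ref, axis=1).max()
        oriented.append(f if direct <= flipped else f[::-1])
    return np.mean(oriented, axis=0)


def bundle_centroid(b: Bundle) -> np.ndarray:
    """Representative fiber of a bundle (see :func:`centroid_of_fibers`)."""
    return centroid_of_fibers(b.fiber_arrays())


def match_groups(
    a1: Atlas, a2: Atlas, d_fiber: float = 5.0, min_frac: float = 0.5
) -> list[tuple[str, str, float, float]]:
    """One-to-one matching of similar bundles across two group atlases.

    A pair qualifies when both of its intersection fractions (fibers with a
    closer-than-``d_fiber`` counterpart in the other bundle) exceed
    ``min_frac``.  Qualifying pairs are resolved greedily by descending mean
    fraction so each bundle appears in at most one match.  Returns tuples
    ``(id1, id2, frac1, frac2)``.
    """
    candidates = []
    for b1 in a1.bundles:
        for b2 in a2.bundles:
            f1, f2 = intersection_fractions(b1, b2, d_fiber)
            if f1 > min_frac and f2 > min_frac:
                candidates.append(((f1 + f2) / 2.0, b1.id, b2.id, f1, f2))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used1: set[str] = set()
    used2: set[str] = set()
    matches = []
    for _, id1, id2, f1, f2 in candidates:
        if id1 in used1 or id2 in used2:
            continue
        used1.add(id1)
        used2.add(id2)
        matches.append((id1, id2, f1, f2))
    return matches


def fuse_bundles(x: Bundle, y: Bundle, bundle_id: str | None = None) -> Bundle:
    """Fiber multiset union of a matched pair, with provenance from both."""
    return Bundle(
        id=bundle_id or f"{x.id}+{y.id}",
        fibers=list(x.fibers) + list(y.fibers),
        hemisphere=x.hemisphere,
        provenance=(x.provenance or [x.id]) + (y.provenance or [y.id]),
    )


def bagging_aggregate(
    atlases: list[Atlas],
    d_clmax: float = 30.0,
    min_votes: int = 8,
    sigma2: float = 60.0,
) -> Atlas:
    """Aggregate bagging repetitions into a final atlas by vote counting.

    The centroid of every bundle from every repetition is computed, the
    centroids are clustered with the same sparse average-link machinery used
    for fibers (cutoff ``d_clmax``), and each cluster whose members span at
    least ``min_votes`` distinct repetitions becomes a final bundle carrying
    the union of its members' fibers and the repetition count as its votes.
    """
    if len(atlases) < min_votes:
        raise ValueError(
            f"{len(atlases)} repetitions cannot reach min_votes={min_votes}"
        )
    members: list[tuple[int, Bundle]] = []
    for rep, atlas in enumerate(atlases):
        for b in atlas.bundles:
            members.append((rep, b))
    if not members:
        return Atlas(bundles=[], provenance=["bagging:empty"])
    n_points = members[0][1].n_points
    centroids = [resample_fiber(bundle_centroid(b), n_points) for _, b in members]
    sd = sparse_pairwise(centroids, d_max=d_clmax)
    dg = average_link_dendrogram(build_affinity_graph(sd, sigma2=sigma2))
    part = adaptive_partition(dg, centroids, d_clmax=d_clmax)

    final: list[Bundle] = []
    for cluster in sorted(part.clusters, key=lambda c: (-len(c), int(c[0]))):
        reps = {members[int(k)][0] for k in cluster}
        if len(reps) < min_votes:
            continue
        fibers: list[tuple[str, np.ndarray]] = []
        provenance: list[str] = []
        hemisphere = members[int(cluster[0])][1].hemisphere
        for k in cluster:
            rep, b = members[int(k)]
            fibers.extend(b.fibers)
            provenance.append(f"rep{rep}:{b.id}")
        final.append(
            Bundle(
                id=f"bundle_{len(final):03d}",
                fibers=fibers,
                hemisphere=hemisphere,
                votes=len(reps),
                provenance=provenance,
            )
        )
    return Atlas(bundles=final, provenance=[f"bagging:{len(atlases)}reps"])


def reflect_bundle(b: Bundle, plane_x: float = 0.0) -> Bundle:
    """Mirror a bundle across the plane x = ``plane_x`` (hemisphere flips)."""
    fibers = []
    for subj, f in b.fibers:
        g = f.copy()
        g[:, 0] = 2.0 * plane_x - g[:, 0]
        fibers.append((subj, g))
    hemi = None
    if b.hemisphere is not None:
        hemi = "right" if b.hemisphere == "left" else "left"
    return replace(b, fibers=fibers, hemisphere=hemi)


def interhemispheric_match(
    left: Atlas,
    right: Atlas,
    d_fiber: float = 5.0,
    min_frac: float = 0.5,
    plane_x: float = 0.0,
) -> list[tuple[str, str, float, float]]:
    """Find bundles common to both hemispheres.

    Right bundles are reflected onto the left hemisphere and matched against
    the left atlas with the usual intersection criterion.  Returns
    ``(left_id, right_id, frac_left, frac_right)`` tuples.
    """
    mirrored = Atlas(
        bundles=[reflect_bundle(b, plane_x) for b in right.bundles],
        space=right.space,
    )
    return match_groups(left, mirrored, d_fiber=d_fiber, min_frac=min_frac)


def symmetrize_atlas(
    left: Atlas,
    right: Atlas,
    correspondence: list[tuple[str, str, float, float]],
    plane_x: float = 0.0,
) -> Atlas:
    """Build the symmetric atlas from an interhemispheric correspondence.

    For each common pair the left bundle and the reflected right bundle are
    fused into the symmetric left bundle, whose exact reflection becomes the
    symmetric right bundle.  Bundles without a counterpart pass through
    unchanged.
    """
    matched_left = {lid for lid, _, _, _ in correspondence}
    matched_right = {rid for _, rid, _, _ in correspondence}
    bundles: list[Bundle] = []
    for lid, rid, _, _ in correspondence:
        lb = left.get(lid)
        rb = right.get(rid)
        sym_left = fuse_bundles(lb, reflect_bundle(rb, plane_x), bundle_id=f"{lid}_sym_l")
        sym_left = replace(sym_left, hemisphere="left", votes=lb.votes)
        sym_right = replace(
            reflect_bundle(sym_left, plane_x), id=f"{lid}_sym_r", votes=rb.votes
        )
        bundles.extend([sym_left, sym_right])
    for b in left.bundles:
        if b.id not in matched_left:
            bundles.append(b)
    for b in right.bundles:
        if b.id not in matched_right:
            bundles.append(b)
    return Atlas(bundles=bundles, space=left.space, provenance=["symmetrized"])


def save_atlas(atlas: Atlas, directory, format: str = "trk") -> None:
    """Write one streamline file per bundle plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"space": atlas.space, "provenance": atlas.provenance, "bundles": []}
    for b in atlas.bundles:
        name = (b.label or b.id).replace("/", "_")
        fname = f"{name}.{format}"
        cs = CentroidSet(
            subject_id="atlas",
            fibers=b.fiber_arrays(),
            hemisphere=b.hemisphere,
            space=atlas.space,
        )
        write_tractogram(cs, directory / fname, format=format)
        manifest["bundles"].append(
            {
                "id": b.id,
                "label": b.label,
                "hemisphere": b.hemisphere,
                "votes": b.votes,
                "file": fname,
                "subjects": [s for s, _ in b.fibers],
                "provenance": b.provenance,
            }
        )
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def load_atlas(directory) -> Atlas:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    bundles = []
    for entry in manifest["bundles"]:
        cs = read_tractogram(directory / entry["file"], space=manifest["space"])
        bundles.append(
            Bundle(
                id=entry["id"],
                fibers=list(zip(entry["subjects"], cs.fibers)),
                hemisphere=entry["hemisphere"],
                label=entry["label"],
                votes=entry["votes"],
                provenance=entry.get("provenance", []),
            )
        )
    return Atlas(bundles=bundles, space=manifest["space"], provenance=manifest["provenance"])
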