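"""Cortical-parcellation-based connection detection and bundle naming.

Short association bundles connect two cortical regions (possibly two spots
of the same gyrus).  Each centroid is oversampled and its extremities probed
against an integer parcellation volume (Desikan-Killiany gyral ROIs) to find
the unordered ROI pair it connects; per bundle, the pair claimed by the
largest fraction of fibers across subjects becomes the bundle's connection
label when that fraction reaches 50%.  Names follow the
``<ABB1>_<ABB2>_<n><x>`` scheme with ``x`` in {i, l, r} for
both-hemispheres / left-only / right-only bundles.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .atlas_builder import Bundle
from .tract_io import ParcellationVolume, resample_fiber

__all__ = [
    "DESIKAN_KILLIANY",
    "DESIKAN_KILLIANY_FULL",
    "ConnectionTally",
    "endpoint_rois",
    "main_connection",
    "name_bundles",
    "write_label_table",
    "read_label_table",
]

# Desikan-Killiany gyral ROIs with conventional short abbreviations.
# Integer labels are sequential; real FreeSurfer label volumes can be remapped
# through a user-supplied table with the same abbreviations.
DESIKAN_KILLIANY_FULL: dict[int, tuple[str, str]] = {
    1: ("B", "Bankssts"),
    2: ("CACg", "Caudal anterior cingulate"),
    3: ("CMF", "Caudal middle frontal"),
    4: ("CC", "Corpus callosum"),
    5: ("Cu", "Cuneus"),
    6: ("En", "Entorhinal"),
    7: ("Fu", "Fusiform"),
    8: ("IP", "Inferior parietal"),
    9: ("IT", "Inferior temporal"),
    10: ("IstCg", "Isthmus cingulate"),
    11: ("LO", "Lateral occipital"),
    12: ("LOrF", "Lateral orbito frontal"),
    13: ("Lg", "Lingual"),
    14: ("MOrF", "Medial orbito frontal"),
    15: ("MT", "Middle temporal"),
    16: ("PaH", "Parahippocampal"),
    17: ("PaC", "Paracentral"),
    18: ("Op", "Pars opercularis"),
    19: ("Or", "Pars orbitalis"),
    20: ("Tr", "Pars triangularis"),
    21: ("PerCa", "Pericalcarine"),
    22: ("PoC", "Postcentral"),
    23: ("PoCg", "Posterior cingulate"),
    24: ("PreC", "Precentral"),
    25: ("PreCu", "Precuneus"),
    26: ("RoACg", "Rostral anterior cingulate"),
    27: ("RoMF", "Rostral middle frontal"),
    28: ("SF", "Superior frontal"),
    29: ("SP", "Superior parietal"),
    30: ("ST", "Superior temporal"),
    31: ("SM", "Supramarginal"),
    32: ("FPol", "Frontal pole"),
    33: ("TPol", "Temporal pole"),
    34: ("TrT", "Transverse temporal"),
    35: ("Ins", "Insula"),
}

DESIKAN_KILLIANY: dict[int, str] = {k: v[0] for k, v in DESIKAN_KILLIANY_FULL.items()}

# The corpus callosum appears in the table for completeness but SWM selection
# removes CC-like fibers upstream; endpoint hits on it are legal yet notable.
FLAGGED_LABELS = frozenset({"CC"})


def write_label_table(path, table: Mapping[int, tuple[str, str]] | None = None) -> None:
    """TSV of (label, abbreviation, full name); defaults to Desikan-Killiany."""
    table = table or DESIKAN_KILLIANY_FULL
    with open(path, "w") as fh:
        fh.write("label\tabbreviation\tname\n")
        for label in sorted(table):
            abb, name = table[label]
            fh.write(f"{label}\t{abb}\t{name}\n")


def read_label_table(path) -> dict[int, str]:
    out: dict[int, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("label"):
            raise ValueError("label table must start with a header line")
        for line in fh:
            if not line.strip():
                continue
            label, abb = line.split("\t")[:2]
            out[int(label)] = abb
    return out


def endpoint_rois(
    f: np.ndarray,
    pv: ParcellationVolume,
    oversample_factor: int = 10,
    probe_depth: int = 3,
) -> tuple[int, int] | None:
    """Unordered ROI label pair connected by a fiber, or None if undetermined.

    The fiber is oversampled so extremity points cannot skip over thin
    cortical ribbon voxels; from each end, up to ``probe_depth`` oversampled
    points are scanned inward for the first non-zero label.  An end that
    finds none (background or outside the volume) makes the pair
    undetermined.
    """
    n_dense = max(2, f.shape[0] * oversample_factor)
    dense = resample_fiber(f, n_dense)
    probe = min(probe_depth, n_dense)
    head = pv.lookup_mm(dense[:probe])
    tail = pv.lookup_mm(dense[-probe:][::-1])
    first = next((int(x) for x in head if x != 0), 0)
    last = next((int(x) for x in tail if x != 0), 0)
    if first == 0 or last == 0:
        return None
    return (first, last) if first <= last else (last, first)


@dataclass
class ConnectionTally:
    """Per ROI-pair fiber counts/fractions and subject counts for one bundle.

    Fractions are computed over the fibers whose endpoint pair could be
    determined (``strict=False``); in strict mode undetermined fibers stay in
    the denominator and count against every pair.
    """

    counts: dict[tuple[int, int], int]
    subject_counts: dict[tuple[int, int], int]
    n_determined: int
    n_fibers: int
    strict: bool = False

    def fractions(self) -> dict[tuple[int, int], float]:
        denom = self.n_fibers if self.strict else self.n_determined
        if denom == 0:
            return {}
        return {pair: c / denom for pair, c in self.counts.items()}


def tally_connections(
    b: Bundle,
    parcellations: Mapping[str, ParcellationVolume],
    oversample_factor: int = 10,
    probe_depth: int = 3,
    strict: bool = False,
) -> ConnectionTally:
    """Count the ROI pair connected by every fiber of a bundle, per subject."""
    counts: Counter = Counter()
    subjects_by_pair: defaultdict[tuple[int, int], set[str]] = defaultdict(set)
    n_det = 0
    for subject, fiber in b.fibers:
        if subject not in parcellations:
            raise KeyError(f"no parcellation for subject {subject!r}")
        pair = endpoint_rois(
            fiber, parcellations[subject], oversample_factor, probe_depth
        )
        if pair is None:
            continue
        n_det += 1
        counts[pair] += 1
        subjects_by_pair[pair].add(subject)
    return ConnectionTally(
        counts=dict(counts),
        subject_counts={p: len(s) for p, s in subjects_by_pair.items()},
        n_determined=n_det,
        n_fibers=len(b.fibers),
        strict=strict,
    )


def main_connection(
    b: Bundle,
    parcellations: Mapping[str, ParcellationVolume],
    min_fiber_frac: float = 0.5,
    oversample_factor: int = 10,
    probe_depth: int = 3,
    strict: bool = False,
) -> tuple[int, int] | None:
    """The bundle's dominant ROI pair, or None when no pair is stable enough.

    Returns the pair with maximal fiber fraction provided that fraction is at
    least ``min_fiber_frac``; bundles failing this are dropped from the
    labeled atlas.  Ties break on (count, subject count, pair) for
    determinism.
    """
    tally = tally_connections(b, parcellations, oversample_factor, probe_depth, strict)
    fracs = tally.fractions()
    if not fracs:
        return None
    best = max(
        fracs,
        key=lambda p: (fracs[p], tally.subject_counts.get(p, 0), (-p[0], -p[1])),
    )
    if fracs[best] >= min_fiber_frac:
        return best
    return None


def name_bundles(
    labeled: list[tuple[tuple[int, int], str, int]],
    label_table: Mapping[int, str] | None = None,
) -> list[str]:
    """Generate ``<ABB1>_<ABB2>_<n><x>`` names for labeled bundles.

    Input tuples are ``(roi_pair, presence, size)`` where ``presence`` is one
    of "i" (both hemispheres), "l", "r", and ``size`` the bundle fiber count.
    Abbreviations are sorted within the pair; the per-pair index ``n`` starts
    at 0 and is assigned in descending size order (ties by input order), so
    the mapping is deterministic and injective.
    """
    table = label_table or DESIKAN_KILLIANY
    for (r1, r2), presence, _ in labeled:
        for r in (r1, r2):
            if r not in table:
                raise KeyError(f"unknown ROI label {r}")
        if presence not in ("i", "l", "r"):
            raise ValueError(f"presence must be i/l/r, got {presence!r}")
    order = sorted(range(len(labeled)), key=lambda k: (-labeled[k][2], k))
    next_index: Counter = Counter()
    names: dict[int, str] = {}
    for k in order:
        (r1, r2), presence, _ = labeled[k]
        abb1, abb2 = sorted((table[r1], table[r2]))
        n = next_index[(r1, r2)]
        next_index[(r1, r2)] += 1
        names[k] = f"{abb1}_{abb2}_{n}{presence}"
    return [names[k] for k in range(len(labeled))]
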