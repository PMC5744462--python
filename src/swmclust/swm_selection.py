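"""Selection of short-fiber centroids and removal of deep-white-matter lookalikes.

Short association (U-shaped) fibers are isolated in two steps: a length
window (35-85 mm by default, inclusive) applied to the native polyline
lengths, then removal of any centroid that comes within a restrictive d_ME
of a reference set of deep-white-matter (DWM) bundles — arcuate segments,
uncinate, cingulum portions, fornix, thalamic radiations, hemisphere-cut
corpus callosum, or whatever reference the caller supplies.  Only a random
sample (20% by default) of the reference fibers is used, which is safe
because DWM bundles are dense and stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fiber_metrics import pairwise_d_me
from .tract_io import CentroidSet, resample_fiber

__all__ = ["DwmReference", "length_filter", "dwm_filter"]


@dataclass
class DwmReference:
    """Named deep-white-matter bundle fiber sets used as an exclusion filter."""

    bundles: Mapping[str, Sequence[np.ndarray]]
    sample_fraction: float = 0.2
    seed: int = 0
    n_points: int = 51

    def __post_init__(self) -> None:
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")
        self.bundles = {
            name: [resample_fiber(np.asarray(f, dtype=np.float64), self.n_points) for f in fibers]
            for name, fibers in self.bundles.items()
        }

    def sampled_fibers(self) -> list[np.ndarray]:
        """Per-bundle uniform sample without replacement, reproducible from seed.

        With ``sample_fraction`` = 1 every fiber is returned (seed-independent).
        """
        rng = np.random.default_rng(self.seed)
        out: list[np.ndarray] = []
        for name in sorted(self.bundles):
            fibers = self.bundles[name]
            if self.sample_fraction >= 1.0:
                out.extend(fibers)
                continue
            k = max(1, int(round(self.sample_fraction * len(fibers))))
            idx = np.sort(rng.choice(len(fibers), size=k, replace=False))
            out.extend(fibers[i] for i in idx)
        return out


def length_filter(
    cs: CentroidSet, min_mm: float = 35.0, max_mm: float = 85.0
) -> CentroidSet:
    """Keep fibers whose native length lies in [min_mm, max_mm] (inclusive)."""
    keep = np.nonzero((cs.lengths >= min_mm) & (cs.lengths <= max_mm))[0]
    return cs.subset(keep)


def dwm_filter(
    cs: CentroidSet, ref: DwmReference, threshold_mm: float = 10.0
) -> CentroidSet:
    """Discard centroids within ``threshold_mm`` (strict) of any DWM sample fiber.

    The reference sample is drawn once per call from the reference's seed.
    An empty reference passes everything through with a warning.
    """
    sample = ref.sampled_fibers()
    if not sample:
        warnings.warn("empty DWM reference: no centroids discarded", stacklevel=2)
        return cs.subset(range(len(cs)))
    if len(cs) == 0:
        return cs.subset([])
    fibers = [resample_fiber(f, ref.n_points) for f in cs.fibers]
    min_d = pairwise_d_me(fibers, sample).min(axis=1)
    keep = np.nonzero(min_d >= threshold_mm)[0]
    return cs.subset(keep)
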