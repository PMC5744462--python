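"""Streamline and label-volume I/O, fiber resampling, and spatial transforms.

Fibers are plain ``(n_points, 3)`` float64 arrays of world (mm) coordinates,
the same convention nibabel's streamline API uses.  A :class:`CentroidSet`
groups the fibers of one subject together with the metadata every
intersubject operation needs (hemisphere, space, per-fiber native length).
Voxel indices never leave :class:`ParcellationVolume`: every public function
speaks millimetres.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "CentroidSet",
    "ParcellationVolume",
    "Transform",
    "TractogramParseError",
    "read_tractogram",
    "write_tractogram",
    "resample_fiber",
    "fiber_length",
    "apply_transform",
    "reflect_hemisphere",
    "clip_at_plane",
]

log = logging.getLogger(__name__)

HEMISPHERES = ("left", "right")
SPACES = ("native", "talairach", "template")

DEFAULT_N_POINTS = 51


class TractogramParseError(ValueError):
    """Raised when a streamline file cannot be parsed."""


def _as_fiber(points: Iterable) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"fiber must be (n, 3), got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("fiber contains non-finite coordinates")
    return pts


def fiber_length(f: np.ndarray) -> float:
    """Polyline length in mm: sum of consecutive Euclidean segment lengths."""
    pts = np.asarray(f, dtype=np.float64)
    if pts.shape[0] < 2:
        raise ValueError("fiber needs at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def resample_fiber(f: np.ndarray, n: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Resample a polyline to ``n`` points equidistant along its arc length.

    The parameterization is by cumulative chord length; endpoints are
    preserved exactly.  Degenerate fibers (all points identical) raise.
    """
    pts = _as_fiber(f)
    if n < 2:
        raise ValueError("n must be >= 2")
    if pts.shape[0] < 2:
        raise ValueError("fiber needs at least 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 0.0:
        raise ValueError("degenerate fiber: all points identical")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, total, n)
    out = np.empty((n, 3), dtype=np.float64)
    for k in range(3):
        out[:, k] = np.interp(target, s, pts[:, k])
    out[0], out[-1] = pts[0], pts[-1]
    return out


@dataclass
class CentroidSet:
    """A subject's collection of fiber centroids with space metadata.

    ``lengths`` are the native (pre-resampling) polyline lengths in mm; they
    are computed from the geometry at construction when not supplied, and are
    carried through resampling so length-based selection always refers to the
    original geometry.
    """

    subject_id: str
    fibers: list[np.ndarray] = field(default_factory=list)
    hemisphere: str | None = None
    space: str = "native"
    lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.hemisphere is not None and self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        if self.space not in SPACES:
            raise ValueError(f"space must be one of {SPACES}")
        self.fibers = [_as_fiber(f) for f in self.fibers]
        if self.lengths is None:
            self.lengths = np.array(
                [fiber_length(f) if len(f) >= 2 else 0.0 for f in self.fibers]
            )
        else:
            self.lengths = np.asarray(self.lengths, dtype=np.float64)
            if len(self.lengths) != len(self.fibers):
                raise ValueError("lengths and fibers disagree in count")

    def __len__(self) -> int:
        return len(self.fibers)

    @property
    def n_points(self) -> int | None:
        counts = {f.shape[0] for f in self.fibers}
        return counts.pop() if len(counts) == 1 else None

    def resampled(self, n: int = DEFAULT_N_POINTS) -> "CentroidSet":
        """Return a copy with every fiber resampled to ``n`` points.

        Native lengths are preserved as metadata.
        """
        return replace(
            self,
            fibers=[resample_fiber(f, n) for f in self.fibers],
            lengths=self.lengths.copy(),
        )

    def subset(self, indices: Sequence[int]) -> "CentroidSet":
        idx = list(indices)
        return replace(
            self,
            fibers=[self.fibers[i] for i in idx],
            lengths=self.lengths[idx],
        )


@dataclass
class ParcellationVolume:
    """Integer label image with its voxel→mm affine and a label table.

    Label 0 is background.  ``label_table`` maps each non-zero integer label
    to an ROI abbreviation (Desikan–Killiany style).
    """

    labels: np.ndarray
    voxel_to_mm: np.ndarray
    label_table: Mapping[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        self.voxel_to_mm = np.asarray(self.voxel_to_mm, dtype=np.float64)
        if self.voxel_to_mm.shape != (4, 4):
            raise ValueError("voxel_to_mm must be 4x4")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"labels missing from label_table: {sorted(missing)}")

    def lookup_mm(self, points_mm: np.ndarray) -> np.ndarray:
        """Nearest-voxel label lookup for mm points; out-of-volume -> 0."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=np.float64))
        inv = np.linalg.inv(self.voxel_to_mm)
        vox = (pts @ inv[:3, :3].T) + inv[:3, 3]
        idx = np.rint(vox).astype(int)
        out = np.zeros(len(idx), dtype=self.labels.dtype)
        inside = np.all((idx >= 0) & (idx < np.array(self.labels.shape)), axis=1)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    @classmethod
    def from_nifti(cls, path, label_table: Mapping[int, str]) -> "ParcellationVolume":
        img = nib.load(str(path))
        return cls(
            labels=np.asarray(img.dataobj).astype(np.int32),
            voxel_to_mm=img.affine,
            label_table=label_table,
        )

    def to_nifti(self, path) -> None:
        nib.save(
            nib.Nifti1Image(self.labels.astype(np.int16), self.voxel_to_mm),
            str(path),
        )


@dataclass
class Transform:
    """Affine (optionally composed with a displacement field) in mm.

    The point map is ``p -> M p (+ field(M p))`` where the field stores mm
    displacements on its own voxel grid and is interpolated trilinearly.
    Points outside the field domain receive the nearest in-field voxel's
    displacement (a warning is logged once per call).
    """

    matrix: np.ndarray
    field: np.ndarray | None = None
    field_voxel_to_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4, 4):
            raise ValueError("matrix must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("singular affine matrix")
        if self.field is not None:
            self.field = np.asarray(self.field, dtype=np.float64)
            if self.field.ndim != 4 or self.field.shape[3] != 3:
                raise ValueError("field must be (i, j, k, 3)")
            if self.field_voxel_to_mm is None:
                raise ValueError("field requires field_voxel_to_mm")
            self.field_voxel_to_mm = np.asarray(
                self.field_voxel_to_mm, dtype=np.float64
            )

    @property
    def kind(self) -> str:
        return "affine" if self.field is None else "affine+field"

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        moved = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        if self.field is None:
            return moved
        inv = np.linalg.inv(self.field_voxel_to_mm)
        vox = moved @ inv[:3, :3].T + inv[:3, 3]
        shape = np.array(self.field.shape[:3])
        outside = np.any((vox < 0) | (vox > shape - 1), axis=1)
        if outside.any():
            log.warning(
                "%d point(s) outside displacement field; using nearest-edge "
                "displacement",
                int(outside.sum()),
            )
        disp = np.stack(
            [
                map_coordinates(self.field[..., k], vox.T, order=1, mode="nearest")
                for k in range(3)
            ],
            axis=1,
        )
        return moved + disp

    @classmethod
    def from_text(cls, path) -> "Transform":
        """Read a 4x4 affine stored as whitespace-separated text."""
        mat = np.loadtxt(str(path))
        return cls(matrix=mat.reshape(4, 4))


def apply_transform(cs: CentroidSet, t: Transform, space: str | None = None) -> CentroidSet:
    """Transform every fiber point; topology and fiber order are unchanged.

    ``space`` optionally updates the set's space tag (e.g. "talairach").
    """
    fibers = [t.apply_points(f) for f in cs.fibers]
    return replace(cs, fibers=fibers, space=space or cs.space, lengths=cs.lengths.copy())


def reflect_hemisphere(cs: CentroidSet, plane_x: float = 0.0) -> CentroidSet:
    """Mirror a set across the midsagittal plane x = ``plane_x``.

    x maps to ``2*plane_x - x``; y and z are untouched; the hemisphere tag is
    flipped.  The reflection is an isometry and an involution.
    """
    if cs.space == "native":
        raise ValueError("reflection requires a midsagittally aligned space")
    fibers = []
    for f in cs.fibers:
        g = f.copy()
        g[:, 0] = 2.0 * plane_x - g[:, 0]
        fibers.append(g)
    hemi = None
    if cs.hemisphere is not None:
        hemi = "right" if cs.hemisphere == "left" else "left"
    return replace(cs, fibers=fibers, hemisphere=hemi, lengths=cs.lengths.copy())


def clip_at_plane(fibers: Sequence[np.ndarray], plane_x: float = 0.0, keep: str = "left") -> list[np.ndarray]:
    """Keep each fiber's points on one side of the plane x = ``plane_x``.

    Generic utility (e.g. for splitting an interhemispheric reference bundle);
    fibers left with fewer than 2 points on the kept side are dropped.
    """
    out = []
    for f in fibers:
        mask = f[:, 0] <= plane_x if keep == "left" else f[:, 0] >= plane_x
        if mask.sum() >= 2:
            out.append(f[mask])
    return out


# --------------------------------------------------------------------------
# File formats


def _format_of(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("trk", "tck", "txt"):
        return suffix
    raise ValueError(f"cannot infer streamline format from {path.name!r}")


def _read_txt(path: Path) -> list[np.ndarray]:
    """Plain-text polyline dialect: one fiber per block of "x y z" lines,
    blocks separated by blank lines."""
    fibers: list[np.ndarray] = []
    block: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                if block:
                    fibers.append(np.asarray(block, dtype=np.float64))
                    block = []
                continue
            parts = line.split()
            if len(parts) != 3:
                raise TractogramParseError(
                    f"{path}:{lineno}: expected 3 coordinates, got {len(parts)}"
                )
            try:
                block.append([float(p) for p in parts])
            except ValueError as exc:
                raise TractogramParseError(f"{path}:{lineno}: {exc}") from exc
    if block:
        fibers.append(np.asarray(block, dtype=np.float64))
    return fibers


def _write_txt(path: Path, fibers: Sequence[np.ndarray]) -> None:
    with open(path, "w") as fh:
        for i, f in enumerate(fibers):
            if i:
                fh.write("\n")
            for x, y, z in f:
                fh.write(f"{x:.8f} {y:.8f} {z:.8f}\n")


def read_tractogram(
    path,
    format: str | None = None,
    subject_id: str = "",
    hemisphere: str | None = None,
    space: str = "native",
) -> CentroidSet:
    """Read a streamline file (TRK, TCK, or the txt dialect) into mm space.

    Returns an empty :class:`CentroidSet` with a warning for an empty file;
    malformed content raises :class:`TractogramParseError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _format_of(path, format)
    if fmt == "txt":
        fibers = _read_txt(path)
    elif fmt in ("trk", "tck"):
        try:
            tractogram_file = nib.streamlines.load(str(path))
        except Exception as exc:  # nibabel raises format-specific errors
            raise TractogramParseError(f"{path}: {exc}") from exc
        fibers = [np.asarray(s, dtype=np.float64) for s in tractogram_file.streamlines]
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not fibers:
        warnings.warn(f"{path}: empty streamline file", stacklevel=2)
    return CentroidSet(
        subject_id=subject_id, fibers=fibers, hemisphere=hemisphere, space=space
    )


def write_tractogram(cs: CentroidSet, path, format: str | None = None) -> None:
    """Write a CentroidSet's fibers in TRK, TCK, or txt form (mm, RAS)."""
    path = Path(path)
    fmt = _format_of(path, format)
    if fmt == "txt":
        _write_txt(path, cs.fibers)
        return
    tractogram = nib.streamlines.Tractogram(cs.fibers, affine_to_rasmm=np.eye(4))
    if fmt == "trk":
        nib.streamlines.save(tractogram, str(path))
    elif fmt == "tck":
        nib.streamlines.save(tractogram, str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")
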