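"""From foreground masks to discrete cilium objects.

Connected cilia voxels are merged into objects by component labeling with
two variants: "straight" filling (6-connectivity in 3D, 4 in 2D) or
"straight_diagonal" filling (26-connectivity, 8 in 2D).  The diagonal
variant better retrieves incompletely labeled cilia but may merge
adjacent ones in dense fields.  Objects are then filtered by a minimum
voxel count, optionally discarded when touching image borders, and — for
time series — linked across frames by a 4D extension of the same flood
fill (spatially connected or coincident voxels in consecutive frames
belong to one object).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preparator import VoxelMask

__all__ = [
    "CiliumObject",
    "label_objects",
    "filter_small",
    "exclude_border",
    "link_time",
    "clean_intensity_channel",
    "objects_to_mask",
]

_VARIANTS = ("straight", "straight_diagonal")


@dataclass
class CiliumObject:
    """One labeled connected component; the unit of quantification.

    ``voxels`` maps timepoint -> integer array of (z, y, x) indices.
    """

    id: int
    voxels: dict[int, np.ndarray]
    shape: tuple[int, int, int, int]  # (t, z, y, x) of the source mask
    touches_border: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.voxels or all(v.shape[0] == 0 for v in self.voxels.values()):
            raise ValueError("cilium object must contain at least one voxel")
        if not self.touches_border:
            self.touches_border = self._border_flags()

    def _border_flags(self) -> dict[str, bool]:
        _, nz, ny, nx = self.shape
        flags = {"x": False, "y": False, "z": False}
        for vox in self.voxels.values():
            if vox.shape[0] == 0:
                continue
            z, y, x = vox[:, 0], vox[:, 1], vox[:, 2]
            flags["x"] |= bool((x == 0).any() or (x == nx - 1).any())
            flags["y"] |= bool((y == 0).any() or (y == ny - 1).any())
            if nz > 1:
                flags["z"] |= bool((z == 0).any() or (z == nz - 1).any())
        return flags

    @property
    def n_voxels(self) -> int:
        return int(sum(v.shape[0] for v in self.voxels.values()))

    @property
    def timepoints(self) -> list[int]:
        return sorted(self.voxels)

    def voxels_at(self, t: int) -> np.ndarray:
        return self.voxels[t]


def _structure_3d(variant: str) -> np.ndarray:
    if variant == "straight":
        return ndimage.generate_binary_structure(3, 1)
    if variant == "straight_diagonal":
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"unknown flood-fill variant {variant!r}; use one of {_VARIANTS}")


def _first_voxel_order(labels: np.ndarray, n: int) -> list[int]:
    """Label ids sorted by raster-scan position of each label's first voxel."""
    flat = labels.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier positions overwrite later ones
    first[flat[nz[::-1]]] = nz[::-1]
    order = sorted(range(1, n + 1), key=lambda lbl: first[lbl])
    return order


def label_objects(mask: VoxelMask, variant: str = "straight_diagonal") -> list[CiliumObject]:
    """Label connected foreground components per timepoint.

    Ids are assigned by raster-scan order of each object's first voxel
    (frames scanned in order), so output ordering is reproducible.
    """
    structure = _structure_3d(variant)
    objects: list[CiliumObject] = []
    next_id = 1
    shape = mask.mask.shape
    for t in range(shape[0]):
        labels, n = ndimage.label(mask.mask[t], structure=structure)
        if n == 0:
            continue
        coords_by_label: dict[int, np.ndarray] = {}
        zz, yy, xx = np.nonzero(labels)
        lbls = labels[zz, yy, xx]
        order = np.argsort(lbls, kind="stable")
        zz, yy, xx, lbls = zz[order], yy[order], xx[order], lbls[order]
        starts = np.searchsorted(lbls, np.arange(1, n + 2))
        for lbl in range(1, n + 1):
            s, e = starts[lbl - 1], starts[lbl]
            coords_by_label[lbl] = np.column_stack([zz[s:e], yy[s:e], xx[s:e]])
        for lbl in _first_voxel_order(labels, n):
            objects.append(
                CiliumObject(id=next_id, voxels={t: coords_by_label[lbl]}, shape=shape)
            )
            next_id += 1
    return objects


def filter_small(objects: list[CiliumObject], min_voxels: int) -> list[CiliumObject]:
    """Drop objects with fewer voxels than the size threshold (>= kept)."""
    if min_voxels < 0:
        raise ValueError("min_voxels must be >= 0")
    return [o for o in objects if o.n_voxels >= min_voxels]


def exclude_border(
    objects: list[CiliumObject], axes: set[str] | tuple[str, ...] = ("x", "y", "z")
) -> tuple[list[CiliumObject], int]:
    """Remove objects touching the image border along any listed axis.

    The z test is skipped for single-slice images.  Returns the surviving
    objects and the number excluded.
    """
    axes = set(axes)
    kept = [o for o in objects if not any(o.touches_border.get(ax, False) for ax in axes)]
    return kept, len(objects) - len(kept)


def link_time(mask: VoxelMask, variant: str = "straight_diagonal") -> list[CiliumObject]:
    """Label objects in 4D: spatial flood fill extended across frames.

    Voxels in consecutive frames belong to the same object when they
    coincide or are spatially connected under the chosen variant
    (temporal moves are restricted to dt = ±1).  Each resulting object
    stores its voxels grouped by timepoint.
    """
    s3 = _structure_3d(variant)
    structure4 = np.zeros((3, 3, 3, 3), dtype=bool)
    center = s3.copy()
    center[1, 1, 1] = True
    for dt in range(3):
        structure4[dt] = center
    labels, n = ndimage.label(mask.mask, structure=structure4)
    if n == 0:
        return []
    shape = mask.mask.shape
    tt, zz, yy, xx = np.nonzero(labels)
    lbls = labels[tt, zz, yy, xx]
    order = np.argsort(lbls, kind="stable")
    tt, zz, yy, xx, lbls = tt[order], zz[order], yy[order], xx[order], lbls[order]
    starts = np.searchsorted(lbls, np.arange(1, n + 2))
    objects = []
    for next_id, lbl in enumerate(_first_voxel_order(labels, n), start=1):
        s, e = starts[lbl - 1], starts[lbl]
        voxels: dict[int, np.ndarray] = {}
        ts = tt[s:e]
        coords = np.column_stack([zz[s:e], yy[s:e], xx[s:e]])
        for t in np.unique(ts):
            voxels[int(t)] = coords[ts == t]
        objects.append(CiliumObject(id=next_id, voxels=voxels, shape=shape))
    return objects


def clean_intensity_channel(
    mask: VoxelMask, min_voxels: int, variant: str = "straight_diagonal"
) -> VoxelMask:
    """Zero connected regions smaller than ``min_voxels`` in an intensity
    channel's mask (speckle removal for the A/B channels)."""
    if min_voxels <= 1:
        return VoxelMask(mask=mask.mask.copy(), source_channel=mask.source_channel)
    structure = _structure_3d(variant)
    out = np.zeros_like(mask.mask)
    for t in range(mask.mask.shape[0]):
        labels, n = ndimage.label(mask.mask[t], structure=structure)
        if n == 0:
            continue
        counts = np.bincount(labels.ravel(), minlength=n + 1)
        keep = counts >= min_voxels
        keep[0] = False
        out[t] = keep[labels]
    return VoxelMask(mask=out, source_channel=mask.source_channel)


def objects_to_mask(
    objects: list[CiliumObject], shape: tuple[int, int, int, int]
) -> VoxelMask:
    """Render a list of objects back into a boolean (t, z, y, x) mask."""
    out = np.zeros(shape, dtype=bool)
    for o in objects:
        for t, vox in o.voxels.items():
            out[t, vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return VoxelMask(mask=out)
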