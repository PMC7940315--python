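"""Per-cilium morphometric and intensity parameters.

Every parameter is computed from the cilium's voxel set, the intensity
channels, and/or its centerline:

* morphology — centre of mass, voxel/metric volume, exposed-face surface
  area, shape complexity index (surface relative to the surface of the
  equal-volume sphere; 1 = perfect sphere), equal-volume sphere radius;
* voxel intensity statistics — min/max/mean/SD (population) and the mean
  of the brightest 10% of voxels, per channel;
* colocalization — ciliary volume that is nonzero in another segmented
  channel, and ciliary volume/centerline length whose intensity exceeds a
  soma-derived background threshold (25-cuboid rule: the image is split
  into a 5×5 grid of cuboids spanning z, the brightest 10% of non-cilium
  voxels are pooled from each, and the threshold is their mean + 1.5·SD);
* centerline measures — arc ("cilia") length, base→tip orientation
  vector, bending index (arc length / chord; 1 = straight), intensity
  profiles interpolated bilinearly in the nearest slice and resampled at
  voxel-width steps, unit tangent vectors and signed curvature along the
  path.

The curvature at a point is computed from the normalized tangents T1, T2
at the points one tangent-window upstream (P1) and downstream (P2) as
|T2 − T1| / 2 / (arc distance P1→P2), signed by the z-component of
T1 × T2.  For an in-plane curve this recovers the familiar 2D signed
curvature convention; note that the /2/ divisor makes the value converge
to half the geometric curvature 1/R on a circle (see docs/methods.md).
"""

from __future__ import annotations

import math

import numpy as np

from .image import CalibratedImage
from .reconstruct import CiliumObject
from .skeleton import CenterlinePath

__all__ = [
    "shape_complexity_index",
    "sphere_radius",
    "morphology_params",
    "intensity_params",
    "background_threshold",
    "colocalized_volume",
    "colocalized_vs_bg_volume",
    "profile",
    "resample_profile",
    "centerline_intensity",
    "colocalized_vs_bg_length",
    "orientation_and_bending",
    "tangents",
    "signed_curvature",
]


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def shape_complexity_index(surface: float, volume: float) -> float:
    """surface / (4π·((3·volume)/(4π))^(2/3)); 1 for a perfect sphere."""
    return float(surface / (4.0 * math.pi * ((3.0 * volume) / (4.0 * math.pi)) ** (2.0 / 3.0)))


def sphere_radius(volume: float) -> float:
    """Radius of the sphere containing the given volume."""
    return float((3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0))


def _exposed_faces(vox: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel count of exposed faces along each axis (6-neighborhood).

    Returns (n_exposed_per_axis (n, 3), is_surface (n,)).
    """
    voxset = set(map(tuple, vox.tolist()))
    n = vox.shape[0]
    exposed = np.zeros((n, 3), dtype=np.int64)
    for i, (z, y, x) in enumerate(vox.tolist()):
        exposed[i, 0] = (1 if (z - 1, y, x) not in voxset else 0) + (
            1 if (z + 1, y, x) not in voxset else 0
        )
        exposed[i, 1] = (1 if (z, y - 1, x) not in voxset else 0) + (
            1 if (z, y + 1, x) not in voxset else 0
        )
        exposed[i, 2] = (1 if (z, y, x - 1) not in voxset else 0) + (
            1 if (z, y, x + 1) not in voxset else 0
        )
    return exposed, exposed.sum(axis=1) > 0


def morphology_params(cilium: CiliumObject, image: CalibratedImage, timepoint: int) -> dict:
    """Centre, volume, surface, shape complexity and sphere radius.

    The centre is the mean voxel-centre position in µm.  The surface is
    the sum of voxel face areas with no ciliary neighbor across them
    (face areas w·h, w·d, h·d).  For single-slice (2D) images the volume
    numerics carry area semantics and the sphere-based descriptors are
    reported as None.
    """
    vox = cilium.voxels_at(timepoint)
    w, h, d = image.voxel_width, image.voxel_height, image.voxel_depth
    centers = (vox[:, ::-1] + 0.5) * np.array([w, h, d])  # (x, y, z) µm
    center = centers.mean(axis=0)
    n = vox.shape[0]
    is_2d = image.nz == 1
    volume = n * image.voxel_volume
    exposed, is_surface = _exposed_faces(vox)
    face_areas = np.array([w * h, w * d, h * d])  # normal to z, y, x
    surface = float((exposed * face_areas).sum())
    out = {
        "center_um": center,
        "n_voxels": n,
        "volume_um3": volume,
        "n_surface_voxels": int(is_surface.sum()),
        "surface_um2": surface,
        "shape_complexity_index": None if is_2d else shape_complexity_index(surface, volume),
        "sphere_radius_um": None if is_2d else sphere_radius(volume),
    }
    return out


# ---------------------------------------------------------------------------
# voxel intensities
# ---------------------------------------------------------------------------

def intensity_params(values: np.ndarray) -> dict:
    """min/max/mean/SD and top-10% mean over a cilium's voxel intensities.

    The top-10% set holds the ⌈0.1·N⌉ (at least 1) brightest voxels; the
    SD is the population standard deviation.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    n = values.size
    k = max(1, math.ceil(0.1 * n))
    top = np.sort(values)[-k:]
    return {
        "min": float(values.min()),
        "max": float(values.max()),
        "mean": float(values.mean()),
        "sd": float(values.std()),
        "top10_mean": float(top.mean()),
    }


def _cilium_values(cilium: CiliumObject, channel: np.ndarray, timepoint: int) -> np.ndarray:
    vox = cilium.voxels_at(timepoint)
    return channel[timepoint, vox[:, 0], vox[:, 1], vox[:, 2]]


# ---------------------------------------------------------------------------
# background (soma) threshold and colocalization
# ---------------------------------------------------------------------------

def background_threshold(
    channel: np.ndarray, all_cilia_mask: np.ndarray, timepoint: int = 0
) -> float | None:
    """Soma-intensity threshold from the 25-cuboid rule.

    The frame is divided into a 5×5 (y, x) grid of cuboids spanning all
    z (remainder rows/columns absorbed by the last cuboid).  From each
    cuboid the brightest ⌈10%⌉ (at least 1) voxels *outside* any cilium
    are collected; the threshold is mean + 1.5·SD (population) of the
    pooled collection.  Returns None when no non-cilium voxel exists.
    """
    frame = np.asarray(channel[timepoint], dtype=np.float64)
    outside = ~np.asarray(all_cilia_mask[timepoint], dtype=bool)
    _, ny, nx = frame.shape
    if ny < 5 or nx < 5:
        raise ValueError("image must be larger than 5x5 pixels in y, x")
    y_edges = [(i * (ny // 5), (i + 1) * (ny // 5) if i < 4 else ny) for i in range(5)]
    x_edges = [(j * (nx // 5), (j + 1) * (nx // 5) if j < 4 else nx) for j in range(5)]
    collected = []
    for y0, y1 in y_edges:
        for x0, x1 in x_edges:
            vals = frame[:, y0:y1, x0:x1][outside[:, y0:y1, x0:x1]]
            if vals.size == 0:
                continue
            k = max(1, math.ceil(0.1 * vals.size))
            collected.append(np.sort(vals)[-k:])
    if not collected:
        return None
    pooled = np.concatenate(collected)
    return float(pooled.mean() + 1.5 * pooled.std())


def colocalized_volume(
    cilium: CiliumObject, segmented_channel: np.ndarray, timepoint: int, voxel_volume: float
) -> tuple[float, float]:
    """Ciliary volume that is nonzero in another (segmented) channel.

    Returns (µm³, % of the cilium volume).
    """
    vals = _cilium_values(cilium, segmented_channel, timepoint)
    n_coloc = int((vals != 0).sum())
    return n_coloc * voxel_volume, 100.0 * n_coloc / vals.size


def colocalized_vs_bg_volume(
    cilium: CiliumObject,
    channel: np.ndarray,
    threshold: float,
    timepoint: int,
    voxel_volume: float,
) -> tuple[float, float]:
    """Ciliary volume with intensity strictly above the soma threshold."""
    vals = _cilium_values(cilium, channel, timepoint)
    n_above = int((vals > threshold).sum())
    return n_above * voxel_volume, 100.0 * n_above / vals.size


# ---------------------------------------------------------------------------
# centerline profiles
# ---------------------------------------------------------------------------

def profile(
    path: CenterlinePath, channel: np.ndarray, image: CalibratedImage, timepoint: int
) -> np.ndarray:
    """Raw intensity profile along the centerline.

    Each path point is assigned the z-slice whose centre is nearest and
    the intensity is interpolated bilinearly among the 4 surrounding
    pixel centres of that slice; points outside the image are clamped.
    """
    frame = np.asarray(channel[timepoint], dtype=np.float64)
    nz, ny, nx = frame.shape
    out = np.empty(path.n_points)
    for i, (x, y, z) in enumerate(path.points):
        zi = int(np.clip(round(z / image.voxel_depth - 0.5), 0, nz - 1))
        fx = np.clip(x / image.voxel_width - 0.5, 0, nx - 1)
        fy = np.clip(y / image.voxel_height - 0.5, 0, ny - 1)
        x0, y0 = int(math.floor(fx)), int(math.floor(fy))
        x1, y1 = min(x0 + 1, nx - 1), min(y0 + 1, ny - 1)
        wx, wy = fx - x0, fy - y0
        out[i] = (
            frame[zi, y0, x0] * (1 - wx) * (1 - wy)
            + frame[zi, y0, x1] * wx * (1 - wy)
            + frame[zi, y1, x0] * (1 - wx) * wy
            + frame[zi, y1, x1] * wx * wy
        )
    return out


def resample_profile(
    raw: np.ndarray, arc_length: np.ndarray, voxel_width: float
) -> np.ndarray:
    """Rescale a raw profile to steps of one voxel width.

    Points are binned by arc length into consecutive voxel-width
    intervals and averaged per bin; empty interior bins are filled by
    linear interpolation.
    """
    raw = np.asarray(raw, dtype=np.float64)
    arc = np.asarray(arc_length, dtype=np.float64)
    total = arc[-1]
    n_bins = max(1, math.ceil(total / voxel_width)) if total > 0 else 1
    idx = np.minimum((arc / voxel_width).astype(int), n_bins - 1)
    sums = np.bincount(idx, weights=raw, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    out = np.full(n_bins, np.nan)
    nzb = counts > 0
    out[nzb] = sums[nzb] / counts[nzb]
    if (~nzb).any():
        filled = np.flatnonzero(nzb)
        out = np.interp(np.arange(n_bins), filled, out[filled])
    return out


def centerline_intensity(raw: np.ndarray) -> tuple[float, float]:
    """(integrated, mean) intensity over the raw per-point profile."""
    raw = np.asarray(raw, dtype=np.float64)
    return float(raw.sum()), float(raw.mean())


def colocalized_vs_bg_length(
    raw: np.ndarray, arc_length: np.ndarray, threshold: float
) -> tuple[float, float]:
    """Centerline length with intensity strictly above the soma threshold.

    Each profile point owns the arc segment to its successor (the last
    point owns none).  Returns (µm, % of the total arc length).
    """
    raw = np.asarray(raw, dtype=np.float64)
    arc = np.asarray(arc_length, dtype=np.float64)
    total = arc[-1]
    if raw.size < 2 or total == 0:
        return 0.0, 0.0
    seg = np.diff(arc)
    above = raw[:-1] > threshold
    length = float(seg[above].sum())
    return length, 100.0 * length / total


# ---------------------------------------------------------------------------
# orientation, tangents, curvature
# ---------------------------------------------------------------------------

def orientation_and_bending(path: CenterlinePath) -> tuple[np.ndarray, float]:
    """Base→tip orientation vector (µm) and the bending index.

    bending = arc length / |base→tip chord|; 1 for a straight cilium,
    infinity (flagged by the caller) for a closed path.
    """
    if path.n_points < 2:
        raise ValueError("path needs at least 2 points")
    vector = path.points[-1] - path.points[0]
    chord = float(np.linalg.norm(vector))
    bending = math.inf if chord == 0 else path.length / chord
    return vector, bending


def _point_at_arc(path: CenterlinePath, s: float) -> np.ndarray:
    s = float(np.clip(s, 0.0, path.arc_length[-1]))
    return np.array(
        [np.interp(s, path.arc_length, path.points[:, k]) for k in range(3)]
    )


def tangents(path: CenterlinePath, delta: float) -> np.ndarray:
    """Unit tangent per centerline point.

    The tangent at arc position s is the normalized vector from the point
    delta µm upstream to the point delta µm downstream (positions clamped
    to the path ends); coincident endpoints yield a zero vector.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    out = np.zeros((path.n_points, 3))
    for i, s in enumerate(path.arc_length):
        p_up = _point_at_arc(path, s - delta)
        p_down = _point_at_arc(path, s + delta)
        v = p_down - p_up
        norm = np.linalg.norm(v)
        if norm > 0:
            out[i] = v / norm
    return out


def signed_curvature(path: CenterlinePath, delta: float) -> np.ndarray:
    """Signed curvature per centerline point, in 1/µm.

    At arc position s, P1 and P2 are the points delta µm upstream and
    downstream, with unit tangents T1 and T2; the magnitude is
    |T2 − T1| / 2 / (arc distance P1→P2) and the sign is that of the
    z-component of T1 × T2 (positive = counter-clockwise turning in the
    xy-plane).  Window positions are clamped at the path ends, so values
    near the ends are boundary estimates.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    tans = tangents(path, delta)
    total = path.arc_length[-1]
    out = np.zeros(path.n_points)
    for i, s in enumerate(path.arc_length):
        s1 = float(np.clip(s - delta, 0.0, total))
        s2 = float(np.clip(s + delta, 0.0, total))
        if s2 <= s1:
            continue
        t1 = _tangent_at_arc(path, tans, s1)
        t2 = _tangent_at_arc(path, tans, s2)
        mag = float(np.linalg.norm(t2 - t1)) / 2.0 / (s2 - s1)
        cross_z = t1[0] * t2[1] - t1[1] * t2[0]
        sign = 1.0 if cross_z > 0 else (-1.0 if cross_z < 0 else 0.0)
        out[i] = mag * (sign if sign != 0 else 1.0) if mag > 0 else 0.0
    return out


def _tangent_at_arc(path: CenterlinePath, tans: np.ndarray, s: float) -> np.ndarray:
    """Tangent at an arbitrary arc position, interpolated between the
    per-point tangents and re-normalized."""
    v = np.array([np.interp(s, path.arc_length, tans[:, k]) for k in range(3)])
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v
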