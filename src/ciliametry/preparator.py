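"""Preprocessing and segmentation of fluorescence channels.

This stage turns the cilia-marker channel (and optionally further protein
channels) into a foreground mask.  Three segmentation families are offered:

* plain histogram thresholding (Otsu, Triangle, Renyi entropy, IsoData,
  Li, Mean, or a user-fixed value), computed either on the stack histogram
  or on the histogram of a maximum-intensity projection — the latter
  boosts the foreground fraction for sparse structures like cilia;
* 3D hysteresis thresholding (strong seeds at/above a high threshold,
  grown through voxels at/above a low threshold);
* an edge-based "Canny3D" segmenter: per-slice 2D Gaussian smoothing,
  3D Sobel gradient magnitude, 3D hysteresis on the gradient image, and
  3D hole filling.  Edge-based segmentation yields larger, closed
  reconstructions that tolerate uneven labeling along the cilium.

The foreground rule everywhere is ``intensity >= threshold``.  Histogram
methods follow the ImageJ convention of 256 bins spanning the data range,
with the resulting cut mapped back to the intensity scale.

Channels are passed as ``(t, z, y, x)`` arrays (see
:meth:`ciliametry.image.CalibratedImage.channel`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.restoration import rolling_ball

__all__ = [
    "VoxelMask",
    "ThresholdSpec",
    "Canny3DSpec",
    "THRESHOLD_METHODS",
    "subtract_background",
    "divide_by_background",
    "smooth_gaussian",
    "histogram_256",
    "auto_threshold",
    "auto_threshold_array",
    "segment_threshold",
    "segment_hysteresis",
    "segment_canny3d",
    "fill_holes_3d",
    "apply_segmentation",
    "connectivity_structure",
]

_EPS = 1e-12


@dataclass
class VoxelMask:
    """Boolean foreground map for one channel, indexed ``(t, z, y, x)``."""

    mask: np.ndarray
    source_channel: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 4:
            raise ValueError("mask must be indexed (t, z, y, x)")


@dataclass
class ThresholdSpec:
    """How to derive an intensity threshold for one channel.

    ``histogram_source`` selects whether the histogram is built from the
    full stack or from its maximum-intensity projection; ``per_timepoint``
    computes an individual threshold for every frame of a time series.
    """

    method: str = "otsu"
    custom_value: float | None = None
    histogram_source: str = "stack"  # or "max_projection"
    per_timepoint: bool = False

    def __post_init__(self) -> None:
        if self.method not in THRESHOLD_METHODS and self.method != "custom":
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.method == "custom" and (
            self.custom_value is None or not np.isfinite(self.custom_value)
        ):
            raise ValueError("custom threshold requires a finite custom_value")
        if self.histogram_source not in ("stack", "max_projection"):
            raise ValueError(f"unknown histogram_source {self.histogram_source!r}")


@dataclass
class Canny3DSpec:
    """Parameters of the edge-based segmenter."""

    gaussian_sigma: float = 1.0
    low_spec: ThresholdSpec = field(default_factory=lambda: ThresholdSpec(method="triangle"))
    high_spec: ThresholdSpec = field(default_factory=lambda: ThresholdSpec(method="otsu"))
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def subtract_background(channel: np.ndarray, radius: float) -> np.ndarray:
    """Rolling-ball background subtraction, applied per 2D slice.

    A ball of the given pixel radius is rolled under each slice's
    intensity surface; the resulting background estimate is subtracted
    and negative values clipped to 0.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    channel = np.asarray(channel, dtype=np.float64)
    out = np.empty_like(channel)
    for t in range(channel.shape[0]):
        for z in range(channel.shape[1]):
            plane = channel[t, z]
            bg = rolling_ball(plane, radius=radius)
            out[t, z] = np.clip(plane - bg, 0, None)
    return out


def divide_by_background(channel: np.ndarray, sigma: float) -> np.ndarray:
    """Flat-field correction: divide each slice by its Gaussian-blurred copy.

    Bright structures on a slowly varying background map to values > 1
    while the illumination gradient flattens to ~1.  A small epsilon
    guards against division by zero on dark images.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    channel = np.asarray(channel, dtype=np.float64)
    out = np.empty_like(channel)
    for t in range(channel.shape[0]):
        for z in range(channel.shape[1]):
            bg = ndimage.gaussian_filter(channel[t, z], sigma)
            out[t, z] = channel[t, z] / np.maximum(bg, _EPS)
    return out


def smooth_gaussian(channel: np.ndarray, sigma: float) -> np.ndarray:
    """2D Gaussian blur applied to each z-slice independently (no z mixing)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    channel = np.asarray(channel, dtype=np.float64)
    if sigma == 0:
        return channel.copy()
    return ndimage.gaussian_filter(channel, sigma=(0, 0, sigma, sigma))


# ---------------------------------------------------------------------------
# histogram thresholding (ImageJ convention: 256 bins over the data range)
# ---------------------------------------------------------------------------

def histogram_256(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """256-bin histogram over the data range; returns (counts, bin edges)."""
    values = np.asarray(values).ravel()
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        hi = lo + 1.0
    counts, edges = np.histogram(values, bins=256, range=(lo, hi))
    return counts, edges


def _bin_to_threshold(k: int, edges: np.ndarray) -> float:
    """Map cut bin k (last background bin) to an intensity threshold.

    Foreground = intensity >= threshold, so the threshold is the lower
    edge of bin k+1.
    """
    k = int(np.clip(k, 0, 254))
    return float(edges[k + 1])


def _otsu_bin(counts: np.ndarray) -> int:
    p = counts.astype(np.float64)
    total = p.sum()
    if total == 0:
        return 0
    p /= total
    centers = np.arange(counts.size, dtype=np.float64)
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b))


def _isodata_bin(counts: np.ndarray) -> int:
    # iterative intermeans: t = (mean below + mean above)/2 until stable
    centers = np.arange(counts.size, dtype=np.float64)
    c = counts.astype(np.float64)
    nz = np.nonzero(c)[0]
    t = int(round(centers[nz].mean() if nz.size else 0))
    for _ in range(1000):
        below = c[: t + 1]
        above = c[t + 1 :]
        mb = (below * centers[: t + 1]).sum() / below.sum() if below.sum() else centers[0]
        ma = (above * centers[t + 1 :]).sum() / above.sum() if above.sum() else centers[-1]
        t_new = int(np.floor((mb + ma) / 2.0))
        if t_new == t:
            break
        t = t_new
    return t


def _triangle_bin(counts: np.ndarray) -> int:
    c = counts.astype(np.float64)
    nz = np.nonzero(c)[0]
    first, last = nz[0], nz[-1]
    peak = int(np.argmax(c))
    # put the long tail to the right of the peak; flip if needed
    flipped = (peak - first) > (last - peak)
    if flipped:
        c = c[::-1]
        n = c.size
        first, last = n - 1 - last, n - 1 - first
        peak = n - 1 - peak
    # maximise distance from the peak→tail-end line to the histogram
    xs = np.arange(peak, last + 1, dtype=np.float64)
    if xs.size < 2:
        best = peak
    else:
        h_peak = c[peak]
        nx = h_peak
        ny = xs[-1] - peak
        d = np.hypot(nx, ny)
        # perpendicular distance below the peak→tail-end line
        dist = -(nx * (xs - peak) + ny * (c[peak : last + 1] - h_peak)) / d
        best = peak + int(np.argmax(dist))
    if flipped:
        best = counts.size - 1 - best
    return int(best)


def _li_threshold(counts: np.ndarray, edges: np.ndarray) -> float:
    # iterative minimum cross-entropy (Li & Tam) on binned intensities
    centers = 0.5 * (edges[:-1] + edges[1:])
    c = counts.astype(np.float64)
    shift = 0.0
    if centers[0] <= 0:  # log requires positive values
        shift = 1.0 - centers[0]
        centers = centers + shift
    t = (c * centers).sum() / c.sum()
    for _ in range(1000):
        below = centers <= t
        wb, wf = c[below].sum(), c[~below].sum()
        if wb == 0 or wf == 0:
            break
        mb = (c[below] * centers[below]).sum() / wb
        mf = (c[~below] * centers[~below]).sum() / wf
        t_new = (mb - mf) / (np.log(mb) - np.log(mf))
        if abs(t_new - t) < 1e-8:
            t = t_new
            break
        t = t_new
    return float(t - shift)


def _renyi_entropy_bin(counts: np.ndarray) -> int:
    """Renyi-entropy threshold: three entropic thresholds at orders
    1/2, 1, and 2, combined by the closeness-weighted rule of the
    classic entropic-correlation method."""
    p = counts.astype(np.float64)
    total = p.sum()
    p /= total
    P1 = np.cumsum(p)
    P2 = 1.0 - P1
    nz = np.nonzero(counts)[0]
    first, last = int(nz[0]), int(nz[-1])

    def entropic_threshold(alpha: float) -> int:
        best_t, best_h = first, -np.inf
        for t in range(first, last + 1):
            if P1[t] < _EPS or P2[t] < _EPS:
                continue
            pb = p[: t + 1] / P1[t]
            pf = p[t + 1 :] / P2[t]
            pb = pb[pb > 0]
            pf = pf[pf > 0]
            if alpha == 1.0:
                h = -(pb * np.log(pb)).sum() - (pf * np.log(pf)).sum()
            else:
                h = (np.log((pb**alpha).sum()) + np.log((pf**alpha).sum())) / (1.0 - alpha)
            if h > best_h:
                best_h, best_t = h, t
        return best_t

    t1, t2, t3 = sorted(
        (entropic_threshold(0.5), entropic_threshold(1.0), entropic_threshold(2.0))
    )
    if abs(t1 - t2) <= 5:
        beta = (1, 2, 1) if abs(t2 - t3) <= 5 else (0, 1, 3)
    else:
        beta = (3, 1, 0) if abs(t2 - t3) <= 5 else (1, 2, 1)
    omega = P1[t3] - P1[t1]
    t_opt = (
        t1 * (P1[t1] + 0.25 * omega * beta[0])
        + 0.25 * t2 * omega * beta[1]
        + t3 * (P2[t3] + 0.25 * omega * beta[2])
    )
    return int(round(t_opt))


THRESHOLD_METHODS = ("otsu", "triangle", "renyi_entropy", "isodata", "li", "mean")


def auto_threshold(counts: np.ndarray, edges: np.ndarray, method: str) -> float:
    """Compute an intensity threshold from a 256-bin histogram.

    Parameters
    ----------
    counts, edges
        As returned by :func:`histogram_256`.
    method
        One of ``otsu, triangle, renyi_entropy, isodata, li, mean``.

    Returns
    -------
    float
        Threshold on the original intensity scale; foreground is
        ``intensity >= threshold``.
    """
    counts = np.asarray(counts)
    if counts.sum() == 0:
        raise ValueError("histogram must have at least one nonzero bin")
    nz = np.nonzero(counts)[0]
    if nz.size == 1:
        warnings.warn("degenerate single-valued histogram; threshold set to that value")
        return float(0.5 * (edges[nz[0]] + edges[nz[0] + 1]))
    centers = 0.5 * (edges[:-1] + edges[1:])
    if method == "otsu":
        return _bin_to_threshold(_otsu_bin(counts), edges)
    if method == "isodata":
        return _bin_to_threshold(_isodata_bin(counts), edges)
    if method == "triangle":
        return _bin_to_threshold(_triangle_bin(counts), edges)
    if method == "renyi_entropy":
        return _bin_to_threshold(_renyi_entropy_bin(counts), edges)
    if method == "mean":
        return float((counts * centers).sum() / counts.sum())
    if method == "li":
        return _li_threshold(counts, edges)
    raise ValueError(f"unknown threshold method {method!r}")


def auto_threshold_array(values: np.ndarray, method: str) -> float:
    """Convenience: 256-bin histogram of the values, then :func:`auto_threshold`."""
    counts, edges = histogram_256(values)
    return auto_threshold(counts, edges, method)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _thresholds_per_frame(channel: np.ndarray, spec: ThresholdSpec) -> np.ndarray:
    """One threshold per frame according to the spec (shared if global)."""
    nt = channel.shape[0]
    if spec.method == "custom":
        return np.full(nt, float(spec.custom_value))

    def source(frames: np.ndarray) -> np.ndarray:
        if spec.histogram_source == "max_projection":
            return frames.max(axis=1)  # collapse z
        return frames

    if spec.per_timepoint:
        return np.array(
            [auto_threshold_array(source(channel[t : t + 1]), spec.method) for t in range(nt)]
        )
    thr = auto_threshold_array(source(channel), spec.method)
    return np.full(nt, thr)


def segment_threshold(
    channel: np.ndarray, spec: ThresholdSpec, source_channel: int = 0
) -> VoxelMask:
    """Threshold a channel into a foreground mask (``intensity >= threshold``).

    The threshold is derived from the stack histogram or from the
    maximum-intensity-projection histogram; with ``per_timepoint`` each
    frame of a time series receives its own threshold.
    """
    channel = np.asarray(channel)
    thr = _thresholds_per_frame(channel, spec)
    mask = channel >= thr[:, None, None, None]
    return VoxelMask(mask=mask, source_channel=source_channel)


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D structuring element for 6- or 26-connectivity."""
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def segment_hysteresis(
    channel: np.ndarray,
    low: float,
    high: float,
    connectivity: int = 26,
    source_channel: int = 0,
) -> VoxelMask:
    """Two-level hysteresis segmentation in 3D, per timepoint.

    Voxels ``>= high`` seed the foreground; voxels in ``[low, high)`` join
    it when they connect (through voxels ``>= low``, with the chosen
    connectivity) to a seed.
    """
    if low > high:
        raise ValueError("low threshold must be <= high threshold")
    channel = np.asarray(channel)
    structure = connectivity_structure(connectivity)
    out = np.zeros(channel.shape, dtype=bool)
    for t in range(channel.shape[0]):
        weak = channel[t] >= low
        labels, n = ndimage.label(weak, structure=structure)
        if n == 0:
            continue
        seeded = np.unique(labels[channel[t] >= high])
        seeded = seeded[seeded > 0]
        out[t] = np.isin(labels, seeded)
    return VoxelMask(mask=out, source_channel=source_channel)


def _sobel_gradient_magnitude(volume: np.ndarray) -> np.ndarray:
    """Gradient magnitude from separable 3D Sobel kernels (2D when z = 1)."""
    volume = np.asarray(volume, dtype=np.float64)
    axes = (1, 2) if volume.shape[0] == 1 else (0, 1, 2)
    g2 = np.zeros_like(volume)
    for ax in axes:
        g = ndimage.sobel(volume, axis=ax, mode="nearest")
        g2 += g * g
    return np.sqrt(g2)


def segment_canny3d(
    channel: np.ndarray, spec: Canny3DSpec, source_channel: int = 0
) -> VoxelMask:
    """Edge-based segmentation: smooth → 3D Sobel → hysteresis → hole fill.

    Slices are smoothed with a 2D kernel (the z-axis of confocal stacks is
    already blurred by the optics); the hysteresis thresholds are computed
    from the gradient image's own histogram via ``low_spec``/``high_spec``.
    The resulting shell is optionally closed by 3D hole filling, producing
    a segmentation that covers the full object including dim interior or
    unevenly labeled stretches.
    """
    channel = np.asarray(channel, dtype=np.float64)
    smoothed = smooth_gaussian(channel, spec.gaussian_sigma)
    grad = np.stack([_sobel_gradient_magnitude(smoothed[t]) for t in range(channel.shape[0])])
    lows = _thresholds_per_frame(grad, spec.low_spec)
    highs = _thresholds_per_frame(grad, spec.high_spec)
    out = np.zeros(channel.shape, dtype=bool)
    for t in range(channel.shape[0]):
        lo, hi = lows[t], highs[t]
        if lo > hi:
            lo, hi = hi, lo
        out[t] = segment_hysteresis(grad[t : t + 1], lo, hi).mask[0]
    mask = VoxelMask(mask=out, source_channel=source_channel)
    if spec.fill_holes:
        mask = fill_holes_3d(mask)
    return mask


def fill_holes_3d(mask: VoxelMask) -> VoxelMask:
    """Fill background cavities enclosed in all three dimensions, per frame.

    A background component becomes foreground iff it has no 6-connected
    path to the volume border.  Idempotent.
    """
    out = np.empty_like(mask.mask)
    for t in range(mask.mask.shape[0]):
        out[t] = ndimage.binary_fill_holes(mask.mask[t])
    return VoxelMask(mask=out, source_channel=mask.source_channel)


def apply_segmentation(channel: np.ndarray, mask: VoxelMask, mode: str) -> np.ndarray:
    """Render a mask into a channel.

    ``binary``: foreground set to the dtype maximum (255 for uint8, 65535
    for uint16, 1.0 for float), background 0.  ``background_removed``:
    foreground keeps its original intensity, background set to 0.
    """
    channel = np.asarray(channel)
    if channel.shape != mask.mask.shape:
        raise ValueError("channel and mask shapes differ")
    if mode == "binary":
        if np.issubdtype(channel.dtype, np.integer):
            fg_value = np.iinfo(channel.dtype).max
        else:
            fg_value = 1.0
        return np.where(mask.mask, np.asarray(fg_value, dtype=channel.dtype), 0).astype(
            channel.dtype
        )
    if mode == "background_removed":
        return np.where(mask.mask, channel, 0).astype(channel.dtype)
    raise ValueError(f"unknown segmentation mode {mode!r}")
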