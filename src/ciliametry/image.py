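"""Calibrated 5D image container and TIFF I/O.

All pipeline stages operate on a single canonical layout: a 5-axis
intensity array indexed ``(t, z, c, y, x)`` together with the physical
voxel sizes in micrometres.  TIFF files written by common acquisition
software (in particular the ImageJ dialect, which stores axes and the
z-spacing in the image description) are normalised into this layout on
read; missing axes are given length 1, so a single 2D plane becomes a
``(1, 1, 1, y, x)`` stack.

Voxel indices are 0-based; the physical position of a voxel centre is
``(index + 0.5) * voxel_size`` along each axis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = ["CalibratedImage", "read_stack", "write_stack", "max_projection"]


@dataclass
class CalibratedImage:
    """A multi-channel, multi-slice, multi-frame image with voxel calibration.

    Parameters
    ----------
    data
        Intensity array indexed ``(t, z, c, y, x)``; non-negative, finite.
    voxel_width, voxel_height
        Pixel size in µm along x and y.
    voxel_depth
        Slice spacing in µm (meaningful when ``nz > 1``).
    frame_interval
        Seconds between frames; 0 for static images.
    channel_labels
        Optional human-readable channel names.
    """

    data: np.ndarray
    voxel_width: float = 1.0
    voxel_height: float = 1.0
    voxel_depth: float = 1.0
    frame_interval: float = 0.0
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"data must have 5 axes (t, z, c, y, x), got {self.data.ndim}"
            )
        if self.voxel_width <= 0 or self.voxel_height <= 0:
            raise ValueError("voxel_width and voxel_height must be > 0")
        if self.nz > 1 and self.voxel_depth <= 0:
            raise ValueError("voxel_depth must be > 0 for multi-slice stacks")
        if np.issubdtype(self.data.dtype, np.floating):
            if not np.isfinite(self.data).all():
                raise ValueError("intensities must be finite")
            if (self.data < 0).any():
                raise ValueError("intensities must be non-negative")
        if not self.channel_labels:
            self.channel_labels = [f"C{i + 1}" for i in range(self.nc)]

    # -- axis lengths -----------------------------------------------------
    @property
    def nt(self) -> int:
        return self.data.shape[0]

    @property
    def nz(self) -> int:
        return self.data.shape[1]

    @property
    def nc(self) -> int:
        return self.data.shape[2]

    @property
    def ny(self) -> int:
        return self.data.shape[3]

    @property
    def nx(self) -> int:
        return self.data.shape[4]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³ (area in µm² when nz == 1)."""
        if self.nz == 1:
            return self.voxel_width * self.voxel_height
        return self.voxel_width * self.voxel_height * self.voxel_depth

    @property
    def voxel_sizes_zyx(self) -> tuple[float, float, float]:
        return (self.voxel_depth, self.voxel_height, self.voxel_width)

    def channel(self, c: int) -> np.ndarray:
        """View of one channel as a ``(t, z, y, x)`` array."""
        if not 0 <= c < self.nc:
            raise IndexError(f"channel {c} out of range (nc={self.nc})")
        return self.data[:, :, c]

    def with_data(self, data: np.ndarray) -> "CalibratedImage":
        """Copy of this image carrying new pixel data, same calibration."""
        return replace(self, data=np.asarray(data), channel_labels=list(self.channel_labels))


_AXES_CANONICAL = "TZCYX"


def _normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Permute/expand an array with tifffile axis labels into (t,z,c,y,x)."""
    axes = axes.upper().replace("S", "C").replace("Q", "Z").replace("I", "Z")
    if data.ndim != len(axes):
        raise ValueError(f"axes string {axes!r} does not match ndim {data.ndim}")
    for ax in axes:
        if ax not in _AXES_CANONICAL:
            raise ValueError(f"unsupported axis {ax!r} in layout {axes!r}")
    if len(set(axes)) != len(axes):
        raise ValueError(f"duplicate axis in layout {axes!r}")
    for ax in _AXES_CANONICAL:
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in _AXES_CANONICAL]
    return np.transpose(data, order)


def read_stack(path, layout_hint: str | None = None) -> CalibratedImage:
    """Read a TIFF stack into the canonical ``(t, z, c, y, x)`` layout.

    Calibration is taken from ImageJ-style metadata / resolution tags when
    present; otherwise voxel sizes default to 1 µm and a warning is issued.

    Parameters
    ----------
    path
        TIFF file to read.
    layout_hint
        Axis-order string (e.g. ``"ZCYX"``) overriding the file's own axis
        annotation; required for plain TIFFs with ambiguous shapes.
    """
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = layout_hint if layout_hint is not None else series.axes
        if data.ndim > 5:
            raise ValueError(f"unsupported layout with {data.ndim} axes")
        data = _normalize_axes(data, axes)

        voxel_width = voxel_height = voxel_depth = None
        frame_interval = 0.0
        ij = tif.imagej_metadata or {}
        if "spacing" in ij:
            voxel_depth = float(ij["spacing"])
        if "finterval" in ij:
            frame_interval = float(ij["finterval"])
        page = tif.pages[0]
        resunit = page.tags.get("ResolutionUnit")
        # resolution tags are meaningful only with a unit or ImageJ metadata
        # (plain TIFF writers emit a default (1, 1) with unit NONE)
        calibrated_res = bool(ij) or (resunit is not None and int(resunit.value) != 1)
        if calibrated_res:
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            if xres is not None and xres.value[0] != 0:
                voxel_width = xres.value[1] / xres.value[0]
            if yres is not None and yres.value[0] != 0:
                voxel_height = yres.value[1] / yres.value[0]

    if voxel_width is None or voxel_height is None or voxel_depth is None:
        if voxel_width is None and voxel_height is None and voxel_depth is None:
            msg = f"{path}: no calibration metadata found; defaulting voxel sizes to 1 µm"
            warnings.warn(msg, stacklevel=2)
            logger.warning(msg)
        voxel_width = 1.0 if voxel_width is None else voxel_width
        voxel_height = 1.0 if voxel_height is None else voxel_height
        voxel_depth = 1.0 if voxel_depth is None else voxel_depth

    return CalibratedImage(
        data=data,
        voxel_width=voxel_width,
        voxel_height=voxel_height,
        voxel_depth=voxel_depth,
        frame_interval=frame_interval,
    )


def write_stack(image: CalibratedImage, path) -> None:
    """Write a :class:`CalibratedImage` as an ImageJ-dialect TIFF.

    ``read_stack(write_stack(x))`` reproduces data, axis lengths and
    calibration (uint8/uint16/float32 data).
    """
    data = image.data
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    metadata = {
        "axes": "TZCYX",
        "spacing": image.voxel_depth,
        "unit": "um",
        "finterval": image.frame_interval,
    }
    tifffile.imwrite(
        str(path),
        data,
        imagej=True,
        resolution=(1.0 / image.voxel_width, 1.0 / image.voxel_height),
        metadata=metadata,
    )


def max_projection(image: CalibratedImage, channel: int) -> CalibratedImage:
    """Maximum-intensity projection over z of one channel, per timepoint.

    Returns a single-channel image with ``nz == 1``; calibration carries over.
    """
    if not 0 <= channel < image.nc:
        raise IndexError(f"channel {channel} out of range (nc={image.nc})")
    proj = image.data[:, :, channel].max(axis=1)  # (t, y, x)
    data = proj[:, np.newaxis, np.newaxis]  # (t, 1, 1, y, x)
    return CalibratedImage(
        data=data,
        voxel_width=image.voxel_width,
        voxel_height=image.voxel_height,
        voxel_depth=image.voxel_depth,
        frame_interval=image.frame_interval,
        channel_labels=[image.channel_labels[channel]],
    )
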