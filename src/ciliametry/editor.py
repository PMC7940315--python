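"""Scripted, fully logged correction of a segmented channel.

Interactive correction of segmentation errors is replaced by a replayable
edit log: each edit is a 2D region of interest (polygon or rectangle)
applied over a z-range at one timepoint, either removing voxels (set to 0)
or adding them (set to the dtype maximum in binary images, or to the raw
channel's intensity in background-removed images).  Replaying the stored
records on the original segmented channel reproduces the edited channel
exactly, which makes every manual correction auditable.

Rasterization rule: a pixel belongs to a polygon iff its center lies
inside (even-odd rule); vertices are (x, y) pixel coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath

__all__ = ["EditRecord", "apply_edit", "replay_edits", "save_edits", "load_edits"]


@dataclass
class EditRecord:
    """One logged add/remove operation on the segmented channel."""

    index: int
    action: str  # "add" | "remove"
    roi: list[tuple[float, float]]  # polygon vertices (x, y), pixel coords
    z_range: tuple[int, int]  # inclusive slice range
    t_index: int = 0

    def __post_init__(self) -> None:
        if self.action not in ("add", "remove"):
            raise ValueError(f"unknown edit action {self.action!r}")
        if len(self.roi) < 3:
            raise ValueError("roi polygon needs at least 3 vertices")
        self.roi = [(float(x), float(y)) for x, y in self.roi]
        self.z_range = (int(self.z_range[0]), int(self.z_range[1]))

    @classmethod
    def rectangle(
        cls,
        index: int,
        action: str,
        x0: float,
        y0: float,
        width: float,
        height: float,
        z_range: tuple[int, int],
        t_index: int = 0,
    ) -> "EditRecord":
        roi = [(x0, y0), (x0 + width, y0), (x0 + width, y0 + height), (x0, y0 + height)]
        return cls(index=index, action=action, roi=roi, z_range=z_range, t_index=t_index)


def _rasterize(roi: list[tuple[float, float]], shape_yx: tuple[int, int]) -> np.ndarray:
    """Boolean (y, x) mask of pixels whose centers fall inside the polygon."""
    ny, nx = shape_yx
    xs = np.array([p[0] for p in roi])
    ys = np.array([p[1] for p in roi])
    x_lo = max(int(np.floor(xs.min())), 0)
    x_hi = min(int(np.ceil(xs.max())) + 1, nx)
    y_lo = max(int(np.floor(ys.min())), 0)
    y_hi = min(int(np.ceil(ys.max())) + 1, ny)
    out = np.zeros(shape_yx, dtype=bool)
    if x_hi <= x_lo or y_hi <= y_lo:
        return out
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    centers = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])
    inside = MplPath(np.column_stack([xs, ys])).contains_points(centers)
    out[y_lo:y_hi, x_lo:x_hi] = inside.reshape(y_hi - y_lo, x_hi - x_lo)
    return out


def apply_edit(
    segmented: np.ndarray,
    record: EditRecord,
    source: np.ndarray | None = None,
    mode: str = "binary",
) -> np.ndarray:
    """Apply one edit record to a segmented ``(t, z, y, x)`` channel.

    ``remove`` zeroes all voxels inside the ROI over the record's z-range
    and frame.  ``add`` sets them to the dtype maximum (binary mode) or to
    the raw ``source`` channel's intensities (background-removed mode).
    """
    segmented = np.asarray(segmented)
    if mode == "background_removed" and record.action == "add" and source is None:
        raise ValueError(
            "add in background-removed mode requires the unsegmented source channel"
        )
    out = segmented.copy()
    region = _rasterize(record.roi, segmented.shape[2:])
    z0, z1 = record.z_range
    t = record.t_index
    for z in range(z0, z1 + 1):
        if record.action == "remove":
            out[t, z][region] = 0
        else:
            if mode == "binary":
                if np.issubdtype(out.dtype, np.integer):
                    out[t, z][region] = np.iinfo(out.dtype).max
                else:
                    out[t, z][region] = 1.0
            else:
                out[t, z][region] = source[t, z][region]
    return out


def replay_edits(
    segmented: np.ndarray,
    records: list[EditRecord],
    source: np.ndarray | None = None,
    mode: str = "binary",
) -> np.ndarray:
    """Apply an ordered list of edit records sequentially.

    Records must be sorted by their ``index`` field; replay is
    deterministic, so the same original channel and log always yield a
    byte-identical edited channel.
    """
    indices = [r.index for r in records]
    if indices != sorted(indices):
        raise ValueError("edit records must be ordered by index")
    out = np.asarray(segmented).copy()
    for record in records:
        out = apply_edit(out, record, source=source, mode=mode)
    return out


def save_edits(records: list[EditRecord], path) -> None:
    """Serialize edit records as JSON (sidecar log of an edited image)."""
    payload = [
        {
            "index": r.index,
            "action": r.action,
            "roi": [[x, y] for x, y in r.roi],
            "z_range": list(r.z_range),
            "t_index": r.t_index,
        }
        for r in records
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_edits(path) -> list[EditRecord]:
    payload = json.loads(Path(path).read_text())
    return [
        EditRecord(
            index=item["index"],
            action=item["action"],
            roi=[tuple(v) for v in item["roi"]],
            z_range=tuple(item["z_range"]),
            t_index=item.get("t_index", 0),
        )
        for item in payload
    ]
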