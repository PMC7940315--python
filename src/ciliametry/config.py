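"""Run configuration: channel roles, per-stage settings, settings logs.

A run is described by a single human-readable YAML file.  Channel roles
(reconstruction / intensity A / intensity B / basal stain) must be
disjoint and exactly one reconstruction channel is required.  Every
processing run writes a plain-text ``key=value`` settings log next to its
outputs; the log can be re-loaded to reproduce the run with identical
preferences.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = [
    "SegmentationSettings",
    "ChannelRoles",
    "ReconstructionSettings",
    "SkeletonSettings",
    "RunConfig",
    "load_config",
    "save_config",
    "save_settings_log",
    "load_settings_log",
]


@dataclass
class SegmentationSettings:
    """Preprocessing and segmentation choices for one channel."""

    method: str = "renyi_entropy"  # threshold method | "custom" | "hysteresis" | "canny3d"
    custom_value: float | None = None
    low_threshold: float | None = None  # hysteresis
    high_threshold: float | None = None
    histogram_source: str = "max_projection"
    per_timepoint: bool = False
    subtract_background_radius: float | None = None  # px
    divide_by_background_sigma: float | None = None  # px
    smooth_sigma: float | None = None  # px
    canny_gaussian_sigma: float = 1.0
    canny_low_method: str = "triangle"
    canny_high_method: str = "otsu"
    fill_holes: bool = True
    connectivity: int = 26
    mode: str = "background_removed"  # or "binary"
    include_unsegmented_copy: bool = True


@dataclass
class ChannelRoles:
    reconstruction: int = 0
    intensity_a: int | None = None
    intensity_b: int | None = None
    basal: int | None = None

    def validate(self) -> None:
        used = [
            ("reconstruction", self.reconstruction),
            ("intensity_a", self.intensity_a),
            ("intensity_b", self.intensity_b),
            ("basal", self.basal),
        ]
        if self.reconstruction is None:
            raise ValueError("config error: a reconstruction channel is required")
        seen: dict[int, str] = {}
        for name, idx in used:
            if idx is None:
                continue
            if idx in seen:
                raise ValueError(
                    f"config error: channel roles must be disjoint; channel {idx} "
                    f"assigned to both {seen[idx]} and {name}"
                )
            seen[idx] = name


@dataclass
class ReconstructionSettings:
    variant: str = "straight"  # or "straight_diagonal"
    min_cilium_size: int = 10  # voxels
    exclude_border_axes: list[str] = field(default_factory=list)
    min_intensity_region_size: int = 1
    intensity_variant: str = "straight"
    a_is_segmented: bool = False
    b_is_segmented: bool = False


@dataclass
class SkeletonSettings:
    sigma_xy: float = 1.0  # px, original scale
    sigma_z: float = 0.0
    tangent_delta_um: float = 1.0


@dataclass
class RunConfig:
    files: list[str] = field(default_factory=list)
    output_dir: str = "."
    channels: ChannelRoles = field(default_factory=ChannelRoles)
    segmentation: dict[str, SegmentationSettings] = field(
        default_factory=lambda: {"reconstruction": SegmentationSettings()}
    )
    reconstruction: ReconstructionSettings = field(default_factory=ReconstructionSettings)
    skeleton: SkeletonSettings = field(default_factory=SkeletonSettings)

    def validate(self) -> None:
        self.channels.validate()
        for role in self.segmentation:
            if role not in ("reconstruction", "intensity_a", "intensity_b"):
                raise ValueError(f"config error: unknown segmentation role {role!r}")
        if self.reconstruction.variant not in ("straight", "straight_diagonal"):
            raise ValueError(
                f"config error: unknown variant {self.reconstruction.variant!r}"
            )


def _build_dataclass(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"config error: unknown key(s) in {context}: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw)
    known_top = {"files", "output_dir", "channels", "segmentation", "reconstruction", "skeleton"}
    unknown = set(raw) - known_top
    if unknown:
        raise ValueError(f"config error: unknown top-level key(s): {sorted(unknown)}")
    channels = _build_dataclass(ChannelRoles, raw.get("channels", {}), "channels")
    seg = {
        role: _build_dataclass(SegmentationSettings, settings or {}, f"segmentation.{role}")
        for role, settings in raw.get("segmentation", {"reconstruction": {}}).items()
    }
    cfg = RunConfig(
        files=list(raw.get("files", [])),
        output_dir=raw.get("output_dir", "."),
        channels=channels,
        segmentation=seg,
        reconstruction=_build_dataclass(
            ReconstructionSettings, raw.get("reconstruction", {}), "reconstruction"
        ),
        skeleton=_build_dataclass(SkeletonSettings, raw.get("skeleton", {}), "skeleton"),
    )
    cfg.validate()
    return cfg


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))


def _flatten(prefix: str, obj) -> list[tuple[str, object]]:
    if isinstance(obj, dict):
        items = []
        for k, v in obj.items():
            items.extend(_flatten(f"{prefix}.{k}" if prefix else str(k), v))
        return items
    return [(prefix, obj)]


def save_settings_log(config: RunConfig, path) -> None:
    """Write the full configuration as a plain-text key=value log."""
    # first line only: the flow-style scalar (drops yaml's "..." end marker)
    lines = [
        f"{key}={yaml.safe_dump(value, default_flow_style=True).splitlines()[0]}"
        for key, value in _flatten("", asdict(config))
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_settings_log(path) -> RunConfig:
    """Re-load a settings log, reproducing the configuration it records."""
    raw: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        parts = key.split(".")
        node = raw
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = yaml.safe_load(value)
    # lists flattened with numeric keys are not produced for this schema
    # except `files` and `exclude_border_axes`, handled by yaml inline dumps
    return config_from_dict(raw)
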