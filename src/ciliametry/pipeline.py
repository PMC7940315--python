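"""End-to-end orchestration: batch segmentation and quantification.

``prepare_image`` applies the configured preprocessing and segmentation
to each channel with a role, rendering the result into the channel
(binary or background-removed) and optionally appending an untouched
copy.  ``quantify_image`` runs reconstruction (labeling → size filter →
border filter → 4D linking), centerline extraction and the full
parameter set, returning one wide table (row = cilium × timepoint) plus
long-format tables for profiles, tangents and curvature.  The batch
entry points process file lists under identical settings, isolate
per-file failures, and write a reloadable settings log next to every
output.
"""

from __future__ import annotations

import logging
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import quantify as q
from .config import RunConfig, save_settings_log
from .image import CalibratedImage, read_stack, write_stack
from .preparator import (
    Canny3DSpec,
    ThresholdSpec,
    VoxelMask,
    apply_segmentation,
    divide_by_background,
    segment_canny3d,
    segment_hysteresis,
    segment_threshold,
    smooth_gaussian,
    subtract_background,
)
from .reconstruct import (
    CiliumObject,
    clean_intensity_channel,
    exclude_border,
    filter_small,
    link_time,
    objects_to_mask,
)
from .skeleton import extract_centerline

logger = logging.getLogger(__name__)

__all__ = ["prepare_image", "quantify_image", "run_preparator", "run_quantify"]


def _segment_channel(channel: np.ndarray, settings, source_channel: int) -> VoxelMask:
    s = settings
    work = np.asarray(channel, dtype=np.float64)
    if s.subtract_background_radius:
        work = subtract_background(work, s.subtract_background_radius)
    if s.divide_by_background_sigma:
        work = divide_by_background(work, s.divide_by_background_sigma)
    if s.smooth_sigma:
        work = smooth_gaussian(work, s.smooth_sigma)

    if s.method == "hysteresis":
        if s.low_threshold is None or s.high_threshold is None:
            raise ValueError("hysteresis segmentation requires low_threshold and high_threshold")
        return segment_hysteresis(
            work, s.low_threshold, s.high_threshold, s.connectivity, source_channel
        )
    if s.method == "canny3d":
        spec = Canny3DSpec(
            gaussian_sigma=s.canny_gaussian_sigma,
            low_spec=ThresholdSpec(
                method=s.canny_low_method,
                histogram_source=s.histogram_source,
                per_timepoint=s.per_timepoint,
            ),
            high_spec=ThresholdSpec(
                method=s.canny_high_method,
                histogram_source=s.histogram_source,
                per_timepoint=s.per_timepoint,
            ),
            fill_holes=s.fill_holes,
        )
        return segment_canny3d(work, spec, source_channel)
    spec = ThresholdSpec(
        method=s.method,
        custom_value=s.custom_value,
        histogram_source=s.histogram_source,
        per_timepoint=s.per_timepoint,
    )
    return segment_threshold(work, spec, source_channel)


def prepare_image(image: CalibratedImage, config: RunConfig) -> CalibratedImage:
    """Segment the configured channels of one image.

    Each role listed in ``config.segmentation`` is processed and its
    channel replaced by the binary / background-removed rendering; with
    ``include_unsegmented_copy`` the original channel is appended after
    all existing channels, preserving raw intensities for later edits
    and intensity measurements.
    """
    config.validate()
    data = image.data.astype(np.float32).copy()
    appended = []
    appended_labels = []
    for role, settings in config.segmentation.items():
        c = getattr(config.channels, role)
        if c is None:
            continue
        channel = image.channel(c)
        mask = _segment_channel(channel, settings, c)
        rendered = apply_segmentation(
            channel.astype(np.float32), mask, settings.mode
        )
        data[:, :, c] = rendered
        if settings.include_unsegmented_copy:
            appended.append(image.channel(c).astype(np.float32))
            appended_labels.append(image.channel_labels[c] + "_raw")
    if appended:
        extra = np.stack(appended, axis=2)
        data = np.concatenate([data, extra], axis=2)
    out = CalibratedImage(
        data=data,
        voxel_width=image.voxel_width,
        voxel_height=image.voxel_height,
        voxel_depth=image.voxel_depth,
        frame_interval=image.frame_interval,
        channel_labels=list(image.channel_labels) + appended_labels,
    )
    return out


def _basal_centroid(
    image: CalibratedImage, basal_channel: int, cilium: CiliumObject, t: int
) -> np.ndarray | None:
    """Position (µm) of the brightest basal-stain voxel near the cilium."""
    ch = image.channel(basal_channel)[t]
    vox = cilium.voxels_at(t)
    pad_xy = max(2, int(round(1.0 / image.voxel_width)))
    pad_z = 2
    lo = np.maximum(vox.min(axis=0) - (pad_z, pad_xy, pad_xy), 0)
    hi = np.minimum(vox.max(axis=0) + (pad_z, pad_xy, pad_xy), np.array(ch.shape) - 1)
    sub = ch[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    if sub.size == 0 or sub.max() <= 0:
        return None
    zyx = np.array(np.unravel_index(int(np.argmax(sub)), sub.shape)) + lo
    sizes = np.array([image.voxel_width, image.voxel_height, image.voxel_depth])
    return (np.asarray(zyx)[::-1] + 0.5) * sizes


def quantify_image(
    image: CalibratedImage, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Reconstruct, skeletonize and quantify all cilia in one image.

    Returns ``(results, profiles, resampled, counts)``: the wide per-
    cilium table, the long per-centerline-point table (arc length,
    position, per-channel profile, tangent, signed curvature), the
    voxel-width-resampled profiles, and the excluded-object counts.
    """
    config.validate()
    roles = config.channels
    rs = config.reconstruction
    recon = image.channel(roles.reconstruction)
    mask = VoxelMask(mask=recon > 0, source_channel=roles.reconstruction)

    objects = link_time(mask, rs.variant)
    n_total = len(objects)
    objects = filter_small(objects, rs.min_cilium_size)
    n_small = n_total - len(objects)
    all_cilia = objects_to_mask(objects, mask.mask.shape) if objects else VoxelMask(
        mask=np.zeros_like(mask.mask)
    )
    n_border = 0
    if rs.exclude_border_axes:
        objects, n_border = exclude_border(objects, rs.exclude_border_axes)
    counts = {"detected": n_total, "excluded_size": n_small, "excluded_border": n_border}

    # intensity channels; optional speckle cleanup for segmented A/B
    channels: dict[str, np.ndarray] = {"reconstruction": recon}
    segmented_flags = {"A": rs.a_is_segmented, "B": rs.b_is_segmented}
    for label, idx, seg in (
        ("A", roles.intensity_a, rs.a_is_segmented),
        ("B", roles.intensity_b, rs.b_is_segmented),
    ):
        if idx is None:
            continue
        ch = image.channel(idx).astype(np.float64)
        if seg and rs.min_intensity_region_size > 1:
            m = clean_intensity_channel(
                VoxelMask(mask=ch > 0, source_channel=idx),
                rs.min_intensity_region_size,
                rs.intensity_variant,
            )
            ch = np.where(m.mask, ch, 0.0)
        channels[label] = ch

    # soma-derived thresholds per intensity channel and timepoint
    bg_thresholds: dict[tuple[str, int], float | None] = {}
    for label in ("A", "B"):
        if label in channels:
            for t in range(image.nt):
                bg_thresholds[(label, t)] = q.background_threshold(
                    channels[label], all_cilia.mask, t
                )

    rows = []
    profile_rows = []
    resampled_rows = []
    delta = config.skeleton.tangent_delta_um
    for obj in objects:
        for t in obj.timepoints:
            flags: list[str] = []
            row: dict = {"ID": obj.id, "Time point": t}
            morph = q.morphology_params(obj, image, t)
            row.update(
                {
                    "x center [µm]": morph["center_um"][0],
                    "y center [µm]": morph["center_um"][1],
                    "z center [µm]": morph["center_um"][2],
                    "Volume [voxel]": morph["n_voxels"],
                    "Volume [µm³]": morph["volume_um3"],
                    "# Surface voxels": morph["n_surface_voxels"],
                    "Surface [µm²]": morph["surface_um2"],
                    "Shape complexity index": morph["shape_complexity_index"],
                    "Sphere radius [µm]": morph["sphere_radius_um"],
                }
            )
            for label, ch in channels.items():
                vals = ch[t][tuple(obj.voxels_at(t).T)]
                stats = q.intensity_params(vals)
                suffix = (
                    "(reconstruction channel)" if label == "reconstruction" else f"(channel {label})"
                )
                row[f"Minimum intensity {suffix}"] = stats["min"]
                row[f"Maximum intensity {suffix}"] = stats["max"]
                row[f"Average intensity {suffix}"] = stats["mean"]
                row[f"Average intensity of the 10% of voxels with highest intensity {suffix}"] = (
                    stats["top10_mean"]
                )
                row[f"SD of intensity {suffix}"] = stats["sd"]
            for label in ("A", "B"):
                if label not in channels:
                    continue
                if segmented_flags[label]:
                    um3, pct = q.colocalized_volume(
                        obj, channels[label], t, image.voxel_volume
                    )
                    row[f"{label}: Colocalized volume [µm³]"] = um3
                    row[f"{label}: Colocalized volume [% of total volume]"] = pct
                thr = bg_thresholds[(label, t)]
                row[f"Intensity threshold {label}"] = thr
                if thr is None:
                    flags.append(f"undefined_bg_threshold_{label}")
                else:
                    um3, pct = q.colocalized_vs_bg_volume(
                        obj, channels[label], thr, t, image.voxel_volume
                    )
                    row[f"{label}: Colocalized compared to BG volume [µm³]"] = um3
                    row[f"{label}: Colocalized compared to BG volume [% of total volume]"] = pct

            basal = None
            if roles.basal is not None:
                basal = _basal_centroid(image, roles.basal, obj, t)
            graph, path = extract_centerline(
                obj,
                image,
                t,
                sigma_xy=config.skeleton.sigma_xy,
                sigma_z=config.skeleton.sigma_z,
                basal_centroid=basal,
            )
            row["# of found skeletons"] = graph.n_skeletons
            row["# branches"] = graph.n_branches
            row["Tree length [µm]"] = graph.tree_length
            flags.extend(graph.flags)
            if path is not None and path.n_points >= 2:
                vector, bending = q.orientation_and_bending(path)
                row["Cilia length [µm]"] = path.length
                row["Orientation vector x [µm]"] = vector[0]
                row["Orientation vector y [µm]"] = vector[1]
                row["Orientation vector z [µm]"] = vector[2]
                row["Cilia bending index"] = bending
                flags.extend(path.flags)

                tans = q.tangents(path, delta)
                curv = q.signed_curvature(path, delta)
                raw_profiles = {}
                for label in ("A", "B"):
                    if label not in channels:
                        continue
                    raw = q.profile(path, channels[label], image, t)
                    raw_profiles[label] = raw
                    integ, mean = q.centerline_intensity(raw)
                    row[f"Integrated {label} intensity"] = integ
                    row[f"Average {label} intensity on centerline"] = mean
                    thr = bg_thresholds[(label, t)]
                    if thr is not None:
                        um, pct = q.colocalized_vs_bg_length(raw, path.arc_length, thr)
                        row[
                            f"{label}: Colocalized on centerline compared to BG volume [µm]"
                        ] = um
                        row[
                            f"{label}: Colocalized on centerline compared to BG volume"
                            " [% total length]"
                        ] = pct
                    res = q.resample_profile(raw, path.arc_length, image.voxel_width)
                    for k, v in enumerate(res):
                        resampled_rows.append(
                            {
                                "ID": obj.id,
                                "Time point": t,
                                "Channel": label,
                                "Step": k,
                                "Arc length [µm]": k * image.voxel_width,
                                "Profile": v,
                            }
                        )
                for i in range(path.n_points):
                    prow = {
                        "ID": obj.id,
                        "Time point": t,
                        "Point": i,
                        "Arc length [µm]": path.arc_length[i],
                        "x [µm]": path.points[i, 0],
                        "y [µm]": path.points[i, 1],
                        "z [µm]": path.points[i, 2],
                        "Tangent vector x": tans[i, 0],
                        "Tangent vector y": tans[i, 1],
                        "Tangent vector z": tans[i, 2],
                        "Signed 3D Curvature [1/µm]": curv[i],
                    }
                    for label, raw in raw_profiles.items():
                        prow[f"Profile {label}"] = raw[i]
                    profile_rows.append(prow)
            else:
                flags.append("no_centerline")
            row["Flags"] = ";".join(flags)
            rows.append(row)

    results = pd.DataFrame(rows)
    profiles = pd.DataFrame(profile_rows)
    resampled = pd.DataFrame(resampled_rows)
    return results, profiles, resampled, counts


# ---------------------------------------------------------------------------
# batch entry points
# ---------------------------------------------------------------------------

def _out_base(path: Path, output_dir: Path) -> Path:
    return output_dir / path.stem


def run_preparator(files: list[str], config: RunConfig) -> list[dict]:
    """Segment a batch of files under identical settings.

    Writes ``<name>_CQP.tif`` and ``<name>_CQP_settings.txt`` per input;
    a failing file does not stop the batch.
    """
    config.validate()
    output_dir = Path(config.output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    summary = []
    for f in files:
        entry = {"file": str(f), "status": "ok", "error": None}
        try:
            image = read_stack(f)
            out = prepare_image(image, config)
            base = _out_base(Path(f), output_dir)
            write_stack(out, f"{base}_CQP.tif")
            save_settings_log(config, f"{base}_CQP_settings.txt")
            entry["output"] = f"{base}_CQP.tif"
        except Exception as exc:  # per-file isolation
            logger.error("failed to prepare %s: %s", f, exc)
            entry.update(status="failed", error=f"{exc}\n{traceback.format_exc()}")
        summary.append(entry)
    return summary


def run_quantify(files: list[str], config: RunConfig) -> list[dict]:
    """Quantify a batch of segmented (and optionally edited) images.

    Per input, writes the wide results table, the long profile table,
    the resampled profiles, a TIFF mask of the objects surviving all
    filters, and the settings log.
    """
    config.validate()
    output_dir = Path(config.output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    summary = []
    for f in files:
        entry = {"file": str(f), "status": "ok", "error": None}
        try:
            image = read_stack(f)
            results, profiles, resampled, counts = quantify_image(image, config)
            base = _out_base(Path(f), output_dir)
            results.to_csv(f"{base}_results.tsv", sep="\t", index=False)
            profiles.to_csv(f"{base}_profiles.tsv", sep="\t", index=False)
            resampled.to_csv(f"{base}_resampled_profiles.tsv", sep="\t", index=False)
            save_settings_log(config, f"{base}_CQ_settings.txt")
            # filtered image: objects surviving all filters, as a mask
            recon = image.channel(config.channels.reconstruction)
            mask = VoxelMask(mask=recon > 0)
            objs = link_time(mask, config.reconstruction.variant)
            objs = filter_small(objs, config.reconstruction.min_cilium_size)
            if config.reconstruction.exclude_border_axes:
                objs, _ = exclude_border(objs, config.reconstruction.exclude_border_axes)
            filtered = objects_to_mask(objs, mask.mask.shape).mask.astype(np.uint8) * 255
            write_stack(
                image.with_data(filtered[:, :, np.newaxis]), f"{base}_filtered.tif"
            )
            entry.update(counts=counts, results=f"{base}_results.tsv", n_cilia=len(results))
        except Exception as exc:
            logger.error("failed to quantify %s: %s", f, exc)
            entry.update(status="failed", error=f"{exc}\n{traceback.format_exc()}")
        summary.append(entry)
    return summary
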