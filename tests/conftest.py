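"""Shared fixtures: phantom scenes generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from ciliametry.config import RunConfig, SegmentationSettings
from ciliametry.pipeline import prepare_image, quantify_image
from ciliametry.synthetic import PhantomSpec, make_scene

CAL = (0.1, 0.1, 0.5)  # µm (width, height, depth)


def basic_config(method: str = "otsu", **recon_kwargs) -> RunConfig:
    cfg = RunConfig()
    cfg.segmentation["reconstruction"] = SegmentationSettings(
        method=method, include_unsegmented_copy=False
    )
    for k, v in recon_kwargs.items():
        setattr(cfg.reconstruction, k, v)
    return cfg


@pytest.fixture(scope="session")
def straight_tube_scene():
    """One in-plane 7 µm tube; segmented image + ground truth."""
    specs = [PhantomSpec(kind="line", start=(2.0, 5.0, 4.0), end=(9.0, 5.0, 4.0))]
    image, truth, gt_masks = make_scene(specs, (16, 128, 128), CAL, seed=11)
    seg = prepare_image(image, basic_config())
    return {"image": image, "segmented": seg, "truth": truth, "gt_masks": gt_masks}


@pytest.fixture(scope="session")
def tilted_tube_scene():
    """10 µm tube tilted 45° out of plane (x–z), anisotropic voxels."""
    c = 10.0 / np.sqrt(2.0)
    specs = [PhantomSpec(kind="line", start=(2.0, 6.0, 1.0), end=(2.0 + c, 6.0, 1.0 + c))]
    image, truth, gt_masks = make_scene(specs, (20, 120, 110), CAL, seed=7)
    seg = prepare_image(image, basic_config())
    return {"image": image, "segmented": seg, "truth": truth, "gt_masks": gt_masks}


@pytest.fixture(scope="session")
def arc_scene():
    """Semicircular tube, radius 5 µm, in the xy-plane."""
    specs = [PhantomSpec(kind="arc", radius=5.0, angle_span=np.pi, offset=(7.0, 2.5, 1.25))]
    image, truth, gt_masks = make_scene(specs, (5, 95, 140), CAL, seed=3)
    seg = prepare_image(image, basic_config())
    return {"image": image, "segmented": seg, "truth": truth, "gt_masks": gt_masks}


@pytest.fixture(scope="session")
def quantified_tilted(tilted_tube_scene):
    cfg = basic_config()
    results, profiles, resampled, counts = quantify_image(
        tilted_tube_scene["segmented"], cfg
    )
    return {"results": results, "profiles": profiles, "counts": counts, "config": cfg}
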